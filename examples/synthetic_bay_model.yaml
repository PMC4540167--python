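# Synthetic stand-in for a coastal-monitoring model specification: an
# anisotropic Matérn-5/2 field on a masked 21x21 grid.  The parameter values
# are representative placeholders chosen for a plausible nutrient field, not
# fitted to any dataset.
kernel:
  family: matern
  phi: 0.25
  kappa: 2.5
  anisotropy:
    angle: 0.52      # radians
    ratio: 2.0
sigma2: 1.0
trend: linear
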