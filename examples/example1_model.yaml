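# Worked-example model: constant trend, unit process variance,
# isotropic exponential correlation exp(-7 * h) on [0,1]^2.
kernel:
  family: exponential
  nu: 7.0
sigma2: 1.0
trend: constant
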