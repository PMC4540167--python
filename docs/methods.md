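# Methods

## Model and criteria

The field is `Y(x) = f(x)'β + ε(x)` with `f` a constant or linear polynomial
basis (`p = 1` or `3` in 2-d) and `ε` a zero-mean Gaussian process with
covariance `σ² c(x,x′;ν)`.  Supported kernels:

* exponential, `c(h) = exp(−ν h)`, `ν > 0` an inverse range;
* Matérn in the geoR parametrization
  `c(h) = (2^{κ−1}Γ(κ))⁻¹ (h/φ)^κ K_κ(h/φ)`, with the closed form
  `(1 + u + u²/3)e^{−u}`, `u = h/φ`, used when `κ = 5/2`;
* optional geometric anisotropy: rotate coordinates by `ψ_A`, stretch the
  second rotated coordinate by `ψ_R ≥ 1` (geoR `coords.aniso` convention),
  then measure Euclidean distance.

Universal-kriging weights and normalized variance come from the standard
closed forms with `A = C⁻¹`, `G = F'AF`:
`w = Ab + AFG⁻¹(f − F'Ab)` and `ρ² = 1 − b'Ab + h'G⁻¹h`.  Weight derivatives
`∂w/∂ν_k` are obtained by implicit differentiation of that closed form;
kernel derivatives are analytic for the exponential rate and the Matérn-5/2
range (`∂c/∂φ = u²(1+u)e^{−u}/(3φ)`) and central finite differences
(relative step `1e−5`, floor `1e−8`, step halved at a domain boundary) for
any other parameter.  The test suite checks the analytic derivatives against
finite differences to `1e−6` and the differentiated unbiasedness constraint
`(∂w/∂ν)'F = 0` to `1e−8`.

Fisher information splits into `M_β = (1/σ²)F'AF` and
`M_ν[k,l] = ½tr(S_k S_l)`, `S_k = A ∂C/∂ν_k`, with `t_k = tr(S_k)`.  The
covariance of the estimator of `ν` defaults to the full Schur-complement
block of the inverse joint information,

```
V_ν = (M_ν − t t′ / (2n))⁻¹,
```

which is identical for every `σ²`; a `sigma2_known=True` flag switches to
`M_ν⁻¹`.  The default was pinned because it reproduces the worked example's
reference `M_EK` value to all printed digits (`1.9124` vs `1.9097` for the
known-`σ²` form); every result object records the flag.

The corrected variance is `ek(x) = σ²[ρ²(x) + tr(V_ν W(x))]` with
`W(x)ₖₗ = (∂w/∂ν_k)'C(∂w/∂ν_l)`; it is `≥ σ²ρ²(x)` everywhere and `0`
exactly at design sites.  `M_EK` maximises `ek` over the prediction set
(default: the full candidate set); ties take the first site in row order.
The compound surrogate is the unnormalized convex combination
`J_α = α·log det M_β + (1−α)·log det M_ν` — any strictly monotone
combination produces Pareto points, and for the shipped examples
`p = s = 1` makes normalization immaterial.

## Dominance, ties and the convex hull

Candidate sets with symmetries (a square grid with a symmetric design)
produce *exactly* tied criterion pairs: designs congruent under rotation /
transposition of the grid.  Float arithmetic separates such ties at the
`1e−15` level, which would make non-dominated counts an accident of
rounding.  All dominance and hull operations therefore snap coordinates to
an absolute tolerance (`1e−10` by default) before comparing: weak dominance
with one strict inequality, exact ties mutually non-dominating and all
retained.  The hull operation flags the strict upper-right convex hull of
the distinct criterion points (collinear interior points excluded; a flag
includes them) and maps the flags back to all tied duplicates.

In the worked example the symmetry orbits have size ~4, so counts of
non-dominated *designs* are multiples of small orbit sizes (302 designs over
80 distinct points at the first exchange scan).  Externally reported counts of the
same quantities are sensitive to how an implementation's rounding happens to
break these ties; the exact-arithmetic convention used here is the stable
one, and the per-scan trace records designs, distinct points and hull points
separately so either view is available.

## Search algorithms

**Local search** scans design slots in order; each slot is tentatively
replaced by each rook (N/S/E/W) neighbour of its current occupant, keeping
any strict improvement immediately, and repeats until a full pass makes no
improvement.  The returned design admits no improving single rook move.

**Simulated annealing** (maximising `J_α`): uniform-random or supplied
initial design; each iteration replaces two random sites by two uniform
draws from the candidate set, locally optimises the candidate, tracks the
best solution, accepts worse moves with Metropolis probability
`exp(Δ/T)`, and cools geometrically (`T ← rT`) whenever the state did not
change.  Defaults `T0 = 0.6`, `r = 0.93`, `Nmax = 5000` are the settings of
the worked example.  The inner loop (roughly `10⁶` small-matrix criterion
evaluations per run) is JIT-compiled over a precomputed per-candidate-set
tableau of correlations, derivatives and trend values; the JIT path is
asserted equal to the plain numpy implementation in the tests.

**Pareto sampling** runs one annealing pass per value of an `α`-grid
(default 11 values in `[0.5, 1]`, the interval where the compound criterion
is meaningful), deduplicates the returned designs, filters to the
non-dominated set, and evaluates `M_EK` once per distinct Pareto value.
Independently converged runs that reach the same front value scatter by the
optimizer's terminal accuracy (~`1e−4` on the log-det scale, two orders of
magnitude below the `≥1e−2` spacing of neighbouring front values), so
sampled points are clustered at a resolution of `1e−3` — counts are stable
for any resolution between those two scales — and each cluster is
represented by its best balanced member (max `c_β + c_ν`).  On the worked
example this yields 7 distinct Pareto values and exactly 7 EK evaluations,
stable across seeds.

**Exchange algorithm**: from a space-filling start, scan all single-site
exchanges (`n(Q−n)` at the first scan, `(n−1)(Q−n)` afterwards — the site
swapped in at the previous scan is not re-exchanged, as those designs were
already enumerated), compute both log-det criteria per exchange, restrict to
the non-dominated set (`restrict="front"`) or its hull (`restrict="hull"`),
evaluate `M_EK` on every restricted design, and move to the best candidate
if it strictly improves, else stop.  Counters report `iterations` = scans
(including the final non-improving one) and `ek_evaluations` = every `M_EK`
call including the initial design's.  Under these conventions the worked
example stops after 3 scans (front) and 4 scans (hull), matching the
reference iteration counts, with 904 and 67 evaluations respectively; the
evaluation totals depend directly on the tie handling described above.

**Greedy augmentation** adds, one site at a time, the maximiser of `ρ²`
(strategy S1) or of the corrected variance (S2), recomputing everything
after each addition.  S1 is space-filling; S2 initially places close pairs,
and the two `M_EK` trajectories converge as `n` grows — the correction term
fades once the design is dense enough to estimate `ν` well.

**Latin hypercube constructors**: `maximin_lh` scores all `n!` permutation
designs on levels `i/(n−1)` (exhaustive, capped at `n = 9`), maximising the
minimum inter-point distance with ties broken by the minimax distance to the
evaluation grid and then lexicographically; for `n = 7` this reproduces the
worked example's reference design.  `perturbed_lh_sample` draws a uniform
random permutation and adds `N(0, sd²)` noise (default `sd = 0.1`), clamped
to `[0,1]` — the random-design law used by the scatter and baseline studies,
an assumption where no law was prescribed.

## Numerical choices

* Linear systems use symmetric factorizations; if the correlation matrix's
  condition estimate exceeds `1e12`, diagonal jitter `1e−10·mean(diag)` is
  added and logged.  The 25×25 worked-example grid never triggers this.
* Ties in every arg-max/arg-min are broken by first index in candidate-file
  row order; exchange enumeration order is (design-slot, candidate index).
* All stochastic operations take explicit seeds and are bit-reproducible
  given (seed, config); result objects echo both.
* `rho2` and the EK correction are clamped at zero against `−1e−16`-scale
  round-off.

## Synthetic data and evaluation studies

`simulate_field` draws field realisations over the candidate set from the
model covariance by Cholesky factorization — it emulates independent
snapshots of a stationary Gaussian field with known parameters.  Real
monitoring data differ in ways the generator deliberately omits: parameters
must be estimated (the per-realisation plug-in re-estimation of an
operational study needs a likelihood fit, which is out of scope — 
`field_eval` kriges with the generating parameters and documents that
difference), fields are usually non-stationary near coasts and sources, and
water-mass structure makes true distances non-Euclidean on non-convex
domains (masked grids here keep Euclidean metric).  Passing tests therefore
demonstrate correctness of the criteria and algorithms under the stated
model, not robustness to model misspecification.

`field_eval` reports, per design, the per-realisation maximum squared
extrapolation error and the empirical maximum mean-square error over the
grid; `scatter_study` and `random_baseline_study` reproduce the
criterion-correlation and random-design-baseline analyses on perturbed-Lh
designs.

## Known limitations

* No maximum-likelihood / REML fitting: covariance parameters are inputs.
* Trend bases limited to constant and linear polynomials.
* Exhaustive Latin-hypercube search is factorial in `n` (capped at 9).
* Two-criterion Pareto machinery only (`K = 2`).
* Continuous-space (off-grid) optimisation and replicated observations are
  not supported.
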