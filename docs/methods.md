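# Methods

## The coarse-grained dimer model

A telomeric G-quadruplex (G4) dimer is represented by two hard cylinders
(HCs), one per G4 unit, with default dimensions `R_HC = 1.26 nm`,
`H = 2.64 nm` — the values that best reproduce dimer SAXS profiles in this
model class.  Two patch families decorate each cylinder:

- a **linker patch** (radius `R0 = 0.53 nm`) on the rim of one base.  The
  patch centres of the two cylinders interact through an *infinite* square
  well of width `2 R0`: the pair may never separate beyond that distance.
  This well is the entire model of the TTA linker — no explicit polymer.
- **stacking patches** (radius `R1 = 0.265 nm`) at the centres of the bases.
  The junction pair interacts through a *finite* square well of width `2 R1`
  and depth `u0`.

All energies are in units of `u0`, so the only thermodynamic control is the
dimensionless effective temperature `T* = k_B T / u0`.  `T* = 0` forces full
stacking; `T* = inf` removes the stacking bias entirely, leaving the purely
geometric ("random stacking") measure.

Patch topology: cylinder A carries its linker patch on its +axis base,
cylinder B on its −axis base, and the stacking pair couples A's +axis base
centre to B's −axis base centre.  This reproduces a single well-defined
junction.  The linker azimuth is a genuine degree of freedom (the rim patch
breaks azimuthal symmetry), sampled by the rotation moves; only one linker
pair acts per junction.  The model deliberately ignores sequence, topology,
electrostatics and hydration — it resolves only unit shape and junction
stacking.

## Overlap detection

Hard cylinders are convex, so two cylinders intersect iff the origin lies in
their Minkowski difference; this is decided by a GJK iteration over the
exact cylinder support function (lateral surface, caps and rims all arise as
support points).  Two robustness measures matter in practice:

- (near-)parallel axes are handled by an exact closed form (axial-interval
  overlap and perpendicular axis distance ≤ `2 R_HC`).  Flat cap-to-cap
  contact — exactly the geometry of a stacked dimer — makes the GJK simplex
  degenerate, so this special case is both exact and a robustness guard;
- degenerate simplices (sliver triangles, flat tetrahedra) are demoted
  rather than trusted, and a repeated support point terminates the iteration
  as "no intersection" (at worst this misreads an exact-touching
  configuration, which is measure-zero for the sampler).

The predicate is validated against a dense point-membership oracle on 1000
random pose pairs, with boundary configurations (verdict flips under a
±0.03 nm inflate/deflate) classified inconclusive.

## Monte Carlo

Canonical NVT* Metropolis sampling over `n_dimers` mutually non-interacting
dimers.  Because the measured SAXS observable is an average over independent
dimeric configurations at high dilution, inter-dimer interactions and
periodic-image bookkeeping are irrelevant; the box only sets the initial
placement density (default ≤ 0.5% volume fraction; a guard rejects > 5%).
Coordinates are not wrapped during a run.

One sweep attempts `2 n_dimers` single-cylinder moves: a uniform translation
within `max_translation` (default 0.25 nm) combined with a rotation about a
random axis within `max_rotation` (default 0.4 rad), applied to one cylinder
of each dimer.  Since dimers are independent, one move per dimer is proposed
and evaluated vectorially; this is statistically identical to sequential
updates.  Acceptance is Metropolis `exp(-dE/T*)` with hard violations
(overlap, broken linker) always rejected; `T* = 0` and `T* = inf` are
separate exact code paths.  Move amplitudes are auto-tuned to 30–50%
acceptance during the first half of thermalization and then frozen, so
production sampling obeys detailed balance.

Initialization places every dimer stacked (coaxial, bases in contact,
linker patches aligned) with uniform random position and orientation.
Equilibration is verified on the total stacking energy trace
(= −number of stacked dimers) with an autocorrelation-robust batch-means
drift test; a drifting trajectory raises a warning and is flagged.  At
strong stacking (`T* ≲ 0.3`) escape from the well is slow (acceptance
`e^{-1/T*}`), so statistical-mechanics checks in the test suite run at
`T* ≥ 0.5` where relaxation completes within the thermalization budget.

Two exact relations anchor correctness: `p_st(T*=0) = 1` identically, and
the two-state balance `odds(T*) = odds(inf) · e^{1/T*}`, with `odds(inf)`
measured by an independent rejection-sampling oracle of the linker-tethered
geometric measure (`p_stack(inf) ≈ 6×10⁻⁴` for the default geometry).

## SAXS synthesis

Every cylinder is replaced by `m` scattering points uniform in its volume
(default 50 at desk scale, 100 at paper scale) and the normalized ensemble
intensity is computed by orientation-averaged Debye sums over intra-dimer
pairs.  The estimator is *unbiased*: diagonal terms are dropped and
same-cylinder / cross-cylinder pair classes are weighted `1/(m(m−1))` and
`1/m²`, so `I(0) = 1` and `E[I(Q)]` equals the continuous normalized dimer
intensity for any `m`.  A raw double sum instead carries an incoherent floor
of order `m` per dimer that dominates the coherent signal at high Q.

The default transform path histograms pair distances (bin 0.005 nm) and
evaluates `sinc` at each bin's mean distance, which agrees with the direct
O(n²) sum to better than 0.2% everywhere, including the deep high-Q minima;
the direct sum is retained as an oracle.  Snapshot-to-snapshot scatter
provides the Monte-Carlo uncertainty on the mean intensity.

Closed forms: the orientation-averaged uniform-cylinder form factor is
evaluated by 256-node Gauss–Legendre quadrature over the axis angle
(`P(0) = 1`, Guinier slope `R_g² = R_HC²/2 + H²/12`), and the two-site dimer
structure factor is `S(Q) = 2 (1 + sin(QR)/(QR))` with `S(0) = 4`.

## Guinier and p(r) analysis

`guinier_rg` scans candidate low-Q windows of at least 10 points, fits
`ln I` vs `Q²` by weighted least squares (weights `(I/σ)²`), requires
`q_max·R_g ≤ 1.3` (configurable) plus an acceptable fit (reduced chi-square
< 3 with uncertainties, else R² > 0.995), and keeps the longest admissible
window (ties favour lower q_min).  Errors come from the weighted-slope
covariance.

`pofr` inverts `I(q) = 4π ∫ p(r) sinc(qr) dr` on a uniform r-grid
(default 80 nodes) with endpoint constraints `p(0) = p(D_max) = 0`,
non-negativity (NNLS) and a second-difference smoothness penalty.  The
penalty weight is picked by a discrepancy heuristic: the largest weight in a
log-spaced scan whose chi-square stays within 10% of the scan minimum
(i.e. the smoothest solution consistent with the data).  The real-space
radius is `R_g² = ∫ r² p dr / (2 ∫ p dr)`.  On synthetic monomer profiles
the reciprocal/real-space discrepancy is 1–2%, matching the few-percent band
expected for ideal monodisperse scatterers.

Kratky curves are reported in the dimensionless form `Q² I(Q)/I(0)` with
`I(0)` from the Guinier fit.  The test suite distinguishes compact from
two-domain shapes by counting inflections of a degree-8 polynomial fit over
Q = 0.4–2.3 nm⁻¹ (one for a bell, three when the extra shoulder is present).

## SAXS fitting

**Stacked fraction.** `I(Q) = A (p_st I0 + (1−p_st) Iinf) + bckg` is
reparametrized as `a0 = A·p_st`, `a1 = A·(1−p_st)` and solved as a
non-negative weighted linear least-squares problem, which enforces
`p_st ∈ [0, 1]` by construction; boundary solutions are flagged.  Weights
combine experimental and simulated uncertainties in quadrature.  A condition
number above 10⁶ on the weighted basis raises "basis indistinguishable".
Uncertainties propagate from the normal-matrix covariance through
`p_st = a0/(a0+a1)`.  At 1% noise on 200 Q points the recovery error is
≈ 0.008 (mean absolute), comfortably inside the ±0.02–0.03 scale of
experimental determinations.

**Inter-unit distance.** Ratio curves `R(Q) = I_T/I_{T+L}` (denominator
interpolated, first-order error propagation, points above 50% relative
error dropped) are fitted simultaneously to
`k (1 + sinc(Q R_T)) / (1 + sinc(Q R_TL))` with `R_T` shared across the
dataset and per-dataset `R_TL` and `k` (`k` can optionally be shared; the
volume interpretation of `k` is not imposed).  Multi-start over `R_T`
initial values guards against the oscillatory landscape.  On ensembles of
increasing stacked fraction the fitted `R_TL` decreases monotonically — the
stacking–compaction linkage.

**Geometry grid search.** `R_HC` is scanned (default 1.18–1.26 nm, step
0.01) and for each radius three heights in 0.06 nm steps are centred on the
constant-Rg height `H = sqrt(12 (Rg_ref² − R_HC²/2))`.  Each candidate runs
the two reference ensembles, fits `p_st`, and is scored by reduced
chi-square; failures are recorded and skipped.

## CD melting analysis

The ellipticity matrix (wavelength × temperature, mdeg) is factorized by
SVD with a deterministic sign convention.  A component is significant when
its relative variance `S_j²/ΣS²` exceeds a floor (default 0.1%) *and* the
lag-1 autocorrelation `C(x) = Σ x_i x_{i+1}` of both its unit-normalized
basis spectrum and amplitude vector exceeds 0.8; counting stops at the first
failure.  Noise vectors decorrelate point-to-point (autocorrelation ≈ 0),
smooth spectral components do not.

The significant amplitude vectors are fitted globally to a sequential
`F ⇌ I ⇌ U` model with van't Hoff constants
`K_i(T) = exp[−ΔH_i/R (1/T − 1/T_m,i)]` (fits run in kelvin, reporting in
°C).  Per-column amplitudes are solved linearly inside the residual
(variable projection), so the nonlinear search covers only
`(ΔH1, Tm1, ΔH2, Tm2)`, multi-started over Tm grids; columns are weighted by
their singular values.  The transition ordering `Tm1 ≤ Tm2` is restored
after fitting.  The **headline Tm** is the temperature where the folded
fraction crosses 1/2 — a convention chosen because single melting
temperatures are customarily reported without one.  When the data are truly
two-state the three-state model collapses degenerately (one transition
becomes spectroscopically silent); the fitted fraction space still
reproduces the two-state melt.

`rsq` is the root of the summed squared pointwise differences between two
spectra (mdeg) — a global topology-change metric and a true metric on fixed
grids.

## Synthetic data

The generators stand in for the experimental SAXS/CD measurements and
define the study conditions:

- **SAXS**: reference ensembles at `T* = 0` and `T* = inf` (desk scale
  300 dimers × 10 snapshots × 50 points/cylinder; paper scale
  3000 × 50 × 100 behind `paper_scale=True`), mixed as
  `I = p_st I0 + (1−p_st) Iinf`, with noise
  `σ(Q) = I (α + β/\sqrt{I/I(0)})`, defaults `α = 0.008`, `β = 0.002`
  (≈ 1% relative at low Q, growing where the signal is weak).  Recovery
  studies at exactly 1% noise set `α = 0.01, β = 0`.
- **Ratio curves**: the closed form above evaluated on the measured Q range
  (0.044–5.21 nm⁻¹, 200 log-spaced points) with relative Gaussian noise;
  ground-truth distances anchored to the experimental scale
  (`R_T = 3.59 nm`, `R_TL ∈ [3.18, 3.50] nm`).
- **CD melts**: Gaussian-band basis spectra for folded (max 290 nm,
  shoulder 270 nm, min 240 nm — the hybrid G4 signature), a parallel-like
  intermediate (max 262 nm, min 240 nm) and a weak unfolded coil, combined
  with sequential three-state fractions at `ΔH1 = 200 kJ/mol, Tm1 = 62 °C,
  ΔH2 = 250 kJ/mol, Tm2 = 75 °C` (headline Tm ≈ 62 °C, the free-telomere
  value) plus 0.25 mdeg white noise on the 220–330 nm × 24–100 °C grids.

What the generators do *not* emulate: instrument smearing and beam geometry,
aggregation upturns, buffer-subtraction artifacts, scan-rate (kinetic)
effects in melting, and any sequence-specific spectral detail.  Passing
recovery tests therefore demonstrates the estimators are correct and
well-calibrated under the model's own assumptions, not that those
assumptions exhaust real measurements.

## Problem sizes and seeds

Desk-scale defaults (300 dimers, 10 snapshots, 50 points/cylinder,
≥ 5×10⁵ attempted moves of thermalization at the default dimer count) keep
any single analysis under ~10 s while leaving Monte-Carlo uncertainties well
below the fitted-parameter tolerances; the paper-scale profile reproduces
the full study conditions.  All randomness flows from explicit integer
seeds; every generator emits a truth record, and recovery tests read ground
truth only through it.

## Known limitations

- The hard-cylinder model cannot resolve G4 topology (hybrid vs parallel)
  or ligand chemistry; all ligand effects enter only through `p_st`.
- GJK decides exact contact only up to a ~10⁻¹⁰ nm tolerance band;
  touching configurations are conventionally "intersecting" except where
  degeneracy guards resolve them as separated.  Both conventions are
  measure-zero for the sampler.
- The three-state CD fit assumes sequential unimolecular transitions and
  temperature-independent enthalpies; baselines are absorbed into the
  species spectra rather than fitted per column.
- The p(r) inversion's discrepancy heuristic is adequate for smooth
  single- and two-domain shapes but is not a substitute for full Bayesian
  regularization on pathological data.
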