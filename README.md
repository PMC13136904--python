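# quadstack

Stacking analysis of telomeric G-quadruplex (G4) dimers: a coarse-grained
patchy hard-cylinder Monte Carlo model, SAXS synthesis and fitting, and CD
melting thermodynamics, in one reproducible Python package.

## The problem

Guanine-rich telomeric DNA folds into G-quadruplexes, and sequences long
enough for two tandem G4 units form dimers whose units may or may not stack
at their interface.  Small-angle X-ray scattering (SAXS) sees this as a
change in compactness; circular dichroism (CD) melting sees the units'
topology and thermal stability.  `quadstack` links the two: it infers the
**stacked fraction** `p_st` of a dimer ensemble from SAXS, the **effective
inter-unit distance** `R_cm` from intensity ratios, and the **unfolding
thermodynamics** from CD melting surfaces — for experimental data or for
synthetic data with known ground truth.

## The model

Each G4 unit is a hard cylinder (default `R_HC = 1.26 nm`, `H = 2.64 nm`).
A dimer is two cylinders tethered by an infinite square well of width
`2 R0 = 1.06 nm` between rim patches (the TTA linker), with a finite square
well of width `2 R1 = 0.53 nm` and depth `u0` between the facing base
centres (stacking).  The dimensionless temperature `T* = k_B T / u0` sets
the stacking strength: Metropolis Monte Carlo in the NVT* ensemble yields
configuration ensembles, from which SAXS intensities follow by Debye sums
over points decorated uniformly into each cylinder.

Experimental profiles are fitted as a two-state mixture of the `T* = 0`
(fully stacked) and `T* = inf` (stacking-blind) reference intensities,

    I(Q) = A [ p_st I0(Q) + (1 - p_st) Iinf(Q) ] + bckg,

and dimer compaction is quantified through the closed-form structure-factor
ratio

    R(Q) = k [1 + sinc(Q R_T)] / [1 + sinc(Q R_TL)],

fitted jointly over free/complex curve sets with `R_T` shared.  CD melting
matrices are factorized by SVD (`D = U S Vᵀ`), the number of spectroscopic
species is determined from singular values and autocorrelation criteria
(threshold 0.8), and the significant amplitude vectors are fitted globally
to a sequential three-state model `F ⇌ I ⇌ U` with van't Hoff constants
`K_i(T) = exp[-ΔH_i/R (1/T - 1/T_m,i)]`.  Details and numerical choices are
in `docs/methods.md`.

## Worked example

Generate a synthetic dimer dataset at a known stacked fraction, then
recover it, together with the unstacked ensemble's radius of gyration:

```
$ quadstack synth saxs --pst 0.13 --seed 11 --out saxs
wrote saxs/i_exp.dat i0.dat iinf.dat truth.json

$ quadstack fit-pst --data saxs/i_exp.dat --i0 saxs/i0.dat --iinf saxs/iinf.dat
p_st = 0.1253 +- 0.0111 (chi2_red = 0.825)

$ quadstack guinier --data saxs/iinf.dat
Rg = 2.140 +- 0.001 nm  I0 = 1  window 0.044-0.462 nm^-1 (99 pts, qRg_max = 0.99)
```

The fitted `p_st = 0.125 ± 0.011` recovers the generating value 0.13 within
one standard error — the same two-state analysis applied to a measured
dimer profile yields its ensemble stacked fraction.  The `T* = inf`
ensemble's Guinier radius (2.14 nm) is the model's prediction for a mostly
unstacked dimer; stacking compacts it to ≈ 1.86 nm.

The CD side, on a synthetic three-state melting surface:

```
$ quadstack synth cdmelt --seed 11 --out cd
wrote cd/melt.csv truth.json

$ quadstack svd-melt --data cd/melt.csv
significant components: 3
dH1 = 199 kJ/mol  Tm1 = 62.16 C
dH2 = 251 kJ/mol  Tm2 = 75.04 C
headline Tm (f_F = 1/2) = 62.00 C
```

Three significant SVD components identify the folded–intermediate–unfolded
pathway, and the global fit recovers the generating thermodynamics
(ΔH1 = 200 kJ/mol, Tm1 = 62 °C, ΔH2 = 250 kJ/mol, Tm2 = 75 °C) to within
one standard error; the headline Tm is the half-unfolding temperature.

The same commands accept measured data: three-column ASCII SAXS profiles
(`Q I σ`, nm⁻¹ or Å⁻¹ auto-detected) such as SASBDB deposits downloaded
manually, and delimited CD matrices with wavelengths in the first column
and temperatures in the header row.  `quadstack grid-search` scans cylinder
dimensions against a dimer profile, and `quadstack fit-ratio` fits R(Q)
curve sets.

## Layout

- `src/quadstack/geometry.py` — hard-cylinder + patch types, overlap,
  junction energy (`src/quadstack/overlap.py`: numba GJK kernel)
- `src/quadstack/mc.py` — NVT* Metropolis engine, trajectories, `p_st`
- `src/quadstack/scattering.py` — point decoration, Debye sums, form
  factors, Guinier, p(r), Kratky
- `src/quadstack/saxs_fit.py` — stacked-fraction, ratio and geometry fits
- `src/quadstack/cd_melting.py` — SVD, significance, three-state fit, RSQ
- `src/quadstack/synth.py` — seed-deterministic synthetic data + truth
  records
- `src/quadstack/io.py`, `src/quadstack/cli.py` — text formats and the
  `quadstack` command
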