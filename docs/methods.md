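# Methods

This note documents the models, defaults and numerical choices behind
`citrusnmr`, and what the synthetic studies do and do not establish.

## Forward model of the extract spectrum

An aqueous mandarin extract in D₂O is modelled as a mixture of four
analytes with arbitrary-unit amounts: sucrose, total glucose, total
fructose and citric acid. Only amount *ratios* matter downstream,
because every integral is anchored to sucrose.

Each marker resonance contributes a set of stick transitions:

| signal | centre (ppm) | pattern | protons | species fraction |
|---|---|---|---|---|
| sucrose glucosyl H-1 | 5.40 | d, J = 3.8 Hz | 1 | 1 |
| α-glucose H-1 | 5.22 | d, J = 3.7 Hz | 1 | 0.36 |
| β-glucose H-1 | 4.63 | d, J = 7.9 Hz | 1 | 0.64 |
| β-furanose fructose H-3/H-4 | 4.09 | narrow unresolved cluster | 2 | 0.25 |
| citrate CH₂ | 2.80 | AB, J = 15.7 Hz, Δδ = 0.13 ppm | 4 | 1 |

Coupling constants are standard literature values and overridable; the
anomer/tautomer fractions are aqueous equilibrium values (α-glucose
0.36, β-furanose fructose 0.25) and are controlled per sample by the
composition object. An optional HDO singlet at 4.70 ppm can be added;
it lies outside every integration window.

Sugar multiplets are treated first-order: the markers sit in
uncluttered regions and weak coupling is adequate there at both fields.
The citrate methylenes are the exception — a two-proton AB pair whose
second-order character grows as the field drops — and are computed from
the exact two-spin solution: with C = √(Δν² + J²), lines at ±(C±J)/2
around the centre with intensities ∝ 1 ∓ J/C. A unit test checks this
against an independent diagonalization of the two-spin Hamiltonian.

The FID is the sum over transitions of decaying complex sinusoids

```
x(t) = Σ A·exp(2πi f t) · exp(−π·lw·t) + noise,
A = amount · protons · fraction · weight · sin(flip) · n_scans
```

with transition frequencies `(δ − carrier)·ν₀ + splitting`, carrier at
4.7 ppm, so J splittings are field-invariant in Hz and ppm separations
are field-invariant in ppm. Complex Gaussian noise has standard
deviation `noise_sd·√n_scans` (coherent signal addition vs √N noise
growth). No T1-recovery bias is modelled: flip angle and scan count act
only as a global amplitude factor, consistent with treating both
acquisition schemes as quantitative.

**Natural linewidths** default to 1.0 Hz at high field and 0.5 Hz on
the benchtop (before the 0.3 Hz processing broadening). The benchtop
value reflects the sub-Hz resolution of modern permanent-magnet
systems; it matters because the fructose integration window
(4.10–4.07 ppm) is only ~1.9 Hz wide at 62.32 MHz, so the captured
fraction of the fructose Lorentzian is sensitive to linewidth. With
0.8 Hz apodized lines the benchtop window captures ~75% of the
fructose signal; the citrate AB outer lines fall outside the benchtop
citrate window by a comparable fraction, and the two losses largely
cancel in the sweetness/acid ratio — the simulated cross-field ratio
differences are 0.1–0.5% per sample.

**Citrate position.** The two experiment series ran at slightly
different temperatures, which displaces the citrate methylene signals;
that is why the integration windows are field-specific (3.02–2.73 ppm
at high field, 2.81–2.54 ppm on the benchtop). The generator emulates
this with a per-scheme citrate centre offset (+0.075 / −0.125 ppm from
the nominal 2.80 ppm), placing the AB system at the centre of each
field's window.

**Replicate structure.** A cohort is a set of varieties, each specified
by a target ratio (a plausible sucrose-dominant sugar profile,
sucrose:glucose:fructose = 70:35:35, with citric acid back-computed) or
by an explicit composition. Replicates perturb every analyte amount by
an independent unit-mean log-normal factor with coefficient of
variation 0.06 by default — a realistic extraction-plus-instrument
repeatability that propagates to sweetness/acid-ratio RSDs of ~5–12%,
comfortably inside the <20% repeatability such replicate sets show.
Each sample also receives a global chemical-shift jitter (σ = 0.002
ppm) that the referencing step must remove. One integer seed drives the
whole cohort.

## Processing chain

1. **Apodization / zero fill / FT**: multiply by exp(−π·0.3·t), zero
   fill 32 K → 64 K complex points, FFT, ppm axis descending. The first
   point is halved to suppress the one-sided-DFT baseline offset. A
   Parseval test pins the energy bookkeeping.
2. **Phase correction**: the original protocol phases manually; here an
   automatic mode minimises a deterministic objective (heavily weighted
   squared negative intensity + Shannon entropy of the normalised real
   part) over (ph0, ph1) with a coarse grid then Nelder–Mead, evaluated
   on a decimated copy for speed. Recovery of known dephasings is
   accurate to ~2°/10°. A fixed-phase mode exists because synthetic
   FIDs have known (zero) phase; large seeded simulation studies use it
   together with `baseline_mode="none"` (synthetic baselines are flat),
   which keeps Monte-Carlo runs cheap without touching the steps under
   study — the automatic modes are exercised by their own tests and by
   the acceptance study.
3. **Baseline correction**: iteratively re-masked polynomial (order 3):
   fit, discard points > 3 robust σ above the fit, refit. Signal-free
   regions therefore define the baseline; an injected linear ramp is
   removed to < 1% of the tallest peak.
4. **Referencing**: the α-glucose anomeric signal is moved to 5.22 ppm.
   The signal position is the intensity centroid of the region above
   30% of the window maximum — for the doublet this is the multiplet
   centre, i.e. the chemical shift. A plain argmax would sit on one of
   the two equal doublet lines (±J/2, which is ±0.03 ppm at 62 MHz) and
   noise would decide which, so the centroid is both more accurate and
   stable. Referencing fails loudly if no peak exceeds 2% of the
   spectrum maximum in the search window.
5. **Alignment**: each spectrum is rigidly shifted by the integer lag
   maximising the cross-correlation of Savitzky–Golay first derivatives
   (window 5 points, order 3) between the spectrum and the cohort
   average, capped at 0.05 ppm; an optional two-segment mode aligns the
   sugar (>3.6 ppm) and citrate regions independently. Interpolation
   onto the common grid is linear.

The chain is purely functional: identical input and parameters give
bit-identical spectra.

## Quantification and scoring

Integrals are plain trapezoids over the verbatim windows (5.54–5.32,
5.29–5.16, 4.63–4.53, 4.10–4.07 ppm; citrate per field as above) — no
peak fitting, following the fixed-range protocol. Bounds are accepted
in either order. Areas are divided by the sucrose area (≡ 1.00
exactly). Negative integrals abort with the window name rather than
clamping: they indicate a phasing/baseline failure that silent
truncation would hide. An optional proton-count normalisation exists
but is off by default, since the protocol scales raw areas only.

The ratio applies Schiffman sweetness weights (1.0 / 1.3 / 0.6) to the
sugar areas and divides by citrate. It is degree-0 homogeneous in the
raw areas, consistent with the arbitrary sucrose anchor.

The acceptability model is OLS of panel score on per-variety mean
ratio. R² is the coefficient of determination; **RMSE uses divisor n**
(√(Σr²/n), the model-error convention that reproduces the reference
values 0.35 and 0.29), not the n−2 regression standard error.
Replicates are averaged per variety before fitting; per-replicate
fitting is available but non-default. Predictions reported for the
reference varieties are in-sample fitted values.

Two rounding artefacts are worth recording. Refitting on the rounded
published mean ratios gives R² = 0.9549 at 60 MHz where 0.96 was
printed, and a fitted value of 4.895 (→ 4.89) for one 400 MHz variety
where 4.90 was printed — both consistent with the original fits having
used unrounded replicate data. The package reports the recomputed
values and the tests accept agreement at print precision (±0.01).

## What the synthetic studies show — and what they do not

The generator reproduces the *geometry* of the assay: field-dependent
Hz scales, second-order citrate collapse, window/linewidth interaction,
replicate and noise statistics, shift jitter. Passing tests demonstrate
that the processing and scoring machinery is unbiased and
field-equivalent **for spectra matching this model**. Real extracts
add strongly coupled sugar ring-proton forests (3.0–4.3 ppm), pH- and
matrix-dependent shifts, residual HDO wander, probe temperature drift
and lineshape asymmetry; none of these is claimed to be emulated, and
true fruit compositions are unknown — varieties are parameterised by
target ratio only. The cross-field agreement of simulated per-sample
ratios (<1%) is therefore a statement about the method's internal
consistency, not a prediction of the 5–16% per-variety differences a
real instrument pair shows.

Problem sizes used by the standing studies: the replicate-RSD study is
5 varieties × 5 replicates per cohort (25 FIDs of 32 K points,
processed at 64 K); the repeatability Monte Carlo aggregates 100 such
seeded cohorts; the field-equivalence study processes 5 compositions ×
2 instruments end to end with the fully automatic chain.

## Degenerate inputs and tie-breaks

- AB with Δν = 0 collapses to the A₂ singlet (one line).
- `replicate_cv = 0` reproduces the variety composition exactly.
- Empty variety tables, zero-variance regressors, < 3 varieties,
  mismatched variety sets, sucrose integral ≤ 0 and citrate area ≤ 0
  all raise immediately with specific messages.
- Alignment with exactly two spectra can be degenerate (the average is
  symmetric between them); cohorts of ≥ 3 spectra are the intended use.
- Windows may be given (high, low) or (low, high); internally
  normalised. The four sugar windows must not overlap.
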