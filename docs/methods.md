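# Methods

This note records the models implemented in `ecmech`, the parameter
choices behind them, and what the synthetic generators do and do not
emulate.

## Fiber alignment index

Collagen fiber orientations measured from polarized-light micrographs are
*axial* data: θ and θ + 180° are the same fiber, so all angles are reduced
mod 180 on input. The per-field statistic is

    AI = (1/N) Σ cos²(θᵢ − θ_median),

with θ_median the ordinary (linear) median of the recorded angles (mean of
the middle two for even N). The linear median mirrors the manual protocol
— angles read against a fixed horizontal line and summarized directly —
and is deliberately *not* a circular median. Two consequences are worth
knowing:

* cos² has period 180°, so individual terms need no wrap handling, but
  the median does: a field whose dominant orientation straddles the 0/180
  reference (some fibers recorded near 0°, the rest near 179°) gets a
  median in mid-range and an artificially low AI. AI is therefore
  invariant under rotations only while no angle crosses the wrap; the
  fiber-cohort generator keeps the dominant direction central (see below).
* Under the formula, uniformly random orientations give AI → 0.5
  (E[cos²] = 0.5), not 0. The common verbal gloss "0 = random" actually
  describes the nematic order parameter 2·AI − 1, which
  `ecmech.fibers.nematic_order` provides as a clearly-labelled
  alternative; AI itself is the primary statistic everywhere.

Protocol guidelines — at least 20 fibers per field, 3 fields per case —
are warnings, not validity conditions: fields and cases below them are
computed and flagged. Case values are unweighted means of field AIs.
Group tests: classical pooled-variance Student t (default) or Wilcoxon
rank-sum, exact for combined n ≤ 20 without ties and normal-approximated
with tie correction otherwise. Degenerate t inputs (zero pooled variance)
return p = 1 for equal means, p = 0 with a warning otherwise.

## Hertz-model stiffness from AFM force maps

All quantities are SI internally (m, N, Pa); the CLI reports kPa. A raw
curve is piezo extension z versus cantilever deflection d with probe
constants k (N/m), R (m), ν. With baseline d₀ (mean pre-contact
deflection), force is F = k·(d − d₀) and indentation is
δ = (z − z_contact) − (d − d₀), clipped at zero before contact. The
spherical (paraboloid, small-indentation) Hertz relation
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} is used exactly as written — no cone,
bottom-effect or viscoelastic corrections.

Because F is linear in E, the least-squares modulus given the contact
point is the closed-form regression slope of F on
(4/3)(1−ν²)⁻¹√R·δ^{3/2}, clipped at zero; this *is* the exact nonlinear
least-squares solution (verified in tests against `scipy.optimize`).

**Contact detection** grid-searches candidate indices in the middle 90% of
the curve (guaranteeing baseline and fit windows), scoring each by the
total squared error of a two-piece model — flat baseline before, Hertz fit
after — and re-estimating E at every candidate. A curve is declared
contact-free when the best fit's predicted force rise does not exceed 3×
the baseline noise; such curves (and fits whose RMS residual exceeds 20%
of the peak force — a threshold loose enough to keep noisy-but-valid fits)
are rejected and counted per map. Map stiffness is the unweighted mean of
accepted fits; whether rejection is applied is configurable and always
logged, since published per-map means rarely state their exclusion rules.
Normalization by tumour-cell count is a plain division, reported in
Pa/cell (the quantity has no standard unit).

**Accuracy.** Signal-to-noise ratio is defined as RMS Hertz-segment force
over noise sd (`synthetic.noise_for_snr`; for a linear ramp the RMS is
half the peak force). At SNR 20 with 200-sample curves the modulus
estimate is unbiased to < 0.1% with CV ≈ 2%; contact localization reaches
the efficient (Cramér–Rao) limit of this estimation problem, about 1.5
samples sd at SNR 10. Localization error *in sample units* grows as
√n_post at fixed SNR, because the Hertz force leaves contact with zero
slope — denser sampling does not localize the kink better in units of
samples.

The tip radius R has no default: nominal radii of commercial tips span
orders of magnitude and the fitted E scales as 1/√R, so it must be
supplied explicitly. ν defaults to 0.5 (incompressible tissue), k to
5 N/m; both are overridable.

## IHC scoring, exact tests, and collagen partitioning

The product score is percentage category (0–4) × intensity (0–3);
expression is "high" iff score ≥ 4 (score 4 itself is high — e.g.
category 2 × intensity 2). Default percentage bins are 0: <5%, 1: 5–25%,
2: 26–50%, 3: 51–75%, 4: >75%, fully configurable; raw percentages are
accepted and binned. Group-by-class counts form a 2×2 table tested with
the two-sided Fisher exact test under the probability-ordering convention
(sum of hypergeometric probabilities of all same-margin tables no more
probable than the observed one, the convention scipy implements); the
bundled published marker cohorts reproduce their reported p-values to 3
decimals under this convention, which is why it — and not chi-square — is
the default; plain and Yates-corrected chi-square are labelled
alternatives. Degenerate margins return p = 1 with a warning.

Ki67 labelling index is 100 × positive/counted, with protocol count minima
(1000 cells for tumour sections, 300 for organoids) enforced as warnings.
Collagen partitioning is insoluble = total − soluble with the insoluble
fraction as the cross-linking readout; conservation holds to machine
precision by construction.

## Cell assays

Wound closure is 100·(A₀ − Aₜ)/A₀ — the standard relative-closure
definition; negative values (wound widening) are allowed with a warning.
The proliferation rate from CCK8 time courses is the ordinary
least-squares slope of log absorbance on time — the natural operational
definition when none is given — so a culture doubling every 24 h has rate
ln 2/24 h⁻¹. Invasion normalization divides the invaded-cell count by the
proliferation-rate ratio (test/reference), removing growth-rate
confounding; ratios are computed per experiment by default (pooling across
replicates is a caller choice).

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed or `numpy` Generator — no global
state — and identical seeds give bit-identical output.

* **Fiber angles** follow an axial von Mises distribution: the doubled
  angle 2θ is von Mises with concentration κ, halved and reduced mod 180;
  κ = 0 is exactly uniform. Two frozen regimes bracket the biology:
  `KAPPA_RANDOM = 0` (disordered, benign-like; expected field AI ≈ 0.545
  at 20 fibers — finite-N bias places the uniform expectation slightly
  above the asymptotic 0.5) and `KAPPA_ALIGNED = 1.11`, found once by
  bisection so the expected field AI is 0.748 (the aligned, carcinoma-like
  regime). The cohort generator draws each field's dominant direction
  uniformly from (45°, 135°) by default, emulating measurement with the
  fiber tract referenced away from the 0/180 wrap; widen to (0°, 180°) to
  study the wrap sensitivity deliberately. Within-case and between-case
  variability both come from per-field sampling; the generator exposes
  fields-per-case and fibers-per-field rather than asserting a particular
  variance decomposition, which real cohorts do not report.
* **Force curves** place a uniform piezo ramp across a contact point
  (snapped on-grid so ground truth is exact), solve
  δ + F(δ)/k = z − z_c per sample by Newton iteration, and add i.i.d.
  Gaussian noise to the force — the simplest model consistent with AFM
  practice. Not emulated: drift, hydrodynamic drag, adhesion on retract,
  tilt, or correlated noise; passing recovery tests therefore shows
  estimator correctness under the stated model, not robustness to every
  instrumental artifact. Force maps draw per-cell moduli from a lognormal
  around the map's median (log-sd 0.2 by default) — tissue stiffness is
  right-skewed and positive.
* **IHC cohorts** are independent binomial draws per group (default 14 vs
  14 with high-expression probabilities 4/14 and 11/14, the margins of the
  bundled COL1A1 cohort). **Collagen assays** draw totals and soluble
  amounts with truncated Gaussian noise so every record satisfies
  0 ≤ soluble ≤ total.
* The demo and analysis drivers use 8×8 force maps of 150-sample curves
  and a 5 vs 50 kPa modulus contrast (the same contrast as the hydrogel
  mimicry conditions soft matrices are compared against); these sizes keep
  the full pipeline interactive while leaving every code path exercised,
  and all of them scale up by argument.

## Numerical choices

* Degrees at every interface, radians only inside trig; conversions are
  centralized in `fibers`/`synthetic`.
* Contact search spans the middle 90% of samples with ≥ 5 post-contact
  points; Newton solves in the simulator run to |g| < 1e-15·z_max.
* The modulus estimate is clipped at zero (E ≥ 0 always); an all-zero
  force curve fits E = 0 rather than erroring.
* CSV outputs begin with comment lines carrying the package version, the
  seed, and a 12-hex config hash; readers skip `#` lines, reject missing
  or non-numeric fields with line numbers, and never silently coerce.
* The demo report is JSON with sorted keys and no timestamps, making
  seeded runs byte-reproducible.

## Known limitations

* AI's wrap sensitivity (above) means recorded angle tables from
  arbitrarily oriented images can under-score alignment; re-reference
  angles so the dominant tract is central before analysis.
* The Hertz stage assumes a spherical elastic contact on a flat,
  semi-infinite sample; thin or layered samples need bottom-effect
  corrections that are out of scope here.
* The exact-test stage addresses 2×2 dichotomized designs only; ordinal
  trend tests across the raw 0–12 scores are not provided.
* Synthetic cohorts are exchangeable across cases; batch, section and
  observer effects present in real pathology data are not modelled.
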