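# ecmech

Quantitative readouts of tumour extracellular-matrix (ECM) remodelling, for
researchers studying how collagen architecture and tissue stiffening
accompany malignant transformation — the motivating system is salivary
carcinoma ex pleomorphic adenoma (CXPA) arising from benign pleomorphic
adenoma (PA), where the carcinoma deposits dense, aligned, cross-linked
type I collagen and stiffens the matrix.

The package implements five analysis stages as a library (`src/ecmech`),
with numbered narrative drivers under `analysis/` and a CLI (`ecmech`):

1. **Collagen fiber alignment** (`ecmech.fibers`). From per-field tables of
   fiber angles θᵢ (degrees, axial, measured against a horizontal
   reference), the alignment index of a field is

       AI = (1/N) · Σᵢ cos²(θᵢ − θ_median),

   with θ_median the ordinary median of the measured angles. AI = 1 for
   perfectly aligned fibers; uniformly random orientations concentrate at
   E[cos²] = 0.5. Field AIs aggregate to unweighted case means; groups are
   compared with Student's t-test or the Wilcoxon rank-sum test.
2. **AFM stiffness** (`ecmech.afm`). Raw piezo–deflection curves are
   converted to force–indentation data (F = k·(d − d₀),
   δ = piezo travel past contact minus cantilever bending), the contact
   point is found by a two-piece model search, and the elastic modulus E
   comes from the spherical-indenter Hertz model

       F = (4/3) · E/(1 − ν²) · √R · δ^{3/2}

   (ν Poisson ratio, default 0.5; R tip radius; k spring constant, default
   5 N/m). Force-map grids (e.g. 50×50 curves over 10×10 µm) are averaged
   over accepted fits and optionally normalized by tumour-cell count.
3. **IHC scoring and exact tests** (`ecmech.histology`). Percentage
   category (0–4) × staining intensity (0–3) gives a product score,
   dichotomized at ≥ 4 into low/high expression; two-group cohorts form
   2×2 tables tested with the two-sided Fisher exact test. Includes the
   Ki67 labelling index and the soluble/insoluble (cross-linked) collagen
   partition insoluble = total − soluble.
4. **Cell assays** (`ecmech.assays`). Wound closure
   100·(A₀ − Aₜ)/A₀, log-linear CCK8 growth rates, and transwell invasion
   counts normalized by the proliferation-rate ratio between conditions.
5. **Synthetic data** (`ecmech.synthetic`). Seeded generators for every
   input above with known ground truth: axial von Mises fiber angles
   (doubled-angle construction), Hertz forward-model force curves with
   contact offset and Gaussian force noise, binomial IHC cohorts, and
   collagen assay records.

## Worked example

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_fiber_alignment.py
python analysis/03_afm_stiffness.py
python analysis/04_ihc_and_collagen.py
```

prints, among other lines:

```
PA: case-mean AI 0.524 +- 0.036 (n=3)
CXPA: case-mean AI 0.721 +- 0.018 (n=3)
Student t = 8.431, two-sided p = 0.0011; rank-sum p = 0.1000
PA: mean E 5.08 kPa (64 fits, 0 rejected), 0.203 kPa/cell over 25 cells
CXPA: mean E 50.55 kPa (64 fits, 0 rejected), 4.212 kPa/cell over 12 cells
COL1A1: (10,4,3,11) -> p = 0.021
```

Reading this: the disordered (PA-like, κ = 0) cohort scores case-mean
alignment indices near 0.5, the aligned (CXPA-like, κ = 1.11) cohort near
0.75, and three cases per group already separate them by t-test (the exact
rank-sum test cannot go below p = 0.1 at n = 3 vs 3). The Hertz fits
recover the simulated 5 kPa and 50 kPa map stiffnesses, and the published
COL1A1 IHC cohort (10 low/4 high in PA vs 3 low/11 high in CXPA)
gives a two-sided Fisher exact p of 0.021. The same stages are available
as CLI subcommands (`ecmech simulate | align | afm-fit | ihc-test |
assays | demo`); `ecmech demo --seed 0 --out DIR` runs everything end to
end and is byte-reproducible under a repeated seed.

## Layout

```
src/ecmech/      library: fibers, afm, histology, assays, synthetic,
                 datasets, io, demo, cli
analysis/        numbered narrative drivers writing under results/
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance.py
docs/methods.md  models, parameters, numerical choices, limitations
```
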