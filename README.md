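# fatsas

Thoracic fat quantification on CT-like volumes with standardized
anatomic space (SAS) slice mapping, exercised end to end on synthetic
phantom cohorts with known ground truth.

The pipeline:

1. **simulate** — generate a seeded cohort of thoracic CT phantoms
   (elliptical body, SAT ring, rib cage, mediastinal VAT, lungs,
   diaphragm dome with sub-diaphragmatic abdominal fat, marrow
   pseudo-fat) plus abdomen/thigh single-slice phantoms.  A known
   "best slice" is planted: at a configurable standardized level each
   compartment's slice area is proportional to its total volume.
2. **segment** — trim to the thoracic extent around the lungs, segment
   the body with per-slice air-cavity filling, threshold fat in the
   closed HU window [−170, −40], split VAT (inside the rib-cage
   interface, per-slice morphological opening) from SAT, and remove
   marrow pseudo-fat inside bone.
3. **calibrate / map** — calibrate mean standardized vertebral landmark
   locations (T2..T10) from reference subjects and map every
   standardized half-level (17 levels) to an acquired slice per subject
   via a piecewise-linear landmark transform.  A proportional linear
   baseline is included for comparison.
4. **quantify** — normalized volumes (÷L³) and slice areas (÷L²), where
   L is the skeletal bounding-box diagonal, plus attenuation histogram
   summaries (mean, median, mode, quartiles).
5. **analyze** — Pearson/Spearman correlations, exhaustive best-1/2/3
   slice search by area-to-volume correlation, Jaccard repeatability,
   and two-group comparisons (pooled/Welch t-test, Mann–Whitney U).

## CLI

```sh
fatsas run-all --config run.yaml --out out/        # full pipeline + manifest
fatsas simulate  --config run.yaml --out out/      # or stage by stage
fatsas segment   --config run.yaml --out out/ --window-lower -150
fatsas calibrate --config run.yaml --out out/
fatsas map       --config run.yaml --out out/
fatsas quantify  --config run.yaml --out out/
fatsas analyze   --config run.yaml --out out/
```

A minimal `run.yaml`:

```yaml
seed: 7
cohort:
  n_subjects: 40
n_calibration: 20
```

Outputs: NIfTI volumes/masks under `cohort/` and `seg/`, the SAS model
and slice table under `sas/`, a tidy `quant/measurements.csv`, and
`analysis/{correlations,best_slices,groups,precision}.csv`.
`manifest.json` records the config hash, seed, and per-file checksums;
identical config + seed reproduce byte-identical artifacts.

## Library use

```python
from fatsas import PhantomParams, generate_cohort, best_slices
from fatsas.pipeline import build_cohort_table

params = PhantomParams(n_subjects=40, seed=1)
cohort = generate_cohort(params)
table, model, results = build_cohort_table(cohort, params)
print(best_slices(table, "VAT", 1))   # -> planted level, rho ~ 0.99
```
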