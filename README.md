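# asymvbm

Voxel-based gray-matter (GM) asymmetry analysis with core-symptom
subgrouping, built around a synthetic multi-site cohort simulator so that
every stage can be validated against known ground truth.

The pipeline:

1. **`asymvbm.cohort`** — simulate a multi-site phenotype table (unequal
   site sizes, ages 7–18, male-skewed, three symptom-dominance
   subpopulations) and blob-phantom GM probability volumes on a symmetric
   grid, with configurable localized left/right asymmetry effects, age
   trends, and a tunable AI–symptom-score coupling. Everything injected is
   recorded in a ground-truth manifest.
2. **`asymvbm.subgroups`** — normalize ADI-R subscale scores
   (`X' = X / X_MAX`), assign each ASD subject to the SI / VA / RRB
   subgroup by the strict-max rule (ties excluded), select age-, gender-
   and site-matched controls, and run the demographic test battery
   (Pearson χ² without continuity correction, two-sample t, Kruskal–Wallis
   + Dunn pairwise z with Bonferroni).
3. **`asymvbm.asymmetry`** — left–right flip about the mid-sagittal plane
   (exact, interpolation-free on centered even grids), symmetric template
   construction, right-hemisphere masking, the asymmetry index
   `AI = ((i1−i2)/((i1+i2)·0.5))·i3` (positive = rightward), and Gaussian
   smoothing (default 8 mm FWHM).
4. **`asymvbm.glm`** — mass-univariate OLS contrasts of AI maps between
   groups with centered age, gender, and full one-hot site covariates
   (pseudo-inverse fit, effective rank reported).
5. **`asymvbm.grf`** — residual-based smoothness (FWHM / resel)
   estimation, connected-component cluster labeling (6/18/26
   connectivity), and Gaussian-random-field corrected cluster p-values
   (voxel p < 0.005, cluster p < 0.05 by default), plus Dice overlap for
   comparing cluster maps.
6. **`asymvbm.behavior`** — cluster-mean AI extraction and partial
   correlations with symptom scores (age/gender/site covariates) or age
   (gender/site covariates).
7. **`asymvbm.pipeline`** / **`asymvbm.cli`** — one-command orchestration
   with YAML config, seeded determinism, and a machine-readable manifest.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the acceptance
criteria end to end (Monte-Carlo null calibration of the family-wise error
rate, power/localization of injected effects, coupling recovery, and the
published contingency-table statistics). The full suite takes a few
minutes on one CPU.

## CLI

```bash
# full run from a YAML config
asymvbm run --config run.yaml --out out/

# individual stages
asymvbm simulate --config cohort.yaml --out sim/
asymvbm subgroup --pheno sim/phenotype.csv --instrument adir --out sub/
asymvbm asym --in sim/volumes --mask-threshold 0.2 --fwhm 8 --out ai/
asymvbm glm --pheno sim/phenotype.csv --ai-dir ai/ --analysis SI --out glm/
asymvbm report --out out/
```

A minimal `run.yaml`:

```yaml
cohort:
  n_asd: 40
  n_td: 40
  n_sites: 4
  grid_shape: [48, 56, 48]
  voxel_size: 3.0
  seed: 7
effects:
  - region_center: [20.0, -18.0, 12.0]
    region_radius: 12.0
    delta: 0.15
    side: right
    target: SI
analyses: [general, SI]
voxel_p: 0.005
cluster_p: 0.05
```

## Conventions

- World coordinates are RAS millimetres; right hemisphere = world x > 0.
- Grids are centered so the mid-sagittal plane falls exactly between two
  voxel columns; flipping is an index reversal, bit-exact.
- Phenotype CSV columns follow the common repository conventions:
  `DX_GROUP` 1 = ASD / 2 = TD, `SEX` 1 = male / 2 = female.
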