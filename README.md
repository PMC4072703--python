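# fawnsurv

Resource selection, multi-predator risk and neonatal survival modelling for
wildlife telemetry studies, exercised end-to-end on synthetic data.

The pipeline implements a use–availability resource-selection analysis with
telemetry-error handling, composite predation-risk covariates, maternal-effect
covariates (winter severity index, birth-mass back-calculation), a ranked set
of Cox proportional-hazards mixed-effects survival models, and spatially
extrapolated suitability / composite-risk / mortality surfaces.

## Components

| Module | What it does |
|---|---|
| `fawnsurv.synthetic` | Seeded generators: clustered landcover patches, road network, smooth predator and NDVI surfaces, fawn telemetry (gamma steps, error ellipses), winter weather, and fates drawn from a proportional-hazards model with fawn/year frailty. |
| `fawnsurv.grid` | Square-cell analysis grid (2115 m²/cell), buffered zonal extraction (26 m discs), availability sampling (415 m), error-ellipse filtering, distance-to-road, linear stretch. |
| `fawnsurv.rsf` | Use–availability logistic models with crossed fawn/year random intercepts (Laplace ML), z-scoring, VIF screening (threshold 7), α = 0.05 additive selection, 5-fold CV (Brier), suitability projection `w = exp(Σβ_k z_k)` stretched to [0, 1]. |
| `fawnsurv.covariates` | Composite predation risk (sum over four species), winter severity index (Σ[(snow+wind+rain) − tmin], Jan 1–Mar 31), birth-mass back-calculation (0.2 kg/day), per-fawn covariate assembly. |
| `fawnsurv.survival` | The 12-model frailty Cox candidate set (Efron ties, penalized partial likelihood, Laplace-integrated log-likelihood), ranked by deviance explained (= LR χ²/2). |
| `fawnsurv.surfaces` | Per-cell end-of-season mortality `stretch(1 − S0_j(te)^exp(βx))` averaged over years, and the three-panel surface bundle. |
| `fawnsurv.cli` | Stage orchestration (`simulate → rsf → covariates → survival → surfaces`), YAML config, deterministic run manifest. |

The two core fitters (`fawnsurv.glmm`, `fawnsurv.frailty`) are written here:
no pre-installed package fits ML logistic GLMMs or Gaussian log-frailty Cox
models with crossed random intercepts. Both reduce exactly to their
fixed-effects counterparts at zero random-effect variance, which the test
suite verifies against `statsmodels` and `lifelines` to 1e-6.

## CLI

```bash
fawnsurv run-all --seed 1 --out-dir out             # full synthetic pipeline
fawnsurv simulate --seed 1 --out-dir out            # any single stage (+ prerequisites)
fawnsurv run-all --config my_config.yaml            # YAML config, flag overrides
```

Outputs are plain text: ESRI ASCII grids for rasters, GeoJSON roads, CSV
tables (use–availability rows, a Table-2-style RSF report, a Table-3-style
ranked survival report, baseline survival curves, the per-cell surface
panel), and a JSON run manifest. Identical configs and seeds give
byte-identical outputs.

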