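# actisig

Multivariate intensity-spectrum signature analysis for accelerometer-measured
physical activity and metabolic health.

Instead of collapsing accelerometry into two or three cut-point summaries,
`actisig` treats the whole intensity spectrum — minutes/day spent in each of
16 counts-per-minute (cpm) intervals, from 0–99 up to ≥8000 cpm — as a single
multivariate exposure, and links it to health outcomes with methods that
tolerate the extreme collinearity of adjacent intensity bins:

- **`actisig.accel`** — epoch-level processing: clock-window restriction
  (06:00–23:59), non-wear detection (≥60 min of consecutive zero counts),
  valid-day screening (≥8 h/day wear on ≥4 days), intensity-spectrum
  extraction, and Evenson-cut-point descriptives (SED/LPA/MPA/VPA/MVPA).
- **`actisig.metabolic`** — risk indices (BMI, waist:height, TC:HDL,
  Friedewald LDL, HOMA), age/sex residualization by OLS, and a composite
  metabolic-health score: the mean of six standardized residuals (SBP,
  triglycerides, TC:HDL, HOMA, waist:height, reversed aerobic-fitness test),
  rescaled to unit SD (higher = worse).
- **`actisig.pls`** — bespoke NIPALS PLS1 with autoscaling, and component
  selection by Monte-Carlo resampling (100 random 50/50 train/validation
  splits; the component count with the minimum median validation RMSEP wins,
  ties toward fewer components; a model that cannot beat the mean-only
  predictor is flagged non-predictive).
- **`actisig.signature`** — target projection of the fitted model onto its
  single predictive direction; signed selectivity ratios (explained/residual
  variance per bin, signed by the target-projection loading) with percentile
  confidence intervals over the Monte-Carlo training halves; SD-weighted
  loadings; univariate correlation tables; loading-pattern comparison;
  SED cut-point sensitivity analysis.
- **`actisig.simulate`** — synthetic cohorts with known ground truth and
  calibrated collinearity (adjacent-bin r ≈ 0.9, negative SED-vs-mid-spectrum
  correlations induced by wear-time closure, outcome signal placed on chosen
  bins), plus a semi-Markov bout-process epoch generator for end-to-end tests.
- **`actisig.pipeline` / `actisig.cli`** — orchestration from a YAML config
  with deterministic seeding and full exclusion accounting.

## CLI

```bash
# write a synthetic cohort (spectrum + panel CSV, optional epoch streams)
actisig simulate --out-dir data --n-subjects 841 --n-epoch-subjects 20 --seed 1

# epoch CSV -> per-subject intensity spectra (valid-day filtered)
actisig features --epoch-csv data/epochs.csv --out data/spectrum.csv

# metabolic panel -> derived indices, adjusted outcomes, composite score
actisig outcomes --panel-csv data/panel.csv --out data/outcomes.csv

# component selection + PLS fit for one outcome
actisig fit --spectrum-csv data/spectrum.csv --outcomes-csv data/outcomes.csv \
    --outcome composite --out model.json --seed 1

# selectivity-ratio profile with confidence intervals
actisig signature --spectrum-csv data/spectrum.csv --outcomes-csv data/outcomes.csv \
    --outcome composite --out sr.csv --seed 1

# everything from a config file
actisig run-all --config config.yaml --seed 1 --output-dir results
```

A minimal `config.yaml`:

```yaml
spectrum_csv: data/spectrum.csv   # or epoch_csv: data/epochs.csv
panel_csv: data/panel.csv
output_dir: results
repetitions: 100
seed: 1
per_outcome_models: true
sex_stratified: true
```

Outputs include per-outcome SR profiles (`sr_<outcome>.csv`), selection
curves, model JSON, a univariate correlation table, descriptives, plot-ready
SR data (`sr_plot_data.json`), and a run manifest.

## Library example

```python
from actisig.simulate import CohortConfig, simulate_cohort
from actisig.metabolic import validate_panel, derive_indices, adjust_outcomes, composite_score
from actisig.pls import select_components
from actisig.signature import build_signature

cohort = simulate_cohort(CohortConfig(n_subjects=841), seed=1)
valid, _ = validate_panel(cohort.panel)
y = composite_score(adjust_outcomes(derive_indices(valid)))
X = cohort.features.loc[valid["subject_id"]].to_numpy()

sel = select_components(X, y, repetitions=100, seed=1)
profile = build_signature(X, y, cohort.bin_labels, sel.n_components, seed=2)
print(profile.to_frame())
```
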