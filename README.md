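# stackenc

Stacked ridge encoding models for naturalistic movie fMRI.

Children watching the same movie in the scanner produce grayordinate time
series that can be predicted from the movie's features. When the features
are organised into competing spaces — low- and high-level audio and visual
— a *stacked* encoding model both predicts the response and reports how the
prediction is divided among the spaces. That division is the scientific
quantity of interest in studies of sensory processing differences (for
example, whether autistic viewers weight low-level visual features more
heavily than high-level ones in social-perception regions such as the
pSTS). This package is for researchers who want that full analysis as a
tested, reusable pipeline: per-grayordinate model fitting, variance
partitioning, permutation significance, parcel pooling, noise ceilings,
and parcel-wise mixed-effects group statistics — plus a synthetic-data
generator with known ground truth, so every stage is testable without
access to restricted clinical data.

## The model

For grayordinate *g* with response **y**_g and feature-space designs
**X**_k (HRF-convolved, TR-locked, z-scored), each space gets a ridge
regression fit with 5-fold cross-validation over contiguous time blocks
(penalty chosen per grayordinate by inner 4-fold CV). The per-space
held-out predictions ŷ_k are combined by stacking weights solved as a
convex quadratic program on the probability simplex:

    α̂ = argmin_α ‖y − Σ_k α_k ŷ_k‖²   s.t.  α_k ≥ 0,  Σ_k α_k = 1

so α_k ∈ [0, 1] indexes space *k*'s relative contribution. Derived metrics:

- **R²** — held-out coefficient of determination (stacked and per space);
- **Ru²** — unique explained variance by clipped subtraction
  (component R² clipped to [0, stacked R²]; unique = stacked − clipped);
- **W_H − W_L**, **W_V − W_A** — weight-difference preference indices in
  [−1, 1], positive meaning high-level (or visual) preference.

Grayordinates are tested against a temporal-permutation null (refit on
reordered responses; p = (1 + #{null ≥ obs})/(1 + B)), FDR-corrected
(Benjamini–Hochberg) across the brain, and pooled into parcel means over
significant grayordinates. Parcel metrics are then modelled across
subjects with a linear mixed model — focal predictor (diagnostic group,
SRS/SSS severity, age, or age interactions) plus age, sex, and SES fixed
effects and a site random intercept — with BH correction across parcels.
Motion QC sweeps run exclusion over 40/60/80% thresholds on the fraction
of volumes with framewise displacement above 0.2 mm.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Simulate a cohort with a known 0.3 shift of visual high-vs-low preference
in two designated "pSTS-like" parcels, fit one subject, then run the full
group pipeline:

```python
import numpy as np
from stackenc import SimulationConfig, fit_stacked, simulate_study
from stackenc.group_stats import GroupModelSpec, fit_group_model
from stackenc.pipeline import run_study

config = SimulationConfig(
    n_subjects_per_group=12, n_grayordinates=48, n_parcels=12,
    n_timepoints=400, snr=1.0, group_pref_shift=0.3, seed=7,
)
study = simulate_study(config)
designs = {name: fm.values for name, fm in study.designs.items()}

sid = study.phenotype["subject_id"].iloc[0]
fit = fit_stacked(designs, study.bold[sid].values.T)
truth = study.truths[sid]
print(f"subject {sid}: mean stacked R^2 = {np.nanmean(fit.stacked_r2):.3f}")
print(f"stacking-weight MAE vs ground truth = "
      f"{np.abs(fit.alphas - truth.weights).mean():.3f}")

bold = {s: b.values.T for s, b in study.bold.items()}
summaries = run_study(designs, bold, truth.parcel_labels, n_perm=39, seed=1)
res = fit_group_model(summaries, study.phenotype,
                      GroupModelSpec(metric="pref_high_vs_low_visual"))
print(res[["parcel", "estimate", "p", "q", "significant"]]
      .round(4).to_string(index=False))
```

Output:

```
subject sub-000: mean stacked R^2 = 0.348
stacking-weight MAE vs ground truth = 0.058
parcel  estimate      p      q  significant
   P00   -0.0287 0.1001 0.3565        False
   P01    0.0040 0.8746 0.8746        False
   P02   -0.0113 0.4973 0.8185        False
   P03    0.0103 0.5173 0.8185        False
   P04   -0.0100 0.7102 0.8185        False
   P05    0.0101 0.5953 0.8185        False
   P06   -0.0130 0.5252 0.8185        False
   P07   -0.0079 0.7303 0.8185        False
   P08   -0.0066 0.7503 0.8185        False
   P09   -0.0224 0.1188 0.3565        False
   P10   -0.3225 0.0000 0.0000         True
   P11   -0.3399 0.0000 0.0000         True
```

The mean stacked R² of 0.348 reflects the simulated signal-to-noise ratio
(the ceiling at snr = 1 is 0.5; a short run and 48 grayordinates leave some
estimation loss), and the fitted stacking weights sit within 0.06 of the
generative mixing weights on average. In the group table, only the two
designated parcels (P10, P11) are flagged at q < 0.05, with negative
estimates near −0.3: under the ASD = 1 coding, the fitted group effect
recovers both the magnitude and the localisation of the injected
preference deficit, while the ten unshifted parcels stay null.

## Command line

A thin CLI wraps the same functions:

```bash
stackenc simulate --config config.yaml --out study/
stackenc qc --confounds sub-001.tsv --out qc.tsv
stackenc fit --bold study/bold/sub-000.npy --features study/features --out metrics.tsv
stackenc permute --bold ... --features ... --n-perm 1000 --out perm.tsv
stackenc pool --metrics metrics.tsv --flags perm.tsv --atlas study/atlas.tsv --out parcels.tsv
stackenc group --summaries parcels.tsv --phenotype study/phenotype.tsv \
    --metric pref_high_vs_low_visual --out group.tsv
```

Every command writes a `provenance.json` (version, seed, config hash)
sufficient to regenerate its outputs exactly.

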