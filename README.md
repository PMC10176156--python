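# motorchart

Growth charts of infant motor development from wearable
posture/movement label streams.

## The problem

Multisensor wearables worn by infants during free play at home can
classify, second by second, which gross-motor posture the infant is in
(supine, prone, side, crawl posture, sitting, standing) and how they are
moving within it (still, proto, elementary, fluent, pivot, roll,
transition).  The open question for clinicians and researchers is how to
turn these label streams into a quantitative, trackable measure of motor
development — one that behaves like the familiar physical growth charts of
length, weight and head circumference.

`motorchart` implements that analysis chain for anyone working with
frame-level activity labels from infant wearables:

1. **Stream processing** — 2.3 s frames with 50% overlap (1.15 s hop;
   120 samples and a 60-sample hop at 52 Hz), removal of low-quality and
   carried frames, 10-minute super-segments feeding a binary free-play
   classifier, and retention accounting per recording.
2. **Motor features** — recording-level posture distributions and
   posture-conditioned movement distributions (6 + 6×7 = 48 features).
3. **Developmental age prediction (DAP)** — the expected age (months) given
   a measurement, via Gaussian-process regression of age on the feature
   vector (RBF + white-noise kernel), evaluated leave-one-subject-out so no
   infant trains its own prediction.  The same machinery produces DAP from
   physical growth measures (length / weight / head circumference, alone or
   combined), putting motor and physical measurements in a common currency.
4. **Growth-chart fitting** — a four-parameter logistic mean model

   f(x) = L + (U − L) / (1 + exp(−k(x − x0)))

   of DAP against age, with goodness-of-fit (R² and σ = RMS residual in
   months) at three levels: every measurement (raw), monthly means, and
   ID-controlled (after removing per-subject random intercepts fitted by
   REML).  Bootstrap percentile CIs for all metrics and parameters.
5. **Measurement noise** — recordings with >2 h of playtime are split into
   1-hour epochs; the SD of within-recording DAP differences divided by √2
   estimates the per-epoch noise, with a K–S normality check and an
   age-dependence correlation.
6. **Longitudinal tracking** — within-subject ΔDAP over all recording pairs,
   binned by measurement interval Δage.
7. **Cohort comparison** — per-category Pearson r and MAE between two
   cohorts' monthly category curves, and chart-parameter CI overlap.

Because real infant-wearable cohorts are not public, the package ships a
first-class **synthetic cohort generator** that emulates the statistical
structure these analyses assume — age-dependent categorical posture and
ordinal movement-maturation models, per-subject developmental offsets,
per-session situational noise, frame-to-frame persistence, playtime/carried/
low-quality session structure, and monotone physical growth curves with
random intercepts — and returns the latent ground truth so that every stage
can be validated by parameter recovery.  All generator defaults are
documented in `src/motorchart/defaults.yaml`.

## Worked example

```python
import numpy as np
import pandas as pd
import motorchart as mc

config = mc.SyntheticConfig(n_subjects=25, seed=42)
cohort, truth = mc.generate_motor_cohort(config)

rows, X = [], []
for rec in mc.cohort_sessions(cohort):
    sel = mc.select_analysis_frames(rec)       # quality ∧ not-carried ∧ playtime
    if sel.excluded:                            # under 20 min of playtime
        continue
    feats = mc.compute_features(sel.frames, recording_id=rec.recording_id)
    X.append(mc.flatten_features(feats))
    rows.append((rec.recording_id, rec.subject_id, rec.age_months))
meta = pd.DataFrame(rows, columns=["recording_id", "subject_id", "age_months"])
ds = mc.DAPDataset(np.vstack(X), meta["age_months"].to_numpy(),
                   meta["subject_id"].to_numpy(), meta["recording_id"].to_numpy())

results = mc.loso_cv(ds, seed=0, n_restarts=2)   # leave-one-subject-out DAP
print("recordings analysed:", len(results))
s = mc.evaluate_dap(results)
print(f"LOSO DAP vs age: slope={s['slope']:.2f}, "
      f"RMSE={s['rmse_months']:.2f} months, R^2={s['r2_vs_age']:.2f}")

chart = mc.build_chart(results, "motor", n_boot=300, n_boot_id=120, seed=0)
print(f"4PL fit: L={chart.fit.L:.1f}, U={chart.fit.U:.1f}, "
      f"x0={chart.fit.x0:.1f}, k={chart.fit.k:.2f}")
for name, label in [("raw", "raw:          "), ("monthly_means", "monthly mean: "),
                    ("id_controlled", "ID-controlled: ")]:
    q = chart.quality[name]
    print(f"{label}R^2={q['r2']:.2f}, sigma={q['sigma']:.2f} months")
```

Output:

```
recordings analysed: 94
LOSO DAP vs age: slope=0.92, RMSE=1.18 months, R^2=0.92
4PL fit: L=4.6, U=17.5, x0=11.1, k=0.37
raw:          R^2=0.93, sigma=1.06 months
monthly mean: R^2=0.99, sigma=0.34 months
ID-controlled: R^2=0.97, sigma=0.74 months
```

Reading these numbers: each recording's DAP tracks chronological age with
about 1.2 months of error, of which a part is each infant's own
developmental pace — removing per-subject offsets (ID-controlled) tightens
σ from 1.06 to 0.74 months, and monthly averaging of many infants tightens
the population curve to R² = 0.99.  That is the growth-chart logic:
population curves are very stable while single measurements carry
situational noise.

The same pipeline runs end-to-end from a shell:

```bash
motorchart generate --n-subjects 20 --seed 1 --out cohort/
motorchart run all --out run/ --seed 1
```

`run all` generates two motor cohorts and a physical-growth cohort,
processes streams, fits DAP models, builds charts for five modalities
(motor, length, weight, head circumference, combined physical), estimates
epoch measurement noise, and writes all tables, plots and a manifest of
seeds under the run directory.

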