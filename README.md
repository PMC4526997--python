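# mobisense

Passive mobile-phone sensing features and severity models for depressive
symptoms.

Smartphones passively record where a person goes (GPS) and how they use
their phone (screen on/off events). Clinically, withdrawal from daily
routines — fewer places visited, more time at home, less regular daily
rhythm — tracks depressive-symptom severity as measured by the PHQ-9
questionnaire (0–27; scores ≥ 5 indicate at least mild symptoms).
`mobisense` implements, as a tested and reusable pipeline, the full chain
from raw sensor logs to severity estimates, for researchers in digital
phenotyping and mobile mental health:

1. **I/O and data sufficiency** — CSV location/screen/score logs; a
   participant's stream is analyzed only if it covers more than 50% of
   the study period (5-minute location bins; days-with-any-event for
   usage).
2. **Preprocessing** — each GPS sample is labeled *stationary* or
   *transition* by thresholding its movement speed at 1 km/h; stationary
   samples are clustered into significant places by K-means, increasing
   K from 1 until every cluster's farthest point lies within 500 m of
   its center; the home cluster is the place most visited between
   midnight and 6 a.m.
3. **Features** — per participant:
   - location variance `LV = ln(σ²_lat + σ²_lon)`
   - number of clusters `N`
   - entropy `H = −Σᵢ pᵢ ln pᵢ` over the cluster-occupancy
     distribution `pᵢ`, and normalized entropy `H / ln N`
   - home stay (fraction of stationary time in the home cluster)
   - circadian movement `CM = ln(E_lat + E_lon)`, where `E` is the mean
     Lomb–Scargle power in the 23.5–24.5 h period band of the
     irregularly sampled coordinate series
   - transition time, total distance (km)
   - phone-usage frequency (sessions/day) and duration (s/day), after
     discarding screen sessions shorter than 30 s
4. **Association statistics** — per-feature Pearson correlations with
   PHQ-9, Welch t-tests between the PHQ-9 < 5 and ≥ 5 groups, and the
   feature–feature correlation matrix.
5. **Severity models** — linear score estimation
   `ŷ = a₀ + Σᵢ aᵢFᵢ` and logistic symptom classification
   `P(symptoms) = σ(b₀ + Σᵢ bᵢFᵢ)` with the 0.5 rule, optionally with an
   elastic-net penalty `λ₁‖w‖₁ + λ₂‖w‖₂²` tuned by inner cross-validation;
   evaluated by B bootstrap resamples, each cross-validated
   leave-one-participant-out, reporting mean (SD) accuracy, sensitivity,
   specificity and NRMSD (RMSD / observed score range).

Because no raw cohort data of this kind are publicly deposited, the
package ships a first-class synthetic-cohort generator
(`mobisense.synthetic`) whose behavioral parameters are monotone
functions of a latent severity, so every stage is testable end to end.

## Worked example

```python
import pandas as pd
import mobisense as ms

spec = ms.CohortSpec(n_participants=28, seed=1)   # 14 days, 5-min sampling
records = ms.generate_cohort(spec)                # default severity link
features = ms.feature_table(records, seed=1)
scores = pd.Series({r.participant_id: r.phq9 for r in records})

print(ms.pearson_with_p(features["normalized_entropy"], scores).r)
rep = ms.bootstrap_lopo_evaluate(features, scores,
                                 ["normalized_entropy"], B=1000, seed=1)
print(100 * rep.accuracy_mean, rep.nrmsd_mean)
```

prints (seed 1):

```
-0.9234290101156856
95.19285714285714 0.12198918914116819
```

i.e. on this synthetic cohort normalized entropy correlates −0.92 with
the simulated PHQ-9 score; a logistic classifier on that single feature
identifies participants with symptoms with 95.2% mean accuracy across
1000 bootstrapped leave-one-out runs, and the linear score model's
root-mean-square error is 12.2% of the observed score range. (Synthetic
cohorts plant strong, clean links; real-cohort numbers are lower.)

The same pipeline is scriptable from the shell:

```bash
mobisense simulate-cohort --config config.yaml --out-dir data/ --seed 1
mobisense extract-features --location-dir data/ --screen-dir data/ \
    --scores data/scores.csv --out features.csv
mobisense associate --features features.csv --scores data/scores.csv \
    --out associations.csv
mobisense evaluate --features features.csv --scores data/scores.csv \
    --feature-set normalized_entropy -B 1000 --seed 1 --out report.csv
```

Identical config and seeds reproduce byte-identical CSVs.

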