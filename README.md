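# restalpha

Resting-state EEG alpha-band biomarkers for schizotypy screening: a tested,
reusable implementation of the analysis chain that discriminates high- from
low-schizotypy individuals (HSG vs. LSG) from two minutes of eyes-closed
EEG, together with a synthetic cohort generator that makes every stage
testable without access to human recordings.

## What it computes

From each recording the pipeline extracts a 14-dimensional feature vector
over four regions of interest (left/right × frontal/parieto-occipital
electrode clusters):

- **IAF** — individual alpha frequency: the strict local maximum of the
  Savitzky–Golay-smoothed power spectrum (0.24 Hz resolution, order 5)
  within 7–13 Hz, per ROI.
- **Alpha amplitude** — maximum alpha-band power per ROI in normalized
  power, 10·log₁₀(μV²).
- **wPLI** — weighted phase lag index,
  `|⟨Im S_xy⟩| / ⟨|Im S_xy|⟩` over 2500 ms windows of the cross-spectrum
  at the subject's alpha peak; in [0, 1] and blind to zero-lag
  (volume-conduction) coupling. Three features: left and right
  fronto-posterior (intra-hemispheric) and posterior inter-hemispheric.
- **TLI** — time lag index: the circular-mean cross-spectral phase
  converted to signed milliseconds, `1000·Δφ/(2πf)`; its sign encodes
  which region's phase leads.

Group inference uses 2 × 2 × 2 mixed-design ANOVAs (group × hemisphere ×
region) with partial η² and noncentral-F 90% CIs, planned directional and
paired t-tests with Cohen's *d* and noncentral-t 90% CIs, and Dunn–Šidák
corrected thresholds `1 − (1 − α)^(1/k)`.

Classification runs a tenfold **nested stratified cross-validation**:
the inner loop jointly selects the feature combination (15-entry
catalogue: {left, right, both} × five feature-family sets), the
classifier family (linear C-SVM or L2 logistic regression) and
C ∈ {0.1, 0.2, 0.3} by balanced accuracy; the winner is refit on the
outer training set and scored once on the untouched outer fold.
Standardization is fit on training rows only at every level. Repetitions
(1000 at full scale) yield mean ± SD sensitivity, specificity, balanced
accuracy, AUC, a vertically averaged ROC with a 99.9% CI band, and the
selection-frequency ranking of the feature combinations.

The synthetic generator produces 64-channel, 120 s, 500 Hz eyes-closed
cohorts with subject-specific alpha peaks, a posterior-dominant amplitude
gradient, 1/f background, white sensor noise, and within-hemisphere
fronto-posterior coupling with a signed, configurable lead/lag. The
shipped two-group parameter set reproduces the direction of every
reported group effect (slower/weaker right-posterior alpha, weaker right
intra-hemispheric wPLI, reversed right TLI in the high-schizotypy group).

## Worked example

```python
from restalpha import (default_group_configs, generate_cohort,
                       features_table, t_test, nested_cv)
from restalpha.montage import CLUSTER_14_MONTAGE

hsg_cfg, lsg_cfg = default_group_configs()
recordings, truth = generate_cohort(hsg_cfg, lsg_cfg, n_per_group=24, seed=0,
                                    montage=CLUSTER_14_MONTAGE,
                                    keep_truth_components=True)
features = features_table(recordings, mode="backprojection")

hsg = features[features.group == "HSG"]
lsg = features[features.group == "LSG"]
print(f"right posterior IAF  HSG {hsg.iaf_posterior_R.mean():.2f} Hz, "
      f"LSG {lsg.iaf_posterior_R.mean():.2f} Hz")
res = t_test(lsg.iaf_posterior_R.dropna(), hsg.iaf_posterior_R.dropna(),
             design="independent", tail="one", direction="greater")
print(f"one-tailed t({res.df}) = {res.t:.2f}, p = {res.p:.4f}, d = {res.cohens_d:.2f}")

report = nested_cv(features, n_repeats=10, seed=0)
s = report.summary
print(f"balanced accuracy {100*s['balanced_accuracy_mean']:.1f}% "
      f"({100*s['balanced_accuracy_sd']:.1f}%), AUC {s['auc_mean']:.2f}")
```

prints

```
right posterior IAF  HSG 10.15 Hz, LSG 10.52 Hz
one-tailed t(45) = 1.68, p = 0.0498, d = 0.49
balanced accuracy 79.2% (3.6%), AUC 0.93
```

The high-schizotypy group's right posterior alpha is slower (the
directional t-test uses 45 degrees of freedom because one simulated
subject had no detectable alpha peak and is excluded listwise), the right
intra-hemispheric time lag reverses sign between groups (+7.9 ms HSG vs.
−11.8 ms LSG in this cohort), and the classifier separates the groups
well above chance. The top-ranked feature combinations are dominated by
posterior activity plus intra-hemispheric connectivity.

The same chain is available from the shell:

```sh
restalpha simulate --n-per-group 24 --seed 0 --out cohort/
restalpha extract  --in cohort/ --out features.tsv
restalpha stats    --features features.tsv --out stats/
restalpha classify --features features.tsv --repeats 50 --seed 0 --out cv/
```

Recordings are interchanged as delimited text (channel × time TSV plus a
JSON sidecar); EDF and BrainVision files are read through MNE.

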