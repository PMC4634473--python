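# wristpose

Posture tracking from a wrist-worn IMU. `wristpose` classifies the six
transition movements between sitting, standing and lying (sit→stand,
stand→sit, sit→lie, lie→sit, stand→lie, lie→stand) from short windows of
triaxial accelerometer (±2 g) and gyroscope (±300 °/s) data, while rejecting
a *no movement* class and an *other movement* class of wrist-intensive
activities of daily living (brushing teeth, typing, lifting a cup, ...) that
mimic transitions. The intended users are researchers building remote
health-monitoring pipelines — daily sit/stand/lie occupancy is a proxy for
activity level and frailty — who want the full recognition chain as a
reusable, testable library rather than an on-device app.

## Method

1. **Preprocessing.** A causal 1-s moving-average filter smooths each of the
   six channels on the continuous stream; labeled 5-s windows (500 samples
   at 100 Hz, 50 at 10 Hz) are then cut, centered on the annotation
   midpoint. Streams can be decimated to 50 or 10 Hz to emulate low-power
   sensing.
2. **Feature bank.** 25 statistics per channel over 7 channels (six axes
   plus the acceleration magnitude ‖a‖) give a 175-entry vector per window:
   time-domain moments (min, max, sum, mean, σ, excess kurtosis, skewness,
   variance, median, RMS, IQR, mean pairwise difference, zero/mean crossing
   rates), one-sided DFT amplitude features with the DC bin excluded
   (energy Σ|X_k|, dominant frequency, spectral peak amplitudes and
   spacing, root-sum-of-squares), and triad-level orientation features
   (covariance eigenvalues, gravity/heading correlation, mean intensity,
   mean rotation angle to the gravity estimate).
3. **Feature selection.** Features are ranked by information gain
   IG(x) = H(y) − Σ_b p(b) H(y|b) in bits, over bins from recursive
   entropy-minimizing discretization with the minimum-description-length
   stopping rule; the top k = 30 are kept. The classical 10:1
   samples-to-features rule (20 subjects × 7 unique actions → at most 14
   features for a linear SVM, 28 for a kernel SVM) motivates the budget.
4. **Classifier.** A soft-margin SVM (C = 100, one-vs-one) with the Pearson
   VII universal kernel

   K(u, v) = 1 / [1 + (2·‖u−v‖·√(2^{1/ω} − 1) / σ)²]^ω,  ω = σ = 1,

   on features min-max scaled to [0, 1] from the training data. An RBF
   kernel and the classic ADL baseline feature set (per-axis mean, σ,
   spectral energy + inter-axis correlations, with or without the
   gyroscope) are available for comparison.
5. **Evaluation.** Leave-one-subject-out cross-validation: feature ranking,
   scaling and training see only the training subjects. Per held-out
   subject, per-class precision and recall are averaged with equal class
   weight and combined as F = 2PR/(P+R); the mean F across subjects is the
   headline score. Classified transitions can be folded through a 3-state
   machine into daily sit/stand/lie occupancy summaries.

Because no public dataset accompanies this problem setting, the package
bundles a seeded synthetic study generator: wrist posture changes are
modeled as rotations of the gravity vector between posture-specific
orientations with a raised-cosine angular-velocity profile, plus
subject-level speed/amplitude/pose variation, sensor noise and ADL
confounder oscillations (see `docs/methods.md`).

## Worked example

```python
import wristpose as wp

cfg = wp.SimConfig(n_subjects=5, reps_per_class=5, rate_hz=10, seed=42)
windows = wp.simulate_study(cfg)
M = wp.feature_matrix(windows)

print("windows:", len(windows), "| features per window:", M.shape[1] - 2)
print("top 5 features:", wp.rank_features(M, 5))
print("linear-SVM feature budget (20 subjects, 7 actions):", wp.feature_budget(20, 7))

report = wp.losocv(M, wp.KernelSpec(), k=30)
print(report.summary())
```

prints

```
windows: 200 | features per window: 175
top 5 features: ['std__az', 'variance__az', 'root_sum_squares__az', 'avg_difference__az', 'iqr__az']
linear-SVM feature budget (20 subjects, 7 actions): 14
Leave-one-subject-out cross-validation
  config: {'kernel': 'puk', 'C': 100.0, 'omega': 1.0, 'sigma': 1.0, 'gamma': None, 'k_features': 30, 'discretizer': 'mdl', 'n_subjects': 5}
  subjects: 5
  mean F-score: 0.837

subject  precision  recall  f_score  micro_f  n_windows
    S01   0.791667   0.850 0.819797    0.850         40
    S02   0.829167   0.825 0.827078    0.825         40
    S03   0.852183   0.775 0.811761    0.775         40
    S04   0.950000   0.950 0.950000    0.950         40
    S05   0.755952   0.800 0.777353    0.800         40
```

Each of the five simulated subjects contributes 40 windows (5 repetitions ×
8 classes); every row is that subject's held-out precision/recall/F when the
model is trained on the other four. The mean F of 0.837 at this small
training size rises above 0.95 at the full 20-subject default.

The same pipeline is scriptable from the shell:

```sh
wristpose simulate --config cfg.yaml --out data/
wristpose extract  --data data/ --rate 10 --out features.csv
wristpose rank     --features features.csv --k 30 --out rankings.csv
wristpose evaluate --features features.csv --kernel puk --k 30 --out report.json
wristpose summarize --events events.csv --initial-state stand --span 0 86400 --out summary.csv
```

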