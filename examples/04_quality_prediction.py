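"""Predict session quality from subgroup transition features with LOOCV.

Sessions are bundled into subgroups of 7 (individual sessions are too short
for stable HMM fits); each subgroup's flattened 3x3 transition matrix feeds
a logistic regression evaluated by subgroup-level leave-one-out cross-
validation, repeated over independent subgroup resamplings.
"""

from mihmm import HMMConfig, SyntheticSpec, generate_dataset, loocv_classify

sset = generate_dataset(SyntheticSpec(seed=7))
cfg = HMMConfig(max_iter=60, tol=1e-4)

for design in ("balanced", "imbalanced_3to1"):
    rep = loocv_classify(sset, design=design, n_iterations=5, config=cfg, seed=21)
    print(f"\n{design}: mean accuracy {rep.mean['accuracy']:.3f} "
          f"(sd {rep.sd['accuracy']:.3f}), ROC AUC {rep.mean['roc_auc']:.3f}")
    for cls in ("high", "low"):
        print(f"  {cls}: precision {rep.mean[f'{cls}_precision']:.2f} "
              f"recall {rep.mean[f'{cls}_recall_sensitivity']:.2f} "
              f"specificity {rep.mean[f'{cls}_specificity']:.2f} "
              f"F1 {rep.mean[f'{cls}_f1']:.2f}")
    print("  mean confusion (rows true high/low):",
          [[round(x, 2) for x in row] for row in rep.confusion_mean.tolist()])

print("\nNear-perfect metrics reflect the generator's separated profiles; the")
print("imbalanced design shows the minority (low) class is harder to detect.")
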