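"""Full pipeline: pre-train, fine-tune, pick a cutoff, report metrics.

Uses a strong-effect phantom so the result is interpretable at a
glance: the fine-tuned classifier should approach the oracle. The
cutoff is chosen on validation scores by maximizing Youden's J
(sensitivity + specificity - 1), the recommended operating-point rule
under class imbalance; metrics are then reported on the held-out test
set.
"""

from smoco.evaluate import adaptive_cutoff, classification_report
from smoco.phantom import generate_cohort
from smoco.protocols import (probe_cohort_config, run_pretraining,
                             split_cohort)
from smoco.train import OptimizerConfig, converter_scores, finetune

cohort = generate_cohort(probe_cohort_config(effect_size=3.0, noise_sd=0.1,
                                             seed=11))
train_l, val, test, unl = split_cohort(cohort, seed=11)

run = run_pretraining(train_l + unl, alpha=1.0, seed=11, epochs=5)
clf, hist = finetune(run.networks.query, train_l,
                     OptimizerConfig(epochs=10, batch_size=16), seed=11,
                     val_samples=val)
print(f"fine-tune loss {hist[0]['loss']:.3f} -> {hist[-1]['loss']:.3f}; "
      f"val AUROC {hist[-1].get('val_auroc', float('nan')):.3f}")

cutoff = adaptive_cutoff([s.label for s in val], converter_scores(clf, val))
rep = classification_report([s.label for s in test],
                            converter_scores(clf, test), cutoff)
print(f"cutoff (Youden-J on validation): {cutoff:.3f}")
print(f"test: AUROC {rep.auroc:.3f}, accuracy {rep.accuracy:.3f}, "
      f"sensitivity {rep.sensitivity:.3f}, specificity {rep.specificity:.3f}")
print("  sensitivity = recall on converters (the minority class);",
      "specificity = recall on non-converters.")
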