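"""Pre-train on a phantom cohort and probe representation quality.

Runs a short label-aware pre-training (alpha = 1) and a plain
instance-discrimination run (alpha = 0) on the same small cohort, then
scores both encoders with the k-NN probe (k = 5) on validation
embeddings. Expect noisy single-seed numbers; the package's benchmark
protocol averages over seeds.
"""

import time

from smoco.evaluate import knn_probe_auroc
from smoco.phantom import generate_cohort
from smoco.protocols import probe_cohort_config, run_pretraining, split_cohort

cohort = generate_cohort(probe_cohort_config(seed=3))
train_l, val, test, unl = split_cohort(cohort, seed=3)
print(f"train {len(train_l)} labeled + {len(unl)} unlabeled, "
      f"val {len(val)}, test {len(test)}")

for alpha in (0.0, 1.0):
    t0 = time.time()
    run = run_pretraining(train_l + unl, alpha=alpha, seed=3, epochs=10)
    a = knn_probe_auroc(run.networks.query, train_l, val)
    kind = "label-aware (alpha=1)" if alpha else "instance-only (alpha=0)"
    print(f"{kind}: final loss {run.history[-1]['loss']:.3f}, "
          f"validation k-NN AUROC {a:.3f}  [{time.time() - t0:.0f}s]")
print("AUROC 0.5 = chance ranking of converters; 1.0 = perfect.")
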