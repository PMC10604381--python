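"""The contrastive objective, step by step, on toy embeddings.

Shows the instance-discrimination loss, the label-aware pull term over
a label-carrying memory queue, and their combination, for a couple of
hand-crafted situations where the expected values are easy to reason
about.
"""

import numpy as np

from smoco.contrastive import (ContrastConfig, MemoryQueue, label_loss,
                               moco_loss, smoco_batch_loss)

rng = np.random.default_rng(0)
unit = lambda v: v / np.linalg.norm(v)

# 1) equal similarities: softmax over 4 entries -> loss = ln 4
a = np.array([1.0, 0.0])
print(f"instance loss, 3 negatives, all similarities equal: "
      f"{moco_loss(a, a, [a, a, a], tau=0.5):.4f}  (ln 4 = {np.log(4):.4f})")

# 2) label-aware term: only same-label queue entries are pulled
q = MemoryQueue(capacity=8, dim=2)
q.enqueue(np.stack([a, a, a]), ["converter", "unlabeled", "unlabeled"])
v = label_loss(a, a, q, "converter", tau=0.5)
print(f"label loss, single same-label entry, equal sims: {v:.4f} (ln 4)")
print(f"label loss for an anchor with no same-label entries: "
      f"{label_loss(a, a, q, 'non-converter', tau=0.5):.4f} (by convention 0)")

# 3) combined batch loss with the breakdown the training loop logs
d = 8
anchors = np.stack([unit(rng.normal(size=d)) for _ in range(4)])
positives = np.stack([unit(rng.normal(size=d)) for _ in range(4)])
labels = ["converter", "non-converter", "unlabeled", "converter"]
queue = MemoryQueue(16, d, prefill=True, rng=rng)
queue.enqueue(np.stack([unit(rng.normal(size=d)) for _ in range(6)]),
              ["converter", "converter", "non-converter", "unlabeled",
               "non-converter", "converter"])
loss, br = smoco_batch_loss(anchors, positives, labels, queue,
                            ContrastConfig(alpha=1.0))
print(f"batch loss {br['total']:.4f} = instance {br['instance']:.4f} "
      f"+ alpha * label {br['label']:.4f}")
print("  (unlabeled anchors contribute no label term; queue entries",
      "labeled 'unlabeled' never count as same-label positives)")
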