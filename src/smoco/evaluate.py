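"""Representation probing, imbalance-aware metrics, and 2D embedding.

Representation quality of a frozen encoder is probed with a k-nearest
neighbor classifier (k = 5): each query point is scored by the
fraction of its k nearest labeled reference embeddings that are
converters, and the scores are summarized by AUROC, the appropriate
threshold-free metric under class imbalance. For the fine-tuned
classifier, the operating cutoff is chosen adaptively on validation
scores by maximizing Youden's J = sensitivity + specificity - 1, and
test performance is reported as AUROC / accuracy / sensitivity /
specificity with converter as the positive class.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclasses.dataclass
class MetricsReport:
    """Classification metrics at a stated probability cutoff."""

    auroc: float
    accuracy: float
    sensitivity: float
    specificity: float
    cutoff: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray([1 if l in (1, "converter") else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def knn_probe(reference: np.ndarray, reference_labels, queries: np.ndarray,
              k: int = 5) -> np.ndarray:
    """Converter-fraction score of each query among its k nearest
    reference embeddings (Euclidean; distance ties broken by reference
    index, so scores are deterministic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = np.asarray(reference, dtype=np.float64)
    qry = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if k > ref.shape[0]:
        raise ValueError("k exceeds reference size")
    y = _as_binary(reference_labels)
    d2 = ((qry[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return y[order].mean(axis=1)


def auroc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney U / (n_pos * n_neg),
    distance ties counted one half)."""
    y = _as_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def adaptive_cutoff(labels, scores) -> float:
    """Cutoff maximizing Youden's J on validation data; ties broken
    toward the higher threshold."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    best_j, best_t = -np.inf, None
    for t in _candidate_cutoffs(s):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


def classification_report(labels, scores, cutoff: float) -> MetricsReport:
    """Confusion-matrix metrics at ``cutoff`` (predict converter when
    score >= cutoff) plus threshold-free AUROC."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    pred = s >= cutoff
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    return MetricsReport(
        auroc=auroc(y, s),
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        cutoff=float(cutoff),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()))


def prevalence_cutoff(labels, scores) -> float:
    """Alternative cutoff: the score quantile matching the validation
    converter prevalence."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    prev = (y == 1).mean()
    return float(np.quantile(s, 1.0 - prev))


def aggregate_repeats(reports: Sequence[MetricsReport]
                      ) -> Dict[str, Tuple[float, float]]:
    """Per-metric sample mean and SD (n - 1 denominator) over repeats."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    out = {}
    for metric in ("auroc", "accuracy", "sensitivity", "specificity"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=np.float64)
        out[metric] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def embed_2d(embeddings: np.ndarray, seed: int = 0,
             n_neighbors: int = 15) -> np.ndarray:
    """UMAP projection of embeddings to 2D with a fixed seed."""
    import umap  # deferred: heavy import

    x = np.asarray(embeddings, dtype=np.float64)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 points for a 2D embedding")
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(n_neighbors, x.shape[0] - 1))
    return np.asarray(reducer.fit_transform(x), dtype=np.float64)


def write_embedding_csv(path, coords: np.ndarray, ids: Sequence[str],
                        labels: Sequence[str]) -> None:
    import pandas as pd

    pd.DataFrame({"id": list(ids), "x": coords[:, 0], "y": coords[:, 1],
                  "label": list(labels)}).to_csv(path, index=False)


# -- probe plumbing used by the training loop ---------------------------------

def knn_probe_auroc(network, reference_samples, query_samples,
                    k: int = 5) -> float:
    """k-NN probe AUROC of a frozen network: labeled training
    embeddings as reference, held-out embeddings as queries."""
    from .encoder import forward_embed

    ref = forward_embed(network, np.stack([s.voxels for s in reference_samples]))
    qry = forward_embed(network, np.stack([s.voxels for s in query_samples]))
    scores = knn_probe(ref, [s.label for s in reference_samples], qry, k=k)
    return auroc([s.label for s in query_samples], scores)
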