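"""Label-carrying memory queue, EMA update, and the contrastive losses.

The instance-discrimination (MoCo) loss pulls the positive view of an
image toward its anchor and pushes the queue entries away:

    L_inst = -log exp(za.z+ / tau) / (exp(za.z+ / tau) + sum_k exp(za.zk / tau))

The label-aware loss additionally pulls queue entries that carry the
same conversion label as a labeled anchor. With M_i the same-label
queue subset and Z the full denominator above, the default
"mean-of-logs" form is

    L_label = -(1/|M_i|) sum_{m in M_i} log exp(za.zm / tau) / Z

and the alternative "log-of-mean" form moves the average inside the
logarithm. Anchors whose M_i is empty contribute zero; queue entries
labeled "unlabeled" never enter M_i. The combined objective averages
L_inst + alpha * L_label over the batch, the label term applying to
labeled anchors only.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

LABEL_CODES = {"non-converter": 0, "converter": 1, "unlabeled": -1}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
LABEL_FORMS = ("mean-of-logs", "log-of-mean")


def label_code(label: str) -> int:
    try:
        return LABEL_CODES[label]
    except KeyError:
        raise ValueError(f"unknown label {label!r}") from None


@dataclasses.dataclass
class ContrastConfig:
    """Hyperparameters of the contrastive objective."""

    temperature: float = 0.2
    alpha: float = 1.0
    queue_size: int = 1024
    ema_m: float = 0.95
    label_loss_form: str = "mean-of-logs"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.ema_m < 1.0:
            raise ValueError("ema_m must be in [0, 1)")
        if self.label_loss_form not in LABEL_FORMS:
            raise ValueError(f"label_loss_form must be one of {LABEL_FORMS}")


class MemoryQueue:
    """FIFO ring buffer of (embedding, label) pairs of capacity K.

    ``prefill`` seeds the queue with K random unit vectors labeled
    "unlabeled" so the contrastive denominator is well-conditioned from
    the first step while the same-label subset stays empty until real
    keys arrive.
    """

    def __init__(self, capacity: int, dim: int, prefill: bool = False,
                 rng: Optional[np.random.Generator] = None):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.dim = dim
        self._emb = np.zeros((capacity, dim), dtype=np.float32)
        self._lab = np.full(capacity, LABEL_CODES["unlabeled"], dtype=np.int8)
        self._ptr = 0
        self._len = 0
        if prefill:
            rng = rng or np.random.default_rng(0)
            v = rng.normal(size=(capacity, dim)).astype(np.float32)
            self._emb[:] = v / np.linalg.norm(v, axis=1, keepdims=True)
            self._len = capacity

    def __len__(self) -> int:
        return self._len

    def enqueue(self, embeddings: np.ndarray, labels: Sequence[str | int]) -> None:
        """Append newest-last; evict oldest-first once capacity is hit."""
        emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float32))
        codes = np.array([label_code(l) if isinstance(l, str) else int(l)
                          for l in labels], dtype=np.int8)
        n = emb.shape[0]
        if n != codes.shape[0]:
            raise ValueError("embeddings and labels length mismatch")
        if n > self.capacity:
            raise ValueError(f"batch of {n} exceeds queue capacity {self.capacity}")
        if emb.shape[1] != self.dim:
            raise ValueError(f"embedding dim {emb.shape[1]} != queue dim {self.dim}")
        idx = (self._ptr + np.arange(n)) % self.capacity
        self._emb[idx] = emb
        self._lab[idx] = codes
        self._ptr = int((self._ptr + n) % self.capacity)
        self._len = min(self.capacity, self._len + n)

    def entries(self) -> Tuple[np.ndarray, np.ndarray]:
        """Snapshot (embeddings, label codes) ordered oldest -> newest."""
        if self._len < self.capacity:
            order = np.arange(self._len)
        else:
            order = (self._ptr + np.arange(self.capacity)) % self.capacity
        return self._emb[order].copy(), self._lab[order].copy()

    @property
    def labels(self) -> List[str]:
        return [CODE_LABELS[int(c)] for c in self.entries()[1]]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {"emb": self._emb.copy(), "lab": self._lab.copy(),
                "ptr": np.array(self._ptr), "len": np.array(self._len)}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        self._emb[:] = state["emb"]
        self._lab[:] = state["lab"]
        self._ptr = int(state["ptr"])
        self._len = int(state["len"])


def enqueue(queue: MemoryQueue, embeddings: np.ndarray,
            labels: Sequence[str | int]) -> MemoryQueue:
    queue.enqueue(embeddings, labels)
    return queue


# -- scalar losses -------------------------------------------------------------

def _check_tau(tau: float) -> None:
    if tau <= 0:
        raise ValueError("temperature must be > 0")


def moco_loss(anchor: np.ndarray, positive: np.ndarray,
              negatives: Sequence[np.ndarray], tau: float = 0.2) -> float:
    """Instance-discrimination loss for one anchor (log-sum-exp stable)."""
    _check_tau(tau)
    a = np.asarray(anchor, dtype=np.float64)
    p = np.asarray(positive, dtype=np.float64)
    if a.shape != p.shape:
        raise ValueError("anchor/positive dimension mismatch")
    ap = float(a @ p) / tau
    negs = np.asarray(negatives, dtype=np.float64)
    if negs.size == 0:
        return 0.0
    if negs.ndim == 1:
        negs = negs[None]
    if negs.shape[1] != a.shape[0]:
        raise ValueError("negative dimension mismatch")
    logits = np.concatenate([[ap], negs @ a / tau])
    m = logits.max()
    return float(m + np.log(np.exp(logits - m).sum()) - ap)


def label_loss(anchor: np.ndarray, positive: np.ndarray, queue: MemoryQueue,
               anchor_label: str, tau: float = 0.2,
               label_loss_form: str = "mean-of-logs") -> float:
    """Label-aware pull loss for one labeled anchor against the queue."""
    _check_tau(tau)
    code = label_code(anchor_label)
    if code == LABEL_CODES["unlabeled"]:
        raise ValueError("label_loss requires a labeled anchor; route "
                         "unlabeled anchors around this loss")
    if label_loss_form not in LABEL_FORMS:
        raise ValueError(f"label_loss_form must be one of {LABEL_FORMS}")
    a = np.asarray(anchor, dtype=np.float64)
    p = np.asarray(positive, dtype=np.float64)
    q_emb, q_lab = queue.entries()
    same = q_lab == code
    n_same = int(same.sum())
    if n_same == 0:
        return 0.0
    ap = float(a @ p) / tau
    aq = q_emb.astype(np.float64) @ a / tau
    logits = np.concatenate([[ap], aq])
    m = logits.max()
    log_z = m + np.log(np.exp(logits - m).sum())
    if label_loss_form == "mean-of-logs":
        return float(log_z - aq[same].mean())
    ms = aq[same].max()
    lse_same = ms + np.log(np.exp(aq[same] - ms).sum())
    return float(log_z - lse_same + np.log(n_same))


# -- batched training loss -----------------------------------------------------

def smoco_batch_loss(anchors: Tensor | np.ndarray,
                     positives: np.ndarray,
                     labels: Sequence[str | int],
                     queue: MemoryQueue,
                     config: ContrastConfig) -> Tuple[Tensor, Dict[str, float]]:
    """Combined loss, averaged over the batch, on one queue snapshot.

    ``anchors`` are query-network embeddings (gradient-tracked when
    training); ``positives`` are key-network embeddings (constants).
    Returns the scalar loss and a breakdown with the mean instance and
    label components.
    """
    if not isinstance(anchors, Tensor):
        anchors = Tensor(np.asarray(anchors))
    B = anchors.shape[0]
    if B == 0:
        raise ValueError("empty batch")
    tau = config.temperature
    _check_tau(tau)
    codes = np.array([label_code(l) if isinstance(l, str) else int(l)
                      for l in labels])
    pos = np.asarray(positives, dtype=anchors.data.dtype)
    q_emb, q_lab = queue.entries()
    q_emb = q_emb.astype(anchors.data.dtype)

    ap = ad.tsum(anchors * Tensor(pos), axis=1, keepdims=True) * (1.0 / tau)
    aq = ad.matmul(anchors, Tensor(q_emb.T)) * (1.0 / tau)       # (B, K)
    m = np.maximum(ap.data, aq.data.max(axis=1, keepdims=True)) if q_emb.size \
        else ap.data
    e_ap = ad.exp(ap - Tensor(m))
    z = e_ap
    if q_emb.size:
        z = z + ad.tsum(ad.exp(aq - Tensor(m)), axis=1, keepdims=True)
    log_z = ad.log(z) + Tensor(m)                                 # (B, 1)
    inst = log_z - ap                                             # (B, 1)

    labeled = codes >= 0
    same = (q_lab[None, :] == codes[:, None]) & labeled[:, None] \
        if q_emb.size else np.zeros((B, 0), dtype=bool)
    n_same = same.sum(axis=1, keepdims=True).astype(anchors.data.dtype)
    valid = (n_same > 0)
    if config.label_loss_form == "mean-of-logs":
        sel_sum = ad.tsum(aq * Tensor(same.astype(aq.data.dtype)),
                          axis=1, keepdims=True) if q_emb.size else Tensor(
                              np.zeros((B, 1), dtype=anchors.data.dtype))
        mean_sim = sel_sum * Tensor(np.where(valid, 1.0 / np.maximum(n_same, 1), 0.0)
                                    .astype(anchors.data.dtype))
        lab_term = (log_z * Tensor(valid.astype(anchors.data.dtype))) - mean_sim
    else:  # log-of-mean
        neg_inf_mask = np.where(same, 0.0, -np.inf).astype(np.float64)
        with_mask = aq + Tensor(neg_inf_mask.astype(aq.data.dtype))
        ms = np.where(valid, with_mask.data.max(axis=1, keepdims=True,
                                                initial=-np.inf), 0.0)
        es = ad.exp(with_mask - Tensor(ms.astype(aq.data.dtype)))
        es = es * Tensor(same.astype(aq.data.dtype))   # kill -inf*0 NaNs
        lse_same = ad.log(ad.tsum(es, axis=1, keepdims=True)
                          + Tensor(np.where(valid, 0.0, 1.0)
                                   .astype(aq.data.dtype))) + Tensor(
                                       ms.astype(aq.data.dtype))
        lab_term = (log_z - lse_same + Tensor(np.log(np.maximum(n_same, 1))
                                              .astype(anchors.data.dtype)))
        lab_term = lab_term * Tensor(valid.astype(anchors.data.dtype))

    loss = ad.tmean(inst + lab_term * config.alpha)
    breakdown = {"instance": float(inst.data.mean()),
                 "label": float(lab_term.data.mean()),
                 "total": float(loss.data)}
    return loss, breakdown


# -- EMA -----------------------------------------------------------------------

def ema_update(theta, phi, m: float):
    """phi <- m * phi + (1 - m) * theta, elementwise and in place.

    ``theta``/``phi`` may be single arrays or matching sequences of
    arrays (e.g. parameter lists); returns ``phi``.
    """
    if not 0.0 <= m < 1.0:
        raise ValueError("m must be in [0, 1)")
    single = isinstance(theta, np.ndarray) or np.isscalar(theta)
    thetas = [theta] if single else list(theta)
    phis = [phi] if single else list(phi)
    if len(thetas) != len(phis):
        raise ValueError("theta and phi must have the same length")
    out = []
    for t, p in zip(thetas, phis):
        t = np.asarray(t, dtype=np.float64) if np.isscalar(t) else t
        p = np.asarray(p, dtype=np.float64) if np.isscalar(p) else p
        if np.shape(t) != np.shape(p):
            raise ValueError("theta/phi shape mismatch")
        p[...] = m * p + (1.0 - m) * t
        out.append(p)
    return out[0] if single else out


def ema_update_networks(query, key, m: float) -> None:
    """EMA update of every key-network parameter from the query network."""
    q_params = dict(query.named_parameters())
    k_params = dict(key.named_parameters())
    for name, kp in k_params.items():
        ema_update(q_params[name].data, kp.data, m)
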