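"""Pre-training (momentum-contrastive, optionally label-aware) and
supervised fine-tuning with class-rebalanced mini-batches.

Pre-training follows the momentum-contrast recipe: each step draws a
mini-batch, makes two augmented views per image, embeds anchors with
the query network (gradients on) and positives with the key network
(no gradients), computes the combined contrastive loss against the
label-carrying memory queue, takes an AdamW step on the query
parameters under a half-cosine learning-rate schedule, EMA-updates the
key parameters, and finally enqueues the positives with their labels
("unlabeled" for the unlabeled pool). Unlabeled anchors contribute
only the instance term — no pseudo-labels are ever assigned.

Fine-tuning swaps the projection head for a single-layer softmax
classifier, keeps all layers trainable, and minimizes cross-entropy on
labeled data with every mini-batch rebalanced to 1:1 by oversampling
the minority class. ``supervised_baseline`` runs the same loop from
random initialization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .augment import AugmentationPolicy, make_view_pair
from .contrastive import (ContrastConfig, MemoryQueue, ema_update_networks,
                          smoco_batch_loss)
from .encoder import (Classifier, EncoderSpec, NetworkPair, SMoCoNetwork,
                      build_networks, to_classifier)
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.optim import AdamW
from .volumes import VolumeSample


@dataclasses.dataclass
class OptimizerConfig:
    """AdamW + schedule settings (defaults follow the study protocol:
    lr 1e-4, beta1 0.9, batch 16, 100 pre-train / 10 fine-tune epochs,
    half-cosine decay to zero)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    epochs: int = 100
    batch_size: int = 16
    schedule: str = "half-cosine"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.schedule not in ("half-cosine", "constant"):
            raise ValueError("schedule must be 'half-cosine' or 'constant'")


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """Half-cosine decay: lr0 * 0.5 * (1 + cos(pi * step / total_steps))."""
    if total_steps <= 0:
        raise ValueError("total_steps must be > 0")
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    return lr0 * 0.5 * (1.0 + float(np.cos(np.pi * step / total_steps)))


def _lr_at(step: int, total: int, cfg: OptimizerConfig) -> float:
    if cfg.schedule == "constant":
        return cfg.learning_rate
    return cosine_lr(step, total, cfg.learning_rate)


def _stack_views(samples: Sequence[VolumeSample],
                 policy: AugmentationPolicy) -> Tuple[np.ndarray, np.ndarray]:
    anchors, positives = [], []
    for s in samples:
        a, p = make_view_pair(s.voxels, policy)
        anchors.append(a)
        positives.append(p)
    return (np.stack(anchors)[:, None], np.stack(positives)[:, None])


class PretrainRun:
    """Stateful pre-training loop with checkpoint support."""

    def __init__(self, samples: Sequence[VolumeSample], networks: NetworkPair,
                 queue: MemoryQueue, contrast: ContrastConfig,
                 optimizer: OptimizerConfig,
                 policy: Optional[AugmentationPolicy] = None, seed: int = 0):
        if not samples:
            raise ValueError("empty pre-training dataset")
        if optimizer.batch_size > len(samples):
            raise ValueError("batch_size exceeds dataset size")
        self.samples = list(samples)
        self.networks = networks
        self.queue = queue
        self.contrast = contrast
        self.optimizer_cfg = optimizer
        self.rng = np.random.default_rng(seed)
        self.policy = policy if policy is not None else AugmentationPolicy(
            rng=np.random.default_rng(seed + 1))
        self.opt = AdamW(networks.query.parameters(),
                         lr=optimizer.learning_rate, beta1=optimizer.beta1,
                         beta2=optimizer.beta2,
                         weight_decay=optimizer.weight_decay)
        self.step = 0
        self.epoch = 0
        self.steps_per_epoch = len(self.samples) // optimizer.batch_size
        self.total_steps = self.steps_per_epoch * optimizer.epochs
        self.history: List[Dict] = []
        self._epoch_order: List[int] = []

    def _next_batch(self) -> List[VolumeSample]:
        if not self._epoch_order:
            self._epoch_order = list(self.rng.permutation(len(self.samples)))
        b = self.optimizer_cfg.batch_size
        idx, self._epoch_order = self._epoch_order[:b], self._epoch_order[b:]
        if len(self._epoch_order) < b:
            self._epoch_order = []
        return [self.samples[i] for i in idx]

    def run_step(self) -> Dict[str, float]:
        batch = self._next_batch()
        labels = [s.label for s in batch]
        xa, xp = _stack_views(batch, self.policy)
        self.networks.query.train()
        self.networks.key.train()
        za = self.networks.query(Tensor(xa))
        with ad.no_grad():
            zp = self.networks.key(Tensor(xp)).data
        loss, breakdown = smoco_batch_loss(za, zp, labels, self.queue,
                                           self.contrast)
        self.opt.zero_grad()
        loss.backward()
        self.opt.lr = _lr_at(self.step, self.total_steps, self.optimizer_cfg)
        self.opt.step()
        ema_update_networks(self.networks.query, self.networks.key,
                            self.contrast.ema_m)
        self.queue.enqueue(zp, labels)
        self.step += 1
        breakdown["lr"] = self.opt.lr
        return breakdown

    def run_epoch(self, probe: Optional[Callable[[SMoCoNetwork], float]] = None
                  ) -> Dict:
        stats: List[Dict[str, float]] = [self.run_step()
                                         for _ in range(self.steps_per_epoch)]
        rec = {"epoch": self.epoch,
               "loss": float(np.mean([s["total"] for s in stats])),
               "instance": float(np.mean([s["instance"] for s in stats])),
               "label": float(np.mean([s["label"] for s in stats])),
               "lr": stats[-1]["lr"]}
        if probe is not None:
            rec["probe_auroc"] = float(probe(self.networks.query))
        self.history.append(rec)
        self.epoch += 1
        return rec

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self)

    @classmethod
    def load(cls, path: str | Path, samples: Sequence[VolumeSample]
             ) -> "PretrainRun":
        return load_checkpoint(path, samples)


def pretrain(samples: Sequence[VolumeSample], networks: NetworkPair,
             queue: MemoryQueue, contrast: ContrastConfig,
             optimizer: OptimizerConfig,
             policy: Optional[AugmentationPolicy] = None, seed: int = 0,
             probe: Optional[Callable[[SMoCoNetwork], float]] = None,
             log_path: Optional[str | Path] = None
             ) -> Tuple[NetworkPair, List[Dict]]:
    """Run the full pre-training schedule; returns networks and the
    per-epoch history of loss components (and probe AUROC if given)."""
    run = PretrainRun(samples, networks, queue, contrast, optimizer,
                      policy=policy, seed=seed)
    log = _open_log(log_path)
    for _ in range(optimizer.epochs):
        rec = run.run_epoch(probe=probe)
        _write_log(log, rec)
    _close_log(log)
    return run.networks, run.history


# -- classifier training -------------------------------------------------------

def _class_indices(samples: Sequence[VolumeSample]) -> Dict[str, List[int]]:
    by: Dict[str, List[int]] = {}
    for i, s in enumerate(samples):
        if s.label == "unlabeled":
            raise ValueError("classifier training requires labeled samples only")
        by.setdefault(s.label, []).append(i)
    if len(by) < 2:
        raise ValueError("training set must contain both classes")
    return by


def _train_classifier(clf: Classifier, samples: Sequence[VolumeSample],
                      optimizer: OptimizerConfig, seed: int,
                      val_samples: Optional[Sequence[VolumeSample]] = None,
                      log_path: Optional[str | Path] = None) -> List[Dict]:
    from .evaluate import auroc  # late import to avoid a cycle

    by_class = _class_indices(samples)
    rng = np.random.default_rng(seed)
    b = optimizer.batch_size
    half = max(1, b // 2)
    n_major = max(len(v) for v in by_class.values())
    batches_per_epoch = max(1, int(np.ceil(n_major / half)))
    total_steps = batches_per_epoch * optimizer.epochs
    opt = AdamW(clf.parameters(), lr=optimizer.learning_rate,
                beta1=optimizer.beta1, beta2=optimizer.beta2,
                weight_decay=optimizer.weight_decay)
    classes = sorted(by_class)            # ["converter", "non-converter"]
    targets_of = {"converter": 1, "non-converter": 0}
    log = _open_log(log_path)
    history: List[Dict] = []
    step = 0
    for epoch in range(optimizer.epochs):
        losses = []
        for _ in range(batches_per_epoch):
            idx = np.concatenate([rng.choice(by_class[c], size=half,
                                             replace=True) for c in classes])
            x = np.stack([samples[i].voxels for i in idx])[:, None]
            y = np.array([targets_of[samples[i].label] for i in idx])
            clf.train()
            logits = clf(Tensor(x))
            loss = ad.cross_entropy_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.lr = _lr_at(step, total_steps, optimizer)
            opt.step()
            step += 1
            losses.append(loss.item())
        rec = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": opt.lr}
        if val_samples:
            scores = converter_scores(clf, val_samples)
            y_val = np.array([targets_of[s.label] for s in val_samples])
            if len(set(y_val)) == 2:
                rec["val_auroc"] = float(auroc(y_val, scores))
        history.append(rec)
        _write_log(log, rec)
    _close_log(log)
    return history


def converter_scores(clf: Classifier,
                     samples: Sequence[VolumeSample]) -> np.ndarray:
    """P(converter) for each sample, in evaluation mode."""
    x = np.stack([s.voxels for s in samples])
    return clf.predict_proba(x)[:, 1]


def finetune(network: SMoCoNetwork, train_samples: Sequence[VolumeSample],
             optimizer: Optional[OptimizerConfig] = None, seed: int = 0,
             val_samples: Optional[Sequence[VolumeSample]] = None,
             log_path: Optional[str | Path] = None
             ) -> Tuple[Classifier, List[Dict]]:
    """Fine-tune a pre-trained query network for conversion prediction
    (default 10 epochs); all layers trainable."""
    if optimizer is None:
        optimizer = OptimizerConfig(epochs=10)
    clf = to_classifier(network, 2, seed=seed)
    history = _train_classifier(clf, train_samples, optimizer, seed,
                                val_samples=val_samples, log_path=log_path)
    return clf, history


def supervised_baseline(train_samples: Sequence[VolumeSample],
                        spec: Optional[EncoderSpec] = None,
                        optimizer: Optional[OptimizerConfig] = None,
                        seed: int = 0,
                        val_samples: Optional[Sequence[VolumeSample]] = None,
                        log_path: Optional[str | Path] = None
                        ) -> Tuple[Classifier, List[Dict]]:
    """Train the classifier from random initialization on labeled data
    only (default 100 epochs)."""
    if optimizer is None:
        optimizer = OptimizerConfig(epochs=100)
    spec = spec or EncoderSpec()
    clf = Classifier(spec, 2, rng=np.random.default_rng(seed))
    history = _train_classifier(clf, train_samples, optimizer, seed,
                                val_samples=val_samples, log_path=log_path)
    return clf, history


# -- logging -------------------------------------------------------------------

def _open_log(path):
    return open(path, "a") if path else None


def _write_log(log, rec):
    if log:
        log.write(json.dumps(rec, sort_keys=True) + "\n")


def _close_log(log):
    if log:
        log.close()


# -- checkpoints ---------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, run: PretrainRun) -> None:
    """Serialize networks, queue, optimizer, RNG states and progress."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": run.networks.spec.to_dict(),
        "contrast": dataclasses.asdict(run.contrast),
        "optimizer": dataclasses.asdict(run.optimizer_cfg),
        "step": run.step,
        "epoch": run.epoch,
        "rng_state": run.rng.bit_generator.state,
        "policy_rng_state": run.policy.rng.bit_generator.state,
        "policy": {k: v for k, v in dataclasses.asdict(run.policy).items()
                   if k != "rng"},
        "history": run.history,
        "epoch_order": list(map(int, run._epoch_order)),
    }
    arrays = {}
    for prefix, net in (("q", run.networks.query), ("k", run.networks.key)):
        for n, v in net.state_dict().items():
            arrays[f"{prefix}:{n}"] = v
    for n, v in run.queue.state_dict().items():
        arrays[f"queue:{n}"] = v
    for n, v in run.opt.state_dict().items():
        arrays[f"opt:{n}"] = v
    np.savez(path, meta=np.array(json.dumps(meta, sort_keys=True)), **arrays)


def load_checkpoint(path: str | Path,
                    samples: Sequence[VolumeSample]) -> PretrainRun:
    with np.load(path, allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(str(arrays.pop("meta")))
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    spec = EncoderSpec.from_dict(meta["spec"])
    contrast = ContrastConfig(**meta["contrast"])
    optimizer = OptimizerConfig(**meta["optimizer"])
    networks = build_networks(spec, seed=0)
    networks.query.load_state_dict(
        {n[2:]: v for n, v in arrays.items() if n.startswith("q:")})
    networks.key.load_state_dict(
        {n[2:]: v for n, v in arrays.items() if n.startswith("k:")})
    queue = MemoryQueue(contrast.queue_size, spec.projection_dim)
    queue.load_state_dict(
        {n[6:]: v for n, v in arrays.items() if n.startswith("queue:")})
    policy = AugmentationPolicy(
        crop_scale_range=tuple(meta["policy"]["crop_scale_range"]),
        flip_lr=meta["policy"]["flip_lr"],
        intensity_scale_sd=meta["policy"]["intensity_scale_sd"],
        intensity_shift_sd=meta["policy"]["intensity_shift_sd"],
        noise_sd=meta["policy"]["noise_sd"],
        rng=np.random.default_rng())
    policy.rng.bit_generator.state = meta["policy_rng_state"]
    run = PretrainRun(samples, networks, queue, contrast, optimizer,
                      policy=policy, seed=0)
    run.opt.load_state_dict(
        {n[4:]: v for n, v in arrays.items() if n.startswith("opt:")})
    run.rng.bit_generator.state = meta["rng_state"]
    run.step = meta["step"]
    run.epoch = meta["epoch"]
    run.history = meta["history"]
    run._epoch_order = meta["epoch_order"]
    return run


def save_classifier(path: str | Path, clf: Classifier) -> None:
    meta = {"version": CHECKPOINT_VERSION, "spec": clf.spec.to_dict(),
            "n_classes": clf.n_classes}
    arrays = {f"c:{n}": v for n, v in clf.state_dict().items()}
    np.savez(path, meta=np.array(json.dumps(meta, sort_keys=True)), **arrays)


def load_classifier(path: str | Path) -> Classifier:
    with np.load(path, allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(str(arrays.pop("meta")))
    clf = Classifier(EncoderSpec.from_dict(meta["spec"]), meta["n_classes"],
                     rng=np.random.default_rng(0))
    clf.load_state_dict({n[2:]: v for n, v in arrays.items()})
    return clf
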