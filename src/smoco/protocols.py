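"""Benchmark protocols on the synthetic phantom.

These functions bundle the full study pipeline — cohort generation,
splitting, pre-training, probing, fine-tuning, adaptive-cutoff
evaluation — at desk scale, so representation-quality and
classification experiments are one call each. They are used by the
examples, the reproduction script and the test suite.

The default cohort (16^3 grid, 60 + 60 labeled and 120 unlabeled
images, effect size 1.5, noise SD 0.5) is the package's standard
benchmark condition: large enough for a stable k-NN probe, small
enough that a pre-training run takes minutes on one CPU core.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np

from .contrastive import ContrastConfig, MemoryQueue
from .encoder import EncoderSpec, build_networks
from .evaluate import (MetricsReport, adaptive_cutoff, classification_report,
                       knn_probe_auroc)
from .phantom import PhantomConfig, PhantomCohort, generate_cohort
from .train import (OptimizerConfig, PretrainRun, converter_scores, finetune)
from .volumes import VolumeSample, make_splits


def probe_cohort_config(effect_size: float = 1.5, noise_sd: float = 0.5,
                        seed: int = 0) -> PhantomConfig:
    """Balanced desk-scale cohort used by the benchmark protocols."""
    return PhantomConfig(grid_size=16, n_converter=60, n_nonconverter=60,
                         n_unlabeled=120, images_per_subject=2,
                         effect_size=effect_size, noise_sd=noise_sd,
                         subject_sd=0.2, prevalence_unlabeled=0.5, seed=seed)


def split_cohort(cohort: PhantomCohort, seed: int
                 ) -> Tuple[List[VolumeSample], List[VolumeSample],
                            List[VolumeSample], List[VolumeSample]]:
    """One stratified 80/10/10 split: (train_labeled, val, test, unlabeled)."""
    labeled = [s for s in cohort.samples if s.label != "unlabeled"]
    unlabeled = [s for s in cohort.samples if s.label == "unlabeled"]
    plan = make_splits([s.image_id for s in labeled],
                       [s.image_id for s in unlabeled],
                       labels={s.image_id: s.label for s in labeled},
                       n_repeats=1, base_seed=seed)[0]
    by_id = {s.image_id: s for s in cohort.samples}
    return ([by_id[i] for i in plan.train_labeled],
            [by_id[i] for i in plan.validation],
            [by_id[i] for i in plan.test],
            [by_id[i] for i in plan.train_unlabeled])


def run_pretraining(train_samples: List[VolumeSample], alpha: float,
                    seed: int, epochs: int = 30,
                    spec: Optional[EncoderSpec] = None,
                    batch_size: int = 16) -> PretrainRun:
    """Pre-train a reduced encoder on a sample list; ``alpha=0`` is the
    plain instance-discrimination (MoCo) configuration."""
    spec = spec or EncoderSpec.reduced()
    contrast = ContrastConfig(alpha=alpha)
    optimizer = OptimizerConfig(epochs=epochs, batch_size=batch_size)
    networks = build_networks(spec, seed=seed)
    queue = MemoryQueue(contrast.queue_size, spec.projection_dim, prefill=True,
                        rng=np.random.default_rng(seed + 1))
    run = PretrainRun(train_samples, networks, queue, contrast, optimizer,
                      seed=seed)
    for _ in range(epochs):
        run.run_epoch()
    return run


def probe_experiment(alpha: float, seed: int, epochs: int = 30,
                     cohort_config: Optional[PhantomConfig] = None) -> float:
    """Validation k-NN probe AUROC of a pre-trained encoder.

    Generates the benchmark cohort (cohort seed = ``seed``), pre-trains
    on labeled training + unlabeled images, and probes validation
    embeddings against labeled training embeddings (k = 5).
    """
    cfg = cohort_config or probe_cohort_config(seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    cohort = generate_cohort(cfg)
    train_l, val, _, unl = split_cohort(cohort, seed)
    run = run_pretraining(train_l + unl, alpha, seed, epochs=epochs)
    return knn_probe_auroc(run.networks.query, train_l, val)


def finetune_experiment(seed: int, effect_size: float = 1.5,
                        noise_sd: float = 0.5, alpha: float = 1.0,
                        pretrain_epochs: int = 5, finetune_epochs: int = 10,
                        cohort_config: Optional[PhantomConfig] = None
                        ) -> MetricsReport:
    """Full pipeline to test-set metrics: pre-train, fine-tune, pick the
    Youden-J cutoff on validation, report on test."""
    cfg = cohort_config or probe_cohort_config(
        effect_size=effect_size, noise_sd=noise_sd, seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    cohort = generate_cohort(cfg)
    train_l, val, test, unl = split_cohort(cohort, seed)
    run = run_pretraining(train_l + unl, alpha, seed, epochs=pretrain_epochs)
    clf, _ = finetune(run.networks.query, train_l,
                      OptimizerConfig(epochs=finetune_epochs, batch_size=16),
                      seed=seed, val_samples=val)
    cutoff = adaptive_cutoff([s.label for s in val],
                             converter_scores(clf, val))
    return classification_report([s.label for s in test],
                                 converter_scores(clf, test), cutoff)
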