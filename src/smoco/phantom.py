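"""Synthetic amyloid-PET-like phantom cohorts.

The generator emulates the structure of an MCI conversion cohort
without any real data: an ellipsoidal "brain" of baseline intensity 1
inside a cubic grid, a cortical-shell signal region whose mean
intensity is elevated by an effect size ``delta`` for images drawn from
the converter distribution, a per-subject random intensity offset
shared by all of a subject's images, and i.i.d. voxel noise. A pool of
unlabeled images is drawn from the same two-class mixture; their
generating class is hidden from all training code but recorded for
oracle evaluation in tests.

Default cohort sizes follow the ~1:3 converter:non-converter imbalance
and a roughly equal-sized unlabeled pool of the motivating study,
scaled to desk size.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .volumes import (MANIFEST_COLUMNS, VolumeSample, write_volume)


@dataclasses.dataclass
class PhantomConfig:
    """Cohort and image-model parameters for the phantom generator.

    ``effect_size`` is the dimensionless mean intensity elevation of the
    cortical shell for converter-distribution images; ``noise_sd`` the
    i.i.d. voxel noise SD; ``subject_sd`` the SD of the subject-level
    intensity offset; ``prevalence_unlabeled`` the probability that an
    unlabeled image is drawn from the converter distribution.
    """

    grid_size: int = 16
    n_converter: int = 40
    n_nonconverter: int = 120
    n_unlabeled: int = 110
    images_per_subject: int = 2
    effect_size: float = 1.5
    noise_sd: float = 0.5
    subject_sd: float = 0.2
    prevalence_unlabeled: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.n_converter, self.n_nonconverter, self.n_unlabeled) < 0:
            raise ValueError("image counts must be >= 0")
        if self.n_converter + self.n_nonconverter + self.n_unlabeled == 0:
            raise ValueError("cohort must contain at least one image")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if not 0.0 <= self.prevalence_unlabeled <= 1.0:
            raise ValueError("prevalence_unlabeled must be in [0, 1]")
        if self.images_per_subject < 1:
            raise ValueError("images_per_subject must be >= 1")


@dataclasses.dataclass
class PhantomCohort:
    """Generated samples plus the oracle information hidden from training."""

    samples: List[VolumeSample]
    manifest: pd.DataFrame
    generating_class: Dict[str, str]      # image_id -> converter / non-converter
    brain_mask: np.ndarray
    signal_mask: np.ndarray
    config: PhantomConfig


def brain_and_shell_masks(grid_size: int):
    """Ellipsoidal brain mask and its cortical-shell signal region.

    The shell is the set of voxels whose normalized ellipsoidal radius
    lies in [0.55, 0.75] — a one-parameter, resolution-independent
    stand-in for cortical amyloid deposition.
    """
    g = grid_size
    c = (g - 1) / 2.0
    radii = np.array([0.45, 0.40, 0.45]) * g
    zz, yy, xx = np.meshgrid(*([np.arange(g)] * 3), indexing="ij")
    rho = np.sqrt(((zz - c) / radii[0]) ** 2 + ((yy - c) / radii[1]) ** 2
                  + ((xx - c) / radii[2]) ** 2)
    brain = rho <= 1.0
    shell = (rho >= 0.55) & (rho <= 0.75)
    if not shell.any():
        raise ValueError(f"grid of size {g} too small to contain the signal shell")
    return brain, shell


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a reproducible phantom cohort from ``config.seed``.

    Each image is ``baseline*brain + delta*[converter]*shell +
    subject_offset*brain + noise``; labels follow the configured counts,
    with unlabeled images carrying the marker "unlabeled" while their
    generating class is recorded separately.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    brain, shell = brain_and_shell_masks(cfg.grid_size)
    brain_f = brain.astype(np.float32)
    shell_f = shell.astype(np.float32)

    # plan images: (label marker, generating class) per image
    plan: List[tuple] = (
        [("converter", "converter")] * cfg.n_converter
        + [("non-converter", "non-converter")] * cfg.n_nonconverter)
    n_unl_conv = int(rng.binomial(cfg.n_unlabeled, cfg.prevalence_unlabeled))
    unl_classes = np.array(["converter"] * n_unl_conv
                           + ["non-converter"] * (cfg.n_unlabeled - n_unl_conv))
    rng.shuffle(unl_classes)
    plan += [("unlabeled", c) for c in unl_classes]

    samples: List[VolumeSample] = []
    generating: Dict[str, str] = {}
    rows = []
    img_idx = 0
    sub_idx = 0
    # group images of the same (label, class) stream into subjects
    streams: Dict[tuple, dict] = {}
    for label, true_class in plan:
        key = (label, true_class)
        st = streams.get(key)
        if st is None or st["left"] == 0:
            sub_idx += 1
            st = {"subject": f"sub{sub_idx:04d}",
                  "offset": float(rng.normal(0.0, cfg.subject_sd)),
                  "left": cfg.images_per_subject, "acq": 0}
            streams[key] = st
        delta = cfg.effect_size if true_class == "converter" else 0.0
        noise = rng.normal(0.0, cfg.noise_sd,
                           size=(cfg.grid_size,) * 3).astype(np.float32)
        vox = (brain_f * (1.0 + st["offset"]) + delta * shell_f + noise)
        image_id = f"img{img_idx:04d}"
        sample = VolumeSample(subject_id=st["subject"],
                              acquisition_index=st["acq"], label=label,
                              voxels=vox, image_id=image_id,
                              image_path=f"{image_id}.nii.gz")
        samples.append(sample)
        generating[image_id] = true_class
        rows.append({"image_path": sample.image_path,
                     "subject_id": st["subject"],
                     "acquisition_index": st["acq"], "label": label})
        st["left"] -= 1
        st["acq"] += 1
        img_idx += 1

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return PhantomCohort(samples=samples, manifest=manifest,
                         generating_class=generating, brain_mask=brain,
                         signal_mask=shell, config=cfg)


def mask_mean_scores(cohort: PhantomCohort,
                     samples: List[VolumeSample] | None = None) -> np.ndarray:
    """Oracle statistic: mean intensity inside the known signal shell."""
    samples = cohort.samples if samples is None else samples
    m = cohort.signal_mask
    return np.array([s.voxels[m].mean() for s in samples])


def write_manifest(samples: List[VolumeSample], path: str | Path) -> None:
    """Write the manifest CSV (one row per image)."""
    if not samples:
        raise ValueError("no samples to write")
    rows = [{"image_path": s.image_path or f"{s.image_id}.nii.gz",
             "subject_id": s.subject_id,
             "acquisition_index": s.acquisition_index,
             "label": s.label} for s in samples]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def save_cohort(cohort: PhantomCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes, manifest.csv and a JSON sidecar with the
    config and hidden generating classes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.samples:
        s.image_path = s.image_path or f"{s.image_id}.nii.gz"
        write_volume(s.voxels, out / Path(s.image_path).name)
    write_manifest(cohort.samples, out / "manifest.csv")
    sidecar = {"config": dataclasses.asdict(cohort.config),
               "generating_class": cohort.generating_class}
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out
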