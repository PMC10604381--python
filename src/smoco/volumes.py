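"""Volume and manifest I/O, spatial standardization, and repeated splits.

Images are spatially normalized 3D volumes (e.g. amyloid-PET registered
to a standard atlas) stored as NIfTI. A manifest CSV maps every image
to a subject, an acquisition index and a conversion label. Volumes are
standardized by symmetric zero-padding to a cube followed by
nearest-neighbor resampling to a target side (72 for the full-scale
protocol). Labeled images are split 80/10/10 into train / validation /
test, repeated ``n_repeats`` times with different seeds; every unlabeled
image joins the training pool of every repeat.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

LABELS = ("converter", "non-converter", "unlabeled")
MANIFEST_COLUMNS = ["image_path", "subject_id", "acquisition_index", "label"]


@dataclasses.dataclass
class VolumeSample:
    """One 3D image plus its provenance.

    ``voxels`` may be None for a lazily loadable stub read from a
    manifest; call :meth:`load` to populate it from ``image_path``.
    """

    subject_id: str
    acquisition_index: int
    label: str
    voxels: Optional[np.ndarray] = None
    image_id: str = ""
    image_path: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r} (expected one of {LABELS})")
        if self.voxels is not None:
            self.voxels = np.asarray(self.voxels, dtype=np.float32)
            if not np.isfinite(self.voxels).all():
                raise ValueError("voxels must be finite")

    def load(self) -> np.ndarray:
        if self.voxels is None:
            import nibabel as nib
            self.voxels = np.asarray(
                nib.load(self.image_path).get_fdata(), dtype=np.float32)
        return self.voxels


def write_volume(voxels: np.ndarray, path: str | Path,
                 voxel_size_mm: float = 1.5) -> None:
    """Write a volume as NIfTI with an isotropic voxel size."""
    import nibabel as nib
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), affine),
             str(path))


def read_manifest(path: str | Path, check_files: bool = False) -> List[VolumeSample]:
    """Read a manifest CSV into lazily loadable sample stubs.

    Raises a ``ValueError`` naming the offending row for a missing
    column, an unknown label marker, or (with ``check_files``) a
    missing image file.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    base = Path(path).parent
    samples: List[VolumeSample] = []
    for i, row in df.iterrows():
        if row["label"] not in LABELS:
            raise ValueError(f"row {i}: unknown label {row['label']!r}")
        p = Path(row["image_path"])
        if not p.is_absolute():
            p = base / p
        if check_files and not p.exists():
            raise ValueError(f"row {i}: image file not found: {p}")
        samples.append(VolumeSample(
            subject_id=str(row["subject_id"]),
            acquisition_index=int(row["acquisition_index"]),
            label=str(row["label"]),
            image_id=Path(row["image_path"]).stem.replace(".nii", ""),
            image_path=str(p)))
    return samples


def standardize_volume(voxels: np.ndarray, target_size: int = 72) -> np.ndarray:
    """Zero-pad to a cube, then nearest-neighbor resample to target^3.

    Padding is centered: each axis is padded to the maximum input
    dimension with equal margins and any odd voxel on the trailing
    side. The nearest-neighbor source index for output voxel ``i`` is
    ``floor((i + 0.5) * in / out)`` (voxel-center alignment), so the
    output contains only values present in the padded input.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {voxels.shape}")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    side = max(voxels.shape)
    pads = []
    for n in voxels.shape:
        total = side - n
        pads.append((total // 2, total - total // 2))
    padded = np.pad(voxels, pads)
    if side == target_size:
        return padded
    src = np.floor((np.arange(target_size) + 0.5) * side / target_size).astype(int)
    src = np.clip(src, 0, side - 1)
    return padded[np.ix_(src, src, src)]


@dataclasses.dataclass
class SplitPlan:
    """One repeat of the labeled 80/10/10 split plus the unlabeled pool."""

    repeat_index: int
    seed: int
    train_labeled: List[str]
    validation: List[str]
    test: List[str]
    train_unlabeled: List[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        return cls(**json.loads(text))


def make_splits(labeled_ids: Sequence[str],
                unlabeled_ids: Sequence[str],
                labels: Optional[Dict[str, str]] = None,
                fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                n_repeats: int = 30,
                base_seed: int = 0,
                group_by_subject: bool = False,
                subject_of: Optional[Dict[str, str]] = None,
                stratify: bool = True) -> List[SplitPlan]:
    """Build ``n_repeats`` deterministic train/validation/test plans.

    Fractions apply to labeled images only, rounded toward train; all
    unlabeled ids enter every plan's training pool. With ``stratify``
    (default) the validation/test counts are drawn per class so each
    holds at least one image of every class present. With
    ``group_by_subject`` no subject spans two partitions (``subject_of``
    maps image id -> subject id).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labeled_ids = list(labeled_ids)
    if group_by_subject and subject_of is None:
        raise ValueError("group_by_subject requires subject_of")
    if stratify and labels is None:
        raise ValueError("stratified splitting requires labels")

    plans: List[SplitPlan] = []
    for r in range(n_repeats):
        seed = int(base_seed) + r
        rng = np.random.default_rng(seed)
        if group_by_subject:
            units = sorted({subject_of[i] for i in labeled_ids})
            members = {u: [i for i in labeled_ids if subject_of[i] == u]
                       for u in units}
        else:
            units = list(labeled_ids)
            members = {u: [u] for u in units}

        if stratify and not group_by_subject:
            groups = {}
            for u in units:
                groups.setdefault(labels[u], []).append(u)
            val_u, test_u = [], []
            for cls in sorted(groups):
                ids = np.array(groups[cls])
                rng.shuffle(ids)
                n = len(ids)
                n_val = max(1, int(np.floor(fractions[1] * n)))
                n_test = max(1, int(np.floor(fractions[2] * n)))
                if n_val + n_test >= n:
                    raise ValueError(f"class {cls!r} too small to split")
                val_u += list(ids[:n_val])
                test_u += list(ids[n_val:n_val + n_test])
        else:
            ids = np.array(units)
            rng.shuffle(ids)
            n = len(ids)
            n_val = max(1, int(np.floor(fractions[1] * n)))
            n_test = max(1, int(np.floor(fractions[2] * n)))
            if n_val + n_test >= n:
                raise ValueError("too few labeled units to split")
            val_u = list(ids[:n_val])
            test_u = list(ids[n_val:n_val + n_test])

        val = sorted(i for u in val_u for i in members[u])
        test = sorted(i for u in test_u for i in members[u])
        held = set(val) | set(test)
        train = sorted(i for i in labeled_ids if i not in held)
        if not train or not val or not test:
            raise ValueError("a labeled partition is empty")
        plans.append(SplitPlan(repeat_index=r, seed=seed,
                               train_labeled=train, validation=val, test=test,
                               train_unlabeled=sorted(unlabeled_ids)))
    return plans
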