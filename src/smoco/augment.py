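"""Stochastic 3D augmentation producing anchor / positive views.

The view transform t(.) composes, in order: a random cubic crop of
linear scale u ~ Uniform(crop_scale_range) resized back to the input
side by nearest neighbor, a random left-right flip, a voxelwise affine
intensity jitter a*x + b, and additive Gaussian noise. The family is
adapted to atlas-registered brain volumes: no rotations (images are
aligned), flips only across the left-right axis (brain near-symmetry),
crops center-biased (brains are centered after registration).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

LR_AXIS = 2  # width axis of (depth, height, width) volumes


@dataclasses.dataclass
class AugmentationPolicy:
    """Parameters of the stochastic view transform.

    ``crop_scale_range`` is the interval for the linear crop scale u
    (u = 1 disables cropping); SDs of zero disable the corresponding
    jitter. ``rng`` is the policy's own RNG stream; each augmentation
    call advances it.
    """

    crop_scale_range: Tuple[float, float] = (0.7, 1.0)
    flip_lr: bool = True
    intensity_scale_sd: float = 0.1
    intensity_shift_sd: float = 0.1
    noise_sd: float = 0.05
    rng: Optional[np.random.Generator] = None

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale_range must satisfy 0 < lo <= hi <= 1")
        if min(self.intensity_scale_sd, self.intensity_shift_sd, self.noise_sd) < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.rng is None:
            self.rng = np.random.default_rng()

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationPolicy":
        return cls(crop_scale_range=(1.0, 1.0), flip_lr=False,
                   intensity_scale_sd=0.0, intensity_shift_sd=0.0,
                   noise_sd=0.0, rng=np.random.default_rng(seed))

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "AugmentationPolicy":
        if name == "identity":
            return cls.identity(seed)
        if name == "default":
            return cls(rng=np.random.default_rng(seed))
        raise ValueError(f"unknown augmentation preset {name!r}")


def _nn_resize_cube(vol: np.ndarray, target: int) -> np.ndarray:
    side = vol.shape[0]
    src = np.floor((np.arange(target) + 0.5) * side / target).astype(int)
    src = np.clip(src, 0, side - 1)
    return vol[np.ix_(src, src, src)]


def augment(voxels: np.ndarray, policy: AugmentationPolicy) -> np.ndarray:
    """One stochastic view of a cubic volume; shape is preserved."""
    v = np.asarray(voxels)
    if v.ndim != 3 or len(set(v.shape)) != 1:
        raise ValueError(f"augment expects a cubic volume, got shape {v.shape}")
    rng = policy.rng
    side = v.shape[0]

    lo, hi = policy.crop_scale_range
    u = float(rng.uniform(lo, hi))
    crop = max(1, int(round(u * side)))
    if crop < side:
        # center-biased (triangular) offset over valid positions
        offs = []
        for _ in range(3):
            t = (rng.uniform() + rng.uniform()) / 2.0
            offs.append(int(np.floor(t * (side - crop + 1))))
        z, y, x = (min(o, side - crop) for o in offs)
        v = v[z:z + crop, y:y + crop, x:x + crop]
        v = _nn_resize_cube(v, side)
    if policy.flip_lr and rng.uniform() < 0.5:
        v = np.flip(v, axis=LR_AXIS)
    a = 1.0 + (rng.normal(0.0, policy.intensity_scale_sd)
               if policy.intensity_scale_sd else 0.0)
    b = (rng.normal(0.0, policy.intensity_shift_sd)
         if policy.intensity_shift_sd else 0.0)
    v = a * v + b
    if policy.noise_sd:
        v = v + rng.normal(0.0, policy.noise_sd, size=v.shape)
    return np.ascontiguousarray(v, dtype=np.float32)


def make_view_pair(voxels: np.ndarray,
                   policy: AugmentationPolicy) -> Tuple[np.ndarray, np.ndarray]:
    """Two independent augmented views: (anchor, positive)."""
    return augment(voxels, policy), augment(voxels, policy)
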