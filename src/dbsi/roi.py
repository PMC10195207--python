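"""Lesion ROI quantification and hindered-map classification.

The quantification chain: co-register maps to the anatomical reference
with a supplied rigid transform, select new or enlarging
contrast-enhancing voxels against the most recent prior segmentation,
subsample to every third axial slice, record per-metric mean
intensities over the ROI, and classify the lesion from the hindered
fraction map against surrounding parenchyma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import LabelMap

__all__ = [
    "RigidTransform",
    "apply_rigid",
    "new_enhancement_mask",
    "sample_slices",
    "roi_means",
    "classify_lesion",
    "reference_shell",
    "LesionCall",
]


@dataclass(frozen=True)
class RigidTransform:
    """World-coordinate rigid transform x -> R x + t (ITK convention:
    maps reference/fixed-space points into moving space)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("need a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, mat) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        return cls(mat[:3, :3], mat[:3, 3])

    def as_matrix(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out


def apply_rigid(moving, transform: RigidTransform, reference_shape,
                moving_affine=None, reference_affine=None, order="trilinear"):
    """Resample ``moving`` onto the reference grid under a rigid transform.

    For each reference voxel index i, the sampled location is
    ``inv(A_mov) @ (R @ (A_ref @ i) + t)`` in moving-volume index
    space. Trilinear interpolation for intensity images, nearest
    neighbour for label maps; out-of-field voxels are 0.
    """
    moving = np.asarray(moving, dtype=float)
    if moving.ndim != 3:
        raise ValueError("moving volume must be 3D")
    A_mov = np.eye(4) if moving_affine is None else np.asarray(moving_affine)
    A_ref = np.eye(4) if reference_affine is None else np.asarray(reference_affine)
    T = transform.as_matrix()
    # full index->index map; ndimage wants x_mov = M x_ref + offset
    M = np.linalg.inv(A_mov) @ T @ A_ref
    spline_order = {"trilinear": 1, "nearest": 0}[order]
    return ndimage.affine_transform(
        moving,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(reference_shape),
        order=spline_order,
        mode="constant",
        cval=0.0,
    )


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LabelMap):
        return mask.labels > 0
    return np.asarray(mask).astype(bool)


def new_enhancement_mask(current_lesion, prior_lesion) -> np.ndarray:
    """Voxels of new or enlarging enhancement.

    Per 26-connected component of the current lesion: a component
    qualifies when its voxels are not fully contained in the prior
    segmentation (new if the overlap is empty, enlarging if smaller
    than the component); qualifying components contribute their voxels
    outside the prior. Stable or shrinking components contribute
    nothing, so the output is always a subset of the current mask.
    """
    cur = _as_bool(current_lesion)
    pri = _as_bool(prior_lesion)
    if cur.shape != pri.shape:
        raise ValueError("current and prior masks must share a grid")
    out = np.zeros_like(cur)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(cur, structure=structure)
    for comp in range(1, n + 1):
        comp_mask = labeled == comp
        newly = comp_mask & ~pri
        if newly.any():  # new (no overlap) or enlarging (partial overlap)
            out |= newly
    return out


def sample_slices(mask, stride: int = 3) -> np.ndarray:
    """Retain mask voxels on every ``stride``-th axial slice.

    Slices are kept at z0, z0+stride, ... where z0 is the lowest slice
    containing mask voxels.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    m = _as_bool(mask)
    zs = np.flatnonzero(m.any(axis=(0, 1)))
    if len(zs) == 0:
        raise ValueError("empty mask")
    keep = np.zeros(m.shape[2], dtype=bool)
    keep[zs[0]::stride] = True
    out = m.copy()
    out[:, :, ~keep] = False
    return out


def roi_means(images: dict, roi) -> pd.Series:
    """Mean intensity of each metric image over the ROI, plus voxel count.

    ``images`` maps metric name to a 3D array co-registered to the ROI
    grid. The result is independent of voxel enumeration order.
    """
    m = _as_bool(roi)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty ROI")
    out = {}
    for name, img in images.items():
        img = np.asarray(img)
        if img.shape != m.shape:
            raise ValueError(f"image {name!r} is not on the ROI grid")
        out[name] = float(img[m].mean())
    out["n_voxels"] = n
    return pd.Series(out)


def reference_shell(lesion, exclude=None, inner: int = 2, outer: int = 6,
                    nonrestricted_map=None, csf_threshold: float = 0.8):
    """Surrounding-parenchyma reference: a morphological shell 2-6
    voxels outside the lesion, excluding lesion/prior-lesion voxels and
    (when a nonrestricted map is given) CSF-like voxels."""
    les = _as_bool(lesion)
    grown_outer = ndimage.binary_dilation(les, iterations=outer)
    grown_inner = ndimage.binary_dilation(les, iterations=inner)
    shell = grown_outer & ~grown_inner
    if exclude is not None:
        shell &= ~_as_bool(exclude)
    if nonrestricted_map is not None:
        shell &= np.asarray(nonrestricted_map) <= csf_threshold
    return shell


@dataclass(frozen=True)
class LesionCall:
    """Classification outcome with its margin (lesion minus reference
    mean hindered fraction)."""

    label: str  # treatment_effect | progression | indeterminate
    margin: float
    lesion_mean: float
    reference_mean: float


def classify_lesion(hindered_map, lesion, reference) -> LesionCall:
    """Call treatment effect vs progression from the hindered map.

    Treatment-effect lesions are hyperintense relative to surrounding
    parenchyma on the hindered fraction map, progression lesions
    hypointense; the margin (difference of ROI means) is reported with
    the label and an exact tie is surfaced as ``indeterminate`` rather
    than silently assigned.
    """
    les = _as_bool(lesion)
    ref = _as_bool(reference)
    if not les.any() or not ref.any():
        raise ValueError("lesion and reference must be non-empty")
    if (les & ref).any():
        raise ValueError("lesion and reference masks overlap")
    hm = np.asarray(hindered_map)
    lesion_mean = float(hm[les].mean())
    reference_mean = float(hm[ref].mean())
    margin = lesion_mean - reference_mean
    if margin > 0:
        label = "treatment_effect"
    elif margin < 0:
        label = "progression"
    else:
        label = "indeterminate"
    return LesionCall(label=label, margin=margin, lesion_mean=lesion_mean,
                      reference_mean=reference_mean)
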