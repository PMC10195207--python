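"""Acquisition geometry and image I/O.

Gradient tables follow the FSL bval/bvec dialect: b-values on one
space-separated line (s/mm^2), directions as three rows of components.
Diffusion volumes are NIfTI-1, 4D, with the last axis indexed by the
gradient table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GradientTable",
    "DWIVolume",
    "LabelMap",
    "build_grid_scheme",
    "read_dwi",
    "write_dwi",
]

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class GradientTable:
    """Diffusion directions and b-values, one entry per acquired volume.

    Parameters
    ----------
    directions : (N, 3) array
        Gradient directions. Entries with ``b > 0`` must be unit vectors;
        b=0 entries conventionally carry the zero vector.
    bvalues : (N,) array
        Diffusion weightings in s/mm^2, non-negative.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self):
        dirs = np.asarray(self.directions, dtype=float)
        bvals = np.asarray(self.bvalues, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be an (N, 3) array")
        if bvals.ndim != 1 or len(bvals) != len(dirs):
            raise ValueError("bvalues and directions must have equal length")
        if len(bvals) < 2:
            # a usable table needs at least one b=0 and one DWI entry;
            # model fits impose their own stronger requirements
            raise ValueError("a gradient table needs at least 2 entries")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(bvals == 0):
            raise ValueError("at least one b=0 entry is required")
        norms = np.linalg.norm(dirs[bvals > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("directions with b > 0 must be unit vectors")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def bvalues_ms_um2(self) -> np.ndarray:
        """b-values converted from s/mm^2 to ms/um^2 (divide by 1000)."""
        return self.bvalues / 1000.0


@dataclass
class DWIVolume:
    """4D diffusion-weighted volume on a regular grid.

    ``data`` is indexed (x, y, z, k) with k running over the gradient
    table; ``affine`` maps voxel indices (0-based) to world mm.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-dimensional")
        if self.data.size == 0:
            raise ValueError("DWI data must be non-empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DWI data must be finite")
        if np.any(self.data < 0):
            raise ValueError("DWI data must be non-negative")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class LabelMap:
    """Integer label volume on the grid of a reference DWI volume.

    ``legend`` maps integer labels to roles such as ``lesion``,
    ``prior_lesion``, ``parenchyma_reference``, ``background``.
    """

    labels: np.ndarray
    legend: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-dimensional")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of voxels whose label has the given role."""
        wanted = [lab for lab, r in self.legend.items() if r == role]
        return np.isin(self.labels, wanted)


def grid_lattice_points(r: int) -> np.ndarray:
    """All integer lattice points q with |q|^2 <= r^2 (origin included)."""
    rng = np.arange(-r, r + 1)
    qx, qy, qz = np.meshgrid(rng, rng, rng, indexing="ij")
    pts = np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=1)
    keep = (pts**2).sum(axis=1) <= r * r
    return pts[keep]


def build_grid_scheme(
    r: int,
    b_max: float,
    collapse_antipodal: bool = True,
    n_b0: int = 1,
) -> GradientTable:
    """Build the q-space grid acquisition scheme.

    Enumerates integer lattice points (qx, qy, qz) with
    qx^2 + qy^2 + qz^2 <= r^2. The origin yields the b=0 entry; every
    other point q yields direction q/|q| at b = b_max * |q|^2 / r^2
    (b scales with |q|^2, the q-space convention). Antipodal pairs
    ±q measure the same diffusion attenuation and are collapsed to a
    single entry by default.

    Parameters
    ----------
    r : int
        Grid radius; r=3 gives the 123-point lattice used for DBSI.
    b_max : float
        Maximum b-value in s/mm^2 (reached at |q| = r).
    collapse_antipodal : bool
        Keep one representative per ±q pair (default True).
    n_b0 : int
        Number of b=0 entries to emit.
    """
    if not (isinstance(r, (int, np.integer)) and r >= 1):
        raise ValueError("r must be an integer >= 1")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    if n_b0 < 1:
        raise ValueError("n_b0 must be >= 1")

    pts = grid_lattice_points(r)
    q2 = (pts**2).sum(axis=1)
    pts = pts[q2 > 0]
    q2 = (pts**2).sum(axis=1)

    if collapse_antipodal:
        # canonical representative: first nonzero component positive
        keep = []
        seen = set()
        for p in pts:
            key = tuple(p)
            nz = p[np.nonzero(p)[0][0]]
            canon = tuple(p if nz > 0 else -p)
            if canon not in seen:
                seen.add(canon)
                keep.append(canon)
        pts = np.array(sorted(keep))
        q2 = (pts**2).sum(axis=1)

    dirs = pts / np.sqrt(q2)[:, None]
    bvals = b_max * q2 / (r * r)

    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvalues = np.concatenate([np.zeros(n_b0), bvals])
    return GradientTable(directions=directions, bvalues=bvalues)


def read_gradient_table(path_bval, path_bvec) -> GradientTable:
    """Read FSL-dialect bval/bvec text files."""
    bvals = np.loadtxt(path_bval, ndmin=1).ravel()
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous; FSL convention is 3 rows of N
        bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise ValueError("bval/bvec entry counts do not match")
    norms = np.linalg.norm(bvecs, axis=1)
    bad = (bvals > 0) & (np.abs(norms - 1.0) > _UNIT_TOL)
    if np.any(bad):
        logger.warning("renormalizing %d non-unit bvec rows", int(bad.sum()))
        bvecs[bad] /= norms[bad, None]
    return GradientTable(directions=bvecs, bvalues=bvals)


def write_gradient_table(table: GradientTable, path_bval, path_bvec) -> None:
    with open(path_bval, "w") as fh:
        fh.write(" ".join(f"{b:.6f}" for b in table.bvalues) + "\n")
    with open(path_bvec, "w") as fh:
        for row in table.directions.T:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def read_dwi(path_image, path_bval, path_bvec) -> tuple:
    """Read a 4D NIfTI plus its gradient files.

    Returns ``(DWIVolume, GradientTable)``; raises on a dimension or
    count mismatch.
    """
    img = nib.load(str(path_image))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D")
    table = read_gradient_table(path_bval, path_bvec)
    if data.shape[3] != len(table):
        raise ValueError(
            f"image has {data.shape[3]} volumes but gradient table has {len(table)}"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    vol = DWIVolume(data=data, voxel_size=voxel_size, affine=img.affine)
    return vol, table


def write_dwi(volume: DWIVolume, table: GradientTable, path_image,
              path_bval, path_bvec, path_sidecar=None) -> None:
    """Write a DWI volume as NIfTI plus FSL bval/bvec files.

    Optionally writes a JSON sidecar with scheme metadata.
    """
    if volume.data.shape[3] != len(table):
        raise ValueError("volume 4th axis must match gradient table length")
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(tuple(volume.voxel_size) + (1.0,))
    nib.save(img, str(path_image))
    write_gradient_table(table, path_bval, path_bvec)
    if path_sidecar is not None:
        meta = {
            "n_volumes": len(table),
            "b_max_s_mm2": float(table.bvalues.max()),
            "n_b0": int(table.b0_mask.sum()),
        }
        Path(path_sidecar).write_text(json.dumps(meta, indent=2))


def read_label_map(path, legend=None) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    return LabelMap(labels=np.round(labels).astype(np.int32), legend=legend or {})


def write_label_map(label_map: LabelMap, path, affine=None) -> None:
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(label_map.labels.astype(np.int16), aff), str(path))
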