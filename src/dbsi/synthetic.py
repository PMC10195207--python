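"""Synthetic phantoms and cohorts.

Everything downstream of acquisition is testable without any download:
``make_phantom`` builds multi-shell DWI volumes from the forward model
with Rician noise and matching ground-truth fraction maps;
``make_cohort`` draws per-patient lesion-ROI metric means and
diagnosis timelines with the group structure of a small
progression-vs-treatment-effect study; ``table1_fixture`` returns the
printed 12-patient timing table used by the timing analysis.

Voxel archetypes
----------------
Tissue voxels are mixtures of four compartments with one dominant
tissue class and partial-volume contamination, the regime in which the
band thresholds (1.0 and 1.5 um^2/ms) separate compartment modes:

* white matter  — fiber-dominant (0.5-0.8)
* tumor         — restricted-dominant (0.4-0.7), high cellularity
* edema/necrosis — hindered-dominant (0.5-0.8)
* csf           — free-water-dominant (0.8-1.0)

Compartment diffusivities are drawn within their bands (restricted
0.2-0.6, hindered 1.15-1.35, free 2.0-3.0 um^2/ms; fiber axial 1.2-2.0,
radial 0.1-0.4), not at band edges: physically, the thresholds were
chosen *between* the characteristic diffusivities of cells, edema and
free water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import DWIVolume, GradientTable, LabelMap, build_grid_scheme
from .fit import ParameterMaps, compute_fractions
from .forward import (
    AnisoComponent,
    DBSIParams,
    IsotropicSpectrum,
    add_rician_noise,
    dbsi_signal,
)

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "table1_fixture",
    "random_voxel_params",
    "archetype_params",
    "classification_phantom",
    "true_fractions",
]

DEFAULT_SPECTRUM_GRID = np.round(np.arange(0.0, 3.01, 0.1), 10)

#: (fiber, restricted, hindered, nonrestricted) fraction ranges per archetype
ARCHETYPE_RANGES = {
    "white_matter": ((0.5, 0.8), (0.0, 0.1), (0.05, 0.2), (0.0, 0.1)),
    # enhancing tumor core: densely cellular, little extracellular edema,
    # so its hindered fraction sits below normal parenchyma
    "tumor": ((0.0, 0.15), (0.45, 0.7), (0.0, 0.1), (0.0, 0.15)),
    # treatment-effect lesion: necrosis/vasogenic edema dominate
    "edema": ((0.0, 0.1), (0.0, 0.15), (0.5, 0.8), (0.1, 0.3)),
    # nonenhancing perilesional zone around HGG lesions: mildly
    # edematous parenchyma with residual fibers
    "peritumoral": ((0.1, 0.3), (0.0, 0.1), (0.3, 0.5), (0.15, 0.35)),
    "csf": ((0.0, 0.0), (0.0, 0.1), (0.0, 0.1), (0.8, 1.0)),
}

_D_RANGES = {"restricted": (0.2, 0.6), "hindered": (1.15, 1.35), "free": (2.0, 3.0)}


def _spike_weights(grid, pairs):
    """Distribute (D, weight) pairs onto the grid, splitting off-grid
    diffusivities between the two neighbouring grid points so the
    discretized spectrum represents the same band mass."""
    w = np.zeros(len(grid))
    for D, wt in pairs:
        j = np.searchsorted(grid, D)
        if j <= 0:
            w[0] += wt
        elif j >= len(grid):
            w[-1] += wt
        else:
            a = (grid[j] - D) / (grid[j] - grid[j - 1])
            w[j - 1] += wt * a
            w[j] += wt * (1 - a)
    return w


def archetype_params(archetype: str, rng, grid=None) -> DBSIParams:
    """Draw one voxel's ground-truth parameters for a tissue archetype."""
    if archetype not in ARCHETYPE_RANGES:
        raise ValueError(f"unknown archetype {archetype!r}")
    grid = DEFAULT_SPECTRUM_GRID if grid is None else np.asarray(grid)
    ranges = ARCHETYPE_RANGES[archetype]
    f = np.array([rng.uniform(lo, hi) for lo, hi in ranges])
    f = f / f.sum()
    Ds = [rng.uniform(*_D_RANGES["restricted"]),
          rng.uniform(*_D_RANGES["hindered"]),
          rng.uniform(*_D_RANGES["free"])]
    w = _spike_weights(grid, zip(Ds, f[1:]))
    aniso = ()
    if f[0] > 1e-12:
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        aniso = (
            AnisoComponent(f[0], rng.uniform(1.2, 2.0), rng.uniform(0.1, 0.4), ori),
        )
    return DBSIParams.normalized(aniso, IsotropicSpectrum(grid, w))


def random_voxel_params(rng, grid=None) -> DBSIParams:
    """Draw a random tissue voxel (archetype chosen uniformly)."""
    arch = list(ARCHETYPE_RANGES)[rng.integers(0, len(ARCHETYPE_RANGES))]
    return archetype_params(arch, rng, grid)


def true_fractions(params: DBSIParams):
    """Ground-truth (fiber, restricted, hindered, nonrestricted)."""
    return np.array(compute_fractions(params.iso, params.fiber_fraction))


@dataclass
class LesionSpec:
    """Spherical lesion region.

    ``params`` is either a DBSIParams (homogeneous region) or an
    archetype name (per-voxel heterogeneous draws). ``overwrite``
    allows nesting inside a previously painted region (e.g. a tumor
    core inside its edema collar); unannounced overlaps are an error.
    """

    center: tuple
    radius: float
    params: object
    label: int = 1
    overwrite: bool = False
    clip: bool = False  # context regions (e.g. edema collars) may clip
    # at the volume edge; true lesions must lie inside the grid


@dataclass
class PhantomSpec:
    """A rectangular phantom: background tissue plus spherical lesions.

    ``snr`` is the Rician signal-to-noise ratio at S0 (``np.inf`` for a
    noise-free phantom).
    """

    shape: tuple = (12, 12, 4)
    background: DBSIParams = None
    lesions: list = field(default_factory=list)
    snr: float = np.inf
    seed: int = 0
    scheme_r: int = 3
    b_max: float = 1500.0

    def __post_init__(self):
        for les in self.lesions:
            if les.clip:
                continue
            c, r = np.asarray(les.center), les.radius
            if np.any(c - r < -0.5) or np.any(c + r > np.asarray(self.shape) - 0.5):
                raise ValueError("lesion extends outside the phantom grid")


def _sphere_mask(shape, center, radius):
    idx = np.indices(shape)
    d2 = sum((idx[k] - center[k]) ** 2 for k in range(3))
    return d2 <= radius**2


def make_phantom(spec: PhantomSpec):
    """Synthesize (DWIVolume, GradientTable, LabelMap, ground-truth maps).

    Signals come from the forward model voxel by voxel, with Rician
    noise at ``spec.snr``; the label map marks lesions by their
    ``label`` and background as 0. Deterministic given ``spec.seed``.
    """
    table = build_grid_scheme(spec.scheme_r, spec.b_max)
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    background = spec.background
    if background is None:
        background = "white_matter"

    labels = np.zeros(shape, dtype=np.int32)
    param_of_label = {0: background}
    for les in spec.lesions:
        if les.label <= 0:
            raise ValueError("lesion labels must be positive")
        mask = _sphere_mask(shape, les.center, les.radius)
        conflict = (labels != 0) & mask & (labels != les.label)
        if conflict.any() and not les.overwrite:
            raise ValueError("overlapping lesions with conflicting parameters")
        labels[mask] = les.label
        param_of_label[les.label] = les.params

    data = np.empty(shape + (len(table),))
    truth = {name: np.zeros(shape) for name in ("fiber", "restricted", "hindered",
                                                "nonrestricted")}
    for lab, par in param_of_label.items():
        m = labels == lab
        if isinstance(par, str):
            # heterogeneous region: an independent archetype draw per voxel
            for idx in np.argwhere(m):
                p = archetype_params(par, rng)
                data[tuple(idx)] = dbsi_signal(table, p)
                fr = true_fractions(p)
                for i, name in enumerate(truth):
                    truth[name][tuple(idx)] = fr[i]
        else:
            data[m] = dbsi_signal(table, par)
            fr = true_fractions(par)
            for i, name in enumerate(truth):
                truth[name][m] = fr[i]
    if np.isfinite(spec.snr):
        data = add_rician_noise(data, spec.snr, rng)

    volume = DWIVolume(data=data, voxel_size=np.array([2.0, 2.0, 2.0]),
                       affine=np.diag([2.0, 2.0, 2.0, 1.0]))
    legend = {0: "background"}
    for les in spec.lesions:
        legend[les.label] = "lesion"
    label_map = LabelMap(labels=labels, legend=legend)
    gt_maps = ParameterMaps(
        fiber=truth["fiber"],
        restricted=truth["restricted"],
        hindered=truth["hindered"],
        nonrestricted=truth["nonrestricted"],
        adc=np.zeros(shape),
        fa=np.zeros(shape),
        mask=np.ones(shape, dtype=bool),
        affine=volume.affine,
    )
    return volume, table, label_map, gt_maps


LESION_LABEL = 1
COLLAR_LABEL = 2


def classification_phantom(kind: str, seed: int, shape=(16, 16, 7),
                           radius: float = 2.5, collar_radius: float = 6.5,
                           snr: float = 30.0):
    """Standard lesion phantom for the hindered-map classification task.

    A spherical enhancing lesion (``kind`` = ``treatment_effect`` →
    edema/necrosis archetype; ``progression`` → tumor-core archetype)
    nested in a perilesional mild-edema collar, on a white-matter
    background. All regions draw per-voxel heterogeneous parameters.
    Returns ``(volume, table, label_map, ground_truth_maps)``.
    """
    core = {"treatment_effect": "edema", "progression": "tumor"}[kind]
    spec = PhantomSpec(
        shape=shape,
        background="white_matter",
        lesions=[
            LesionSpec(center=tuple(s // 2 for s in shape), radius=collar_radius,
                       params="peritumoral", label=COLLAR_LABEL, clip=True),
            LesionSpec(center=tuple(s // 2 for s in shape), radius=radius,
                       params=core, label=LESION_LABEL, overwrite=True),
        ],
        snr=snr,
        seed=seed,
    )
    vol, table, label_map, gt = make_phantom(spec)
    label_map.legend = {0: "background", LESION_LABEL: "lesion",
                        COLLAR_LABEL: "parenchyma_reference"}
    return vol, table, label_map, gt


METRICS = (
    "hindered", "restricted", "nonrestricted", "fiber",
    "adc", "fa", "t1w_gd", "t2w", "flair",
)


@dataclass
class CohortSpec:
    """Generative model for a two-group patient cohort.

    Per-metric (mean, sd) pairs per group drive the lesion-ROI metric
    draws; the timing model is surgery-to-DBSI delay (log-normal) plus
    a standard-of-care extra delay that is a point mass at 0 with
    probability ``p_no_extra_delay`` and log-normal otherwise —
    reproducing the observed ties at zero difference.

    Defaults mirror the published group statistics where given
    (hindered 0.17 +/- 0.02 treatment effect vs 0.08 +/- 0.03
    progression); all other metrics default to overlapping
    distributions (no group difference).
    """

    n_treatment_effect: int = 4
    n_progression: int = 5
    group_means: dict = None
    timing_mu: float = np.log(15.0)  # median DBSI delay ~15 weeks post surgery
    timing_sigma: float = 0.35
    p_no_extra_delay: float = 1.0 / 3.0
    extra_mu: float = np.log(15.0)  # median extra SOC delay ~15 weeks
    extra_sigma: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_treatment_effect < 0 or self.n_progression < 0:
            raise ValueError("group counts must be >= 0")
        if self.group_means is None:
            means = {m: ((0.5, 0.1), (0.5, 0.1)) for m in METRICS}
            means["hindered"] = ((0.17, 0.02), (0.08, 0.03))
            means["restricted"] = ((0.30, 0.08), (0.33, 0.08))
            means["nonrestricted"] = ((0.30, 0.08), (0.30, 0.08))
            means["fiber"] = ((0.20, 0.06), (0.22, 0.06))
            means["adc"] = ((1.2, 0.2), (1.2, 0.2))
            means["fa"] = ((0.25, 0.08), (0.25, 0.08))
            self.group_means = means
        for m, ((m1, s1), (m2, s2)) in self.group_means.items():
            if s1 < 0 or s2 < 0:
                raise ValueError(f"negative sd for metric {m}")


def make_cohort(spec: CohortSpec):
    """Draw (records DataFrame, metric table DataFrame) for one cohort.

    The records frame has columns Subject, Diagnosis,
    SurgeryToDBSI_weeks, SurgeryToSOC_weeks; the metric table has one
    column per metric plus Subject/Diagnosis. Deterministic given
    ``spec.seed``; patients are independent draws.
    """
    if spec.n_treatment_effect == 0 and spec.n_progression == 0:
        raise ValueError("cohort needs at least one patient")
    rng = np.random.default_rng(spec.seed)
    rows = []
    metrics_rows = []
    groups = ["treatment_effect"] * spec.n_treatment_effect + [
        "progression"
    ] * spec.n_progression
    for i, diagnosis in enumerate(groups):
        gi = 0 if diagnosis == "treatment_effect" else 1
        dbsi_weeks = float(rng.lognormal(spec.timing_mu, spec.timing_sigma))
        if rng.uniform() < spec.p_no_extra_delay:
            extra = 0.0
        else:
            extra = float(rng.lognormal(spec.extra_mu, spec.extra_sigma))
        soc_weeks = dbsi_weeks + extra
        subject = f"S{i + 1:03d}"
        rows.append(
            dict(Subject=subject, Diagnosis=diagnosis,
                 SurgeryToDBSI_weeks=round(dbsi_weeks, 1),
                 SurgeryToSOC_weeks=round(soc_weeks, 1))
        )
        vals = {
            m: float(rng.normal(*spec.group_means[m][gi])) for m in spec.group_means
        }
        metrics_rows.append(dict(Subject=subject, Diagnosis=diagnosis, **vals))
    records = pd.DataFrame(rows)
    metric_table = pd.DataFrame(metrics_rows)
    return records, metric_table


# The published 12-patient timing table: subject, diagnosis, weeks from
# surgery to DBSI-assisted and to standard-of-care diagnosis, and the
# printed difference. The difference column is carried verbatim rather
# than recomputed: it was derived from unrounded dates, so it can
# differ from the subtraction of the independently rounded times in the
# last decimal (C1-006: printed 20.1 vs 52.3 - 32.1 = 20.2).
_TABLE1_ROWS = [
    ("C1-001", "stable", None, None, None),
    ("C1-002", "excluded", None, None, None),
    ("C1-003", "treatment_effect", 11.3, 11.3, 0.0),
    ("C1-004", "treatment_effect", 23.0, 75.0, 52.0),
    ("C1-005", "treatment_effect", 12.7, 20.4, 7.7),
    ("C1-006", "progression", 32.1, 52.3, 20.1),
    ("C1-007", "treatment_effect", 14.9, 65.6, 50.7),
    ("C1-008", "progression", 16.6, 31.6, 15.0),
    ("C1-009", "progression", 15.7, 23.4, 7.7),
    ("C1-010", "progression", 19.0, 19.0, 0.0),
    ("C1-011", "progression", 12.4, 12.4, 0.0),
    ("C1-012", "stable", None, None, None),
]


def table1_fixture() -> pd.DataFrame:
    """The 12 printed patient rows (including Stable/Excluded with N/A)."""
    return pd.DataFrame(
        _TABLE1_ROWS,
        columns=[
            "Subject",
            "Diagnosis",
            "SurgeryToDBSI_weeks",
            "SurgeryToSOC_weeks",
            "Difference_weeks",
        ],
    )
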