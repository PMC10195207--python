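"""Multi-tensor forward signal model.

A voxel's normalized diffusion signal is a linear combination of
discrete anisotropic (axially symmetric) tensors plus a spectrum of
isotropic tensors:

    S_k/S_0 = sum_i f_i exp(-b_k l_perp_i) exp(-b_k (l_par_i - l_perp_i) cos^2 phi_ik)
              + sum_j f(D_j) exp(-b_k D_j)

with phi_ik the angle between gradient k and the i-th tensor axis.
The isotropic integral over [a, b] is discretized on a diffusivity
grid; the grid weights ARE the discrete signal fractions.

Units: b-values in ms/um^2 internally (1500 s/mm^2 = 1.5 ms/um^2),
diffusivities in um^2/ms, so exponents are dimensionless products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import GradientTable

__all__ = [
    "AnisoComponent",
    "IsotropicSpectrum",
    "DBSIParams",
    "aniso_signal",
    "iso_signal",
    "dbsi_signal",
    "add_rician_noise",
    "add_gaussian_noise",
]

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class AnisoComponent:
    """One axially symmetric anisotropic tensor component.

    fraction : signal-intensity fraction in [0, 1]
    lambda_par, lambda_perp : axial/radial diffusivity, um^2/ms
    orientation : unit 3-vector (principal axis)
    """

    fraction: float
    lambda_par: float
    lambda_perp: float
    orientation: np.ndarray

    def __post_init__(self):
        ori = np.asarray(self.orientation, dtype=float)
        if ori.shape != (3,):
            raise ValueError("orientation must be a 3-vector")
        if abs(np.linalg.norm(ori) - 1.0) > _UNIT_TOL:
            raise ValueError("orientation must be a unit vector")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.lambda_perp < 0 or self.lambda_par < self.lambda_perp:
            raise ValueError("need lambda_par >= lambda_perp >= 0")
        object.__setattr__(self, "orientation", ori)


@dataclass(frozen=True)
class IsotropicSpectrum:
    """Non-negative weights f(D) on an increasing diffusivity grid (um^2/ms)."""

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if grid.ndim != 1 or grid.shape != weights.shape:
            raise ValueError("grid and weights must be equal-length 1D arrays")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if grid[0] < 0:
            raise ValueError("diffusivities must be non-negative")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)

    @property
    def total(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class DBSIParams:
    """Full voxel parameterization: anisotropic components + isotropic spectrum.

    A normalized voxel has fractions summing to 1 (checked to 1e-6).
    """

    aniso: tuple
    iso: IsotropicSpectrum

    def __post_init__(self):
        object.__setattr__(self, "aniso", tuple(self.aniso))
        total = self.total_fraction
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {total:.8f}")

    @property
    def total_fraction(self) -> float:
        return sum(c.fraction for c in self.aniso) + self.iso.total

    @property
    def fiber_fraction(self) -> float:
        return sum(c.fraction for c in self.aniso)

    @staticmethod
    def normalized(aniso, iso: IsotropicSpectrum) -> "DBSIParams":
        """Build params rescaling all fractions to sum to 1."""
        aniso = tuple(aniso)
        total = sum(c.fraction for c in aniso) + iso.total
        if total <= 0:
            raise ValueError("total fraction must be positive")
        aniso = tuple(
            AnisoComponent(c.fraction / total, c.lambda_par, c.lambda_perp,
                           c.orientation)
            for c in aniso
        )
        iso = IsotropicSpectrum(iso.grid, iso.weights / total)
        return DBSIParams(aniso=aniso, iso=iso)


def _to_ms_um2(b):
    """Convert b from s/mm^2 to ms/um^2."""
    return np.asarray(b, dtype=float) / 1000.0


def aniso_signal(b_ms_um2, grad_dir, comp: AnisoComponent):
    """Unit-fraction signal of one anisotropic tensor.

    exp(-b l_perp) * exp(-b (l_par - l_perp) cos^2 phi), with
    cos phi = grad_dir . orientation. `b_ms_um2` is in ms/um^2.
    Vectorized over b / grad_dir leading axes.
    """
    b = np.asarray(b_ms_um2, dtype=float)
    g = np.asarray(grad_dir, dtype=float)
    scalar = b.ndim == 0 and g.ndim == 1
    b = np.atleast_1d(b)
    g = np.atleast_2d(g)
    norms = np.linalg.norm(g, axis=1)
    nonzero_b = b > 0
    if np.any(np.abs(norms[nonzero_b] - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit vectors")
    cos2 = (g @ comp.orientation) ** 2
    out = np.exp(-b * comp.lambda_perp) * np.exp(
        -b * (comp.lambda_par - comp.lambda_perp) * cos2
    )
    return float(out[0]) if scalar else out


def iso_signal(b_ms_um2, D):
    """Unit-weight isotropic tensor signal exp(-b D)."""
    b = np.asarray(b_ms_um2, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(b < 0) or np.any(D < 0):
        raise ValueError("b and D must be non-negative")
    out = np.exp(-b * D)
    return float(out) if out.ndim == 0 else out


def dbsi_signal(table: GradientTable, params: DBSIParams,
                auto_normalize: bool = False) -> np.ndarray:
    """Normalized signals S_k/S_0 for every entry of the gradient table.

    Requires normalized params (fractions summing to 1); pass
    ``auto_normalize=True`` to rescale instead of raising.
    """
    if abs(params.total_fraction - 1.0) > 1e-6:
        if auto_normalize:
            params = DBSIParams.normalized(params.aniso, params.iso)
        else:
            raise ValueError("params are not normalized; fractions must sum to 1")
    b = table.bvalues_ms_um2
    dirs = table.directions
    signal = np.zeros(len(table))
    for comp in params.aniso:
        cos2 = (dirs @ comp.orientation) ** 2
        signal += comp.fraction * np.exp(
            -b * (comp.lambda_perp + (comp.lambda_par - comp.lambda_perp) * cos2)
        )
    # discretized spectrum: weight-per-gridpoint sum
    signal += np.exp(-np.outer(b, params.iso.grid)) @ params.iso.weights
    return signal


def add_rician_noise(signals, snr: float, seed) -> np.ndarray:
    """Corrupt magnitude signals with Rician noise.

    Returns sqrt((s + n1)^2 + n2^2) with n1, n2 ~ N(0, 1/snr),
    the magnitude-MR noise model for S_0-normalized data.
    `seed` may be an int or a numpy Generator.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(signals, dtype=float)
    sigma = 1.0 / snr
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def add_gaussian_noise(signals, snr: float, seed) -> np.ndarray:
    """Additive Gaussian alternative (sd = 1/snr), floored at 0."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(signals, dtype=float)
    return np.maximum(s + rng.normal(0.0, 1.0 / snr, size=s.shape), 0.0)
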