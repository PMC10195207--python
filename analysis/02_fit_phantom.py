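"""Fit fraction maps on a noise-free phantom and tabulate recovery error.

The forward-inverse round trip on a small noise-free phantom is the
basic correctness check of the spectral fit: every voxel's fitted
fiber/restricted/hindered/nonrestricted fraction is compared with the
generating value.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dbsi.fit import FitConfig, fit_map
from dbsi.synthetic import classification_phantom


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    vol, table, labels, gt = classification_phantom(
        "treatment_effect", seed=args.seed, snr=np.inf, shape=(10, 10, 5),
        radius=2.0, collar_radius=4.5,
    )
    mask = np.ones(vol.shape3d, dtype=bool)
    maps = fit_map(vol, table, mask, FitConfig())

    rows = []
    for name in ("fiber", "restricted", "hindered", "nonrestricted"):
        err = np.abs(maps.as_dict()[name] - gt.as_dict()[name])
        rows.append(dict(metric=name, mae=float(err.mean()), max_err=float(err.max())))
    table_df = pd.DataFrame(rows)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table_df.to_csv(out / "phantom_fit_error.csv", index=False)
    print("noise-free phantom round trip (per-voxel fraction recovery):")
    print(table_df.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
    overall = table_df["mae"].mean()
    print(f"overall mean absolute error {overall:.5f} (expected < 0.02)")


if __name__ == "__main__":
    main()
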