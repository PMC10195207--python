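"""Simulate lesion phantoms and write them to disk.

Builds one treatment-effect and one progression phantom (spherical
lesion in a perilesional edema collar on white-matter background,
Rician noise at SNR 30), writes the DWI volumes, gradient files and
label maps under scratch/ (binary imaging data) and a ground-truth
summary under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dbsi import write_dwi
from dbsi.acquisition import write_label_map
from dbsi.synthetic import COLLAR_LABEL, LESION_LABEL, classification_phantom


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--snr", type=float, default=30.0)
    ap.add_argument("--scratch", default="scratch/phantoms")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    scratch = Path(args.scratch)
    scratch.mkdir(parents=True, exist_ok=True)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    summary = {}
    for kind in ("treatment_effect", "progression"):
        vol, table, labels, gt = classification_phantom(
            kind, seed=args.seed, snr=args.snr
        )
        stem = scratch / kind
        write_dwi(vol, table, f"{stem}.nii.gz", f"{stem}.bval", f"{stem}.bvec",
                  path_sidecar=f"{stem}.json")
        write_label_map(labels, f"{stem}_labels.nii.gz", affine=vol.affine)
        lesion = labels.labels == LESION_LABEL
        collar = labels.labels == COLLAR_LABEL
        summary[kind] = {
            "n_lesion_voxels": int(lesion.sum()),
            "n_collar_voxels": int(collar.sum()),
            "gt_hindered_lesion": float(gt.hindered[lesion].mean()),
            "gt_hindered_collar": float(gt.hindered[collar].mean()),
            "snr": args.snr,
            "n_volumes": len(table),
        }
        print(
            f"{kind}: lesion {lesion.sum()} voxels, ground-truth hindered "
            f"{summary[kind]['gt_hindered_lesion']:.3f} vs collar "
            f"{summary[kind]['gt_hindered_collar']:.3f}"
        )

    (out / "phantom_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote DWI + labels under {scratch}/ and summary to {out}/phantom_summary.json")


if __name__ == "__main__":
    main()
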