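"""Simulate the synthetic working-memory cohort and write it to disk.

Generates a two-condition cohort of subjects whose sensor data arise from
two coupled oscillatory source patches (anterior driver, posterior
receiver; unidirectional saturating coupling anterior -> posterior), and
stores one HDF5 file per subject under scratch/cohort/ together with the
shared head model and the ground truth.

Usage: python analysis/01_simulate_cohort.py [--subjects N] [--seed S]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from srcconn.io import save_epochs
from srcconn.synthetic import CohortSpec, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def simulate(n_subjects: int, seed: int, out_dir: Path) -> None:
    spec = CohortSpec(n_subjects=n_subjects, n_trials=20, n_samples=768,
                      snr_db=5.0)
    hm, cohort = generate_cohort(spec, seed=seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(
        out_dir / "head_model.npz",
        sensor_positions=hm.sensor_positions,
        grid_positions=hm.grid_positions,
        grid_spacing=hm.grid_spacing,
        leadfield=hm.leadfield,
    )
    for rec in cohort:
        for cond, ep in rec["epochs"].items():
            save_epochs(out_dir / f"{rec['subject_id']}_{cond}.h5", ep,
                        rec["ground_truth"])
    meta = {
        "n_subjects": n_subjects,
        "seed": seed,
        "conditions": list(spec.conditions),
        "fs": spec.fs,
        "snr_db": spec.snr_db,
        "true_source_centers": [
            int(v) for v in cohort[0]["ground_truth"].source_voxel_indices
        ],
    }
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))
    print(f"wrote {n_subjects} subjects x {len(spec.conditions)} conditions "
          f"to {out_dir}")
    print(f"true source patch centers (grid indices): "
          f"{meta['true_source_centers']}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--subjects", type=int, default=12,
                    help="cohort size (full study scale is 50; 12 is desk scale)")
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()
    simulate(args.subjects, args.seed, args.out)
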