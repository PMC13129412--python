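"""Shared loader for the simulated cohort written by 01_simulate_cohort."""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np

from srcconn.containers import HeadModel
from srcconn.io import load_epochs, load_ground_truth

ROOT = Path(__file__).resolve().parents[1]
# HDF5 epochs are bulky binaries: they live under scratch/, while the
# derived tables and cluster JSON go to results/
COHORT_DIR = ROOT / "scratch" / "cohort"


def load_cohort(cohort_dir: Path = COHORT_DIR):
    """Load (head_model, cohort records, meta); simulate first if absent."""
    if not (cohort_dir / "cohort.json").exists():
        print("cohort not found; running 01_simulate_cohort.py first")
        subprocess.run(
            [sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")],
            check=True,
        )
    meta = json.loads((cohort_dir / "cohort.json").read_text())
    hm_npz = np.load(cohort_dir / "head_model.npz")
    hm = HeadModel(
        sensor_positions=hm_npz["sensor_positions"],
        grid_positions=hm_npz["grid_positions"],
        grid_spacing=float(hm_npz["grid_spacing"]),
        leadfield=hm_npz["leadfield"],
    )
    cohort = []
    for s in range(meta["n_subjects"]):
        sid = f"sub-{s + 1:03d}"
        rec = {"subject_id": sid, "epochs": {}}
        for cond in meta["conditions"]:
            path = cohort_dir / f"{sid}_{cond}.h5"
            rec["epochs"][cond] = load_epochs(path)
            rec["ground_truth"] = load_ground_truth(path)
        cohort.append(rec)
    return hm, cohort, meta
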