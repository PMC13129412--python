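"""Group-level inference on the normalized connectivity table.

Tests the planted anterior -> posterior asymmetry (paired t with
Benjamini-Hochberg correction across contrasts, per measure) and compares
average network connectivity between conditions, mirroring the structure
of the source-connectivity analyses the pipeline implements.

Usage: python analysis/05_group_stats.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from srcconn.connectivity import ConnectivityResult
from srcconn.group_stats import (
    asymmetry_tests,
    average_network_connectivity,
    paired_compare,
)

from _cohort import ROOT


def table_to_cohort(df: pd.DataFrame):
    cohort = []
    for sid, sub in df.groupby("subject"):
        rec = {}
        for cond, cc in sub.groupby("condition"):
            K = int(max(cc["source"].max(), cc["target"].max())) + 1
            lcs = np.zeros((K, K))
            ncs = np.zeros((K, K))
            for _, row in cc.iterrows():
                mat = lcs if row["measure"] == "lcs" else ncs
                mat[int(row["target"]), int(row["source"])] = row["value"]
            rec[cond] = ConnectivityResult(
                lcs=lcs, ncs=ncs, normalized=True, condition=cond,
                subject_id=sid,
            )
        cohort.append(rec)
    return cohort


def main() -> None:
    path = ROOT / "results" / "connectivity.csv"
    if not path.exists():
        raise SystemExit(
            "results/connectivity.csv not found - run "
            "analysis/04_connectivity.py first"
        )
    df = pd.read_csv(path)
    cohort = table_to_cohort(df)
    conditions = list(cohort[0].keys())
    K = cohort[0][conditions[0]].K
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]

    rows = []
    print(f"{len(cohort)} subjects, {K} regions, conditions {conditions}")
    for measure in ("lcs", "ncs"):
        print(f"--- directional asymmetry ({measure}) ---")
        for t in asymmetry_tests(cohort, pairs, measure=measure):
            print(f"  {t.comparison}: t({t.df}) = {t.t:.2f}, p = {t.p:.4g}, "
                  f"p_fdr = {t.p_fdr:.4g}, d = {t.d:.2f}")
            rows.append({"family": "asymmetry", "measure": measure,
                         "comparison": t.comparison, "t": t.t, "df": t.df,
                         "p": t.p, "p_fdr": t.p_fdr, "d": t.d, "n": t.n})
        avg = {
            cond: np.array([
                average_network_connectivity(rec[cond], measure)
                for rec in cohort
            ])
            for cond in conditions
        }
        cmp = paired_compare(avg[conditions[0]], avg[conditions[1]],
                             label=f"{measure} avg-net {conditions[0]} vs "
                                   f"{conditions[1]}")
        print(f"  {cmp.comparison}: t({cmp.df}) = {cmp.t:.2f}, "
              f"p = {cmp.p:.4g} (means "
              f"{avg[conditions[0]].mean():.3f} vs "
              f"{avg[conditions[1]].mean():.3f})")
        rows.append({"family": "average_network", "measure": measure,
                     "comparison": cmp.comparison, "t": cmp.t, "df": cmp.df,
                     "p": cmp.p, "p_fdr": cmp.p_fdr, "d": cmp.d, "n": cmp.n})
    dest = ROOT / "results" / "group_stats.csv"
    pd.DataFrame(rows).to_csv(dest, index=False)
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
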