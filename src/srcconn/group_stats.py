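"""Cohort-level inference on normalized directed connectivity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityResult, Measure


@dataclass
class GroupStatsResult:
    """One paired contrast: t, two-sided p, BH-adjusted p, paired Cohen's d."""

    comparison: str
    t: float
    df: int
    p: float
    p_fdr: float
    d: float
    n: int


def _paired_t(diff: np.ndarray) -> tuple[float, float, float]:
    """t, two-sided p and paired Cohen's d for a vector of differences."""
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, 0.0
        # zero-variance nonzero shift: t undefined / unbounded
        return np.inf * np.sign(diff.mean()), 0.0, np.inf * np.sign(diff.mean())
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), float(diff.mean() / sd)


def asymmetry_tests(
    cohort: Sequence[dict[str, ConnectivityResult]],
    pairs: Sequence[tuple[int, int]],
    measure: Measure = "ncs",
) -> list[GroupStatsResult]:
    """Directional-asymmetry t-tests with Benjamini-Hochberg correction.

    For each directed pair (i, j) and each condition, tests forward (j -> i
    read as region j to region i: here the contrast is value[i, j] minus
    value[j, i], i.e. (j -> i) vs (i -> j)) across subjects with a paired
    two-sided t-test.  Positive t means stronger forward than reverse
    transfer.  BH adjustment spans the whole family of contrasts in the
    call (all pairs x conditions for one band and measure).  Masked
    (non-significant) connections enter as their stored zeros.
    """
    if len(cohort) < 3:
        raise ValueError("at least 3 subjects required")
    conditions = list(cohort[0].keys())
    for rec in cohort:
        if list(rec.keys()) != conditions:
            raise ValueError("all subjects must share the same conditions")
        for r in rec.values():
            if not r.normalized:
                raise ValueError("asymmetry_tests expects normalized results")

    results: list[GroupStatsResult] = []
    pvals: list[float] = []
    for cond in conditions:
        values = np.stack([rec[cond].values(measure) for rec in cohort])
        for (i, j) in pairs:
            diff = values[:, i, j] - values[:, j, i]
            t, p, d = _paired_t(diff)
            results.append(
                GroupStatsResult(
                    comparison=(
                        f"{measure} {cond}: ({j}->{i}) vs ({i}->{j})"
                    ),
                    t=t, df=len(diff) - 1, p=p, p_fdr=np.nan,
                    d=d, n=len(diff),
                )
            )
            pvals.append(p)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, pa in zip(results, p_adj):
        r.p_fdr = float(pa)
    return results


def average_network_connectivity(
    result: ConnectivityResult, measure: Measure = "ncs"
) -> float:
    """Mean of all non-self directed values (masked entries count as 0)."""
    if result.K < 2:
        raise ValueError("need at least 2 regions")
    offdiag = ~np.eye(result.K, dtype=bool)
    return float(result.values(measure)[offdiag].mean())


def paired_compare(
    values_a: np.ndarray, values_b: np.ndarray, label: str = ""
) -> GroupStatsResult:
    """Single planned paired comparison of per-subject scalars (no FDR)."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.shape != values_b.shape:
        raise ValueError("paired inputs must have equal length and order")
    n = len(values_a)
    if n < 3:
        raise ValueError("at least 3 subjects required")
    diff = values_a - values_b
    t, p, d = _paired_t(diff)
    return GroupStatsResult(
        comparison=label or "a vs b", t=t, df=n - 1, p=p, p_fdr=p, d=d, n=n
    )
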