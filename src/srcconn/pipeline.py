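"""End-to-end orchestration: configuration, import dialects and the full
sensor-to-group analysis."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as _io
from .beamform import (
    dbscan_cluster,
    contrast_map,
    dics_common_filter,
    dics_power,
    extract_virtual_series,
    lcmv_common_filter,
    select_top_voxels,
)
from .connectivity import (
    TrainConfig,
    apply_significance,
    concatenate_trials,
    connectivity_measures,
    fit_nmvar_ann,
    normalize_subject,
    select_model_order,
    time_shift_surrogates,
)
from .containers import HeadModel, SensorEpochs
from .group_stats import (
    asymmetry_tests,
    average_network_connectivity,
    paired_compare,
)
from .spectral import (
    cluster_permutation_test,
    compute_csd,
    compute_tfr,
    min_csd_window,
    sensor_neighbors,
)

logger = logging.getLogger("srcconn")


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, with field-standard defaults.

    Bands are theta (4-7 Hz) and alpha (8-12 Hz); contrast windows are the
    band-specific intervals guaranteeing three cycles of the lowest band
    frequency ([0.2, 0.95] s theta, [0.6, 1.0] s alpha) and the
    connectivity window is [0, 1] s.  Beamformer: 5% regularization, top 2%
    voxel selection, DBSCAN eps 1.5 x grid spacing with minimum 3 voxels.
    Connectivity: surrogate count 100 at q = 0.05.  CBPT: 500 permutations
    at two-sided alpha 0.05.
    """

    bands: dict = field(
        default_factory=lambda: {"theta": (4.0, 7.0), "alpha": (8.0, 12.0)}
    )
    contrast_windows: dict = field(
        default_factory=lambda: {"theta": (0.2, 0.95), "alpha": (0.6, 1.0)}
    )
    connectivity_window: tuple = (0.0, 1.0)
    beamformer: dict = field(
        default_factory=lambda: {
            "reg_fraction": 0.05,
            "top_fraction": 0.02,
            "eps_factor": 1.5,
            "min_pts": 3,
        }
    )
    connectivity: dict = field(
        default_factory=lambda: {
            "p_max": 10,
            "hidden_units": 10,
            "n_surrogates": 100,
            "q": 0.05,
            "max_iter": 200,
        }
    )
    cbpt: dict = field(
        default_factory=lambda: {
            "n_perm": 500,
            "alpha": 0.05,
            "neighbor_radius": 0.4,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, band in self.bands.items():
            lo, hi = band
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r} must be well-ordered: {band}")
            window = self.contrast_windows.get(name)
            if window is None:
                raise ValueError(f"no contrast window for band {name!r}")
            dur = window[1] - window[0]
            need = min_csd_window(band)
            if dur < need - 1e-12:
                raise ValueError(
                    f"contrast window {window} for band {name!r} is shorter "
                    f"than the 3-cycle minimum {need:.3f} s"
                )
        if self.connectivity_window[1] <= self.connectivity_window[0]:
            raise ValueError("connectivity window must be well-ordered")
        for key in ("reg_fraction", "top_fraction"):
            v = self.beamformer[key]
            if not 0 < v <= 1:
                raise ValueError(f"beamformer {key} must be in (0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["connectivity_window"] = tuple(raw["connectivity_window"])
        raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        raw["contrast_windows"] = {
            k: tuple(v) for k, v in raw["contrast_windows"].items()
        }
        return cls(**raw)


def read_epochs(
    path: str | Path,
    format: str = "repo-hdf5",
    **kwargs,
) -> SensorEpochs:
    """Import epoched sensor data from a named dialect.

    ``repo-hdf5`` is the canonical layout written by the synthetic module;
    ``delimited`` is long-format text (see io.read_delimited_epochs, which
    needs a side-car sensor-position table); ``edf`` requires an EDF reader
    (pyEDFlib or mne), which is not available in this installation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "repo-hdf5":
        return _io.load_epochs(path)
    if format == "delimited":
        return _io.read_delimited_epochs(path, **kwargs)
    if format == "edf":
        raise _io.FormatError(
            "EDF import needs an EDF reader (pyEDFlib or mne), which is not "
            "installed; convert to the delimited or HDF5 dialect instead"
        )
    raise ValueError(f"unknown format {format!r}")


def _band_window_power(
    epochs: SensorEpochs,
    band: tuple[float, float],
    window: tuple[float, float],
) -> np.ndarray:
    """Trial-averaged power per sensor, averaged over band and window."""
    freqs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1e-9)
    win_len = max(min_csd_window(band), 0.25)
    tfr = compute_tfr(
        epochs, freqs, window_length=win_len, step=0.05, average_trials=True
    )
    tmask = (tfr.times >= window[0] - win_len / 2 - 1e-9) & (
        tfr.times <= window[1] + win_len / 2 + 1e-9
    )
    if not tmask.any():
        tmask = np.ones_like(tfr.times, dtype=bool)
    return tfr.power[0][:, :, tmask].mean(axis=(1, 2))


def run_pipeline(
    config: PipelineConfig,
    cohort: Sequence[dict],
    hm: HeadModel,
    out_dir: str | Path | None = None,
    bands: Sequence[str] | None = None,
) -> dict:
    """Run the full analysis on a cohort and return the results bundle.

    ``cohort`` is a sequence of subject records as produced by
    ``synthetic.generate_cohort``: each has ``subject_id`` and an
    ``epochs`` dict mapping the two condition labels to SensorEpochs.

    Per band the stages are: sensor band-power CBPT; CSD and common DICS
    filter (pooled over subjects and conditions); per-condition source
    power, contrast map, top-fraction selection and DBSCAN clustering
    (activity clusters per condition pool, contrast clusters from the
    signed difference); LCMV virtual series per activity cluster;
    group-level model-order selection; per-subject ANN fits, connectivity
    measures, time-shifted surrogate masking and subject normalization;
    and group asymmetry and average-network statistics.
    """
    if len(cohort) < 2:
        raise ValueError("at least 2 subjects required for group stages")
    t_start = time.time()
    conditions = list(cohort[0]["epochs"].keys())
    if len(conditions) != 2:
        raise ValueError("pipeline expects exactly two conditions")
    band_names = list(bands) if bands is not None else list(config.bands)
    rng_master = np.random.SeedSequence(config.seed)
    bundle: dict = {
        "config": json.loads(config.to_json()),
        "conditions": conditions,
        "bands": {},
        "log": {"started": t_start},
    }

    for bi, band_name in enumerate(band_names):
        band = config.bands[band_name]
        cwin = config.contrast_windows[band_name]
        stage = f"band {band_name}"
        try:
            out = _run_band(
                config, cohort, hm, band_name, band, cwin, conditions,
                rng_master.spawn(1)[0],
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
        bundle["bands"][band_name] = out

    bundle["log"]["elapsed_s"] = time.time() - t_start
    if out_dir is not None:
        _write_bundle(bundle, cohort, hm, Path(out_dir))
    return bundle


def _run_band(
    config: PipelineConfig,
    cohort: Sequence[dict],
    hm: HeadModel,
    band_name: str,
    band: tuple[float, float],
    cwin: tuple[float, float],
    conditions: list[str],
    seq: np.random.SeedSequence,
) -> dict:
    bm = config.beamformer
    cc = config.connectivity
    seeds = seq.generate_state(16) % 2**31
    out: dict = {"band": band}

    # --- sensor-level band power and CBPT -------------------------------
    logger.info("[%s] sensor power and cluster permutation test", band_name)
    power = {
        cond: np.stack([
            _band_window_power(
                rec["epochs"][cond].select_condition(cond), band, cwin
            )
            for rec in cohort
        ])
        for cond in conditions
    }
    graph = sensor_neighbors(
        hm.sensor_positions, config.cbpt["neighbor_radius"]
    )
    cbpt = cluster_permutation_test(
        power[conditions[0]], power[conditions[1]], graph,
        n_perm=config.cbpt["n_perm"], alpha=config.cbpt["alpha"],
        seed=int(seeds[0]),
    )
    out["cbpt"] = {
        "clusters": [
            {
                "sensors": c["sensors"].tolist(),
                "sign": c["sign"],
                "mass": c["mass"],
                "p": c["p"],
            }
            for c in cbpt.clusters
        ],
        "n_permutations": cbpt.n_permutations,
    }

    # --- CSD, common DICS filter, power maps, clusters -------------------
    logger.info("[%s] DICS source localization", band_name)
    csd_by_cond = {}
    for cond in conditions:
        csds = [
            compute_csd(rec["epochs"][cond].select_condition(cond), band, cwin)
            for rec in cohort
        ]
        pooled = sum(c.csd * c.n_trials_used for c in csds) / sum(
            c.n_trials_used for c in csds
        )
        csd_by_cond[cond] = type(csds[0])(
            csd=0.5 * (pooled + pooled.conj().T), band=tuple(band),
            window=tuple(cwin),
            n_trials_used=sum(c.n_trials_used for c in csds),
        )
    filters = dics_common_filter(
        list(csd_by_cond.values()), hm, bm["reg_fraction"]
    )
    maps = {
        cond: dics_power(filters, csd_by_cond[cond], condition=cond)
        for cond in conditions
    }
    contrast = contrast_map(maps[conditions[0]], maps[conditions[1]])

    acs_by_cond = {}
    for cond in conditions:
        top = select_top_voxels(maps[cond], bm["top_fraction"])
        acs_by_cond[cond] = dbscan_cluster(
            top, hm, bm["eps_factor"], bm["min_pts"], kind="activity"
        )
    top_c = select_top_voxels(contrast, bm["top_fraction"])
    ccs = dbscan_cluster(
        top_c, hm, bm["eps_factor"], bm["min_pts"], kind="contrast",
        signs=np.sign(contrast.nai[top_c]),
    )
    # shared activity clusters for connectivity: pooled across conditions
    pooled_map = maps[conditions[0]]
    pooled_nai = 0.5 * (maps[conditions[0]].nai + maps[conditions[1]].nai)
    pooled_map = type(pooled_map)(
        nai=pooled_nai, raw_power=pooled_nai, condition="pooled",
        band=tuple(band), window=tuple(cwin),
    )
    acs = dbscan_cluster(
        select_top_voxels(pooled_map, bm["top_fraction"]),
        hm, bm["eps_factor"], bm["min_pts"], kind="activity",
    )
    for i, c in enumerate(acs):
        c.label = f"AC{i + 1}"
    out["activity_clusters"] = acs
    out["activity_clusters_by_condition"] = acs_by_cond
    out["contrast_clusters"] = ccs
    out["source_maps"] = maps
    out["contrast_map"] = contrast
    if len(acs) < 2:
        warnings.warn(
            f"band {band_name}: fewer than 2 activity clusters; "
            "connectivity stage skipped", stacklevel=2,
        )
        return out

    # --- LCMV virtual series --------------------------------------------
    logger.info("[%s] LCMV virtual time series", band_name)
    lcmv = {}
    for rec in cohort:
        eps = [rec["epochs"][c].select_condition(c) for c in conditions]
        filt = lcmv_common_filter(
            eps, hm, config.connectivity_window, bm["reg_fraction"]
        )
        lcmv[rec["subject_id"]] = {
            cond: extract_virtual_series(
                filt, ep, acs, band, config.connectivity_window
            )
            for cond, ep in zip(conditions, eps)
        }

    # --- group-level model order ----------------------------------------
    pooled_series = []
    for rec in cohort:
        for cond in conditions:
            s, b = concatenate_trials(lcmv[rec["subject_id"]][cond])
            pooled_series.append(s)
    group = np.concatenate(pooled_series, axis=1)
    n_trial_samples = lcmv[cohort[0]["subject_id"]][conditions[0]].data.shape[2]
    group_bounds = np.arange(group.shape[1] // n_trial_samples) * n_trial_samples
    order = select_model_order(group, group_bounds, cc["p_max"])
    out["order_selection"] = order
    p = order.p_opt
    logger.info("[%s] group model order p = %d", band_name, p)

    # --- per-subject connectivity ----------------------------------------
    train_cfg = TrainConfig(max_iter=cc["max_iter"])
    per_subject: list[dict] = []
    for si, rec in enumerate(cohort):
        sid = rec["subject_id"]
        masked = {}
        for ci, cond in enumerate(conditions):
            vs = lcmv[sid][cond]
            series, bounds = concatenate_trials(vs)
            fit_seed = int((seeds[1] + 7919 * si + 104729 * ci) % 2**31)
            model = fit_nmvar_ann(
                series, bounds, p, cc["hidden_units"],
                train_cfg=train_cfg, seed=fit_seed,
            )
            res = connectivity_measures(
                model, series, bounds, condition=cond, band=band,
                subject_id=sid,
            )
            null = time_shift_surrogates(
                vs, p, cc["hidden_units"], cc["n_surrogates"],
                seed=int((seeds[2] + 7919 * si + 104729 * ci) % 2**31),
                train_cfg=train_cfg,
            )
            masked[cond] = apply_significance(res, null, cc["q"])
        a, b = normalize_subject((masked[conditions[0]], masked[conditions[1]]))
        per_subject.append({conditions[0]: a, conditions[1]: b})
    out["connectivity"] = per_subject

    # --- group statistics -------------------------------------------------
    K = len(acs)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    out["asymmetry"] = {
        measure: asymmetry_tests(per_subject, pairs, measure=measure)
        for measure in ("lcs", "ncs")
    }
    out["average_network"] = {}
    for measure in ("lcs", "ncs"):
        avg = {
            cond: np.array([
                average_network_connectivity(rec[cond], measure)
                for rec in per_subject
            ])
            for cond in conditions
        }
        out["average_network"][measure] = {
            "per_subject": avg,
            "condition_compare": paired_compare(
                avg[conditions[0]], avg[conditions[1]],
                label=f"{measure} {conditions[0]} vs {conditions[1]} ({band_name})",
            ),
        }
    return out


def _write_bundle(bundle: dict, cohort, hm, out_dir: Path) -> None:
    """Persist the serializable parts of a results bundle."""
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(bundle["config"], sort_keys=True, indent=2)
    )
    rows = []
    stat_rows = []
    for band_name, res in bundle["bands"].items():
        if "contrast_clusters" in res:
            _io.clusters_to_json(
                res["contrast_clusters"],
                out_dir / f"contrast_clusters_{band_name}.json",
            )
            _io.clusters_to_json(
                res["activity_clusters"],
                out_dir / f"activity_clusters_{band_name}.json",
            )
            _io.source_map_to_table(
                res["contrast_map"], hm,
                out_dir / f"contrast_map_{band_name}.csv",
            )
        for rec in res.get("connectivity", []):
            for cond, r in rec.items():
                for i in range(r.K):
                    for j in range(r.K):
                        if i == j:
                            continue
                        for measure in ("lcs", "ncs"):
                            rows.append({
                                "subject": r.subject_id,
                                "band": band_name,
                                "condition": cond,
                                "source": j,
                                "target": i,
                                "measure": measure,
                                "value": float(r.values(measure)[i, j]),
                                "significant": bool(
                                    r.significant[measure][i, j]
                                ) if r.significant else True,
                            })
        for measure, tests in res.get("asymmetry", {}).items():
            for t in tests:
                stat_rows.append({
                    "band": band_name, "measure": measure,
                    "comparison": t.comparison, "t": t.t, "df": t.df,
                    "p": t.p, "p_fdr": t.p_fdr, "d": t.d, "n": t.n,
                })
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "connectivity.csv", index=False)
    if stat_rows:
        pd.DataFrame(stat_rows).to_csv(out_dir / "group_stats.csv", index=False)
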