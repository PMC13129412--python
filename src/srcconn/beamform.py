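"""Source localization: DICS/LCMV beamforming, top-voxel selection,
density-based source clustering and virtual time-series extraction.

Conventions fixed here (the literature leaves them open): filters are
computed from the real part of the (pooled) cross-spectral density, source
orientation is scalar (one leadfield row per voxel), pooling across
conditions is trial-count weighted, and cluster averaging sign-aligns
voxel series to the cluster's strongest voxel to undo the beamformer's
per-voxel sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal
from sklearn.cluster import DBSCAN

from .containers import HeadModel, SensorEpochs
from .spectral import CSDMatrix


@dataclass
class SpatialFilterSet:
    """Unit-gain beamformer filters, one row of weights per voxel."""

    weights: np.ndarray               # (N_v, N_s)
    regularization_fraction: float
    head_model: HeadModel

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        gains = np.einsum("vs,vs->v", self.weights, self.head_model.leadfield)
        if not np.allclose(gains, 1.0, atol=1e-8):
            raise ValueError("unit-gain constraint violated")


@dataclass
class SourcePowerMap:
    """Per-voxel beamformer power; ``nai`` is noise-normalized.

    ``kind='power'`` maps are nonnegative; ``kind='contrast'`` maps hold a
    signed difference of two noise-normalized maps.
    """

    nai: np.ndarray
    raw_power: np.ndarray
    condition: str
    band: tuple[float, float]
    window: tuple[float, float]
    kind: Literal["power", "contrast"] = "power"

    def __post_init__(self) -> None:
        self.nai = np.asarray(self.nai, dtype=float)
        self.raw_power = np.asarray(self.raw_power, dtype=float)
        if not np.all(np.isfinite(self.nai)):
            raise ValueError("nai contains non-finite values")
        if self.kind == "power" and np.any(self.nai < 0):
            raise ValueError("noise-normalized power must be nonnegative")


@dataclass
class VoxelCluster:
    """A spatially contiguous group of selected voxels (AC or CC)."""

    member_voxel_indices: np.ndarray
    centroid: np.ndarray
    kind: Literal["activity", "contrast"] = "activity"
    sign: Literal["A>B", "B>A", "n/a"] = "n/a"
    label: str = ""

    def __post_init__(self) -> None:
        self.member_voxel_indices = np.asarray(
            sorted(self.member_voxel_indices), dtype=int
        )
        self.centroid = np.asarray(self.centroid, dtype=float)

    @property
    def size(self) -> int:
        return len(self.member_voxel_indices)


@dataclass
class VirtualSeries:
    """Band-passed, cluster-averaged source time courses per trial."""

    data: np.ndarray                  # (trials, K_clusters, samples)
    fs: float
    band: tuple[float, float]
    window: tuple[float, float]
    condition: str
    cluster_refs: list[VoxelCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x clusters x samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def _unit_gain_filters(
    C_real: np.ndarray, hm: HeadModel, reg_fraction: float
) -> np.ndarray:
    """w_v = (l C_r^-1 l^T)^-1 l C_r^-1 for every leadfield row l."""
    if reg_fraction < 0:
        raise ValueError("reg_fraction must be >= 0")
    n_s = C_real.shape[0]
    lam = reg_fraction * np.trace(C_real) / n_s
    C_r = C_real + lam * np.eye(n_s)
    L = hm.leadfield
    try:
        CiLT = np.linalg.solve(C_r, L.T)       # (N_s, N_v)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase reg_fraction"
        ) from exc
    denom = np.einsum("vs,sv->v", L, CiLT)
    if np.any(np.abs(denom) < 1e-300):
        raise np.linalg.LinAlgError(
            "degenerate leadfield/covariance pair; increase reg_fraction"
        )
    return CiLT.T / denom[:, None]


def dics_common_filter(
    csd_by_condition: Sequence[CSDMatrix],
    hm: HeadModel,
    reg_fraction: float = 0.05,
) -> SpatialFilterSet:
    """Common DICS spatial filter from condition CSDs pooled by trial count.

    The pooled CSD is the trial-count-weighted mean of the condition CSDs;
    filters are built from its real part with diagonal loading
    ``lambda = reg_fraction * trace / N_s`` and satisfy unit gain at every
    voxel by construction.
    """
    if not csd_by_condition:
        raise ValueError("need at least one CSD")
    band = csd_by_condition[0].band
    window = csd_by_condition[0].window
    for c in csd_by_condition[1:]:
        if c.band != band or c.window != window:
            raise ValueError("all CSDs must share band and window")
    weights_n = np.array([c.n_trials_used for c in csd_by_condition], dtype=float)
    pooled = sum(
        w * c.csd for w, c in zip(weights_n, csd_by_condition)
    ) / weights_n.sum()
    W = _unit_gain_filters(pooled.real, hm, reg_fraction)
    return SpatialFilterSet(
        weights=W, regularization_fraction=reg_fraction, head_model=hm
    )


def dics_power(
    filters: SpatialFilterSet,
    csd: CSDMatrix,
    condition: str = "",
) -> SourcePowerMap:
    """Source power through a common filter, normalized by projected noise.

    ``raw_power[v] = Re(w_v C w_v^H)``; the spatially inhomogeneous noise
    model projects an isotropic noise floor at the smallest eigenvalue of
    Re(C) through the filter: ``noise[v] = lambda_min |w_v|^2``.  The neural
    activity index ``nai = raw_power / noise`` cancels the beamformer's
    depth-dependent gain.
    """
    W = filters.weights
    if W.shape[1] != csd.csd.shape[0]:
        raise ValueError("filters and CSD disagree on sensor count")
    C = csd.csd
    raw = np.einsum("vs,st,vt->v", W, C, W).real
    lam_min = float(np.linalg.eigvalsh(0.5 * (C + C.conj().T).real).min())
    if lam_min <= 0:
        raise ValueError(
            f"smallest CSD eigenvalue {lam_min:.3e} is not positive; "
            "noise normalization undefined"
        )
    noise = lam_min * np.einsum("vs,vs->v", W, W)
    return SourcePowerMap(
        nai=raw / noise, raw_power=raw, condition=condition,
        band=csd.band, window=csd.window,
    )


def contrast_map(map_a: SourcePowerMap, map_b: SourcePowerMap) -> SourcePowerMap:
    """Signed voxelwise difference of noise-normalized power (A minus B)."""
    if map_a.nai.shape != map_b.nai.shape:
        raise ValueError("source maps live on different grids")
    if map_a.band != map_b.band or map_a.window != map_b.window:
        raise ValueError("source maps disagree on band or window")
    return SourcePowerMap(
        nai=map_a.nai - map_b.nai,
        raw_power=map_a.raw_power - map_b.raw_power,
        condition=f"{map_a.condition}-{map_b.condition}",
        band=map_a.band,
        window=map_a.window,
        kind="contrast",
    )


def select_top_voxels(source_map: SourcePowerMap, fraction: float = 0.02) -> np.ndarray:
    """Indices of the ``ceil(fraction * N_v)`` voxels of largest |value|.

    Ties are broken by ascending voxel index for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    values = np.abs(source_map.nai)
    k = int(np.ceil(fraction * len(values)))
    order = np.argsort(-values, kind="stable")
    return np.sort(order[:k])


def dbscan_cluster(
    voxel_indices: np.ndarray,
    hm: HeadModel,
    eps_factor: float = 1.5,
    min_pts: int = 3,
    kind: Literal["activity", "contrast"] = "activity",
    signs: np.ndarray | None = None,
) -> list[VoxelCluster]:
    """Group selected voxels by density with eps = eps_factor * grid spacing.

    ``eps_factor=1.5`` includes edge-adjacent lattice voxels; ``min_pts=3``
    discards clusters below three voxels (noise points are dropped).
    Clusters are sorted by descending size, then ascending centroid x.
    ``signs`` (per selected voxel, +1/-1) optionally assigns each contrast
    cluster its dominant direction.
    """
    if eps_factor <= 0:
        raise ValueError("eps_factor must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    if voxel_indices.size == 0:
        return []
    coords = hm.grid_positions[voxel_indices]
    labels = DBSCAN(
        eps=eps_factor * hm.grid_spacing, min_samples=min_pts
    ).fit_predict(coords)

    clusters: list[VoxelCluster] = []
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        members = voxel_indices[sel]
        sign: Literal["A>B", "B>A", "n/a"] = "n/a"
        if signs is not None:
            s = np.sign(np.sum(np.asarray(signs)[sel]))
            sign = "A>B" if s > 0 else ("B>A" if s < 0 else "n/a")
        clusters.append(
            VoxelCluster(
                member_voxel_indices=members,
                centroid=coords[sel].mean(axis=0),
                kind=kind,
                sign=sign,
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.centroid[0]))
    return clusters


def lcmv_common_filter(
    epochs_by_condition: Sequence[SensorEpochs],
    hm: HeadModel,
    window: tuple[float, float],
    reg_fraction: float = 0.05,
) -> SpatialFilterSet:
    """Common LCMV filter from the pooled time-domain covariance.

    The covariance pools the windowed, per-trial-demeaned samples of every
    condition; the filter formula is the same regularized unit-gain solution
    as DICS, applied to the real covariance.
    """
    segs = []
    for ep in epochs_by_condition:
        times = ep.times
        mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} outside epoch support")
        seg = ep.data[:, :, mask]
        seg = seg - seg.mean(axis=-1, keepdims=True)
        segs.append(seg.transpose(1, 0, 2).reshape(ep.n_sensors, -1))
    X = np.concatenate(segs, axis=1)
    n_s = X.shape[0]
    if X.shape[1] < n_s:
        import warnings

        warnings.warn(
            f"only {X.shape[1]} samples for a {n_s}-sensor covariance",
            stacklevel=2,
        )
    C = (X @ X.T) / X.shape[1]
    W = _unit_gain_filters(C, hm, reg_fraction)
    return SpatialFilterSet(
        weights=W, regularization_fraction=reg_fraction, head_model=hm
    )


def design_bandpass_fir(
    band: tuple[float, float], fs: float, transition_hz: float = 2.0
) -> np.ndarray:
    """Hamming-windowed sinc band-pass FIR.

    Order = ceil(3.3 / normalized transition width), rounded up to even so
    the filter has integer group delay; ``numtaps = order + 1`` (odd,
    type-I linear phase).
    """
    order = int(np.ceil(3.3 * fs / transition_hz))
    if order % 2:
        order += 1
    return signal.firwin(
        order + 1, list(band), pass_zero=False, fs=fs, window="hamming"
    )


def extract_virtual_series(
    filters: SpatialFilterSet,
    epochs: SensorEpochs,
    clusters: Sequence[VoxelCluster],
    band: tuple[float, float],
    window: tuple[float, float],
    transition_hz: float = 2.0,
    decimate: int | None = None,
) -> VirtualSeries:
    """Cluster-averaged band-passed virtual source time courses.

    Per voxel, the beamformer output ``y_v(t) = w_v . x(t)`` is computed on
    the FULL epoch, band-passed with a zero-net-delay windowed-sinc FIR
    (centred convolution compensates the group delay), and then cropped to
    the analysis window.  Within each cluster the voxel series are
    sign-aligned to the cluster's largest-power voxel (flipped when their
    pooled correlation is negative) before averaging; the beamformer's
    arbitrary per-voxel sign would otherwise cancel coherent activity.

    The band-passed series are finally decimated to roughly 4x the band's
    upper edge (``decimate=None`` picks ``floor(fs / (4 * band_hi))``;
    pass 1 to disable).  A 256-Hz narrowband series is ~30x oversampled:
    without decimation one-step prediction is near-deterministic and any
    autoregressive model of it is ill-conditioned.  The FIR doubles as the
    anti-alias filter.
    """
    if not clusters:
        raise ValueError("clusters must be non-empty")
    if not (0 < band[0] < band[1] < epochs.fs / 2):
        raise ValueError("band must lie within (0, fs/2)")
    h = design_bandpass_fir(band, epochs.fs, transition_hz)
    if len(h) - 1 >= epochs.n_samples:
        raise ValueError(
            f"FIR order {len(h) - 1} >= epoch length {epochs.n_samples}; "
            "use longer epochs or a wider transition band"
        )
    if decimate is None:
        decimate = max(1, int(epochs.fs // (4.0 * band[1])))
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    times = epochs.times
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} outside epoch support")

    n_out = int(mask.sum())
    out = np.empty((epochs.n_trials, len(clusters), n_out))
    for ci, cluster in enumerate(clusters):
        W = filters.weights[cluster.member_voxel_indices]     # (n_vox, N_s)
        # (trials, n_vox, samples) beamformer output on the full epoch
        y = np.einsum("vs,tsn->tvn", W, epochs.data)
        filt = np.apply_along_axis(
            lambda v: np.convolve(v, h, mode="same"), -1, y
        )[:, :, mask]
        pooled = filt.transpose(1, 0, 2).reshape(filt.shape[1], -1)
        ref = int(np.argmax(pooled.var(axis=1)))
        ref_series = pooled[ref]
        flips = np.ones(pooled.shape[0])
        denom = np.linalg.norm(pooled, axis=1) * np.linalg.norm(ref_series)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, pooled @ ref_series / denom, 1.0)
        flips[corr < 0] = -1.0
        out[:, ci, :] = np.einsum("v,tvn->tn", flips, filt) / pooled.shape[0]
    out = out[:, :, ::decimate]
    return VirtualSeries(
        data=out, fs=epochs.fs / decimate, band=tuple(band),
        window=tuple(window),
        condition=str(epochs.condition[0]) if epochs.n_trials else "",
        cluster_refs=list(clusters),
    )
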