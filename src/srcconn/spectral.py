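"""Time-frequency analysis, cross-spectral density and sensor-level
cluster-based permutation statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from scipy.signal.windows import hann
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .containers import SensorEpochs


@dataclass
class TFR:
    """Time-frequency power, trials (or subjects) x sensors x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_length: float
    baseline_mode: Literal["none", "percent", "dB"] = "none"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.baseline_mode == "none" and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")


@dataclass
class CSDMatrix:
    """Sensor cross-spectral density averaged over a band and time window."""

    csd: np.ndarray
    band: tuple[float, float]
    window: tuple[float, float]
    n_trials_used: int

    def __post_init__(self) -> None:
        self.csd = np.asarray(self.csd, dtype=complex)
        if not np.allclose(self.csd, self.csd.conj().T, atol=1e-10):
            raise ValueError("CSD must be Hermitian")
        diag = np.diag(self.csd)
        if np.any(diag.real < -1e-12) or np.any(np.abs(diag.imag) > 1e-10):
            raise ValueError("CSD diagonal must be real and nonnegative")


@dataclass
class NeighborGraph:
    """Symmetric sensor adjacency from a distance criterion."""

    adjacency: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("no self-neighbors allowed")


@dataclass
class ClusterTestResult:
    """Outcome of a sensor-space cluster-based permutation test."""

    clusters: list[dict]
    n_permutations: int
    alpha: float
    observed_t: np.ndarray

    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] < self.alpha]


def compute_tfr(
    epochs: SensorEpochs,
    freqs: np.ndarray,
    window_length: float,
    step: float,
    average_trials: bool = False,
) -> TFR:
    """Sliding-window Hann-tapered spectrogram at the requested frequencies.

    Each time center takes a Hann-tapered segment of ``window_length``
    seconds, Fourier-transforms it, and reads power (one-sided density,
    µV²/Hz) at the DFT bin nearest each requested frequency.  Centers whose
    window would exceed the epoch are dropped; no zero-padding.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = epochs.fs
    win_n = int(round(window_length * fs))
    if win_n < 8:
        raise ValueError("window_length * fs must be at least 8 samples")
    if win_n > epochs.n_samples:
        raise ValueError(
            f"window of {window_length:.3f} s exceeds epoch duration "
            f"{epochs.n_samples / fs:.3f} s"
        )
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("freqs must lie in (0, fs/2)")

    step_n = max(int(round(step * fs)), 1)
    taper = hann(win_n, sym=False)
    # one-sided PSD normalization: |X|^2 * 2 / (fs * sum(w^2))
    norm = 2.0 / (fs * np.sum(taper**2))
    fft_freqs = np.fft.rfftfreq(win_n, d=1.0 / fs)
    bins = np.array([int(np.argmin(np.abs(fft_freqs - f))) for f in freqs])

    half = win_n // 2
    starts = np.arange(0, epochs.n_samples - win_n + 1, step_n)
    centers = starts + half
    times = epochs.t0 + centers / fs

    power = np.empty((epochs.n_trials, epochs.n_sensors, len(freqs), len(starts)))
    for w, s0 in enumerate(starts):
        seg = epochs.data[:, :, s0:s0 + win_n] * taper
        spec = np.fft.rfft(seg, axis=-1)
        psd = (np.abs(spec) ** 2) * norm
        # rfft end bins are not doubled in a one-sided density
        psd[..., 0] /= 2.0
        if win_n % 2 == 0:
            psd[..., -1] /= 2.0
        power[:, :, :, w] = psd[:, :, bins]
    if average_trials:
        power = power.mean(axis=0, keepdims=True)
    return TFR(power=power, freqs=freqs, times=times, window_length=window_length)


def baseline_normalize(
    tfr: TFR, baseline: tuple[float, float], mode: Literal["percent", "dB"]
) -> TFR:
    """Express power relative to the mean over a baseline interval.

    percent: ``(P - Pb) / Pb * 100``; dB: ``10 log10(P / Pb)``, with Pb the
    time-mean over the baseline per observation, sensor and frequency.
    """
    lo, hi = baseline
    mask = (tfr.times >= lo) & (tfr.times <= hi)
    if not mask.any():
        raise ValueError(
            f"baseline [{lo}, {hi}] s not covered by TFR times "
            f"[{tfr.times[0]:.3f}, {tfr.times[-1]:.3f}]"
        )
    pb = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(pb == 0):
        raise ValueError("zero baseline power; cannot normalize")
    if mode == "percent":
        out = (tfr.power - pb) / pb * 100.0
    elif mode == "dB":
        out = 10.0 * np.log10(tfr.power / pb)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return TFR(
        power=out, freqs=tfr.freqs, times=tfr.times,
        window_length=tfr.window_length, baseline_mode=mode,
    )


def min_csd_window(band: tuple[float, float], n_cycles: int = 3) -> float:
    """Minimum admissible CSD window: ``n_cycles`` of the band's lowest
    frequency (e.g. 3 cycles at 4 Hz -> 0.75 s; at 8 Hz -> 0.375 s)."""
    lo = band[0]
    if lo <= 0:
        raise ValueError("band lower edge must be positive")
    return n_cycles / lo


def compute_csd(
    epochs: SensorEpochs,
    band: tuple[float, float],
    window: tuple[float, float],
) -> CSDMatrix:
    """Trial- and bin-averaged cross-spectral density over a band and window.

    Per trial, the windowed segment is Hann-tapered and Fourier-transformed;
    the complex outer products of the sensor spectra are averaged over the
    DFT bins inside the band and over trials.  The window must span at least
    3 cycles of the band's lowest frequency.
    """
    duration = window[1] - window[0]
    need = min_csd_window(band)
    if duration < need - 1e-12:
        raise ValueError(
            f"window of {duration:.3f} s too short for band {band}: "
            f"3 cycles of {band[0]:g} Hz require {need:.3f} s"
        )
    fs = epochs.fs
    times = epochs.times
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    n_win = int(mask.sum())
    if n_win < 8:
        raise ValueError("analysis window contains too few samples")

    seg = epochs.data[:, :, mask]
    taper = hann(n_win, sym=False)
    spec = np.fft.rfft(seg * taper, axis=-1)
    fft_freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    fmask = (fft_freqs >= band[0]) & (fft_freqs <= band[1])
    if not fmask.any():
        raise ValueError(f"no DFT bin falls inside band {band} for this window")
    S = spec[:, :, fmask]                                   # (trials, N_s, bins)
    scale = 2.0 / (fs * np.sum(taper**2))
    csd = np.einsum("tib,tjb->ij", S, S.conj()) * scale / (
        S.shape[0] * S.shape[2]
    )
    csd = 0.5 * (csd + csd.conj().T)  # enforce exact Hermitian symmetry
    return CSDMatrix(
        csd=csd, band=tuple(band), window=tuple(window),
        n_trials_used=epochs.n_trials,
    )


def sensor_neighbors(positions: np.ndarray, radius: float) -> NeighborGraph:
    """Distance-criterion sensor neighborhood: j neighbors i iff
    ``0 < |pos_i - pos_j| <= radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions = np.asarray(positions, dtype=float)
    d = squareform(pdist(positions))
    off = d[~np.eye(len(d), dtype=bool)]
    if off.size and off.min() == 0.0:
        raise ValueError("duplicate sensor positions")
    adjacency = (d > 0) & (d <= radius)
    return NeighborGraph(adjacency=adjacency, radius=radius)


def _clusters_from_t(
    t: np.ndarray, threshold: float, adjacency: np.ndarray
) -> list[tuple[np.ndarray, int, float]]:
    """Connected suprathreshold components of common sign: (sensors, sign, mass)."""
    out: list[tuple[np.ndarray, int, float]] = []
    for sign in (1, -1):
        supra = np.where(sign * t > threshold)[0]
        if supra.size == 0:
            continue
        sub = adjacency[np.ix_(supra, supra)]
        n_comp, labels = connected_components(
            csr_matrix(sub), directed=False
        )
        for comp in range(n_comp):
            members = supra[labels == comp]
            out.append((members, sign, float(t[members].sum())))
    return out


def cluster_permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Paired two-sided cluster-based permutation test over sensors.

    Per-sensor paired t statistics are thresholded at the two-sided critical
    t (0.05, df = n-1); suprathreshold sensors of common sign are grouped
    into connected clusters under the neighbor graph, each scored by its
    t-mass.  The Monte Carlo null is the maximum absolute cluster mass under
    random within-subject condition swaps (sign flips of the paired
    differences).  Cluster p = (1 + #{null >= |mass|}) / (n_perm + 1);
    comparing |mass| to a max-|mass| null makes the test two-sided at level
    ``alpha`` directly.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.shape != values_b.shape:
        raise ValueError("paired inputs must have identical shape")
    n, n_sensors = values_a.shape
    if n < 3:
        raise ValueError("at least 3 subjects required")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    diff = values_a - values_b
    threshold = float(stats.t.ppf(1.0 - 0.05 / 2.0, df=n - 1))

    def tstat(d: np.ndarray) -> np.ndarray:
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
        return t

    t_obs = tstat(diff)
    observed = _clusters_from_t(t_obs, threshold, graph.adjacency)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_perm = tstat(diff * flips[i][:, None])
        perm_clusters = _clusters_from_t(t_perm, threshold, graph.adjacency)
        if perm_clusters:
            null_max[i] = max(abs(m) for _, _, m in perm_clusters)

    clusters = []
    for members, sign, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(
            {"sensors": members, "sign": sign, "mass": mass, "p": float(p)}
        )
    clusters.sort(key=lambda c: c["p"])
    return ClusterTestResult(
        clusters=clusters, n_permutations=n_perm, alpha=alpha, observed_t=t_obs
    )
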