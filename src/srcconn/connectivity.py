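"""ANN-based nonlinear MVAR directed connectivity.

The estimator fits a one-hidden-layer tanh network that predicts the next
(z-scored) sample of every source region from the last ``p`` samples of all
regions — a nonlinear multivariate autoregressive model.  Directed
influence j -> i is split into:

* linear connectivity strength (LCS): the RMS over lags of the network's
  first-order Taylor coefficients at the origin, which reduce exactly to
  VAR coefficients when the network is linear; and
* nonlinear connectivity strength (NCS): the RMS deviation of the
  per-sample input-output Jacobian from that linear part, which is zero to
  machine precision for an effectively linear network.

Significance uses time-shifted surrogates: each region's concatenated
series is independently circularly shifted (destroying cross-region
alignment, preserving marginal spectra) and the whole estimator — ANN fit
included — is recomputed per surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .beamform import VirtualSeries

Measure = Literal["lcs", "ncs"]


@dataclass
class OrderSelection:
    """AIC/SBC curves from linear VAR fits and the elbow-selected order."""

    p_opt: int
    aic_curve: np.ndarray
    sbc_curve: np.ndarray
    logdet_curve: np.ndarray
    flatten_tolerance: float


@dataclass
class TrainConfig:
    """L-BFGS training schedule for the ANN (deterministic given seed).

    Hidden units are initialized as random unit directions with per-unit
    gains log-uniform on [gain_lo, gain_hi] — spanning near-linear to
    saturating regimes — and the output layer is solved by least squares on
    those features before L-BFGS refines everything jointly.  This start
    point removes most of the optimizer's burn-in, so ``max_iter`` can stay
    small; raise it for final-quality fits.
    """

    max_iter: int = 200
    ftol: float = 1e-11
    gtol: float = 1e-8
    gain_lo: float = 0.3
    gain_hi: float = 3.0


@dataclass
class NMVARModel:
    """Trained one-hidden-layer tanh network over lagged z-scored inputs."""

    p: int
    K: int
    input_weights: np.ndarray    # (H, K*p)
    input_bias: np.ndarray       # (H,)
    output_weights: np.ndarray   # (K, H)
    output_bias: np.ndarray      # (K,)
    input_mean: np.ndarray       # (K,) per-channel standardization
    input_scale: np.ndarray      # (K,)
    training_diagnostics: dict
    seed: int

    @property
    def hidden_units(self) -> int:
        return self.input_weights.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Network output for lagged z-scored inputs X (N, K*p)."""
        H = np.tanh(X @ self.input_weights.T + self.input_bias)
        return H @ self.output_weights.T + self.output_bias


@dataclass
class ConnectivityResult:
    """K x K directed linear / nonlinear strengths for one fit."""

    lcs: np.ndarray
    ncs: np.ndarray
    significant: dict[Measure, np.ndarray] | None = None
    normalized: bool = False
    condition: str = ""
    band: tuple[float, float] = (0.0, 0.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.lcs = np.asarray(self.lcs, dtype=float)
        self.ncs = np.asarray(self.ncs, dtype=float)
        if np.any(self.lcs < 0) or np.any(self.ncs < 0):
            raise ValueError("connectivity strengths must be nonnegative")

    @property
    def K(self) -> int:
        return self.lcs.shape[0]

    def values(self, measure: Measure) -> np.ndarray:
        return self.lcs if measure == "lcs" else self.ncs


@dataclass
class SurrogateDistribution:
    """Connectivity strengths under the time-shifted surrogate null."""

    samples: dict[Measure, np.ndarray]   # each (n_surrogates, K, K)
    method: str = "time-shift"
    seed: int = 0

    @property
    def n_surrogates(self) -> int:
        return self.samples["lcs"].shape[0]


def concatenate_trials(vs: VirtualSeries) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate trials to one K x N series; return trial-start indices.

    The boundary list lets downstream fits exclude training samples whose
    lag window would straddle two trials.
    """
    if vs.n_trials < 1:
        raise ValueError("need at least one trial")
    n_samples = vs.data.shape[2]
    series = vs.data.transpose(1, 0, 2).reshape(vs.n_regions, -1)
    boundaries = np.arange(vs.n_trials) * n_samples
    return series, boundaries


def _valid_targets(n_total: int, boundaries: np.ndarray, p: int) -> np.ndarray:
    """Target indices whose p-lag window stays inside a single trial."""
    bounds = np.sort(np.asarray(boundaries, dtype=int))
    ends = np.append(bounds[1:], n_total)
    idx = []
    for b, e in zip(bounds, ends):
        idx.append(np.arange(b + p, e))
    return np.concatenate(idx) if idx else np.array([], dtype=int)


def _lagged_design(
    series: np.ndarray, targets: np.ndarray, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """X (N, K*p) with u_t = [x(t-1); ...; x(t-p)], Y (N, K) = x(t)."""
    K = series.shape[0]
    X = np.empty((len(targets), K * p))
    for k in range(p):
        X[:, k * K:(k + 1) * K] = series[:, targets - 1 - k].T
    Y = series[:, targets].T
    return X, Y


def select_model_order(
    series: np.ndarray,
    boundaries: np.ndarray,
    p_max: int,
    tolerance: float = 0.05,
) -> OrderSelection:
    """Select the VAR model order where AIC and SBC flatten.

    For p = 1..p_max a linear VAR is fitted by least squares on the common
    sample set valid at p_max (so fits are exactly nested);
    ``AIC(p) = ln det S_p + 2 p K^2 / N`` and
    ``SBC(p) = ln det S_p + p K^2 ln N / N`` with S_p the residual
    covariance.  The elbow of a criterion is the smallest p whose relative
    improvement ``(crit(p) - crit(p+1)) / (crit(1) - crit(p_max))`` drops
    below ``tolerance``; the selected order is the larger of the two elbows.
    """
    series = np.asarray(series, dtype=float)
    K, n_total = series.shape
    if p_max < 2:
        raise ValueError("p_max must be >= 2")
    targets = _valid_targets(n_total, boundaries, p_max)
    n_eff = len(targets)
    if n_eff <= 10 * K * p_max:
        raise ValueError(
            f"only {n_eff} usable samples; need > {10 * K * p_max} for p_max={p_max}"
        )

    logdets = np.empty(p_max)
    aic = np.empty(p_max)
    sbc = np.empty(p_max)
    for p in range(1, p_max + 1):
        X, Y = _lagged_design(series, targets, p)
        Xd = np.column_stack([np.ones(n_eff), X])
        coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        resid = Y - Xd @ coef
        S = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            logdet = -np.inf
        logdets[p - 1] = logdet
        aic[p - 1] = logdet + 2.0 * p * K**2 / n_eff
        sbc[p - 1] = logdet + p * K**2 * np.log(n_eff) / n_eff

    def elbow(crit: np.ndarray) -> int:
        denom = crit[0] - crit[-1]
        if denom <= 0:
            return 1
        for p in range(1, p_max):
            if (crit[p - 1] - crit[p]) / denom < tolerance:
                return p
        return p_max

    if aic[0] - aic[-1] <= 0 and sbc[0] - sbc[-1] <= 0:
        warnings.warn(
            "information criteria do not improve with lag order; "
            "series appears temporally unstructured, selecting p = 1",
            stacklevel=2,
        )
    p_opt = max(elbow(aic), elbow(sbc))
    return OrderSelection(
        p_opt=p_opt, aic_curve=aic, sbc_curve=sbc,
        logdet_curve=logdets, flatten_tolerance=tolerance,
    )


def _unpack(theta: np.ndarray, K: int, p: int, H: int):
    n_in = K * p
    i = 0
    W_in = theta[i:i + H * n_in].reshape(H, n_in); i += H * n_in
    b_in = theta[i:i + H]; i += H
    W_out = theta[i:i + K * H].reshape(K, H); i += K * H
    b_out = theta[i:i + K]
    return W_in, b_in, W_out, b_out


def _loss_grad(theta: np.ndarray, X: np.ndarray, Y: np.ndarray, K: int, p: int, H: int):
    """Mean-squared-error loss and analytic gradient of the tanh network."""
    N = X.shape[0]
    W_in, b_in, W_out, b_out = _unpack(theta, K, p, H)
    Z = X @ W_in.T + b_in
    A = np.tanh(Z)
    pred = A @ W_out.T + b_out
    err = pred - Y
    loss = float(np.mean(err**2))
    scale = 2.0 / (N * K)
    g_out = scale * err.T @ A                 # (K, H)
    g_bout = scale * err.sum(axis=0)          # (K,)
    back = (err @ W_out) * (1.0 - A**2)       # (N, H)
    g_in = scale * back.T @ X                 # (H, K*p)
    g_bin = scale * back.sum(axis=0)          # (H,)
    grad = np.concatenate([g_in.ravel(), g_bin, g_out.ravel(), g_bout])
    return loss, grad


def fit_nmvar_ann(
    series: np.ndarray,
    boundaries: np.ndarray,
    p: int,
    hidden_units: int = 10,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> NMVARModel:
    """Fit the nonlinear MVAR network to a concatenated source series.

    Inputs are the z-scored lagged vectors (length K*p, lag windows never
    crossing trial boundaries); the network has one hidden tanh layer and
    linear outputs predicting the next z-scored sample of all K regions.
    Training minimizes mean squared error with L-BFGS from a seeded random
    initialization; the fit is a pure function of (data, seed, config).
    """
    cfg = train_cfg or TrainConfig()
    series = np.asarray(series, dtype=float)
    K, n_total = series.shape
    mean = series.mean(axis=1)
    scale = series.std(axis=1)
    scale[scale == 0] = 1.0
    z = (series - mean[:, None]) / scale[:, None]

    targets = _valid_targets(n_total, boundaries, p)
    X, Y = _lagged_design(z, targets, p)
    n_eff = len(targets)
    H = hidden_units
    n_params = H * (K * p + 1) + K * (H + 1)
    if n_eff < 20 * n_params:
        warnings.warn(
            f"{n_eff} training samples for {n_params} parameters; "
            "fit may be under-determined",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    gains = np.exp(rng.uniform(np.log(cfg.gain_lo), np.log(cfg.gain_hi), H))
    dirs = rng.standard_normal((H, K * p))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    W_in0 = gains[:, None] * dirs
    b_in0 = rng.uniform(-0.5, 0.5, H)
    feats = np.tanh(X @ W_in0.T + b_in0)
    coef, *_ = np.linalg.lstsq(
        np.column_stack([feats, np.ones(len(feats))]), Y, rcond=None
    )
    theta0 = np.concatenate([
        W_in0.ravel(), b_in0, coef[:-1].T.ravel(), coef[-1]
    ])
    res = minimize(
        _loss_grad, theta0, args=(X, Y, K, p, H), jac=True, method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "ftol": cfg.ftol, "gtol": cfg.gtol},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"non-finite training loss (seed={seed}, cfg={cfg})"
        )
    W_in, b_in, W_out, b_out = _unpack(res.x, K, p, H)

    pred = np.tanh(X @ W_in.T + b_in) @ W_out.T + b_out
    var = Y.var(axis=0)
    var[var == 0] = 1.0
    nmse = ((pred - Y) ** 2).mean(axis=0) / var
    corr = np.array([
        np.corrcoef(pred[:, k], Y[:, k])[0, 1] if Y[:, k].std() > 0 else 0.0
        for k in range(K)
    ])
    if np.all(nmse > 0.95):
        warnings.warn("model uninformative: NMSE > 0.95 on all channels",
                      stacklevel=2)
    return NMVARModel(
        p=p, K=K, input_weights=W_in, input_bias=b_in,
        output_weights=W_out, output_bias=b_out,
        input_mean=mean, input_scale=scale,
        training_diagnostics={
            "nmse": nmse, "corr": corr, "n_samples": n_eff,
            "loss": float(res.fun), "n_iter": int(res.nit),
        },
        seed=seed,
    )


def linearize_model(model: NMVARModel) -> np.ndarray:
    """Lag-resolved linear coefficients A (K x K x p) of the network.

    First-order Taylor expansion at zero (z-scored) input:
    ``A = W_out diag(1 - tanh^2(b_in)) W_in``, reshaped per lag.  With zero
    biases and weights realizing a linear map, A recovers that map exactly
    (tanh'(0) = 1).
    """
    d0 = 1.0 - np.tanh(model.input_bias) ** 2
    A_flat = model.output_weights @ (d0[:, None] * model.input_weights)
    K, p = model.K, model.p
    return A_flat.reshape(K, p, K).transpose(0, 2, 1)


def connectivity_measures(
    model: NMVARModel,
    series: np.ndarray,
    boundaries: np.ndarray,
    condition: str = "",
    band: tuple[float, float] = (0.0, 0.0),
    subject_id: str = "",
) -> ConnectivityResult:
    """Split directed influence into linear and nonlinear strengths.

    With A the Taylor linearization and J_t the per-sample Jacobian
    ``W_out diag(1 - tanh^2(z_t)) W_in``::

        LCS(j -> i) = sqrt( sum_k A[i, j, k]^2 )
        NCS(j -> i) = sqrt( mean_t sum_k (J_t - A)[i, j, k]^2 )

    The Jacobian deviation is evaluated over the model's own training
    samples.  Self-terms are computed but flagged; group averages exclude
    them.
    """
    series = np.asarray(series, dtype=float)
    K, n_total = series.shape
    if K != model.K:
        raise ValueError("series and model disagree on region count")
    z = (series - model.input_mean[:, None]) / model.input_scale[:, None]
    targets = _valid_targets(n_total, boundaries, model.p)
    if len(targets) < 100:
        raise ValueError(f"only {len(targets)} usable samples; need >= 100")
    X, _ = _lagged_design(z, targets, model.p)

    A = linearize_model(model)
    lcs = np.sqrt((A**2).sum(axis=2))

    Z = X @ model.input_weights.T + model.input_bias
    d = 1.0 - np.tanh(Z) ** 2
    d0 = 1.0 - np.tanh(model.input_bias) ** 2
    delta = d - d0
    C = delta.T @ delta / delta.shape[0]                     # (H, H)
    W_out, W_in = model.output_weights, model.input_weights
    ncs2_flat = np.einsum(
        "ih,ig,hg,hm,gm->im", W_out, W_out, C, W_in, W_in, optimize=True
    )
    ncs2 = np.clip(
        ncs2_flat.reshape(K, model.p, K).transpose(0, 2, 1).sum(axis=2),
        0.0, None,
    )
    return ConnectivityResult(
        lcs=lcs, ncs=np.sqrt(ncs2), condition=condition,
        band=band, subject_id=subject_id,
    )


def time_shift_surrogates(
    vs: VirtualSeries,
    p: int,
    hidden_units: int = 10,
    n_surrogates: int = 100,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
) -> SurrogateDistribution:
    """Connectivity null from independently time-shifted regions.

    Per surrogate each region's concatenated series is circularly shifted by
    an offset drawn uniformly from [0.1 N, 0.9 N], destroying cross-region
    temporal alignment while preserving per-region autocovariance (up to
    wraparound); the full estimator — ANN fit plus measures — is recomputed
    with a fresh derived seed.  A surrogate whose fit fails is retried up to
    3 times with a new seed.

    Shifting moves each region's trial edges (and adds a wrap seam) to new
    positions; lag windows crossing any region's shifted discontinuity are
    excluded from the surrogate fit, exactly as boundary-crossing windows
    are excluded from the observed fit.  Without this the seams read as
    artificial nonlinear transitions, surrogate NCS is inflated, and the
    mask becomes conservative (measured false-positive rate far below q).
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    series, boundaries = concatenate_trials(vs)
    K, N = series.shape
    lo, hi = int(np.floor(0.1 * N)), int(np.ceil(0.9 * N))
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_surrogates)

    lcs_samples = np.empty((n_surrogates, K, K))
    ncs_samples = np.empty((n_surrogates, K, K))
    for s, child in enumerate(children):
        state = child.generate_state(8)
        rng = np.random.default_rng(state[0])
        shifts = rng.integers(lo, hi + 1, size=K)
        shifted = np.stack([np.roll(series[k], int(shifts[k])) for k in range(K)])
        cuts = {0}
        for k in range(K):
            cuts.update(
                int(b) for b in (np.asarray(boundaries) + int(shifts[k])) % N
            )
        surr_bounds = np.sort(np.fromiter(cuts, dtype=int))
        for attempt in range(3):
            try:
                fit_seed = int(state[1 + attempt] % 2**31)
                model = fit_nmvar_ann(
                    shifted, surr_bounds, p, hidden_units,
                    train_cfg=train_cfg, seed=fit_seed,
                )
                res = connectivity_measures(model, shifted, surr_bounds)
                break
            except (RuntimeError, np.linalg.LinAlgError) as exc:   # pragma: no cover
                warnings.warn(
                    f"surrogate {s} fit failed (attempt {attempt + 1}): {exc}",
                    stacklevel=2,
                )
        else:   # pragma: no cover
            raise RuntimeError(f"surrogate {s} failed after 3 attempts")
        lcs_samples[s] = res.lcs
        ncs_samples[s] = res.ncs
    return SurrogateDistribution(
        samples={"lcs": lcs_samples, "ncs": ncs_samples}, seed=seed
    )


def empirical_upper_quantile(samples: np.ndarray, q: float) -> np.ndarray:
    """Permutation-convention (1-q) quantile along axis 0.

    Returns the k-th order statistic with ``k = ceil((1 - q) (n + 1))``
    (capped at n).  The add-one accounts for the observed statistic being
    part of the exchangeable set, so that under the null
    ``P(observed > threshold) = floor(q (n + 1)) / (n + 1) ~= q`` for any
    surrogate count — with the plain ``ceil((1 - q) n)`` rule, 20
    surrogates at q = 0.05 would yield a 9.5% rate instead of 5%.
    """
    n = samples.shape[0]
    k = int(np.ceil((1.0 - q) * (n + 1)))
    k = min(max(k, 1), n)
    return np.sort(samples, axis=0)[k - 1]


def apply_significance(
    result: ConnectivityResult,
    null: SurrogateDistribution,
    q: float = 0.05,
) -> ConnectivityResult:
    """Mask connections not exceeding the surrogate (1-q) quantile.

    A connection is significant iff its observed strength strictly exceeds
    the inclusive empirical (1-q) quantile of its own surrogate sample;
    non-significant entries are set to 0.  An observed value exactly equal
    to a zero-variance null is (conservatively) non-significant.
    """
    K = result.K
    if null.samples["lcs"].shape[1:] != (K, K):
        raise ValueError("surrogate distribution does not match result shape")
    masks: dict[Measure, np.ndarray] = {}
    new = {"lcs": result.lcs.copy(), "ncs": result.ncs.copy()}
    for measure in ("lcs", "ncs"):
        thr = empirical_upper_quantile(null.samples[measure], q)
        sig = result.values(measure) > thr
        masks[measure] = sig
        new[measure][~sig] = 0.0
    return ConnectivityResult(
        lcs=new["lcs"], ncs=new["ncs"], significant=masks,
        normalized=result.normalized, condition=result.condition,
        band=result.band, subject_id=result.subject_id,
    )


def normalize_subject(
    results_by_condition: tuple[ConnectivityResult, ConnectivityResult],
) -> tuple[ConnectivityResult, ConnectivityResult]:
    """Scale a subject's two condition results to [0, 1] per measure.

    The divisor is the maximum value across both conditions and all
    non-self connections, separately for the linear and nonlinear measure,
    so the subject's maximum becomes exactly 1.  An all-zero measure is
    returned unchanged with a warning.
    """
    a, b = results_by_condition
    if a.lcs.shape != b.lcs.shape:
        raise ValueError("condition results have mismatched shapes")
    if a.subject_id != b.subject_id:
        raise ValueError("normalize_subject pairs results of one subject")
    offdiag = ~np.eye(a.K, dtype=bool)
    out = []
    divisors: dict[Measure, float] = {}
    for measure in ("lcs", "ncs"):
        divisor = max(
            float(a.values(measure)[offdiag].max()),
            float(b.values(measure)[offdiag].max()),
        )
        if divisor == 0.0:
            warnings.warn(
                f"all-zero {measure} for subject {a.subject_id!r}; "
                "normalization skipped", stacklevel=2,
            )
            divisor = 1.0
        divisors[measure] = divisor
    for r in (a, b):
        out.append(
            ConnectivityResult(
                lcs=r.lcs / divisors["lcs"],
                ncs=r.ncs / divisors["ncs"],
                significant=r.significant,
                normalized=True,
                condition=r.condition,
                band=r.band,
                subject_id=r.subject_id,
            )
        )
    return out[0], out[1]
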