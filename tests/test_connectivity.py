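"""Nonlinear MVAR estimator tests: order selection, fitting, the
linear/nonlinear split, surrogates, significance and normalization."""

import numpy as np
import pytest

from srcconn.beamform import VirtualSeries
from srcconn.connectivity import (
    ConnectivityResult,
    NMVARModel,
    TrainConfig,
    apply_significance,
    concatenate_trials,
    connectivity_measures,
    empirical_upper_quantile,
    fit_nmvar_ann,
    linearize_model,
    normalize_subject,
    select_model_order,
    time_shift_surrogates,
    _lagged_design,
    _valid_targets,
)
from srcconn.synthetic import simulate_source_dynamics

from conftest import make_uncoupled_gt


def make_vs(data, fs=256.0):
    return VirtualSeries(
        data=data, fs=fs, band=(8.0, 12.0), window=(0.0, 1.0), condition="x"
    )


def simulate_var(coefs, n, seed, noise=1.0):
    """Plain linear VAR simulator (independent oracle for order selection)."""
    K, _, p = coefs.shape
    rng = np.random.default_rng(seed)
    x = np.zeros((K, n + 200))
    eps = rng.standard_normal((K, n + 200)) * noise
    for t in range(p, n + 200):
        acc = eps[:, t]
        for k in range(p):
            acc = acc + coefs[:, :, k] @ x[:, t - 1 - k]
        x[:, t] = acc
    return x[:, 200:]


class TestConcatenate:
    def test_counting(self):
        vs = make_vs(np.zeros((15, 2, 256)))
        series, bounds = concatenate_trials(vs)
        assert series.shape == (2, 15 * 256)
        assert len(bounds) == 15

    def test_single_trial(self):
        data = np.random.default_rng(0).standard_normal((1, 3, 100))
        series, bounds = concatenate_trials(make_vs(data))
        assert bounds.tolist() == [0]
        assert np.array_equal(series, data[0])

    def test_round_trip(self):
        data = np.random.default_rng(1).standard_normal((4, 2, 50))
        series, bounds = concatenate_trials(make_vs(data))
        split = np.stack(np.split(series, bounds[1:], axis=1))
        assert np.array_equal(split, data)

    def test_lag_windows_never_cross_boundaries(self):
        targets = _valid_targets(20, np.array([0, 10]), 3)
        assert targets.tolist() == [3, 4, 5, 6, 7, 8, 9, 13, 14, 15, 16, 17, 18, 19]


class TestOrderSelection:
    def test_var3_recovery(self):
        """p_opt = 3 for a VAR(3) in most seeds (10-seed spot check; the
        full 50-seed version runs in the acceptance suite)."""
        A = np.zeros((2, 2, 3))
        A[:, :, 0] = [[0.4, 0.1], [0.0, 0.3]]
        A[:, :, 1] = [[-0.3, 0.0], [0.1, -0.2]]
        A[:, :, 2] = [[0.0, 0.3], [0.3, 0.2]]
        hits = 0
        for seed in range(10):
            x = simulate_var(A, 8192, seed)
            sel = select_model_order(x, np.array([0]), 6, tolerance=0.05)
            hits += sel.p_opt == 3
        assert hits >= 9

    def test_white_noise_selects_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 4096))
        with pytest.warns(UserWarning, match="unstructured"):
            sel = select_model_order(x, np.array([0]), 6)
        assert sel.p_opt == 1

    def test_loglik_monotone_on_nested_fits(self):
        """ln det of the residual covariance never increases with order on
        the shared sample set (least-squares likelihood property)."""
        A = np.zeros((2, 2, 2))
        A[:, :, 0] = [[0.5, 0.2], [0.0, 0.4]]
        A[:, :, 1] = [[-0.2, 0.0], [0.1, -0.3]]
        x = simulate_var(A, 4096, 11)
        sel = select_model_order(x, np.array([0]), 8)
        assert np.all(np.diff(sel.logdet_curve) <= 1e-12)


class TestFit:
    def _series(self, seed=0, n_trials=10, n_samples=400):
        A = np.zeros((2, 2, 2))
        A[:, :, 0] = [[0.5, 0.3], [0.0, 0.5]]
        A[:, :, 1] = [[-0.2, 0.0], [0.0, -0.2]]
        data = np.stack([
            simulate_var(A, n_samples, seed * 100 + i) for i in range(n_trials)
        ])
        return concatenate_trials(make_vs(data))

    def test_linear_var_nmse_comparable(self):
        """On linear VAR data the ANN matches the linear fit within 10%."""
        series, bounds = self._series(seed=1)
        model = fit_nmvar_ann(series, bounds, 2, 10, seed=0)
        nmse = model.training_diagnostics["nmse"]
        assert np.all(nmse < 1.0)
        # linear oracle on the same design
        z = (series - series.mean(1, keepdims=True)) / series.std(1, keepdims=True)
        tg = _valid_targets(series.shape[1], bounds, 2)
        X, Y = _lagged_design(z, tg, 2)
        Xd = np.column_stack([np.ones(len(X)), X])
        coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        lin_nmse = ((Xd @ coef - Y) ** 2).mean(axis=0) / Y.var(axis=0)
        assert np.all(nmse <= lin_nmse * 1.10)

    def test_bit_determinism(self):
        series, bounds = self._series(seed=2)
        m1 = fit_nmvar_ann(series, bounds, 2, 8, seed=5)
        m2 = fit_nmvar_ann(series, bounds, 2, 8, seed=5)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(
            m1.training_diagnostics["nmse"], m2.training_diagnostics["nmse"]
        )

    def test_nonlinear_coupling_beats_linear_held_out(self, gt_alpha):
        """Planted saturating coupling: ANN beats the linear VAR on a
        held-out 20% split (paired over seeds)."""
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            x = simulate_source_dynamics(gt_alpha, 12, 400, 256.0, "high",
                                         seed=seed)
            series, bounds = concatenate_trials(make_vs(x))
            z = (series - series.mean(1, keepdims=True)) / series.std(
                1, keepdims=True
            )
            tg = _valid_targets(series.shape[1], bounds, 2)
            X, Y = _lagged_design(z, tg, 2)
            n_train = int(0.8 * len(X))
            # train on the first 80% of trials via a truncated series
            cut_boundary = bounds[int(0.8 * len(bounds))]
            m = fit_nmvar_ann(
                series[:, :cut_boundary], bounds[bounds < cut_boundary],
                2, 10, seed=seed,
            )
            zs = (series - m.input_mean[:, None]) / m.input_scale[:, None]
            Xs, Ys = _lagged_design(zs, tg, 2)
            Xte, Yte = Xs[n_train:], Ys[n_train:]
            ann = ((m.predict(Xte) - Yte) ** 2).mean() / Yte.var()
            Xd = np.column_stack([np.ones(n_train), Xs[:n_train]])
            coef, *_ = np.linalg.lstsq(Xd, Ys[:n_train], rcond=None)
            lin = (
                (np.column_stack([np.ones(len(Xte)), Xte]) @ coef - Yte) ** 2
            ).mean() / Yte.var()
            wins += ann < lin
        assert wins >= n_seeds - 1


def build_linear_network(M, p, scale=1e-4):
    """Network that realizes the exact linear map M (K x Kp) by driving
    tanh in its linear regime and rescaling the output weights."""
    K = M.shape[0]
    H = M.shape[1]
    # one hidden unit per input dimension: W_in = scale * I
    W_in = np.eye(H) * scale
    W_out = M / scale
    return NMVARModel(
        p=p, K=K, input_weights=W_in, input_bias=np.zeros(H),
        output_weights=W_out, output_bias=np.zeros(K),
        input_mean=np.zeros(K), input_scale=np.ones(K),
        training_diagnostics={"nmse": np.zeros(K), "corr": np.ones(K),
                              "n_samples": 0, "loss": 0.0, "n_iter": 0},
        seed=0,
    )


class TestLinearization:
    def test_exact_linear_map_recovered(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((2, 4)) * 0.4
        model = build_linear_network(M, p=2)
        A = linearize_model(model)
        expect = M.reshape(2, 2, 2).transpose(0, 2, 1)
        assert np.allclose(A, expect, atol=1e-10)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        K, p, H = 2, 3, 7
        model = NMVARModel(
            p=p, K=K,
            input_weights=rng.standard_normal((H, K * p)),
            input_bias=rng.standard_normal(H) * 0.3,
            output_weights=rng.standard_normal((K, H)),
            output_bias=rng.standard_normal(K),
            input_mean=np.zeros(K), input_scale=np.ones(K),
            training_diagnostics={}, seed=0,
        )
        A = linearize_model(model)
        eps = 1e-6
        for m in range(K * p):
            up = np.zeros((1, K * p)); up[0, m] = eps
            dn = -up
            fd = (model.predict(up)[0] - model.predict(dn)[0]) / (2 * eps)
            k, j = divmod(m, K)
            assert np.allclose(A[:, j, k], fd, atol=1e-6)

    def test_output_scaling_linearity(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((2, 2))
        model = build_linear_network(M, p=1)
        A1 = linearize_model(model)
        model.output_weights = model.output_weights * 3.0
        assert np.allclose(linearize_model(model), 3.0 * A1)


class TestMeasures:
    def test_effectively_linear_network_has_zero_ncs(self):
        """NCS/LCS < 1e-3 when the network operates in tanh's linear regime."""
        rng = np.random.default_rng(0)
        M = rng.standard_normal((2, 4)) * 0.4
        model = build_linear_network(M, p=2)
        series = rng.standard_normal((2, 2000))
        res = connectivity_measures(model, series, np.array([0]))
        ratio = res.ncs / np.maximum(res.lcs, 1e-12)
        assert np.all(ratio < 1e-3)

    def test_directionality_recovered(self, gt_alpha):
        """Planted nonlinear 1 -> 2: NCS(1->2) > NCS(2->1) in >= 90% of seeds."""
        wins = 0
        for seed in range(10):
            x = simulate_source_dynamics(gt_alpha, 10, 400, 256.0, "high",
                                         seed=seed)
            series, bounds = concatenate_trials(make_vs(x))
            m = fit_nmvar_ann(series, bounds, 2, 10,
                              train_cfg=TrainConfig(max_iter=100), seed=seed)
            res = connectivity_measures(m, series, bounds)
            wins += res.ncs[1, 0] > res.ncs[0, 1]
        assert wins >= 9

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 3000))
        for k in range(3):  # give channels some autocorrelation
            x[k] = np.convolve(x[k], np.ones(4) / 4, mode="same")
        m = fit_nmvar_ann(x, np.array([0]), 2, 8, seed=1)
        res = connectivity_measures(m, x, np.array([0]))
        perm = [2, 0, 1]
        xp = x[perm]
        mp = fit_nmvar_ann(xp, np.array([0]), 2, 8, seed=1)
        resp = connectivity_measures(mp, xp, np.array([0]))
        # equivariance holds for the model's *inputs/outputs*: check via a
        # permuted refit of identical data rather than weight surgery
        assert resp.lcs.shape == res.lcs.shape
        # deterministic same-seed refit of permuted data reproduces the
        # permuted measures only approximately (different optimization
        # path); instead verify exact equivariance on a fixed network
        M = np.random.default_rng(0).standard_normal((3, 6)) * 0.3
        fixed = build_linear_network(M, p=2)
        r1 = connectivity_measures(fixed, x, np.array([0]))
        pm = np.ix_(perm, perm)
        fixed_p = build_linear_network(
            M.reshape(3, 2, 3)[perm][:, :, perm].reshape(3, 6), p=2
        )
        r2 = connectivity_measures(fixed_p, xp, np.array([0]))
        assert np.allclose(r2.lcs, r1.lcs[pm], atol=1e-10)
        assert np.allclose(r2.ncs, r1.ncs[pm], atol=1e-8)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((2, 2)) * 0.3
        model = build_linear_network(M, p=1)
        with pytest.raises(ValueError, match="usable samples"):
            connectivity_measures(model, rng.standard_normal((2, 50)),
                                  np.array([0]))


class TestSurrogates:
    def test_marginal_autocovariance_preserved(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal((2, 40, 64)), axis=-1)
        x -= x.mean(-1, keepdims=True)
        vs = make_vs(x.transpose(1, 0, 2))
        series, _ = concatenate_trials(vs)
        # a circular shift preserves the circular autocovariance exactly
        shifted = np.roll(series[0], 537)
        n = len(shifted)
        for lag in (1, 5, 20):
            orig = series[0] @ np.roll(series[0], lag) / n
            surr = shifted @ np.roll(shifted, lag) / n
            assert orig == pytest.approx(surr, rel=1e-12)

    def test_coupled_data_exceeds_null(self, gt_alpha):
        """Observed NCS(1->2) beats the surrogate 95th percentile for
        strongly coupled data in most seeds."""
        cfg = TrainConfig(max_iter=80)
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            x = simulate_source_dynamics(gt_alpha, 10, 400, 256.0, "high",
                                         seed=seed)
            vs = make_vs(x)
            series, bounds = concatenate_trials(vs)
            m = fit_nmvar_ann(series, bounds, 2, 10, train_cfg=cfg, seed=seed)
            res = connectivity_measures(m, series, bounds)
            null = time_shift_surrogates(vs, 2, 10, 20, seed=seed + 900,
                                         train_cfg=cfg)
            thr = empirical_upper_quantile(null.samples["ncs"], 0.05)
            hits += res.ncs[1, 0] > thr[1, 0]
        assert hits >= n_seeds - 1

    def test_determinism(self, gt_alpha):
        x = simulate_source_dynamics(gt_alpha, 6, 300, 256.0, "low", seed=3)
        vs = make_vs(x)
        cfg = TrainConfig(max_iter=40)
        a = time_shift_surrogates(vs, 2, 6, 3, seed=7, train_cfg=cfg)
        b = time_shift_surrogates(vs, 2, 6, 3, seed=7, train_cfg=cfg)
        assert np.array_equal(a.samples["ncs"], b.samples["ncs"])


class TestSignificance:
    def _result(self, lcs, ncs):
        return ConnectivityResult(lcs=np.asarray(lcs, float),
                                  ncs=np.asarray(ncs, float))

    def _null(self, lcs_samples, ncs_samples):
        from srcconn.connectivity import SurrogateDistribution

        return SurrogateDistribution(
            samples={"lcs": np.asarray(lcs_samples, float),
                     "ncs": np.asarray(ncs_samples, float)}
        )

    def test_below_all_surrogates_masked(self):
        obs = self._result([[0, 0.1], [0.1, 0]], [[0, 0.1], [0.1, 0]])
        samples = np.ones((20, 2, 2))
        res = apply_significance(obs, self._null(samples, samples), 0.05)
        assert np.all(res.lcs == 0)
        assert not res.significant["ncs"].any()

    def test_above_all_surrogates_retained(self):
        obs = self._result([[0, 5.0], [4.0, 0]], [[0, 5.0], [4.0, 0]])
        samples = np.abs(np.random.default_rng(0).standard_normal((20, 2, 2)))
        res = apply_significance(obs, self._null(samples, samples), 0.05)
        assert res.lcs[0, 1] == 5.0
        assert res.significant["lcs"][0, 1]

    def test_zero_variance_null_conservative(self):
        obs = self._result([[0, 1.0], [1.0, 0]], [[0, 1.0], [1.0, 0]])
        samples = np.ones((10, 2, 2))
        res = apply_significance(obs, self._null(samples, samples), 0.05)
        assert not res.significant["lcs"].any()

    def test_quantile_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for n, q in [(20, 0.05), (100, 0.05), (37, 0.10)]:
            s = rng.standard_normal((n, 2, 2))
            got = empirical_upper_quantile(s, q)
            k = min(int(np.ceil((1 - q) * (n + 1))), n)
            expect = np.stack(
                [np.sort(s[:, i, j])[k - 1] for i in range(2) for j in range(2)]
            ).reshape(2, 2)
            assert np.allclose(got, expect)


class TestNormalization:
    def _pair(self, a_lcs, a_ncs, b_lcs, b_ncs, sid="s1"):
        a = ConnectivityResult(lcs=np.asarray(a_lcs, float),
                               ncs=np.asarray(a_ncs, float), subject_id=sid)
        b = ConnectivityResult(lcs=np.asarray(b_lcs, float),
                               ncs=np.asarray(b_ncs, float), subject_id=sid)
        return a, b

    def test_max_becomes_exactly_one(self):
        a, b = self._pair([[0, 0.4], [0.8, 0]], [[0, 0.2], [0.1, 0]],
                          [[0, 0.3], [0.5, 0]], [[0, 0.6], [0.1, 0]])
        na, nb = normalize_subject((a, b))
        off = ~np.eye(2, dtype=bool)
        assert max(na.lcs[off].max(), nb.lcs[off].max()) == 1.0
        assert max(na.ncs[off].max(), nb.ncs[off].max()) == 1.0
        for r in (na, nb):
            assert np.all(r.lcs[off] <= 1.0) and np.all(r.ncs[off] <= 1.0)
            assert r.normalized

    def test_all_zero_warns(self):
        a, b = self._pair(np.zeros((2, 2)), np.zeros((2, 2)),
                          np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="all-zero"):
            na, nb = normalize_subject((a, b))
        assert np.all(na.lcs == 0)

    def test_scale_invariance(self):
        a, b = self._pair([[0, 0.4], [0.8, 0]], [[0, 0.2], [0.1, 0]],
                          [[0, 0.3], [0.5, 0]], [[0, 0.6], [0.1, 0]])
        n1 = normalize_subject((a, b))
        a7 = ConnectivityResult(lcs=7 * a.lcs, ncs=7 * a.ncs, subject_id="s1")
        b7 = ConnectivityResult(lcs=7 * b.lcs, ncs=7 * b.ncs, subject_id="s1")
        n2 = normalize_subject((a7, b7))
        assert np.allclose(n1[0].lcs, n2[0].lcs)
        assert np.allclose(n1[1].ncs, n2[1].ncs)
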