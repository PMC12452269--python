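"""Cox partial likelihood, proximal maps, joint objective, and fitting."""

import numpy as np
import pandas as pd
import pytest

import ianam as ia
from ianam.fit import cox_npll_grad, _prox_groups_batch
from ianam.penalty import spearman_weights


def prox_objective_grid(v, t, lam, a, width=8.0, npts=100001):
    """Brute-force prox oracle: minimize (1/(2t))(u-v)^2 + rho(u) on a grid."""
    us = np.linspace(v - width, v + width, npts)
    obj = (us - v) ** 2 / (2 * t) + ia.mcp_value(us, lam, a)
    return us[np.argmin(obj)]


class TestCoxNpll:
    def test_two_sample_hand_value(self):
        # events at t=1 (risk set both) and t=2 (risk set itself):
        # -L = -(1/2)[(0 - log 2) + (0 - log 1)] = log(2)/2
        val = ia.cox_npll(np.zeros(2), np.array([1.0, 2.0]), np.array([1, 1]))
        assert val == pytest.approx(np.log(2) / 2)

    def test_location_invariance(self, rng):
        f = rng.standard_normal(30)
        y = rng.exponential(1, 30)
        delta = rng.integers(0, 2, 30)
        delta[0] = 1
        v1 = ia.cox_npll(f, y, delta)
        v2 = ia.cox_npll(f + 57.3, y, delta)
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_matches_statsmodels_breslow_offset(self, rng):
        # PHReg with the predictor as offset and a zero coefficient returns
        # the Breslow log partial likelihood at that fixed predictor
        from statsmodels.duration.hazard_regression import PHReg

        n = 50
        f = rng.standard_normal(n)
        y = rng.exponential(2, n)
        delta = rng.integers(0, 2, n)
        delta[:3] = 1
        model = PHReg(
            y, rng.standard_normal((n, 1)), status=delta, offset=f,
            ties="breslow",
        )
        ref = -model.loglike(np.zeros(1)) / n
        assert ia.cox_npll(f, y, delta) == pytest.approx(ref, rel=1e-10)

    def test_tied_times_share_risk_set(self):
        # three events all at t = 1: each has the full risk set
        f = np.array([0.5, -0.2, 0.1])
        val = ia.cox_npll(f, np.ones(3), np.ones(3))
        lse = np.log(np.exp(f).sum())
        expected = -(f - lse).sum() / 3
        assert val == pytest.approx(expected)

    def test_all_censored_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="censored"):
            val = ia.cox_npll(np.ones(4), np.arange(1.0, 5.0), np.zeros(4))
        assert val == 0.0

    def test_gradient_matches_finite_differences(self, rng):
        n = 25
        f = rng.standard_normal(n)
        y = rng.exponential(1, n)
        y[5] = y[7]  # include a tie
        delta = rng.integers(0, 2, n)
        delta[:2] = 1
        g = cox_npll_grad(f, y, delta)
        assert g.sum() == pytest.approx(0.0, abs=1e-12)
        eps = 1e-6
        for i in (0, 5, 7, 12):
            fp = f.copy()
            fp[i] += eps
            fm = f.copy()
            fm[i] -= eps
            fd = (ia.cox_npll(fp, y, delta) - ia.cox_npll(fm, y, delta)) / (
                2 * eps
            )
            assert g[i] == pytest.approx(fd, abs=1e-7)


class TestProx:
    def test_zero_input(self):
        assert ia.prox_mcp(0.0, 1.0, 1.0, 3.0) == 0.0

    @pytest.mark.parametrize(
        "v,t,lam,a,expected",
        [
            (5.0, 1.0, 1.0, 3.0, 5.0),     # beyond a*lam: identity
            (2.0, 1.0, 1.0, 3.0, 1.5),     # firm-thresholding zone
            (0.5, 1.0, 1.0, 3.0, 0.0),     # below t*lam: exact zero
        ],
    )
    def test_known_values(self, v, t, lam, a, expected):
        assert ia.prox_mcp(v, t, lam, a) == pytest.approx(expected)

    def test_matches_grid_oracle_on_random_instances(self, rng):
        for _ in range(100):
            a = rng.uniform(1.5, 8.0)
            t = rng.uniform(0.05, min(a - 0.1, 2.0))
            lam = rng.uniform(0.0, 2.0)
            v = rng.uniform(-6, 6)
            grid = prox_objective_grid(v, t, lam, a)
            assert ia.prox_mcp(v, t, lam, a) == pytest.approx(
                grid, abs=2e-4
            )

    def test_ill_posed_step_rejected(self):
        with pytest.raises(ValueError):
            ia.prox_mcp(1.0, 3.0, 1.0, 3.0)

    def test_group_prox_zero_in_zero_out(self):
        np.testing.assert_array_equal(
            ia.prox_group_mcp(np.zeros(4), 0.5, 1.0, 0.5), np.zeros(4)
        )

    def test_group_prox_identity_regime(self, rng):
        # both proxes in their identity zone: vector unchanged
        b = np.array([5.0, 4.0, -6.0])
        out = ia.prox_group_mcp(b, t=0.5, lam_group=1.0, lam_elem=1.0, a=3.0)
        np.testing.assert_allclose(out, b)

    def test_group_prox_thresholds_whole_group(self):
        b = np.array([0.01, 0.02, -0.01])
        out = ia.prox_group_mcp(b, t=0.5, lam_group=1.0, lam_elem=0.5, a=3.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_group_prox_main_entry_passes_elementwise_stage(self):
        # large main effect, tiny interactions: interactions zeroed by the
        # elementwise stage, main survives the group stage
        b = np.array([4.0, 0.05, -0.03])
        out = ia.prox_group_mcp(b, t=0.5, lam_group=0.5, lam_elem=0.5, a=3.0)
        assert out[0] != 0.0
        np.testing.assert_array_equal(out[1:], 0.0)

    def test_batch_matches_single(self, rng):
        groups = rng.standard_normal((12, 4))
        got = _prox_groups_batch(groups, 0.4, 0.9, 0.45, 3.0)
        for j in range(12):
            np.testing.assert_allclose(
                got[j], ia.prox_group_mcp(groups[j], 0.4, 0.9, 0.45, 3.0),
                rtol=1e-12,
            )


class TestJointObjective:
    def test_no_penalty_equals_sum_of_nplls(self, tiny_data, rng):
        train, _, _ = tiny_data
        work = train.standardized()
        gem = ia.GEModel(work.q, work.r, (1, 4, 1), rng=rng, coef_init=0.3)
        im = ia.ImagingModel(work.q, work.p, (1, 4, 1), rng=rng, coef_init=0.3)
        pcfg = ia.PenaltyConfig()
        total = ia.joint_objective(gem, im, work, None, pcfg, "joint")
        expected = ia.cox_npll(
            gem.linear_predictor(work.d, work.z), work.y, work.delta
        ) + ia.cox_npll(
            im.linear_predictor(work.d, work.x), work.y, work.delta
        )
        assert total == pytest.approx(expected, rel=1e-12)

    def test_term_by_term_decomposition(self, tiny_data, rng):
        train, _, _ = tiny_data
        work = train.standardized()
        gem = ia.GEModel(work.q, work.r, (1, 4, 1), rng=rng, coef_init=0.3)
        im = ia.ImagingModel(work.q, work.p, (1, 4, 1), rng=rng, coef_init=0.3)
        w = spearman_weights(work.z, work.x, 0.8)
        pcfg = ia.PenaltyConfig(lam1=0.2, lam2=0.3, lam3=0.01)
        total = ia.joint_objective(gem, im, work, w, pcfg, "joint")
        parts = (
            ia.cox_npll(gem.linear_predictor(work.d, work.z), work.y, work.delta)
            + ia.cox_npll(im.linear_predictor(work.d, work.x), work.y, work.delta)
            + ia.sparse_group_penalty(gem.groups, 0.2, 3.0, np.sqrt(work.q + 1))
            + ia.sparse_group_penalty(im.groups, 0.3, 3.0, np.sqrt(work.q + 1))
            + 0.01 * ia.agreement_penalty(gem, im, w, work.d, work.z, work.x)
        )
        assert total == pytest.approx(parts, rel=1e-10)

    def test_ge_only_mode_drops_imaging_terms(self, tiny_data, rng):
        train, _, _ = tiny_data
        work = train.standardized()
        gem = ia.GEModel(work.q, work.r, (1, 4, 1), rng=rng, coef_init=0.3)
        pcfg = ia.PenaltyConfig(lam1=0.2, lam3=0.5)
        total = ia.joint_objective(gem, None, work, None, pcfg, "ge_only")
        expected = ia.cox_npll(
            gem.linear_predictor(work.d, work.z), work.y, work.delta
        ) + ia.sparse_group_penalty(gem.groups, 0.2, 3.0, np.sqrt(work.q + 1))
        assert total == pytest.approx(expected, rel=1e-12)


class TestFitJoint:
    def test_huge_lam1_zeroes_all_gene_coefficients(self, tiny_data):
        train, _, _ = tiny_data
        pcfg = ia.PenaltyConfig(lam1=50.0, lam2=50.0)
        fcfg = ia.FitConfig(max_epochs=30, learning_rate=0.1, seed=0,
                            mode="ge_only", layer_sizes=(1, 4, 1))
        res = ia.fit_joint(train, pcfg, fcfg)
        assert res.selected_main == []
        assert res.selected_inter == []
        np.testing.assert_array_equal(res.gem.beta, 0.0)
        np.testing.assert_array_equal(res.gem.gamma, 0.0)
        # E coefficients are never proximal-shrunk
        assert np.any(res.gem.alpha != 0.0)

    def test_lam3_zero_joint_matches_ge_only_fit(self, tiny_data):
        train, _, _ = tiny_data
        pcfg = ia.PenaltyConfig(lam1=0.1, lam2=0.1, lam3=0.0)
        kw = dict(max_epochs=25, learning_rate=0.1, seed=7,
                  layer_sizes=(1, 4, 1))
        joint = ia.fit_joint(train, pcfg, ia.FitConfig(mode="joint", **kw))
        solo = ia.fit_joint(train, pcfg, ia.FitConfig(mode="ge_only", **kw))
        np.testing.assert_array_equal(joint.gem.beta, solo.gem.beta)
        np.testing.assert_array_equal(joint.gem.gamma, solo.gem.gamma)
        for w1, w2 in zip(joint.gem.nets.weights, solo.gem.nets.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_monotone_descent_with_backtracking(self, tiny_data):
        train, _, _ = tiny_data
        pcfg = ia.PenaltyConfig(lam1=0.1, lam2=0.1, lam3=1e-4)
        fcfg = ia.FitConfig(max_epochs=40, learning_rate=0.3, seed=3,
                            mode="joint", optimizer="gd", backtracking=True,
                            layer_sizes=(1, 4, 1))
        res = ia.fit_joint(train, pcfg, fcfg)
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6)

    def test_deterministic_given_seed(self, tiny_data):
        train, _, _ = tiny_data
        pcfg = ia.PenaltyConfig(lam1=0.1, lam2=0.1)
        kw = dict(max_epochs=15, learning_rate=0.1, seed=11, mode="joint",
                  layer_sizes=(1, 4, 1), optimizer="adam")
        r1 = ia.fit_joint(train, pcfg, ia.FitConfig(**kw))
        r2 = ia.fit_joint(train, pcfg, ia.FitConfig(**kw))
        np.testing.assert_array_equal(r1.gem.psi, r2.gem.psi)
        assert r1.objective_trace == r2.objective_trace

    def test_linear_limit_recovers_cox_solver(self):
        # frozen zero nets + no penalty = linear Cox partial likelihood;
        # coefficients must match an established solver
        from lifelines import CoxPHFitter

        design = ia.SimDesign(n=200, r=5, p=3, q=2, n_main=3, n_inter=3,
                              example="linear", seed=11)
        train, _, _ = ia.make_dataset(design)
        fcfg = ia.FitConfig(max_epochs=4000, learning_rate=0.5, tol=1e-12,
                            seed=0, mode="ge_only", penalty_flavor="none",
                            train_nets=False, coef_init=0.0)
        res = ia.fit_joint(train, ia.PenaltyConfig(), fcfg)

        work = train.standardized()
        cols = {f"z{j}": work.z[:, j] for j in range(5)}
        cols.update({
            f"dz{k}{j}": work.d[:, k] * work.z[:, j]
            for j in range(5) for k in range(2)
        })
        cols.update({f"d{k}": work.d[:, k] for k in range(2)})
        df = pd.DataFrame(cols)
        df["T"], df["E"] = train.y, train.delta
        cph = CoxPHFitter().fit(df, "T", "E")
        mine = np.concatenate([
            res.gem.beta,
            [res.gem.gamma[k, j] for j in range(5) for k in range(2)],
            res.gem.alpha,
        ])
        ref = np.array(
            [cph.params_[f"z{j}"] for j in range(5)]
            + [cph.params_[f"dz{k}{j}"] for j in range(5) for k in range(2)]
            + [cph.params_[f"d{k}"] for k in range(2)]
        )
        np.testing.assert_allclose(mine, ref, atol=1e-2)

    def test_heredity_in_sparse_group_fits(self, tiny_data):
        train, _, _ = tiny_data
        for lam in (0.05, 0.15, 0.4):
            res = ia.fit_joint(
                train,
                ia.PenaltyConfig(lam1=lam, lam2=lam),
                ia.FitConfig(max_epochs=40, learning_rate=0.1, seed=2,
                             mode="ge_only", layer_sizes=(1, 4, 1)),
            )
            groups = res.gem.groups
            for (k, j) in res.selected_inter:
                assert np.any(groups[j] != 0.0), (
                    f"interaction ({k},{j}) selected but group {j} zeroed"
                )

    def test_missing_imaging_rejected(self, tiny_data):
        train, _, _ = tiny_data
        no_img = ia.SurvivalDataset(d=train.d, z=train.z, y=train.y,
                                    delta=train.delta)
        with pytest.raises(ValueError, match="imaging"):
            ia.fit_joint(no_img, ia.PenaltyConfig(),
                         ia.FitConfig(mode="joint"))


class TestSelectTuning:
    def test_single_point_grid_returns_it(self, tiny_data):
        train, _, _ = tiny_data
        fcfg = ia.FitConfig(max_epochs=10, learning_rate=0.1, seed=0,
                            mode="ge_only", layer_sizes=(1, 4, 1))
        lambdas, res = ia.select_tuning(
            train, {"lam1": [0.2]}, fcfg
        )
        assert lambdas == (0.2, 0.0, 0.0)
        assert res.criterion is not None

    def test_sparser_fit_wins_ties(self, tiny_data):
        # with equal likelihood, BIC strictly prefers fewer nonzero
        # coefficients, so an enormous lam1 (empty model) beats a huge one
        # only through the likelihood; check df monotonicity directly
        from ianam.fit import _bic

        train, _, _ = tiny_data
        fcfg = ia.FitConfig(max_epochs=15, learning_rate=0.1, seed=0,
                            mode="ge_only", layer_sizes=(1, 4, 1))
        res_dense = ia.fit_joint(train, ia.PenaltyConfig(lam1=0.01), fcfg)
        res_sparse = ia.fit_joint(train, ia.PenaltyConfig(lam1=50.0), fcfg)
        df_dense = np.count_nonzero(res_dense.gem.psi)
        df_sparse = np.count_nonzero(res_sparse.gem.psi)
        assert df_sparse < df_dense
        b_dense = _bic(res_dense, train, fcfg)
        b_sparse = _bic(res_sparse, train, fcfg)
        assert np.isfinite(b_dense) and np.isfinite(b_sparse)

    def test_empty_grid_rejected(self, tiny_data):
        train, _, _ = tiny_data
        with pytest.raises(ValueError):
            ia.select_tuning(train, {"lam1": []}, ia.FitConfig(mode="ge_only"))
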