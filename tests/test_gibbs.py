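"""Sampler components against closed forms, plus whole-chain contracts."""

import numpy as np
import pandas as pd
import pytest

from gamcross import _kernels
from gamcross.gibbs import (
    ConsistencyError,
    McmcConfig,
    build_design,
    derive_correlation,
    run_chain,
    sample_gametic_covariance,
    sample_scalar_variance,
)


class TestBuildDesign:
    def test_sow_incidence_column_sums(self, small_dataset):
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        off, n_sow = md.segments["sow"]
        counts = np.bincount(md.bank_levels_of_record[3], minlength=md.n_levels)
        per_sow = d["phenotypes"].groupby("sow_id", sort=False).size()
        for k, sid in enumerate(md.sow_ids):
            assert counts[off + k] == per_sow[sid]

    def test_parity_pooled_at_five(self, small_dataset):
        d = small_dataset
        ph = d["phenotypes"].copy()
        ph.loc[ph.index[:7], "parity"] = [1, 2, 3, 4, 5, 6, 7]
        md = build_design(ph, d["grm"]["E"].index, d["grm"]["R"].index)
        lv = md.bank_levels_of_record[1][:7] - md.segments["parity"][0]
        assert list(lv % 5 + 1) == [1, 2, 3, 4, 5, 5, 5]

    def test_fixed_effects_full_rank_after_constraints(self, small_dataset):
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        assert md.fixed_effect_rank_ok()

    def test_orphan_sow_raises(self, small_dataset):
        d = small_dataset
        ph = d["phenotypes"].copy()
        extra = ph.iloc[[0]].assign(sow_id="GHOST1")
        with pytest.raises(ConsistencyError, match="GHOST1"):
            build_design(
                pd.concat([ph, extra]), d["grm"]["E"].index, d["grm"]["R"].index
            )

    def test_record_role_routing(self, small_dataset):
        """ER records use (p_E, m_R); RE records use (p_R, m_E)."""
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        er = md.cross_code == 0
        assert (md.rec_role["E"][er] == 0).all() and (md.rec_role["R"][er] == 1).all()
        assert (md.rec_role["E"][~er] == 1).all() and (md.rec_role["R"][~er] == 0).all()


class TestScalarConditional:
    def test_single_record_closed_form(self):
        """One record, one effect: mean = w*y / (w + prior_prec)."""
        y, s2e, prior_prec = 3.0, 2.0, 0.5
        e = np.array([y])
        w = np.array([1 / s2e])
        vals = np.zeros(1)
        _kernels.sweep_scalar(
            e, w, vals, np.array([True]), np.array([prior_prec]),
            np.array([0, 1], dtype=np.int64), np.array([0], dtype=np.int64),
            np.zeros(1),
        )
        expected = (y / s2e) / (1 / s2e + prior_prec)
        assert vals[0] == pytest.approx(expected)
        assert e[0] == pytest.approx(y - expected)

    def test_flat_prior_limit_is_gls_mean(self, rng):
        """Zero prior precision: conditional mean is the LS estimate."""
        y = rng.normal(5.0, 1.0, 200)
        e = y.copy()
        w = np.full(200, 1 / 0.3)
        vals = np.zeros(1)
        _kernels.sweep_scalar(
            e, w, vals, np.array([True]), np.zeros(1),
            np.array([0, 200], dtype=np.int64), np.arange(200, dtype=np.int64),
            np.zeros(1),
        )
        assert vals[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_gametic_single_site_closed_form(self):
        """One gamete, one record, fixed V: matches the scalar posterior."""
        V = np.array([[0.25, 0.0], [0.0, 0.25]])
        Vinv = np.linalg.inv(V)
        G = np.eye(1)
        y, s2e = 1.7, 0.9
        e = np.array([y])
        w = np.array([1 / s2e])
        U = np.zeros((1, 2))
        Q = np.zeros((1, 2))
        _kernels.sweep_gametic(
            e, w, U, G, Q, Vinv, np.array([0], dtype=np.int64),
            np.array([0, 1], dtype=np.int64), np.array([0], dtype=np.int64),
            np.zeros(2),
        )
        prec = 1 / s2e + Vinv[0, 0]
        assert U[0, 0] == pytest.approx((y / s2e) / prec)
        # data-free maternal role: conditional prior mean is 0 when sigma_pm=0
        assert U[0, 1] == pytest.approx(0.0)

    def test_two_gamete_toy_marginal_moments(self, rng):
        """G=I, sigma_pm=0: sampled marginals match independent closed form."""
        V = np.array([[0.4, 0.0], [0.0, 0.4]])
        Vinv = np.linalg.inv(V)
        G = np.eye(2)
        y = np.array([2.0, -1.0])
        s2e = 1.0
        w = np.full(2, 1 / s2e)
        U = np.zeros((2, 2))
        Q = np.zeros((2, 2))
        indptr = np.array([0, 1, 2], dtype=np.int64)
        recs = np.array([0, 1], dtype=np.int64)
        active = np.array([0, 0], dtype=np.int64)
        draws = np.empty((20000, 2))
        e = y.copy()
        for k in range(20000):
            z = rng.standard_normal(4)
            _kernels.sweep_gametic(e, w, U, G, Q, Vinv, active, indptr, recs, z)
            draws[k] = U[:, 0]
        prec = 1 / s2e + 1 / V[0, 0]
        for g in range(2):
            assert draws[:, g].mean() == pytest.approx((y[g] / s2e) / prec, abs=0.02)
            assert draws[:, g].var() == pytest.approx(1 / prec, rel=0.05)


class TestVarianceConditionals:
    def test_scalar_variance_moment_recovery(self, rng):
        x = rng.normal(0, np.sqrt(4.296), 10000)
        draws = np.array([sample_scalar_variance(x, rng) for _ in range(400)])
        se = draws.std() / np.sqrt(len(draws)) + 4.296 * np.sqrt(2 / 10000)
        assert abs(draws.mean() - 4.296) < 3 * se + 0.05

    def test_scalar_variance_quadrature_oracle_two_records(self, rng):
        """n=2 flat-prior conditional vs numeric scaled-inv-chi2 CDF."""
        from scipy import stats

        x = np.array([1.0, -2.0])
        ss = float(x @ x)
        draws = np.array([sample_scalar_variance(x, rng, dof_offset=0) for _ in range(50000)])
        # df=2 scaled inverse chi-square: ss/draw ~ chi2(2)
        ks = stats.kstest(ss / draws, "chi2", args=(2,)).statistic
        assert ks < 0.02

    def test_zero_residuals_flagged(self, rng):
        with pytest.warns(UserWarning, match="degenerate"):
            sample_scalar_variance(np.zeros(5), rng)

    def test_covariance_moment_oracle_identity_G(self, rng):
        V_true = np.array([[0.3, 0.12], [0.12, 0.2]])
        n = 4000
        L = np.linalg.cholesky(V_true)
        U = rng.standard_normal((n, 2)) @ L.T
        draws = np.array(
            [sample_gametic_covariance(U, np.eye(n), rng) for _ in range(200)]
        )
        target = U.T @ U / n
        se = draws.std(axis=0) / np.sqrt(200)
        assert np.all(np.abs(draws.mean(axis=0) - target) < 3 * se + 0.02)

    def test_zero_effects_flagged(self, rng):
        with pytest.warns(UserWarning, match="degenerate"):
            sample_gametic_covariance(np.zeros((10, 2)), np.eye(10), rng)

    def test_covariance_draw_symmetric_pd(self, rng):
        U = rng.standard_normal((50, 2))
        V = sample_gametic_covariance(U, np.eye(50), rng)
        assert V[0, 1] == V[1, 0]
        assert np.linalg.eigvalsh(V)[0] > 0


class TestCorrelation:
    def test_identity_gives_zero(self):
        assert derive_correlation(np.eye(2)) == 0.0

    def test_boundary_case(self):
        V = np.array([[0.2, 0.2], [0.2, 0.2]])
        assert derive_correlation(V) == pytest.approx(1.0)

    def test_arithmetic(self):
        V = np.array([[0.206, 0.1], [0.1, 0.197]])
        assert derive_correlation(V) == pytest.approx(0.1 / np.sqrt(0.206 * 0.197))

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(derive_correlation(np.diag([0.0, 1.0])))


class TestRunChain:
    def test_determinism_under_fixed_seed(self, small_dataset):
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        cfg = McmcConfig(n_iter=300, burn_in=100, thin=2, seed=5)
        a = run_chain(md, d["grm"]["E"], d["grm"]["R"], cfg)
        b = run_chain(md, d["grm"]["E"], d["grm"]["R"], cfg)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_stored_draws_valid(self, small_dataset):
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        cfg = McmcConfig(n_iter=600, burn_in=200, thin=4, seed=1)
        s = run_chain(md, d["grm"]["E"], d["grm"]["R"], cfg)
        assert len(s.draws) == 100
        for o in ("E", "R"):
            r = s.draws[f"r_pm{o}"]
            assert r.between(-1, 1).all()
            det = (s.draws[f"sigma2_p{o}"] * s.draws[f"sigma2_m{o}"]
                   - s.draws[f"sigma_pm{o}"] ** 2)
            assert (det > 0).all()
        assert (s.draws[[c for c in s.draws if c.startswith("sigma2")]] > 0).all().all()

    def test_null_gametic_variance_recovered_near_zero(self):
        """Data with zero gametic effects: posterior mass of s2_p near 0."""
        from conftest import table4_params

        from gamcross.simulate import CrossDesign, simulate_dataset

        params = table4_params()
        for tp in (params.tnb, params.nba):
            tp.V_E = np.zeros((2, 2))
            tp.V_R = np.zeros((2, 2))
        design = CrossDesign(
            n_sires_E=10, n_dams_E=20, n_sires_R=10, n_dams_R=20,
            n_er_sows=200, n_re_sows=200,
        )
        data = simulate_dataset(
            n_founders_E=25, n_founders_R=25, n_snp=400,
            design=design, params=params, seed=31,
        )
        md = build_design(
            data["phenotypes"], data["grm"]["E"].index, data["grm"]["R"].index
        )
        s = run_chain(
            md, data["grm"]["E"], data["grm"]["R"],
            McmcConfig(n_iter=12_000, burn_in=3_000, thin=5, seed=32),
        )
        for p in ("sigma2_pE", "sigma2_mE", "sigma2_pR", "sigma2_mR"):
            assert s.draws[p].median() < 0.25

    def test_tidy_round_trip(self, small_dataset):
        d = small_dataset
        md = build_design(d["phenotypes"], d["grm"]["E"].index, d["grm"]["R"].index)
        cfg = McmcConfig(n_iter=220, burn_in=20, thin=2, seed=3)
        s = run_chain(md, d["grm"]["E"], d["grm"]["R"], cfg)
        from gamcross.gibbs import McmcSamples

        back = McmcSamples.from_tidy(s.to_tidy())
        merged = back.draws[s.draws.columns]
        pd.testing.assert_frame_equal(merged, s.draws, check_dtype=False)


@pytest.mark.parametrize(
    "kwargs", [dict(burn_in=10, n_iter=5), dict(thin=0), dict(sweep_order="x")]
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        McmcConfig(**kwargs)
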