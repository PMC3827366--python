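"""Cyclic spline basis, penalized fitting, GCV, limits and recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from windgain.gam import CircularGainGAM, CyclicSpline


def make_data(seed=0, n=200, noise=60.0, surface=None, kappa=1.0):
    rng = np.random.default_rng(seed)
    speed = rng.weibull(2.0, n) * 8.0
    direction = np.degrees(rng.vonmises(np.deg2rad(270.0), kappa, n)) % 360.0
    season = np.repeat(["2009/10", "2010/11"], [n // 2, n - n // 2])
    stage = rng.choice(["guard", "creche"], n)
    if surface is None:
        surface = lambda s, d: 250.0 + 10.0 * s * np.cos(np.deg2rad(d - 270.0))
    y = surface(speed, direction) + rng.normal(0.0, noise, n)
    return pd.DataFrame(
        {
            "gain_g": y,
            "speed_ms": speed,
            "direction_deg": direction,
            "season": season,
            "stage": stage,
        }
    )


class TestCyclicSpline:
    def test_rows_at_0_and_360_identical(self):
        sp = CyclicSpline(8)
        assert np.array_equal(sp.basis(0.0), sp.basis(360.0))

    def test_interpolates_coefficients_at_knots(self):
        sp = CyclicSpline(8)
        assert np.allclose(sp.basis(sp.knots), np.eye(8), atol=1e-12)

    def test_constant_in_penalty_null_space(self):
        S = CyclicSpline(8).penalty()
        ones = np.ones(8)
        assert abs(ones @ S @ ones) < 1e-12
        # PSD with exactly one zero eigenvalue
        w = np.linalg.eigvalsh(S)
        assert w[0] > -1e-12 and np.sum(w < 1e-12) == 1

    def test_penalty_matches_quadrature_for_cosine(self):
        """β'Sβ for the spline interpolating cos(d·π/180) at k=10 knots agrees
        with the numerical integral of the squared second derivative."""
        sp = CyclicSpline(10)
        beta = np.cos(np.deg2rad(sp.knots))
        form = beta @ sp.penalty() @ beta
        true, _ = quad(lambda d: ((np.pi / 180.0) ** 2 * np.cos(np.deg2rad(d))) ** 2, 0, 360)
        assert form == pytest.approx(true, rel=1e-2)

    def test_continuity_at_seam(self):
        sp = CyclicSpline(7)
        rng = np.random.default_rng(4)
        beta = rng.normal(size=7)
        eps = 1e-7
        left = (sp.basis(360.0 - eps) @ beta).item()
        right = (sp.basis(eps) @ beta).item()
        assert left == pytest.approx(right, abs=1e-5)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            CyclicSpline(3)


class TestModelConstruction:
    def test_k_exceeding_distinct_directions_errors(self):
        df = make_data(n=30)
        df["direction_deg"] = np.tile([0.0, 90.0, 180.0, 270.0, 45.0], 6)
        with pytest.raises(ValueError, match="distinct"):
            CircularGainGAM.from_dataframe(df, k=8)

    def test_too_few_days_errors(self):
        with pytest.raises(ValueError, match="20"):
            CircularGainGAM.from_dataframe(make_data(n=15))

    def test_listwise_deletion_logged(self):
        df = make_data(n=40)
        df.loc[3, "gain_g"] = np.nan
        df.loc[7, "speed_ms"] = np.nan
        m = CircularGainGAM.from_dataframe(df)
        assert m.n_dropped == 2 and m.nobs == 38

    def test_collinear_parametric_terms_error(self):
        df = make_data(n=60)
        df["stage"] = df["season"]  # stage duplicates season
        with pytest.raises(ValueError, match="collinear"):
            CircularGainGAM.from_dataframe(df)

    def test_smooths_sum_to_zero_over_data(self):
        df = make_data(n=100)
        m = CircularGainGAM.from_dataframe(df)
        X1 = m.exog[:, m.term_slices["s(direction)"]]
        assert np.allclose(X1.sum(axis=0), 0.0, atol=1e-8)


class TestFittingLimits:
    def test_infinite_lambda_equals_parametric_ols(self):
        df = make_data(seed=1, n=150)
        m = CircularGainGAM.from_dataframe(df)
        res = m.fit(lam=np.inf)
        Xp = m.exog[:, : m.term_slices["speed"].stop]
        beta, *_ = np.linalg.lstsq(Xp, m.gain, rcond=None)
        assert np.allclose(res.fittedvalues, Xp @ beta, atol=1e-8)
        assert res.edf["s(direction)"] == 0.0

    def test_zero_lambda_equals_full_basis_ols(self):
        df = make_data(seed=2, n=150)
        m = CircularGainGAM.from_dataframe(df)
        res = m.fit(lam=0.0)
        beta, *_ = np.linalg.lstsq(m.exog, m.gain, rcond=None)
        assert np.allclose(res.fittedvalues, m.exog @ beta, atol=1e-8)
        assert res.edf_total == pytest.approx(m.nparams, abs=1e-6)

    def test_fitted_plus_residuals_equals_response(self):
        df = make_data(seed=3, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(10.0, 100.0))
        assert np.array_equal(res.fittedvalues + res.resid,
                              CircularGainGAM.from_dataframe(df).gain)

    def test_matches_direct_normal_equations(self):
        """Independent penalized-regression reference: direct solve of
        (X'X + Σ λ_j S_j) β = X'y at fixed λ, compared on fitted values."""
        df = make_data(seed=4, n=120)
        m = CircularGainGAM.from_dataframe(df)
        lam = {"s(direction)": 25.0, "s(direction):speed": 3000.0}
        res = m.fit(lam=lam)
        S = m._embedded_penalties()
        A = m.exog.T @ m.exog + sum(lam[s] * S[s] for s in lam)
        beta_ref = np.linalg.solve(A, m.exog.T @ m.gain)
        assert np.allclose(res.fittedvalues, m.exog @ beta_ref, atol=1e-6)
        assert np.allclose(res.params, beta_ref, atol=1e-6)

    def test_edf_monotone_in_lambda(self):
        df = make_data(seed=5, n=150)
        m = CircularGainGAM.from_dataframe(df)
        for smooth in m.smooth_names:
            last = np.inf
            for lam in 10.0 ** np.arange(-3, 10):
                other = {s: 1.0 for s in m.smooth_names}
                other[smooth] = lam
                edf = m.fit(lam=other).edf[smooth]
                assert edf <= last + 1e-8
                last = edf

    def test_edf_bounds(self):
        df = make_data(seed=6, n=150)
        m = CircularGainGAM.from_dataframe(df)
        res = m.fit(lam=1.0)
        for s in m.smooth_names:
            assert 0.0 < res.edf[s] <= m.k - 1

    def test_deviance_explained_100pct_on_noise_free_data(self):
        # response generated exactly in the model's span
        df = make_data(seed=7, n=150, noise=0.0)
        m0 = CircularGainGAM.from_dataframe(df)
        rng = np.random.default_rng(70)
        beta_true = rng.normal(0.0, 5.0, m0.nparams)
        df["gain_g"] = m0.exog @ beta_true
        res = CircularGainGAM.from_dataframe(df).fit(lam=0.0)
        assert res.deviance_explained == pytest.approx(100.0, abs=1e-6)


class TestGCVSelection:
    def test_selected_score_beats_grid(self):
        df = make_data(seed=8, n=120)
        m = CircularGainGAM.from_dataframe(df)
        res = m.fit()
        for l1 in 10.0 ** np.arange(-2, 9, 2):
            for l2 in 10.0 ** np.arange(-2, 9, 2):
                cand = m.fit(lam=(l1, l2))
                assert res.gcv_score <= cand.gcv_score + 1e-9

    def test_pure_linear_truth_shrinks_smooths_and_recovers_slope(self):
        """Data with no direction effect: smooth EDFs collapse and the wind
        speed slope is recovered within 2 SE in ≥ 90% of seeded fits."""
        hits, edf1, edf2 = 0, [], []
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            n = 150
            speed = rng.weibull(2.0, n) * 8.0
            direction = rng.uniform(0.0, 360.0, n)
            y = 250.0 + 12.0 * speed + rng.normal(0, 40.0, n)
            m = CircularGainGAM(y, speed, direction)
            res = m.fit()
            i = m.term_slices["speed"].start
            if abs(res.params[i] - 12.0) <= 2.0 * res.bse[i]:
                hits += 1
            edf1.append(res.edf["s(direction)"])
            edf2.append(res.edf["s(direction):speed"])
        assert hits / n_runs >= 0.9
        # GCV occasionally undersmooths a single run; the typical fit
        # collapses both smooths to (near) their null-space floor of zero
        assert np.median(edf1) < 0.5 and np.median(edf2) < 0.5


class TestPredictionSurface:
    def test_periodic_in_direction(self):
        df = make_data(seed=9, n=150)
        res = CircularGainGAM.from_dataframe(df).fit()
        speeds = np.linspace(0.0, 15.0, 6)
        p0 = res.predict(np.zeros(6), speeds)
        p360 = res.predict(np.full(6, 359.999999), speeds)
        assert np.allclose(p0, p360, atol=1e-4)

    def test_recovers_westerly_optimum(self):
        df = make_data(seed=10, n=300, noise=40.0)
        res = CircularGainGAM.from_dataframe(df).fit()
        dirs = np.arange(0.0, 360.0, 1.0)
        pred = res.predict(dirs, 10.0)
        best = dirs[np.argmax(pred)]
        assert abs((best - 270.0 + 180.0) % 360.0 - 180.0) <= 20.0

    def test_surface_is_deterministic(self):
        df = make_data(seed=11, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(1.0, 1.0))
        a = res.predict_surface()
        b = res.predict_surface()
        pd.testing.assert_frame_equal(a, b)

    def test_extrapolation_flagged(self):
        df = make_data(seed=12, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(1.0, 1.0))
        surf = res.predict_surface(speeds=np.array([df.speed_ms.max() + 5.0]))
        assert surf["extrapolated"].all()

    def test_empty_grid_errors(self):
        df = make_data(seed=13, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            res.predict_surface(directions=np.array([]))

    def test_reference_levels_recorded(self):
        df = make_data(seed=14, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(1.0, 1.0))
        surf = res.predict_surface()
        assert surf.attrs["reference_levels"]["season"] == "2009/10"


class TestTermTable:
    def test_table_shape_and_content(self):
        df = make_data(seed=15, n=150)
        res = CircularGainGAM.from_dataframe(df).fit()
        tab = res.term_table()
        assert list(tab.columns) == ["term", "edf", "F", "p"]
        assert set(tab.term) == {
            "season",
            "stage",
            "speed",
            "s(direction)",
            "s(direction):speed",
        }
        assert ((tab.p >= 0) & (tab.p <= 1)).all()

    def test_strong_interaction_detected(self):
        df = make_data(seed=16, n=300, noise=30.0)
        res = CircularGainGAM.from_dataframe(df).fit()
        tab = res.term_table().set_index("term")
        assert tab.loc["s(direction):speed", "p"] < 0.01

    def test_summary_mentions_key_quantities(self):
        df = make_data(seed=17, n=100)
        res = CircularGainGAM.from_dataframe(df).fit(lam=(1.0, 1.0))
        text = res.summary()
        assert "deviance explained" in text
        assert "s(direction):speed" in text
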