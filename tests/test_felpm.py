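"""Estimation core: within transformation, cluster sandwich, Wald machinery."""

import numpy as np
import pandas as pd
import pytest

import carebundle as cb
from carebundle.felpm import CollinearityError


def _random_panel(seed=0, n=50, n_clusters=5, k=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {f"x{j}": rng.standard_normal(n) for j in range(k)}
        | {
            "y": rng.standard_normal(n),
            "hospital": rng.integers(0, n_clusters, n).astype(str),
        }
    )
    return df


def brute_force_cr(df, xcols, cluster, absorb=None, cr1=True):
    """Independent sandwich oracle: explicit dummies, per-cluster outer products."""
    X = df[xcols].to_numpy(float)
    if absorb is not None:
        D = pd.get_dummies(df[absorb], dtype=float).to_numpy()
        X = np.column_stack([X, D])
        k_reported = len(xcols)
    else:
        X = np.column_stack([np.ones(len(df)), X])
        k_reported = len(xcols) + 1
    y = df["y"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    groups = df[cluster].to_numpy()
    for g in np.unique(groups):
        m = groups == g
        s = X[m].T @ u[m]
        meat += np.outer(s, s)
    V = bread @ meat @ bread
    G = len(np.unique(groups))
    n, K = X.shape
    if cr1:
        V = V * (G / (G - 1)) * ((n - 1) / (n - K))
    if absorb is not None:
        return beta[:k_reported], V[:k_reported, :k_reported]
    return beta, V


class TestIdentities:
    def test_saturated_did_equals_difference_in_means(self):
        """With one hospital per country and a single split, the FE interaction
        is exactly the raw difference-in-differences of the four cell means."""
        cells = {  # (hospital, post): (mean, n)
            ("E", 0): (0.1, 10), ("E", 1): (0.6, 10),
            ("W", 0): (0.1, 10), ("W", 1): (0.2, 10),
        }
        rows = []
        for (h, post), (mean, n) in cells.items():
            ones = int(round(mean * n))
            for i in range(n):
                rows.append({"hospital": h, "post": float(post),
                             "england_post": float(post) * (h == "E"),
                             "y": float(i < ones)})
        df = pd.DataFrame(rows)
        spec = cb.PanelSpec(outcome="y", regressors=("post", "england_post"),
                            absorb="hospital", cluster="hospital")
        fit = cb.FixedEffectsLPM(df, spec).fit()
        assert fit.params["england_post"] == pytest.approx(0.4, abs=1e-8)

    def test_cr0_equals_hc0_with_singleton_clusters(self):
        df = _random_panel(seed=1, n=40, n_clusters=40)
        df["cluster"] = np.arange(len(df)).astype(str)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x2"),
                            absorb=None, cluster="cluster")
        fit = cb.FixedEffectsLPM(df, spec).fit(cov_type="CR0")
        import statsmodels.api as sm

        X = sm.add_constant(df[["x0", "x1", "x2"]])
        hc0 = sm.OLS(df["y"], X).fit(cov_type="HC0")
        assert np.allclose(fit.cov.to_numpy(), hc0.cov_params().to_numpy(), atol=1e-12)

    def test_cluster_sandwich_matches_brute_force(self):
        df = _random_panel(seed=2)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x2"),
                            absorb=None, cluster="hospital")
        fit = cb.FixedEffectsLPM(df, spec).fit()
        beta, V = brute_force_cr(df, ["x0", "x1", "x2"], "hospital")
        # column order in both: [const, x0, x1, x2]
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert np.allclose(fit.cov.to_numpy(), V, atol=1e-10)

    def test_within_transformation_equals_explicit_dummies(self):
        df = _random_panel(seed=3, n=200, n_clusters=15)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x2"),
                            absorb="hospital", cluster="hospital")
        fit = cb.FixedEffectsLPM(df, spec).fit()
        beta, V = brute_force_cr(df, ["x0", "x1", "x2"], "hospital", absorb="hospital")
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert np.allclose(fit.cov.to_numpy(), V, atol=1e-8)

    def test_permutation_invariance(self):
        df = _random_panel(seed=4, n=120, n_clusters=8)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x2"),
                            absorb="hospital", cluster="hospital")
        fit1 = cb.FixedEffectsLPM(df, spec).fit()
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = cb.FixedEffectsLPM(shuffled, spec).fit()
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10)
        assert np.allclose(fit1.bse.to_numpy(), fit2.bse.to_numpy(), atol=1e-10)


class TestDiagnostics:
    def test_collinear_columns_named(self):
        df = _random_panel(seed=5)
        df["x_dup"] = df["x0"] * 2.0
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x_dup"),
                            absorb="hospital", cluster="hospital")
        with pytest.raises(CollinearityError) as err:
            cb.FixedEffectsLPM(df, spec).fit()
        assert set(err.value.columns) & {"x0", "x_dup"}

    def test_constant_absorbed_by_fe_is_collinear(self):
        df = _random_panel(seed=6)
        df["country_dummy"] = (df["hospital"].astype(int) < 3).astype(float)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "country_dummy"),
                            absorb="hospital", cluster="hospital")
        with pytest.raises(CollinearityError, match="country_dummy"):
            cb.FixedEffectsLPM(df, spec).fit()

    def test_singletons_counted_and_retained(self):
        df = _random_panel(seed=7, n=21, n_clusters=20)
        spec = cb.PanelSpec(outcome="y", regressors=("x0",),
                            absorb="hospital", cluster="hospital")
        fit = cb.FixedEffectsLPM(df, spec).fit()
        assert fit.nobs == 21
        assert fit.n_singletons >= 1

    def test_requires_two_clusters(self):
        df = _random_panel(seed=8)
        df["hospital"] = "only_one"
        spec = cb.PanelSpec(outcome="y", regressors=("x0",), absorb=None, cluster="hospital")
        with pytest.raises(ValueError, match="2 clusters"):
            cb.FixedEffectsLPM(df, spec).fit()


class TestWald:
    @pytest.fixture()
    def fit(self):
        df = _random_panel(seed=9, n=200, n_clusters=12)
        spec = cb.PanelSpec(outcome="y", regressors=("x0", "x1", "x2"),
                            absorb="hospital", cluster="hospital")
        return cb.FixedEffectsLPM(df, spec).fit()

    def test_single_coefficient_is_squared_z(self, fit):
        w = fit.wald_joint(["x1"])
        z = fit.params["x1"] / fit.bse["x1"]
        assert w.statistic == pytest.approx(z**2, rel=1e-10)
        assert w.df == 1

    def test_orthogonal_coefficients_sum_of_squares(self, fit):
        """With the cross-covariance zeroed, the joint statistic is the sum of squared z-scores."""
        import copy

        f = copy.deepcopy(fit)
        f.cov.loc["x0", "x1"] = f.cov.loc["x1", "x0"] = 0.0
        w = f.wald_joint(["x0", "x1"])
        z2 = sum((f.params[c] / f.bse[c]) ** 2 for c in ("x0", "x1"))
        assert w.statistic == pytest.approx(z2, rel=1e-10)

    def test_lincomb_matches_manual(self, fit):
        est, se, _ = fit.lincomb(["x0", "x1"], weights=[1.0, -1.0])
        manual = fit.params["x0"] - fit.params["x1"]
        var = (fit.cov.loc["x0", "x0"] + fit.cov.loc["x1", "x1"]
               - 2 * fit.cov.loc["x0", "x1"])
        assert est == pytest.approx(manual)
        assert se == pytest.approx(np.sqrt(var))

    def test_pvalues_use_g_minus_1_df(self, fit):
        from scipy import stats

        t = fit.tvalues["x0"]
        assert fit.pvalues["x0"] == pytest.approx(2 * stats.t.sf(abs(t), fit.n_clusters - 1))

    def test_summary_renders_stars_and_counts(self, fit):
        text = fit.summary()
        assert f"clusters = {fit.n_clusters}" in text
        assert "t with G-1 df" in text
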