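"""Linear probability model with absorbed group fixed effects and clustered errors.

The estimator is ordinary least squares on within-group-demeaned data (the
fixed effect absorbed by demeaning), with a cluster-robust sandwich
covariance

    V = c * (X'X)^{-1} [ sum_g (X_g' u_g)(X_g' u_g)' ] (X'X)^{-1}

assembled cluster by cluster. The default small-sample factor is CR1,
``c = G/(G-1) * (N-1)/(N-K)``, with ``K`` counting both the regressors and
the absorbed group intercepts; CR0 (``c = 1``) is available behind a flag.
Inference uses the t distribution with ``G - 1`` degrees of freedom, the
standard convention when the number of clusters is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient after the within transformation."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "collinear columns after within-transformation: " + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class PanelSpec:
    """An estimand description: outcome, regressors, absorbed FE, cluster."""

    outcome: str
    regressors: tuple[str, ...]
    absorb: str | None = "hospital"
    cluster: str = "hospital"

    def __post_init__(self):
        object.__setattr__(self, "regressors", tuple(self.regressors))


@dataclass
class WaldTest:
    statistic: float
    df: int
    pvalue: float  # chi-square reference (classical Wald)
    f_statistic: float
    df_denom: int
    f_pvalue: float  # F(df, G-1) reference, conservative with few clusters


_STARS = ((0.01, "***"), (0.05, "**"), (0.10, "*"))


def _stars(p: float) -> str:
    for cut, sym in _STARS:
        if p < cut:
            return sym
    return ""


@dataclass
class FEResults:
    """Estimates, cluster-robust covariance and diagnostics from one fit."""

    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    n_clusters: int
    n_absorbed: int
    n_singletons: int
    cov_type: str
    spec: PanelSpec
    effects: dict = field(default_factory=dict)  # named effect -> coefficient name
    extras: dict = field(default_factory=dict)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def df_inference(self) -> int:
        return self.n_clusters - 1

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_inference), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_inference)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def effect(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) of a named effect registered by the pipeline."""
        coef = self.effects[name]
        return float(self.params[coef]), float(self.bse[coef]), float(self.pvalues[coef])

    def wald_joint(self, names) -> WaldTest:
        """Wald test that the named coefficients are jointly zero."""
        names = list(names)
        r = self.params[names].to_numpy()
        V = self.cov.loc[names, names].to_numpy()
        try:
            stat = float(r @ linalg.solve(V, r, assume_a="pos"))
        except linalg.LinAlgError as exc:
            raise ValueError(f"singular subcovariance for {names}") from exc
        q = len(names)
        g1 = self.df_inference
        f = stat / q
        return WaldTest(
            statistic=stat,
            df=q,
            pvalue=float(stats.chi2.sf(stat, q)),
            f_statistic=f,
            df_denom=g1,
            f_pvalue=float(stats.f.sf(f, q, g1)),
        )

    def lincomb(self, names, weights=None) -> tuple[float, float, float]:
        """Estimate, SE and p of a linear combination of coefficients."""
        names = list(names)
        w = np.ones(len(names)) if weights is None else np.asarray(weights, float)
        est = float(w @ self.params[names].to_numpy())
        se = float(np.sqrt(w @ self.cov.loc[names, names].to_numpy() @ w))
        p = float(2 * stats.t.sf(abs(est / se), self.df_inference))
        return est, se, p

    def summary(self, title: str | None = None) -> str:
        lines = []
        lines.append(title or f"FE-LPM results: {self.spec.outcome}")
        lines.append("=" * 64)
        lines.append(
            f"N = {self.nobs:,}   clusters = {self.n_clusters}   "
            f"absorbed groups = {self.n_absorbed}   cov = {self.cov_type}"
        )
        if self.n_singletons:
            lines.append(f"singleton absorbed groups retained: {self.n_singletons}")
        lines.append("-" * 64)
        lines.append(f"{'coefficient':<32}{'estimate':>10}{'SE':>10}{'':>5}")
        for name in self.params.index:
            lines.append(
                f"{name:<32}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{_stars(self.pvalues[name]):>5}"
            )
        lines.append("-" * 64)
        lines.append("*** p<0.01, ** p<0.05, * p<0.1; t with G-1 df, G = clusters")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "outcome": self.spec.outcome,
            "nobs": int(self.nobs),
            "n_clusters": int(self.n_clusters),
            "cov_type": self.cov_type,
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
        }
        if self.effects:
            d["effects"] = {
                name: dict(zip(("estimate", "se", "pvalue"), self.effect(name)))
                for name in self.effects
            }
        return d


class FixedEffectsLPM:
    """OLS on a binary (or count) outcome with an absorbed fixed effect.

    Parameters
    ----------
    data : DataFrame containing the outcome, regressors, absorb and cluster
        columns. Regressors must already be numeric (dummy-encoded).
    spec : PanelSpec naming them.
    """

    def __init__(self, data: pd.DataFrame, spec: PanelSpec):
        self.spec = spec
        cols = [spec.outcome, *spec.regressors, spec.cluster]
        if spec.absorb:
            cols.append(spec.absorb)
        missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        self.data = data
        self._xnames = list(spec.regressors)
        if spec.absorb is None:
            self._xnames = ["const", *self._xnames]

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: PanelSpec) -> "FixedEffectsLPM":
        return cls(data, spec)

    # -- internals -------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, int]:
        spec = self.spec
        df = self.data
        y = df[spec.outcome].to_numpy(dtype=np.float64)
        X = df[list(spec.regressors)].to_numpy(dtype=np.float64)
        if spec.absorb is None:
            X = np.column_stack([np.ones(len(y)), X])
            n_absorbed = 0
            n_singletons = 0
        else:
            codes, _ = pd.factorize(df[spec.absorb], sort=True)
            n_absorbed = codes.max() + 1
            counts = np.bincount(codes)
            n_singletons = int((counts == 1).sum())
            # within transformation: subtract group means
            gm_y = np.bincount(codes, weights=y) / counts
            y = y - gm_y[codes]
            for j in range(X.shape[1]):
                gm = np.bincount(codes, weights=X[:, j]) / counts
                X[:, j] = X[:, j] - gm[codes]
        cluster_codes, _ = pd.factorize(df[spec.cluster], sort=True)
        return y, X, cluster_codes, np.asarray(self._xnames), n_absorbed, n_singletons

    def fit(self, cov_type: str = "CR1") -> FEResults:
        """Estimate; ``cov_type`` is "CR1" (default) or "CR0".

        Raises CollinearityError naming the offending columns if the design is
        rank deficient after demeaning (e.g. a post-period main effect with
        year dummies, or a country main effect with hospital fixed effects).
        """
        if cov_type not in ("CR0", "CR1"):
            raise ValueError(f"cov_type must be CR0 or CR1, got {cov_type!r}")
        y, X, clusters, names, n_absorbed, n_singletons = self._design()
        n, k = X.shape

        # rank check with column pivoting so the collinear columns can be named
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(n, k) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int((diag > tol).sum())
        if rank < k:
            raise CollinearityError(names[piv[rank:]])

        XtX = X.T @ X
        beta = linalg.solve(XtX, X.T @ y, assume_a="pos")
        u = y - X @ beta

        G = int(clusters.max()) + 1
        if G < 2:
            raise ValueError("cluster-robust covariance requires at least 2 clusters")
        # meat: sum over clusters of (X_g' u_g)(X_g' u_g)'
        scores = X * u[:, None]
        B = np.zeros((G, k))
        np.add.at(B, clusters, scores)
        meat = B.T @ B
        bread = linalg.inv(XtX)
        V = bread @ meat @ bread
        if cov_type == "CR1":
            k_total = k + n_absorbed
            V = V * (G / (G - 1)) * ((n - 1) / (n - k_total))

        idx = pd.Index(names, name="coefficient")
        return FEResults(
            params=pd.Series(beta, index=idx),
            cov=pd.DataFrame(V, index=idx, columns=idx),
            nobs=n,
            n_clusters=G,
            n_absorbed=n_absorbed,
            n_singletons=n_singletons,
            cov_type=cov_type,
            spec=self.spec,
        )
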