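"""Provider decision model under bundled versus itemized pay-for-performance.

A provider can deliver two costly care processes. Under a *bundled* scheme the
funder pays a single price ``P`` only if both processes are delivered; under an
*itemized* scheme each process earns its own price ``p1``/``p2``. Costs are
``c1``, ``c2`` with a joint-provision synergy ``s >= 0`` so that
``c12 = c1 + c2 - s``. Providers maximise financial surplus, choosing among
none / only process 1 / only process 2 / both. Ties (zero or equal profits)
resolve to the lower-effort option, so every decision rule uses strict
inequalities.

Comparing the two schemes at ``P = p1 + p2`` partitions the cost plane into
regions: A/B (both under bundling, a single process under itemization) and
C/D (nothing under bundling, a single process under itemization), plus the
cells where the two schemes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from shapely.geometry import Polygon, box

Choice = Literal["none", "only1", "only2", "both"]
Region = Literal["A", "B", "C", "D", "both_both", "none_none", "degenerate"]

#: effort ordering used to break profit ties (lower effort preferred)
_CHOICE_ORDER: tuple[Choice, ...] = ("none", "only1", "only2", "both")


@dataclass(frozen=True)
class CostProfile:
    """Costs of the two care processes and their joint-provision synergy."""

    c1: float
    c2: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"cost synergy must be non-negative, got s={self.s}")

    @property
    def c12(self) -> float:
        """Joint cost ``c1 + c2 - s`` (derived, never stored)."""
        return self.c1 + self.c2 - self.s


@dataclass(frozen=True)
class PaymentScheme:
    """Either a bundled price ``P`` or per-process prices ``p1``, ``p2``."""

    mode: Literal["bundled", "itemized"]
    P: float | None = None
    p1: float | None = None
    p2: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "bundled":
            if self.P is None:
                raise ValueError("bundled scheme requires a bundled price P")
        elif self.mode == "itemized":
            if self.p1 is None or self.p2 is None:
                raise ValueError("itemized scheme requires prices p1 and p2")
        else:
            raise ValueError(f"unknown payment mode {self.mode!r}")

    @classmethod
    def bundled(cls, P: float) -> "PaymentScheme":
        return cls(mode="bundled", P=P)

    @classmethod
    def itemized(cls, p1: float, p2: float) -> "PaymentScheme":
        return cls(mode="itemized", p1=p1, p2=p2)


@dataclass(frozen=True)
class BenefitProfile:
    """Patient benefit of each process and of joint provision."""

    b1: float
    b2: float
    b12: float

    def __post_init__(self) -> None:
        if min(self.b1, self.b2, self.b12) < 0:
            raise ValueError("benefits must be non-negative")

    @property
    def has_synergy(self) -> bool:
        return self.b12 > self.b1 + self.b2


@dataclass(frozen=True)
class ProviderDecision:
    choice: Choice
    pi1: float
    pi2: float
    pi12: float


@dataclass(frozen=True)
class PopulationSpec:
    """A cost distribution over providers.

    Families:

    - ``"uniform"``: independent U(k1, u1) x U(k2, u2); params
      ``lower=(k1, k2)``, ``upper=(u1, u2)``.
    - ``"lognormal"``: independent shifted lognormals ``k + LN(mu, sigma)``;
      params ``lower=(k1, k2)``, ``mu=(m1, m2)``, ``sigma=(s1, s2)``.
    - ``"gauss_copula"``: the two marginals above coupled through a Gaussian
      copula with correlation ``rho`` (param ``marginals`` = "uniform" or
      "lognormal").
    - ``"points"``: an exact finite-support population; params
      ``points`` (m, 2) and ``weights`` (m,); no sampling noise.
    """

    family: Literal["uniform", "lognormal", "gauss_copula", "points"]
    params: dict = field(default_factory=dict)
    n_providers: int = 100_000
    seed: int = 0


@dataclass(frozen=True)
class SchemeComparison:
    """Monte Carlo (or exact, for finite support) scheme comparison."""

    shares: dict  # scheme -> {choice: share}
    region_shares: dict  # region label -> share
    spending: dict  # scheme -> mean funder payment per provider
    benefit: dict  # scheme -> mean patient benefit per provider
    n_providers: int
    seed: int | None


# ---------------------------------------------------------------------------
# single-provider decisions


def decide_bundled(cost: CostProfile, scheme: PaymentScheme) -> ProviderDecision:
    """Optimal choice when payment requires both processes.

    The provider delivers both iff ``P > c12`` strictly; partial provision is
    never profitable because it earns nothing.
    """
    if scheme.mode != "bundled":
        raise ValueError("decide_bundled requires a bundled scheme")
    pi12 = scheme.P - cost.c12
    choice: Choice = "both" if pi12 > 0 else "none"
    return ProviderDecision(choice=choice, pi1=-cost.c1, pi2=-cost.c2, pi12=pi12)


def decide_itemized(cost: CostProfile, scheme: PaymentScheme) -> ProviderDecision:
    """Optimal choice under per-process prices.

    Profit-maximising among {none, only1, only2, both} with strict
    inequalities; ties resolve to the lower-effort option. Off boundaries this
    reproduces the familiar inequalities: only1 iff ``c1 < p1`` and
    ``c2 > p2 + s``, both iff ``c1 < p1 + s``, ``c2 < p2 + s`` and
    ``pi12 > 0``, and symmetrically for only2.
    """
    if scheme.mode != "itemized":
        raise ValueError("decide_itemized requires an itemized scheme")
    pi1 = scheme.p1 - cost.c1
    pi2 = scheme.p2 - cost.c2
    pi12 = scheme.p1 + scheme.p2 - cost.c12  # = p1 + p2 - c1 - c2 + s
    profits = {"none": 0.0, "only1": pi1, "only2": pi2, "both": pi12}
    best: Choice = "none"
    for option in _CHOICE_ORDER[1:]:
        if profits[option] > profits[best]:
            best = option
    return ProviderDecision(choice=best, pi1=pi1, pi2=pi2, pi12=pi12)


def classify_region(cost: CostProfile, p1: float, p2: float, s: float | None = None) -> Region:
    """Cross-tabulate the itemized and bundled (``P = p1 + p2``) choices.

    A/B: both under bundling but a single process under itemization;
    C/D: none under bundling but a single process under itemization.
    Points lying exactly on a decision boundary are labelled ``degenerate``.
    """
    if s is None:
        s = cost.s
    cost = CostProfile(c1=cost.c1, c2=cost.c2, s=s)
    P = p1 + p2
    boundaries = (
        cost.c1 - p1,
        cost.c2 - p2,
        cost.c1 - (p1 + s),
        cost.c2 - (p2 + s),
        cost.c1 + cost.c2 - (P + s),
    )
    if any(b == 0 for b in boundaries):
        return "degenerate"
    itemized = decide_itemized(cost, PaymentScheme.itemized(p1, p2)).choice
    bundled = decide_bundled(cost, PaymentScheme.bundled(P)).choice
    table: dict[tuple[str, str], Region] = {
        ("only1", "both"): "A",
        ("only2", "both"): "B",
        ("only1", "none"): "C",
        ("only2", "none"): "D",
        ("both", "both"): "both_both",
        ("none", "none"): "none_none",
    }
    try:
        return table[(itemized, bundled)]
    except KeyError:  # (both, none) and (none, both) are impossible off-boundary
        return "degenerate"


# ---------------------------------------------------------------------------
# vectorised decisions


def _decide_bundled_vec(c1: np.ndarray, c2: np.ndarray, s: float, P: float) -> np.ndarray:
    """0 = none, 3 = both (codes follow _CHOICE_ORDER)."""
    return np.where(P - (c1 + c2 - s) > 0, 3, 0)


def _decide_itemized_vec(
    c1: np.ndarray, c2: np.ndarray, s: float, p1: float, p2: float
) -> np.ndarray:
    pi1 = p1 - c1
    pi2 = p2 - c2
    pi12 = p1 + p2 - c1 - c2 + s
    # replicate the strict, lower-effort-tie scalar rule
    best = np.zeros(c1.shape, dtype=np.int8)
    best_profit = np.zeros_like(pi1)
    for code, profit in ((1, pi1), (2, pi2), (3, pi12)):
        better = profit > best_profit
        best = np.where(better, code, best)
        best_profit = np.where(better, profit, best_profit)
    return best


# ---------------------------------------------------------------------------
# population simulation


def _sample_costs(pop: PopulationSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (c1, c2, weights)."""
    rng = np.random.default_rng(pop.seed)
    p = pop.params
    n = pop.n_providers
    if pop.family == "points":
        pts = np.asarray(p["points"], dtype=float)
        w = np.asarray(p.get("weights", np.full(len(pts), 1.0 / len(pts))), dtype=float)
        w = w / w.sum()
        return pts[:, 0], pts[:, 1], w
    if pop.family == "uniform":
        k1, k2 = p.get("lower", (0.0, 0.0))
        u1, u2 = p["upper"]
        c1 = rng.uniform(k1, u1, n)
        c2 = rng.uniform(k2, u2, n)
    elif pop.family == "lognormal":
        k1, k2 = p.get("lower", (0.0, 0.0))
        m1, m2 = p.get("mu", (0.0, 0.0))
        s1, s2 = p.get("sigma", (1.0, 1.0))
        c1 = k1 + rng.lognormal(m1, s1, n)
        c2 = k2 + rng.lognormal(m2, s2, n)
    elif pop.family == "gauss_copula":
        from scipy import stats

        rho = p.get("rho", 0.0)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        u = stats.norm.cdf(z)
        marginals = p.get("marginals", "uniform")
        k1, k2 = p.get("lower", (0.0, 0.0))
        if marginals == "uniform":
            u1, u2 = p["upper"]
            c1 = k1 + u[:, 0] * (u1 - k1)
            c2 = k2 + u[:, 1] * (u2 - k2)
        elif marginals == "lognormal":
            m1, m2 = p.get("mu", (0.0, 0.0))
            s1, s2 = p.get("sigma", (1.0, 1.0))
            c1 = k1 + stats.lognorm.ppf(u[:, 0], s1, scale=np.exp(m1))
            c2 = k2 + stats.lognorm.ppf(u[:, 1], s2, scale=np.exp(m2))
        else:
            raise ValueError(f"unsupported copula marginals {marginals!r}")
    else:
        raise ValueError(f"unsupported density family {pop.family!r}")
    w = np.full(n, 1.0 / n)
    return c1, c2, w


def simulate_population(
    pop: PopulationSpec,
    bundled: PaymentScheme,
    itemized: PaymentScheme,
    benefit: BenefitProfile,
    s: float = 0.0,
) -> SchemeComparison:
    """Aggregate provider choices, spending and patient benefit per scheme.

    Spending is the funder outlay per provider (``P`` when both processes are
    delivered under bundling; ``p1``/``p2`` per delivered process under
    itemization). Benefit is ``b12`` / ``b1`` / ``b2`` / 0 according to the
    provider's choice. Results are exact for the ``points`` family and Monte
    Carlo otherwise, reproducible from ``pop.seed``.
    """
    if bundled.mode != "bundled" or itemized.mode != "itemized":
        raise ValueError("pass (bundled, itemized) schemes in that order")
    c1, c2, w = _sample_costs(pop)
    ch_b = _decide_bundled_vec(c1, c2, s, bundled.P)
    ch_i = _decide_itemized_vec(c1, c2, s, itemized.p1, itemized.p2)

    def shares_of(codes: np.ndarray) -> dict[str, float]:
        return {
            name: float(w[codes == code].sum())
            for code, name in enumerate(_CHOICE_ORDER)
        }

    shares = {"bundled": shares_of(ch_b), "itemized": shares_of(ch_i)}

    region_codes = {
        "A": (ch_i == 1) & (ch_b == 3),
        "B": (ch_i == 2) & (ch_b == 3),
        "C": (ch_i == 1) & (ch_b == 0),
        "D": (ch_i == 2) & (ch_b == 0),
        "both_both": (ch_i == 3) & (ch_b == 3),
        "none_none": (ch_i == 0) & (ch_b == 0),
    }
    region_shares = {k: float(w[m].sum()) for k, m in region_codes.items()}

    spending = {
        "bundled": float((w * np.where(ch_b == 3, bundled.P, 0.0)).sum()),
        "itemized": float(
            (
                w
                * (
                    itemized.p1 * np.isin(ch_i, (1, 3))
                    + itemized.p2 * np.isin(ch_i, (2, 3))
                )
            ).sum()
        ),
    }
    ben_by_code = np.array([0.0, benefit.b1, benefit.b2, benefit.b12])
    benefit_means = {
        "bundled": float((w * ben_by_code[ch_b]).sum()),
        "itemized": float((w * ben_by_code[ch_i]).sum()),
    }
    return SchemeComparison(
        shares=shares,
        region_shares=region_shares,
        spending=spending,
        benefit=benefit_means,
        n_providers=len(c1),
        seed=pop.seed if pop.family != "points" else None,
    )


# ---------------------------------------------------------------------------
# closed-form areas on a uniform rectangle (oracle for the simulation)


def _halfplane(a1: float, a2: float, b: float, radius: float) -> Polygon:
    """Polygon approximating the half-plane {a1*x + a2*y <= b} out to radius."""
    norm = float(np.hypot(a1, a2))
    n = np.array([a1, a2]) / norm
    p0 = n * (b / norm)
    t = np.array([-n[1], n[0]])
    r = radius
    corners = [p0 + r * t, p0 - r * t, p0 - r * t - 2 * r * n, p0 + r * t - 2 * r * n]
    return Polygon(corners)


def region_area_uniform(
    p1: float,
    p2: float,
    s: float,
    bounds: tuple[float, float, float, float],
) -> dict[str, float]:
    """Exact region probabilities for independent uniform costs.

    ``bounds`` is ``(k1, u1, k2, u2)``: the uniform support
    ``[k1, u1] x [k2, u2]``. Returns the probability mass of each decision
    cell and comparison region (``P = p1 + p2``), obtained by clipping the
    half-planes that define each decision rule against the support rectangle.
    """
    k1, u1, k2, u2 = bounds
    if not (np.isfinite([k1, u1, k2, u2]).all()):
        raise ValueError("uniform support must be bounded")
    if u1 <= k1 or u2 <= k2:
        raise ValueError("degenerate uniform support")
    P = p1 + p2
    support = box(k1, k2, u1, u2)
    radius = 10 * (abs(u1) + abs(u2) + abs(k1) + abs(k2) + P + s + 1)

    def clip(*halfplanes: Polygon) -> Polygon:
        poly = support
        for hp in halfplanes:
            poly = poly.intersection(hp)
        return poly

    le = _halfplane  # {a1*x + a2*y <= b}
    ge = lambda a1, a2, b: _halfplane(-a1, -a2, -b, radius)  # noqa: E731

    bundled_both = clip(le(1, 1, P + s, radius))
    itemized_both = clip(le(1, 0, p1 + s, radius), le(0, 1, p2 + s, radius), le(1, 1, P + s, radius))
    itemized_only1 = clip(le(1, 0, p1, radius), ge(0, 1, p2 + s))
    itemized_only2 = clip(le(0, 1, p2, radius), ge(1, 0, p1 + s))
    itemized_none = support.difference(itemized_both).difference(itemized_only1).difference(itemized_only2)

    total = support.area
    areas = {
        "bundled_both": bundled_both.area,
        "bundled_none": total - bundled_both.area,
        "itemized_both": itemized_both.area,
        "itemized_only1": itemized_only1.area,
        "itemized_only2": itemized_only2.area,
        "itemized_none": itemized_none.area,
        "A": itemized_only1.intersection(bundled_both).area,
        "B": itemized_only2.intersection(bundled_both).area,
        "C": itemized_only1.difference(bundled_both).area,
        "D": itemized_only2.difference(bundled_both).area,
        "both_both": itemized_both.area,  # itemized-both is nested in bundled-both
        "none_none": itemized_none.area,  # itemized-none never bundles (pi12 <= 0)
    }
    return {k: v / total for k, v in areas.items()}
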