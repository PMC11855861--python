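"""Exponential reinforcer-demand modelling.

The model describes how consumption ``Q`` of a reinforcer falls as its unit
price ``C`` (responses required per reinforcer) rises::

    log10 Q = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

``Q0`` is demand intensity (consumption at zero price), ``alpha`` the rate of
decline in relative log consumption with standardized price, and ``k`` the
log10 range of the curve, conventionally shared across the curves being
compared.  Derived indices:

* essential value ``EV = 1 / (100 * alpha * k**1.5)`` — a price-scale-free
  index of how well the reinforcer maintains responding,
* ``Pmax`` — the price at which expenditure ``C * Q(C)`` peaks (demand
  elasticity passes -1),
* ``Omax`` — the peak expenditure itself.

Fitting is nonlinear least squares on the log10 consumption scale, either per
curve or jointly across curves with a single shared ``k``.  Nested fits are
compared with the extra sum-of-squares F test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, NoUnitElasticPointError, UnfittableCurveError, ValidationError

__all__ = [
    "DEFAULT_PRICE_LADDER",
    "UNIT_DOSE_MG_PER_KG",
    "Group",
    "DemandParams",
    "ConsumptionCurve",
    "DemandFit",
    "GroupFitComparison",
    "ExponentialDemandModel",
    "SharedKDemandModel",
    "predict_log10_consumption",
    "predict_consumption",
    "derive_essential_value",
    "derive_pmax",
    "derive_omax",
    "unit_elasticity_point",
    "infer_k_from_expenditure_ratio",
    "infer_shared_k_from_indices",
    "fit_demand_individual",
    "fit_demand_shared_k",
    "group_mean_curves",
    "compare_alpha_extra_ss_f",
    "dose_from_infusions",
]

LN10 = math.log(10.0)

#: Escalating fixed-ratio price ladder used in the long-access
#: self-administration design this package models.
DEFAULT_PRICE_LADDER: tuple[int, ...] = (1, 3, 5, 8, 12, 18, 26, 38, 58, 86, 130, 195, 292)

#: Methamphetamine unit dose per infusion (mg/kg), weight-adjusted at run time.
UNIT_DOSE_MG_PER_KG: float = 0.05


class Group(str, Enum):
    """Experimental condition of a subject."""

    METH = "METH"
    SAL = "SAL"


def _as_group(value) -> Group:
    if isinstance(value, Group):
        return value
    try:
        return Group(str(value).upper())
    except ValueError as exc:
        raise ValidationError(f"unknown group label {value!r}; expected METH or SAL") from exc


@dataclass(frozen=True)
class DemandParams:
    """Parameters of the exponential demand equation; all strictly positive."""

    q0: float
    alpha: float
    k: float

    def __post_init__(self):
        for name in ("q0", "alpha", "k"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")


@dataclass
class ConsumptionCurve:
    """One subject's (price, consumption) observations on an FR ladder.

    Consumption may be in reinforcers or mg/kg; zero consumption is allowed
    and simply excluded from log-scale fitting.
    """

    subject_id: str
    group: Group
    prices: np.ndarray
    consumption: np.ndarray

    def __post_init__(self):
        self.group = _as_group(self.group)
        self.prices = np.asarray(self.prices, dtype=float)
        self.consumption = np.asarray(self.consumption, dtype=float)
        if self.prices.ndim != 1 or self.prices.shape != self.consumption.shape:
            raise ValidationError("prices and consumption must be 1-D and equally long")
        if np.any(~np.isfinite(self.prices)) or np.any(self.prices <= 0):
            raise ValidationError("prices must be finite and > 0")
        if len(np.unique(self.prices)) != len(self.prices):
            raise ValidationError(f"duplicate prices in curve {self.subject_id!r}")
        if np.any(~np.isfinite(self.consumption)) or np.any(self.consumption < 0):
            raise ValidationError("consumption must be finite and >= 0")

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.consumption > 0))


@dataclass
class DemandFit:
    """A fitted demand curve with derived behavioral-economic indices."""

    subject_id: str
    group: Group
    params: DemandParams
    ev: float
    pmax: float
    omax_analytic: float
    omax_observed: float | None
    rss: float
    n_points_used: int
    r_squared: float
    converged: bool = True


@dataclass
class GroupFitComparison:
    """Extra sum-of-squares F comparison of nested demand fits."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_reduced: float
    fits_full: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# model arithmetic


def predict_log10_consumption(params: DemandParams, price) -> np.ndarray | float:
    """log10 consumption at ``price``.

    ``price=0`` is permitted and returns ``log10(Q0)`` (the intensity limit);
    the curve decreases toward ``log10(Q0) - k`` as price grows.
    """
    if not isinstance(params, DemandParams):
        params = DemandParams(*params)
    c = np.asarray(price, dtype=float)
    if np.any(c < 0):
        raise ValidationError("price must be >= 0")
    out = np.log10(params.q0) + params.k * (np.exp(-params.alpha * params.q0 * c) - 1.0)
    return float(out) if np.isscalar(price) else out


def predict_consumption(params: DemandParams, price):
    """Consumption on the linear scale, ``10 ** predict_log10_consumption``."""
    return 10.0 ** np.asarray(predict_log10_consumption(params, price))


def derive_essential_value(params: DemandParams) -> float:
    """Essential value ``EV = 1 / (100 * alpha * k**1.5)``."""
    if not isinstance(params, DemandParams):
        params = DemandParams(*params)
    return 1.0 / (100.0 * params.alpha * params.k**1.5)


PmaxMethod = Literal["exact", "hursh_approx"]


def unit_elasticity_point(k: float, method: PmaxMethod = "exact") -> float:
    """Solve for the standardized price ``u = alpha*Q0*C`` of unit elasticity.

    ``method="exact"`` returns the smaller root of ``u*exp(-u) = 1/(k*ln 10)``
    (the stationary point of expenditure under the model), via the principal
    Lambert-W branch.  ``method="hursh_approx"`` returns the historical
    closed-form approximation ``(0.084*k + 0.65) / k**1.5``, which many legacy
    demand-curve templates use and which therefore reproduces their printed
    Pmax/Omax values.
    """
    if not (np.isfinite(k) and k > 0):
        raise ValidationError(f"k must be finite and > 0, got {k!r}")
    if method == "hursh_approx":
        return (0.084 * k + 0.65) / k**1.5
    a = 1.0 / (k * LN10)
    if a >= math.exp(-1.0):
        raise NoUnitElasticPointError(
            f"no unit-elasticity point: k*ln(10) = {k * LN10:.4f} <= e, expenditure has no interior maximum"
        )
    return float(-special.lambertw(-a, k=0).real)


def derive_pmax(params: DemandParams, method: PmaxMethod = "exact") -> float:
    """Price of maximal expenditure, ``Pmax = u / (alpha * Q0)``.

    ``u`` depends only on ``k`` (see :func:`unit_elasticity_point`), so Pmax is
    inversely proportional to ``alpha * Q0`` across curves sharing ``k``.
    """
    if not isinstance(params, DemandParams):
        params = DemandParams(*params)
    u = unit_elasticity_point(params.k, method=method)
    return u / (params.alpha * params.q0)


def derive_omax(
    params: DemandParams,
    curve: ConsumptionCurve | None = None,
    method: PmaxMethod = "exact",
) -> tuple[float, float | None]:
    """Maximal expenditure, analytic and (optionally) observed.

    Analytic: expenditure of the fitted curve at Pmax.  Observed: the largest
    ``price * consumption`` over the supplied curve's points (first maximizer
    on ties).  Returns ``(omax_analytic, omax_observed_or_None)``.
    """
    if not isinstance(params, DemandParams):
        params = DemandParams(*params)
    pmax = derive_pmax(params, method=method)
    omax_analytic = pmax * float(predict_consumption(params, pmax))
    omax_observed = None
    if curve is not None:
        expenditure = curve.prices * curve.consumption
        omax_observed = float(expenditure[int(np.argmax(expenditure))])
    return omax_analytic, omax_observed


def infer_k_from_expenditure_ratio(ratio: float, method: PmaxMethod = "exact") -> float:
    """Back-solve the shared ``k`` from the ratio ``Omax / (Q0 * Pmax)``.

    Under the model that ratio equals ``10 ** (k * (exp(-u(k)) - 1))`` and
    depends only on ``k``, so a cohort's near-constant observed ratio pins the
    shared range constant.
    """
    if not (0 < ratio < 1):
        raise ValidationError("expenditure ratio must lie in (0, 1)")

    def f(k):
        u = unit_elasticity_point(k, method=method)
        return k * (math.exp(-u) - 1.0) - math.log10(ratio)

    lo = 1.3 if method == "exact" else 0.2
    return float(optimize.brentq(f, lo, 50.0, xtol=1e-12))


def infer_shared_k_from_indices(q0, ev, pmax, omax) -> tuple[float, float]:
    """Back-solve ``(k, u)`` from a cohort table of derived demand indices.

    Under a shared range constant, two ratios of the printed indices depend
    only on ``k`` and the standardized unit-elasticity price ``u``:
    ``Omax/(Q0*Pmax) = 10**(k*(exp(-u)-1))`` and
    ``Omax/EV = 100 * k**1.5 * u * Omax/(Q0*Pmax)``.  Solving both mean
    ratios jointly recovers the generating ``k`` without assuming how the
    producing software located the unit-elasticity point (exact root or the
    closed-form approximation).  Rows with non-positive EV are excluded from
    the second ratio (their printed EV carries no significant digits).

    Returns ``(k, u)``.
    """
    q0 = np.asarray(q0, float)
    ev = np.asarray(ev, float)
    pmax = np.asarray(pmax, float)
    omax = np.asarray(omax, float)
    r1 = float(np.mean(omax / (q0 * pmax)))
    pos = ev > 0
    if not np.any(pos):
        raise ValidationError("no rows with positive EV")
    r2 = float(np.mean(omax[pos] / ev[pos]))

    def equations(x):
        k, u = x
        return [
            k * (math.exp(-u) - 1.0) - math.log10(r1),
            100.0 * k**1.5 * u * r1 - r2,
        ]

    (k, u), info, ier, msg = optimize.fsolve(
        equations, x0=[2.4, 0.25], full_output=True, xtol=1e-13
    )
    if ier != 1 or max(abs(v) for v in info["fvec"]) > 1e-8:
        raise ConvergenceError(f"shared-k back-solve did not converge: {msg}")
    return float(k), float(u)


def dose_from_infusions(n_infusions: float, unit_dose: float = UNIT_DOSE_MG_PER_KG) -> float:
    """Total self-administered dose (mg/kg) from an infusion count."""
    if not (np.isfinite(unit_dose) and unit_dose > 0):
        raise ValidationError("unit_dose must be > 0")
    if not (np.isfinite(n_infusions) and n_infusions >= 0):
        raise ValidationError("n_infusions must be >= 0")
    return float(n_infusions) * float(unit_dose)


# ---------------------------------------------------------------------------
# fitting


def _log10_residuals(log_params, prices, log10_q, k_fixed=None):
    if k_fixed is None:
        lq0, lalpha, lk = log_params
        k = math.exp(lk)
    else:
        lq0, lalpha = log_params
        k = k_fixed
    q0 = math.exp(lq0)
    alpha = math.exp(lalpha)
    pred = math.log10(q0) + k * (np.exp(-alpha * q0 * prices) - 1.0)
    return pred - log10_q


def _k_init_rule(log10_q: np.ndarray) -> float:
    """Conventional seed for the range constant: observed log10 span + 0.5."""
    span = float(np.max(log10_q) - np.min(log10_q))
    return max(span + 0.5, 1.2)


def _alpha_init_grid(prices, log10_q, q0, k):
    """Pick the best alpha over a decade grid to seed the optimizer."""
    best, best_sse = 1e-3, np.inf
    for alpha in 10.0 ** np.arange(-5, 0.5, 0.5):
        pred = math.log10(q0) + k * (np.exp(-alpha * q0 * prices) - 1.0)
        sse = float(np.sum((pred - log10_q) ** 2))
        if sse < best_sse:
            best, best_sse = alpha, sse
    return best


def _fit_single_curve(
    prices: np.ndarray,
    consumption: np.ndarray,
    k: float | Literal["free"],
    n_starts: int,
    random_state: int,
    max_nfev: int,
):
    """Multi-start NLS on (log Q0, log alpha[, log k]); returns (params, rss, n_used)."""
    pos = consumption > 0
    prices_fit = prices[pos]
    log10_q = np.log10(consumption[pos])
    n_used = int(pos.sum())
    free_k = isinstance(k, str) and k == "free"
    min_pts = 4 if free_k else 3
    if n_used == 0:
        raise UnfittableCurveError("all-zero consumption; nothing to fit on the log scale")
    if n_used < min_pts:
        raise UnfittableCurveError(
            f"need >= {min_pts} points with positive consumption, got {n_used}"
        )

    q0_init = float(consumption[pos][np.argmin(prices_fit)])
    k_init = _k_init_rule(log10_q) if free_k else float(k)
    if not free_k and not (np.isfinite(k_init) and k_init > 0):
        raise ValidationError(f"fixed k must be > 0, got {k!r}")
    alpha_init = _alpha_init_grid(prices_fit, log10_q, q0_init, k_init)

    base = [math.log(q0_init), math.log(alpha_init)]
    if free_k:
        base.append(math.log(k_init))
    base = np.asarray(base)

    rng = np.random.default_rng(random_state)
    starts = [base]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(base + rng.normal(0.0, 0.4, size=base.size))

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                _log10_residuals,
                x0,
                args=(prices_fit, log10_q, None if free_k else k_init),
                method="lm" if len(log10_q) >= len(x0) else "trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        rss = 2.0 * res.cost
        if best is None or rss < best[1] - 1e-14:
            best = (res, rss)
    if best is None:
        raise ConvergenceError("demand fit failed from every start")
    res, rss = best
    if free_k:
        q0, alpha, kv = np.exp(res.x)
    else:
        q0, alpha = np.exp(res.x)
        kv = k_init
    params = DemandParams(q0=float(q0), alpha=float(alpha), k=float(kv))
    return params, float(rss), n_used, bool(res.success)


def _r_squared(curve: ConsumptionCurve, rss: float) -> float:
    pos = curve.consumption > 0
    log10_q = np.log10(curve.consumption[pos])
    tss = float(np.sum((log10_q - log10_q.mean()) ** 2))
    if tss == 0.0:
        return 1.0 if rss < 1e-12 else float("nan")
    return 1.0 - rss / tss


def _make_fit(curve: ConsumptionCurve, params: DemandParams, rss: float, n_used: int,
              converged: bool, pmax_method: PmaxMethod = "exact") -> DemandFit:
    ev = derive_essential_value(params)
    pmax = derive_pmax(params, method=pmax_method)
    omax_a, omax_o = derive_omax(params, curve, method=pmax_method)
    return DemandFit(
        subject_id=curve.subject_id,
        group=curve.group,
        params=params,
        ev=ev,
        pmax=pmax,
        omax_analytic=omax_a,
        omax_observed=omax_o,
        rss=rss,
        n_points_used=n_used,
        r_squared=_r_squared(curve, rss),
        converged=converged,
    )


class ExponentialDemandModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares exponential demand curve for one subject.

    Parameters
    ----------
    k : "free" or float, default "free"
        Range constant: estimated jointly with Q0 and alpha, or held fixed.
    n_starts : int, default 5
        Jittered multi-starts for the optimizer; the best-RSS solution wins.
    random_state : int, default 0
        Seed for start jitter only; the objective itself is deterministic.
    pmax_method : {"exact", "hursh_approx"}, default "exact"
        How the unit-elasticity price is computed for the derived indices.

    Attributes
    ----------
    q0_, alpha_, k_ : fitted parameters (all > 0).
    ev_, pmax_, omax_ : derived indices at the fitted parameters.
    rss_ : residual sum of squares on the log10 consumption scale.
    r_squared_, n_points_used_, converged_ : fit diagnostics.
    """

    def __init__(self, k="free", n_starts=5, random_state=0, max_nfev=10000,
                 pmax_method: PmaxMethod = "exact"):
        self.k = k
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nfev = max_nfev
        self.pmax_method = pmax_method

    def fit(self, X, y):
        """Fit to prices ``X`` (1-D or single-column) and consumption ``y``."""
        prices = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        curve = ConsumptionCurve("<anon>", Group.METH, prices, y)
        params, rss, n_used, ok = _fit_single_curve(
            curve.prices, curve.consumption, self.k, self.n_starts, self.random_state, self.max_nfev
        )
        self.q0_, self.alpha_, self.k_ = params.q0, params.alpha, params.k
        self.params_ = params
        self.rss_ = rss
        self.n_points_used_ = n_used
        self.converged_ = ok
        self.r_squared_ = _r_squared(curve, rss)
        self.ev_ = derive_essential_value(params)
        self.pmax_ = derive_pmax(params, method=self.pmax_method)
        self.omax_, _ = derive_omax(params, method=self.pmax_method)
        return self

    def predict(self, X):
        """Predicted consumption (linear scale) at prices ``X``."""
        prices = np.asarray(X, dtype=float).reshape(-1)
        return predict_consumption(self.params_, prices)

    def predict_log10(self, X):
        prices = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(predict_log10_consumption(self.params_, prices))


def fit_demand_individual(
    curve: ConsumptionCurve,
    k: float | Literal["free"] = "free",
    n_starts: int = 5,
    random_state: int = 0,
    pmax_method: PmaxMethod = "exact",
) -> DemandFit:
    """Fit one subject's curve; ``k`` may be free or fixed."""
    params, rss, n_used, ok = _fit_single_curve(
        curve.prices, curve.consumption, k, n_starts, random_state, 10000
    )
    return _make_fit(curve, params, rss, n_used, ok, pmax_method)


class SharedKDemandModel(BaseEstimator):
    """Joint demand fit across curves with one shared range constant ``k``.

    Minimizes the pooled log10-scale RSS over per-curve ``(Q0_i, alpha_i)``
    plus one global ``k`` (``2 * n_curves + 1`` parameters).  Pass the long
    format to :meth:`fit`: prices as ``X``, consumption as ``y`` and a curve
    label per observation via ``groups``.
    """

    def __init__(self, n_starts=5, random_state=0, max_nfev=20000,
                 pmax_method: PmaxMethod = "exact"):
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nfev = max_nfev
        self.pmax_method = pmax_method

    def fit(self, X, y, groups):
        prices = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        groups = np.asarray(groups)
        if not (prices.shape == y.shape == groups.shape):
            raise ValidationError("X, y and groups must align")
        labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
        curves = [
            ConsumptionCurve(str(lab), Group.METH, prices[groups == lab], y[groups == lab])
            for lab in labels
        ]
        k, fits, rss = _fit_shared_k(curves, self.n_starts, self.random_state,
                                     self.max_nfev, self.pmax_method)
        self.k_ = k
        self.fits_ = {lab: f for lab, f in zip(labels, fits)}
        self.rss_ = rss
        return self


def _fit_shared_k(curves, n_starts, random_state, max_nfev, pmax_method):
    fittable = []
    for c in curves:
        if c.n_positive < 3:
            raise UnfittableCurveError(
                f"curve {c.subject_id!r} has {c.n_positive} positive points; need >= 3"
            )
        fittable.append(c)
    if len(fittable) == 1:
        fit = fit_demand_individual(fittable[0], k="free", n_starts=n_starts,
                                    random_state=random_state, pmax_method=pmax_method)
        return fit.params.k, [fit], fit.rss

    # seed each curve with a fixed-k individual fit at the pooled k rule
    all_log10 = np.concatenate([np.log10(c.consumption[c.consumption > 0]) for c in fittable])
    k0 = _k_init_rule(all_log10)
    seeds = []
    for c in fittable:
        p, _, _, _ = _fit_single_curve(c.prices, c.consumption, k0, 1, random_state, 5000)
        seeds.append((math.log(p.q0), math.log(p.alpha)))

    data = [(c.prices[c.consumption > 0], np.log10(c.consumption[c.consumption > 0]))
            for c in fittable]

    def residuals(x):
        lk = x[0]
        k = math.exp(lk)
        out = []
        for i, (pr, lq) in enumerate(data):
            q0 = math.exp(x[1 + 2 * i])
            alpha = math.exp(x[2 + 2 * i])
            out.append(math.log10(q0) + k * (np.exp(-alpha * q0 * pr) - 1.0) - lq)
        return np.concatenate(out)

    base = np.concatenate([[math.log(k0)], np.asarray(seeds).ravel()])
    rng = np.random.default_rng(random_state)
    starts = [base] + [base + rng.normal(0, 0.3, size=base.size) for _ in range(max(n_starts - 1, 0))]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, method="lm", xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or 2 * res.cost < 2 * best.cost - 1e-14:
            best = res
    if best is None:
        raise ConvergenceError("shared-k joint fit failed from every start")
    k = math.exp(best.x[0])
    fits = []
    total_rss = 0.0
    for i, c in enumerate(fittable):
        q0 = math.exp(best.x[1 + 2 * i])
        alpha = math.exp(best.x[2 + 2 * i])
        params = DemandParams(q0=q0, alpha=alpha, k=k)
        pos = c.consumption > 0
        resid = np.asarray(predict_log10_consumption(params, c.prices[pos])) - np.log10(c.consumption[pos])
        rss = float(np.sum(resid**2))
        total_rss += rss
        fits.append(_make_fit(c, params, rss, int(pos.sum()), bool(best.success), pmax_method))
    return float(k), fits, float(total_rss)


def group_mean_curves(curves: Sequence[ConsumptionCurve]) -> list[ConsumptionCurve]:
    """Average consumption across subjects at each price, per group.

    This is the "grouped" analysis convention: one mean curve per condition,
    averaging over whichever subjects have an observation at a given price.
    """
    out = []
    for grp in dict.fromkeys(c.group for c in curves):
        members = [c for c in curves if c.group == grp]
        prices = sorted({float(p) for c in members for p in c.prices})
        mean_q = []
        for p in prices:
            vals = [c.consumption[c.prices == p][0] for c in members if np.any(c.prices == p)]
            mean_q.append(float(np.mean(vals)))
        out.append(ConsumptionCurve(f"group:{grp.value}", grp, np.asarray(prices), np.asarray(mean_q)))
    return out


def fit_demand_shared_k(
    curves: Sequence[ConsumptionCurve],
    grouping: Literal["per-subject", "per-group"] = "per-subject",
    n_starts: int = 5,
    random_state: int = 0,
    pmax_method: PmaxMethod = "exact",
) -> tuple[float, list[DemandFit]]:
    """Joint fit with a single shared ``k``.

    ``grouping="per-group"`` first collapses subjects to group-mean curves;
    ``"per-subject"`` shares ``k`` across individual curves.  Returns the
    shared ``k`` and one :class:`DemandFit` per fitted curve.
    """
    if grouping == "per-group":
        curves = group_mean_curves(curves)
    elif grouping != "per-subject":
        raise ValidationError(f"unknown grouping {grouping!r}")
    if len(curves) == 0:
        raise ValidationError("no curves supplied")
    k, fits, _ = _fit_shared_k(list(curves), n_starts, random_state, 20000, pmax_method)
    return k, fits


# ---------------------------------------------------------------------------
# nested-model comparison


def _shared_alpha_reduced_fit(curves, n_starts, random_state, max_nfev=20000):
    """Reduced model: one alpha across curves, per-curve Q0, one shared k."""
    data = [(c.prices[c.consumption > 0], np.log10(c.consumption[c.consumption > 0]))
            for c in curves]
    all_log10 = np.concatenate([lq for _, lq in data])
    k0 = _k_init_rule(all_log10)
    seeds = []
    for c in curves:
        p, _, _, _ = _fit_single_curve(c.prices, c.consumption, k0, 1, random_state, 5000)
        seeds.append(p)
    alpha0 = float(np.exp(np.mean([math.log(p.alpha) for p in seeds])))

    def residuals(x):
        k = math.exp(x[0])
        alpha = math.exp(x[1])
        out = []
        for i, (pr, lq) in enumerate(data):
            q0 = math.exp(x[2 + i])
            out.append(math.log10(q0) + k * (np.exp(-alpha * q0 * pr) - 1.0) - lq)
        return np.concatenate(out)

    base = np.asarray([math.log(k0), math.log(alpha0)] + [math.log(p.q0) for p in seeds])
    rng = np.random.default_rng(random_state)
    starts = [base] + [base + rng.normal(0, 0.3, size=base.size) for _ in range(max(n_starts - 1, 0))]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, method="lm", xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-14:
            best = res
    if best is None:
        raise ConvergenceError("reduced (shared-alpha) fit failed from every start")
    return 2.0 * float(best.cost), len(base)


def compare_alpha_extra_ss_f(
    curves: Sequence[ConsumptionCurve],
    grouping: Literal["per-group", "per-subject"] = "per-group",
    n_starts: int = 5,
    random_state: int = 0,
) -> GroupFitComparison:
    """Extra sum-of-squares F test for a group difference in ``alpha``.

    Full model: shared ``k``, per-group ``Q0`` and ``alpha``.  Reduced model:
    shared ``k``, per-group ``Q0``, a single ``alpha``.  With two groups this
    gives one numerator degree of freedom.  By convention the comparison runs
    on group-mean curves (``grouping="per-group"``); ``"per-subject"`` keeps
    individual curves and shares ``alpha`` across all of them in the reduced
    model.
    """
    group_labels = list(dict.fromkeys(c.group for c in curves))
    if len(group_labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(group_labels)}")
    if grouping == "per-group":
        curves = group_mean_curves(curves)
    curves = list(curves)

    k, fits, rss_full = _fit_shared_k(curves, n_starts, random_state, 20000, "exact")
    n_params_full = 2 * len(curves) + 1
    rss_reduced, n_params_reduced = _shared_alpha_reduced_fit(curves, n_starts, random_state)
    rss_reduced = max(rss_reduced, rss_full)  # nesting can only be violated numerically

    n_points = int(sum(c.n_positive for c in curves))
    df_num = n_params_full - n_params_reduced
    df_den = n_points - n_params_full
    if df_den <= 0:
        raise ValidationError("not enough points for the full model's degrees of freedom")
    if rss_full <= 0:
        return GroupFitComparison(math.inf, df_num, df_den, 0.0, rss_full, rss_reduced, fits)
    f_stat = ((rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return GroupFitComparison(float(f_stat), df_num, df_den, p, rss_full, rss_reduced, fits)
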