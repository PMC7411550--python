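"""Distributed-lag conditional quasi-Poisson model.

The case-crossover analysis conditions a Poisson regression on the total
count within each stratum, eliminating the stratum intercepts and leaving a
multinomial likelihood

    l(beta) = sum_s [ sum_i y_si x_si' beta - Y_s log sum_i exp(x_si' beta) ]

whose maximizer coincides with the stratum-fixed-effects Poisson estimate.
Overdispersion is handled quasi-likelihood style: the coefficient covariance
is scaled by the Pearson dispersion

    phi = X^2_Pearson / (N_days - N_informative_strata - n_params),

where the informative-stratum count stands in for the absorbed intercepts.
The design couples six dust-lag indicators (lags 0-5) with natural-spline
confounders: temperature at lags 0 and 1 and dew point at lag 0 (3 df
each), a long-term date spline (8 df per calendar year of span), and linear
PM2.5 and ozone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    SeparationError,
    UnidentifiedError,
)

logger = logging.getLogger(__name__)

#: default dust-day PM10 elevation used for scenario scaling (ug/m3)
DEFAULT_DELTA_PM10 = 47.8

_ALIAS_TOL = 1e-8


# ---------------------------------------------------------------------------
# spline basis


def natural_spline_basis(
    values, df: int, boundary_knots: tuple[float, float] | None = None
) -> np.ndarray:
    """Natural cubic spline basis of rank ``df``.

    Linear beyond the boundary knots (zero second derivative); interior
    knots at equally spaced quantiles of ``values``; boundary knots at the
    min/max unless supplied.  ``df = 1`` reduces to the identity (linear)
    column.  The intercept is not included.
    """
    x = np.asarray(values, dtype=float)
    if df < 1:
        raise DomainError("spline df must be >= 1")
    if not np.all(np.isfinite(x)):
        raise DomainError("spline values must be finite")
    if df == 1:
        return x[:, None].copy()

    if boundary_knots is None:
        lo, hi = float(np.min(x)), float(np.max(x))
    else:
        lo, hi = map(float, boundary_knots)
    interior = np.quantile(x, np.arange(1, df) / df)
    knots = np.concatenate([[lo], interior, [hi]])
    if len(np.unique(knots)) != len(knots):
        raise DegenerateDataError(
            f"cannot place {df + 1} distinct spline knots on the supplied values"
        )

    def d(k: int) -> np.ndarray:
        # truncated-cubic difference quotient against the last knot
        return (
            np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        ) / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(len(knots) - 2)
    for k in range(len(knots) - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class DesignSpec:
    """Covariate blocks entering the distributed-lag design.

    A block is omitted when its df is 0 (splines) or its flag is False
    (linear terms).  ``date_df_per_year`` is multiplied by the number of
    distinct calendar years spanned by the data.
    """

    lag_terms: int = 6
    temperature_lag0_df: int = 3
    temperature_lag1_df: int = 3
    dewpoint_df: int = 3
    date_df_per_year: int = 8
    pm25: bool = True
    ozone: bool = True

    def __post_init__(self) -> None:
        if self.lag_terms < 1:
            raise DomainError("at least the dust lag block must be present")

    @classmethod
    def main(cls) -> "DesignSpec":
        return cls()

    @classmethod
    def dust_only(cls, lag_terms: int = 6) -> "DesignSpec":
        return cls(
            lag_terms=lag_terms,
            temperature_lag0_df=0,
            temperature_lag1_df=0,
            dewpoint_df=0,
            date_df_per_year=0,
            pm25=False,
            ozone=False,
        )

    def required_covariates(self) -> list[str]:
        cols = []
        if self.temperature_lag0_df:
            cols.append("temperature")
        if self.temperature_lag1_df:
            cols.append("temperature_lag1")
        if self.dewpoint_df:
            cols.append("dewpoint")
        if self.pm25:
            cols.append("pm25")
        if self.ozone:
            cols.append("ozone")
        return cols


@dataclass
class DesignMatrix:
    X: np.ndarray
    names: list[str]
    aliased: list[str]
    rows: np.ndarray  # integer index into the source table
    stratum_ids: np.ndarray


def _sequential_rank_prune(
    X: np.ndarray, names: list[str], stratum_ids: np.ndarray, tol: float = _ALIAS_TOL
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop columns with no independent within-stratum variation.

    Columns are centered within stratum (the conditional likelihood only
    sees within-stratum contrasts), normalized, then admitted greedily in
    order, so earlier columns (the dust lags) take precedence over later
    confounder columns when collinear.
    """
    Xc = X - pd.DataFrame(X).groupby(np.asarray(stratum_ids), sort=False).transform("mean").values
    norms = np.linalg.norm(Xc, axis=0)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0

    kept: list[int] = []
    aliased: list[str] = []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        if norms[j] <= tol * max(1.0, scale[j]):
            aliased.append(names[j])  # stratum-constant
            continue
        v = Xc[:, j] / norms[j]
        r = v.copy()
        for q in Q:
            r -= q @ v * q
        rn = np.linalg.norm(r)
        if rn <= tol:
            aliased.append(names[j])
            continue
        Q.append(r / rn)
        kept.append(j)
    return X[:, kept], [names[j] for j in kept], aliased


def build_design(
    stratum_days: pd.DataFrame, spec: DesignSpec, outcome: str | None = None
) -> DesignMatrix:
    """Assemble the distributed-lag design from an expanded stratum-day table.

    Rows missing any model-required covariate (or the outcome, when given)
    are dropped (complete-case).  Collinear columns — including spline
    columns absorbed by the stratum structure — are detected on the
    within-stratum-centered matrix with tolerance 1e-8 and reported as
    aliased.
    """
    lag_cols = [f"dust_lag{k}" for k in range(spec.lag_terms)]
    required = lag_cols + spec.required_covariates()
    if outcome is not None:
        required = required + [outcome]
    missing = [c for c in required if c not in stratum_days.columns]
    if missing:
        raise DegenerateDataError(f"stratum-day table lacks columns: {missing}")
    mask = stratum_days[required].notna().all(axis=1).values
    sub = stratum_days.loc[mask]
    if len(sub) == 0:
        raise DegenerateDataError("no complete-case rows to build a design from")

    blocks: list[np.ndarray] = []
    names: list[str] = []

    blocks.append(sub[lag_cols].to_numpy(dtype=float))
    names.extend(lag_cols)

    def add_spline(col_values, df_: int, label: str) -> None:
        basis = natural_spline_basis(np.asarray(col_values, dtype=float), df_)
        # orthonormalize the nuisance block: same column span, far better
        # conditioning than the raw truncated-power basis at high df
        q, r = np.linalg.qr(basis - basis.mean(axis=0))
        keep_cols = np.abs(np.diag(r)) > _ALIAS_TOL * max(1.0, np.abs(r[0, 0]))
        blocks.append(q[:, keep_cols])
        names.extend(f"{label}_ns{i + 1}" for i in range(int(keep_cols.sum())))

    if spec.temperature_lag0_df:
        add_spline(sub["temperature"], spec.temperature_lag0_df, "temp_l0")
    if spec.temperature_lag1_df:
        add_spline(sub["temperature_lag1"], spec.temperature_lag1_df, "temp_l1")
    if spec.dewpoint_df:
        add_spline(sub["dewpoint"], spec.dewpoint_df, "dew_l0")
    if spec.date_df_per_year:
        dates = pd.to_datetime(sub["date"])
        n_years = dates.dt.year.nunique()
        t = (dates - dates.min()).dt.days.to_numpy(dtype=float)
        add_spline(t, spec.date_df_per_year * n_years, "date")
    if spec.pm25:
        blocks.append(sub[["pm25"]].to_numpy(dtype=float))
        names.append("pm25")
    if spec.ozone:
        blocks.append(sub[["ozone"]].to_numpy(dtype=float))
        names.append("ozone")

    X = np.hstack(blocks)
    sid = sub["stratum_id"].to_numpy()
    Xk, kept_names, aliased = _sequential_rank_prune(X, names, sid)
    if aliased:
        logger.info("aliased %d design columns: %s", len(aliased), aliased)
    return DesignMatrix(
        X=Xk, names=kept_names, aliased=aliased, rows=np.flatnonzero(mask), stratum_ids=sid
    )


# ---------------------------------------------------------------------------
# conditional quasi-Poisson fit


@dataclass
class FitResult:
    beta: pd.Series
    vcov: pd.DataFrame
    dispersion: float
    n_days: int
    n_strata: int
    n_params: int
    n_iter: int
    gradient_norm: float
    aliased: list[str] = field(default_factory=list)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.beta.index)


def _stratum_blocks(stratum_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(stratum_ids, kind="stable")
    sorted_ids = stratum_ids[order]
    change = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
    sizes = np.diff(np.r_[change, len(sorted_ids)])
    return order, change, sizes


def fit_conditional_quasipoisson(
    y,
    X,
    stratum_ids,
    names: list[str] | None = None,
    max_iter: int = 50,
    gtol: float = 1e-8,
    eta_cap: float = 30.0,
) -> FitResult:
    """Maximize the stratum-conditional (multinomial) Poisson likelihood.

    Newton-Raphson from beta = 0 with step-halving on likelihood decrease;
    convergence when the max absolute gradient falls below ``gtol``.
    Strata with zero total count or a single day are non-informative and
    dropped before fitting.  The covariance is the inverse observed
    information scaled by the Pearson dispersion.

    Raises :class:`SeparationError` when the within-sample linear-predictor
    spread diverges past ``eta_cap`` (monotone likelihood) and
    :class:`ConvergenceError` if the iteration cap is reached with a large
    gradient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sid = np.asarray(stratum_ids)
    if not (len(y) == len(X) == len(sid)):
        raise DomainError("y, X and stratum_ids must have equal length")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    order, starts, sizes = _stratum_blocks(sid)
    y, X = y[order], X[order]
    totals = np.add.reduceat(y, starts)
    keep = (totals > 0) & (sizes >= 2)
    if not keep.any():
        raise DegenerateDataError("no informative strata (positive totals, >=2 days)")
    row_keep = np.repeat(keep, sizes)
    y, X = y[row_keep], X[row_keep]
    sid_kept = sid[order][row_keep]
    sizes = sizes[keep]
    totals = totals[keep]
    starts = np.r_[0, np.cumsum(sizes)[:-1]]

    # dropping non-informative strata can re-introduce collinearity; prune
    # again on the retained rows so the information matrix stays invertible
    X, names, aliased = _sequential_rank_prune(X, list(names), sid_kept)
    if not names:
        raise DegenerateDataError("no covariate varies within the informative strata")
    n, p = X.shape
    G = len(sizes)

    # fit on unit-norm columns for conditioning; results are mapped back
    col_scale = np.linalg.norm(X, axis=0)
    col_scale[col_scale == 0] = 1.0
    X = X / col_scale

    rep = lambda v: np.repeat(v, sizes)

    def state(beta: np.ndarray):
        eta = X @ beta
        m = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - rep(m))
        denom = np.add.reduceat(ex, starts)
        pr = ex / rep(denom)
        ll = float(y @ eta - totals @ (np.log(denom) + m))
        return pr, ll

    beta = np.zeros(p)
    pr, ll = state(beta)
    n_iter = 0
    grad_norm = np.inf
    for n_iter in range(1, max_iter + 1):
        mu = rep(totals) * pr
        grad = X.T @ (y - mu)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < gtol:
            break
        W1 = X.T @ (X * mu[:, None])
        B = np.add.reduceat(pr[:, None] * X, starts, axis=0)
        H = W1 - (B * totals[:, None]).T @ B
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by pruning
            raise ConvergenceError(f"singular information matrix: {exc}", grad_norm)
        new_beta = beta + step
        pr_new, ll_new = state(new_beta)
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            pr_new, ll_new = state(new_beta)
            halvings += 1
        if float(np.max(np.abs(new_beta - beta))) < 1e-13:
            beta, pr, ll = new_beta, pr_new, ll_new
            mu = rep(totals) * pr
            grad_norm = float(np.max(np.abs(X.T @ (y - mu))))
            break
        beta, pr, ll = new_beta, pr_new, ll_new
        if float(np.ptp(X @ beta)) > eta_cap:
            raise SeparationError(
                f"linear-predictor spread exceeded {eta_cap}: likely complete separation",
                grad_norm,
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (max |gradient| = {grad_norm:.3g})",
            grad_norm,
        )

    # boundary solution: a day absorbs its stratum's entire total with fitted
    # probability ~1, i.e. the likelihood is monotone (complete separation)
    at_boundary = (pr > 1.0 - 1e-6) & (np.abs(y - rep(totals)) < 0.5) & (y > 0)
    if at_boundary.any():
        raise SeparationError(
            "fitted stratum probabilities reached the boundary: monotone likelihood",
            grad_norm,
        )

    mu = rep(totals) * pr
    W1 = X.T @ (X * mu[:, None])
    B = np.add.reduceat(pr[:, None] * X, starts, axis=0)
    H = W1 - (B * totals[:, None]).T @ B
    pearson = float(np.sum((y - mu) ** 2 / mu))
    df_resid = n - G - p
    if df_resid > 0:
        dispersion = pearson / df_resid
    else:
        logger.warning("nonpositive residual df (%d); dispersion set to 1", df_resid)
        dispersion = 1.0
    Hinv = linalg.inv(H)
    Hinv = (Hinv + Hinv.T) / 2.0
    vcov = dispersion * Hinv / np.outer(col_scale, col_scale)
    return FitResult(
        beta=pd.Series(beta / col_scale, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        dispersion=dispersion,
        n_days=n,
        n_strata=G,
        n_params=p,
        n_iter=n_iter,
        gradient_norm=grad_norm,
        aliased=aliased,
    )


def fit_stratum_table(
    stratum_days: pd.DataFrame, endpoint: str, spec: DesignSpec, **fit_kwargs
) -> tuple[FitResult, DesignMatrix]:
    """Build the design for one endpoint and fit the conditional model."""
    ycol = f"count_{endpoint}"
    dm = build_design(stratum_days, spec, outcome=ycol)
    y = stratum_days[ycol].to_numpy(dtype=float)[dm.rows]
    fit = fit_conditional_quasipoisson(y, dm.X, dm.stratum_ids, names=dm.names, **fit_kwargs)
    fit.aliased = dm.aliased + fit.aliased
    return fit, dm


# ---------------------------------------------------------------------------
# estimates and transforms


@dataclass
class LagEstimate:
    """A lag (or lag-window) association on the percent-increase scale."""

    label: str
    beta: float
    se: float
    percent: float
    ci_low: float
    ci_high: float
    p: float


def percent_increase(beta_k: float, se_k: float, level: float = 0.95, label: str = "") -> LagEstimate:
    """100*(exp(beta)-1) with a Wald CI back-transformed to percent."""
    if se_k < 0:
        raise DomainError("standard error must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    pct = 100.0 * math.expm1(beta_k)
    lo = 100.0 * math.expm1(beta_k - z * se_k)
    hi = 100.0 * math.expm1(beta_k + z * se_k)
    if se_k > 0:
        pval = 2.0 * stats.norm.sf(abs(beta_k) / se_k)
    else:
        pval = float(beta_k == 0.0)
    return LagEstimate(label=label, beta=beta_k, se=se_k, percent=pct, ci_low=lo, ci_high=hi, p=pval)


def lag_window_average(fit: FitResult, lags, level: float = 0.95, label: str | None = None) -> LagEstimate:
    """Uniform-weight contrast over several lag coefficients.

    Estimate c'beta with variance c'Vc for c placing weight 1/|lags| on
    each requested ``dust_lag<k>`` coefficient.  Raises
    :class:`UnidentifiedError` when a requested lag was aliased out of the
    fit.
    """
    lags = list(lags)
    terms = [f"dust_lag{k}" for k in lags]
    for t in terms:
        if t not in fit.beta.index:
            raise UnidentifiedError(f"lag term {t!r} not retained in fit (aliased?)")
    c = pd.Series(0.0, index=fit.beta.index)
    c[terms] = 1.0 / len(terms)
    est = float(c @ fit.beta)
    var = float(c @ fit.vcov.values @ c)
    if label is None:
        label = f"lag {min(lags)}-{max(lags)}" if len(lags) > 1 else f"lag {lags[0]}"
    return percent_increase(est, math.sqrt(max(var, 0.0)), level=level, label=label)


def joint_lag_wald(fit: FitResult, lags) -> tuple[float, int, float]:
    """Joint Wald chi-square test that all requested lag coefficients are zero."""
    terms = [f"dust_lag{k}" for k in lags if f"dust_lag{k}" in fit.beta.index]
    if not terms:
        raise UnidentifiedError("no lag terms retained in fit")
    b = fit.beta[terms].values
    V = fit.vcov.loc[terms, terms].values
    stat = float(b @ linalg.solve(V, b, assume_a="pos"))
    dof = len(terms)
    return stat, dof, float(stats.chi2.sf(stat, dof))


@dataclass
class ScenarioResult:
    """A lag estimate rescaled to a hypothetical storm PM10 concentration."""

    label: str
    target_pm10: float
    delta_pm10: float
    percent: float
    ci_low: float
    ci_high: float


def scale_scenario(
    est: LagEstimate,
    delta_pm10: float = DEFAULT_DELTA_PM10,
    target_pm10: float = 400.0,
) -> ScenarioResult:
    """Extrapolate a dust-day percent increase to a target PM10 concentration.

    The log relative risk is assumed linear in concentration: each of the
    center and CI bounds p (percent) maps to
    ``100*(exp(log(1 + p/100) * target/delta) - 1)``.
    """
    if delta_pm10 <= 0 or target_pm10 <= 0:
        raise DomainError("delta_pm10 and target_pm10 must be positive")
    ratio = target_pm10 / delta_pm10

    def f(p: float) -> float:
        if p <= -100.0:
            raise DomainError(f"percent change {p} <= -100 cannot be rescaled")
        return 100.0 * math.expm1(math.log1p(p / 100.0) * ratio)

    return ScenarioResult(
        label=est.label,
        target_pm10=target_pm10,
        delta_pm10=delta_pm10,
        percent=f(est.percent),
        ci_low=f(est.ci_low),
        ci_high=f(est.ci_high),
    )


def lag_estimates_table(
    fit: FitResult,
    max_lag: int = 5,
    windows=((0, 1, 2), (3, 4, 5), (0, 1, 2, 3, 4, 5)),
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-lag and lag-window estimates as a tidy results table."""
    ses = fit.se()
    rows = []
    for k in range(max_lag + 1):
        term = f"dust_lag{k}"
        if term not in fit.beta.index:
            continue
        est = percent_increase(float(fit.beta[term]), float(ses[term]), level, label=f"lag {k}")
        rows.append(est)
    for w in windows:
        w = [k for k in w if k <= max_lag]
        if not w:
            continue
        try:
            rows.append(lag_window_average(fit, w, level=level))
        except UnidentifiedError:
            continue
    return pd.DataFrame(
        {
            "term": [e.label for e in rows],
            "estimate": [e.beta for e in rows],
            "se": [e.se for e in rows],
            "percent": [e.percent for e in rows],
            "ci_low": [e.ci_low for e in rows],
            "ci_high": [e.ci_high for e in rows],
            "p": [e.p for e in rows],
            "dispersion": fit.dispersion,
        }
    )
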