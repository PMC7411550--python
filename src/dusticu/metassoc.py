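"""Dust-day contrasts in meteorology and air pollution.

Estimates the additive difference of an environment variable on dust-storm
days versus other days in the same case-crossover strata, using a linear
mixed model with a random intercept per stratum (ZIP x year-quarter) and a
natural spline on date (8 df per year) for time-of-year control.  This is
the stage that confirms reported storms correspond to real ground-level PM
elevations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .ccmodel import natural_spline_basis
from .exceptions import UnidentifiedError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class AssociationEstimate:
    variable: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str = "mixed"


def _design(sub: pd.DataFrame, date_df_per_year: int) -> np.ndarray:
    dates = pd.to_datetime(sub["date"])
    t = (dates - dates.min()).dt.days.to_numpy(dtype=float)
    n_years = dates.dt.year.nunique()
    cols = [np.ones(len(sub)), sub["dust"].to_numpy(dtype=float)]
    if date_df_per_year:
        basis = natural_spline_basis(t, date_df_per_year * n_years)
        cols.extend(basis.T)
    return np.column_stack(cols)


def fit_dust_association(
    exposures: pd.DataFrame,
    variable: str,
    date_df_per_year: int = 8,
    method: str = "mixed",
    level: float = 0.95,
) -> AssociationEstimate:
    """Dust-day additive contrast for one variable, in its own units.

    ``exposures`` must carry stratum_id, date, dust and the variable.
    ``method="mixed"`` fits a REML random-intercept model; ``method="ols"``
    drops the random intercept (the degenerate zero-variance limit, kept as
    an oracle).  Raises :class:`UnidentifiedError` when no stratum has
    within-stratum dust variation.
    """
    sub = exposures.dropna(subset=[variable]).copy()
    if len(sub) < 3:
        raise UnidentifiedError(f"too few observed days for {variable!r}")
    varies = sub.groupby("stratum_id")["dust"].nunique()
    if not (varies > 1).any():
        raise UnidentifiedError(
            f"dust indicator constant within every stratum; {variable!r} contrast unidentified"
        )

    X = _design(sub, date_df_per_year)
    y = sub[variable].to_numpy(dtype=float)

    if method == "mixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=sub["stratum_id"].to_numpy())
            res = model.fit(reml=True)
        est = float(res.fe_params[1])
        se = float(res.bse_fe[1])
    elif method == "ols":
        res = sm.OLS(y, X).fit()
        est = float(res.params[1])
        se = float(res.bse[1])
    else:
        raise ValueError(f"unknown method {method!r}")

    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 0.0
    return AssociationEstimate(
        variable=variable,
        estimate=est,
        se=se,
        ci_low=est - z * se,
        ci_high=est + z * se,
        p=max(p, _P_FLOOR),
        method=method,
    )


def association_table(
    exposures: pd.DataFrame,
    variables=("ozone", "pm25", "pm10", "precipitation", "temperature", "dewpoint"),
    **kwargs,
) -> pd.DataFrame:
    """Dust-day contrasts for several variables as a tidy table."""
    rows = []
    for var in variables:
        try:
            est = fit_dust_association(exposures, var, **kwargs)
        except UnidentifiedError as exc:
            logger.warning("skipping %s: %s", var, exc)
            continue
        rows.append(
            (est.variable, est.estimate, est.se, est.ci_low, est.ci_high, est.p)
        )
    return pd.DataFrame(
        rows, columns=["variable", "estimate", "se", "ci_low", "ci_high", "p"]
    )
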