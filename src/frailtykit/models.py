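"""Per-trial associations between frailty and trial outcomes.

Serious adverse events (SAEs) are modelled with Poisson regression on the
first-event indicator with an offset for log observation time (participants
are censored at first SAE or end of follow-up, so the count is 0/1 and the
exponentiated coefficient is an incidence rate ratio).  Trial attrition
(withdrawal before the stipulated endpoint) is modelled with logistic
regression.  Both models are adjusted for age and sex, the frailty index is
rescaled by 10 so coefficients are per 0.1-unit FI, and a sex x FI
interaction can be added post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataError, FitError

Z95 = 1.96  # conventional normal quantile for 95% Wald intervals


@dataclass(frozen=True)
class InteractionTerm:
    beta: float
    se: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    """Log-scale estimate for the FI term (per 0.1-unit FI) plus covariates."""

    model: str
    beta: float
    se: float
    ci95: tuple[float, float]
    effect: float
    n: int
    n_events: int
    covariates: Mapping[str, tuple[float, float]]
    interaction: InteractionTerm | None = None

    @property
    def effect_ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))


def to_female(sex: pd.Series) -> pd.Series:
    """Code sex as a female indicator (female = 1)."""
    if pd.api.types.is_numeric_dtype(sex):
        vals = sex.astype(float)
        if not set(np.unique(vals.dropna())) <= {0.0, 1.0}:
            raise DataError("numeric sex column must be a 0/1 female indicator")
        return vals
    mapping = {"f": 1.0, "female": 1.0, "m": 0.0, "male": 0.0}
    out = sex.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = sorted(set(sex[out.isna()].astype(str)))
        raise DataError(f"unrecognised sex codes {bad}; expected F/M or 0/1")
    return out


def prepare_outcomes(events: pd.DataFrame, follow_up: float) -> pd.DataFrame:
    """Apply the censoring rule to a raw events table.

    ``events`` has one or more rows per participant with columns
    ``participant_id``, ``sae_time`` (time of an SAE, NaN/absent if none)
    and ``attrition`` (0/1).  Each participant is censored at their first
    SAE or at end of follow-up, whichever comes first; later events are
    ignored.  Returns one row per participant with ``sae_event``,
    ``observation_time`` and ``attrition``.
    """
    if follow_up <= 0:
        raise DataError("follow_up must be positive")
    df = events.copy()
    if "sae_time" not in df.columns:
        df["sae_time"] = np.nan
    times = pd.to_numeric(df["sae_time"], errors="coerce")
    if (times <= 0).any():
        raise DataError("SAE event times must be strictly positive")
    if (times > follow_up).any():
        bad = df.loc[times > follow_up, "participant_id"].iloc[0]
        raise DataError(
            f"SAE time exceeds follow-up ({follow_up}) for participant {bad!r}"
        )
    df["sae_time"] = times
    grouped = df.groupby("participant_id", sort=False).agg(
        first_sae=("sae_time", "min"), attrition=("attrition", "max")
    )
    event = grouped["first_sae"].notna()
    out = pd.DataFrame(
        {
            "participant_id": grouped.index,
            "sae_event": event.astype(int).to_numpy(),
            "observation_time": np.where(event, grouped["first_sae"], float(follow_up)),
            "attrition": grouped["attrition"].astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def _design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    quadratic: bool,
    interaction: bool,
) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["fi10"] = 10.0 * data["fi"].astype(float)
    if "age" in covariates:
        X["age_years"] = data["age_years"].astype(float)
    if "sex" in covariates or interaction:
        X["female"] = to_female(data["sex"]).to_numpy()
    if quadratic:
        X["fi10_sq"] = X["fi10"] ** 2
    if interaction:
        if X["female"].nunique() < 2:
            raise FitError("sex x FI interaction requires both sexes in the sample")
        X["female_x_fi10"] = X["female"] * X["fi10"]
    if X.isna().any().any():
        raise DataError("design matrix contains missing values")
    return X


def _check_fit(res, model: str) -> None:
    if not getattr(res, "converged", True):
        raise FitError(f"{model}: IRLS did not converge")
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise FitError(f"{model}: non-finite estimates (possible separation)")
    if np.any(np.abs(params) > 50) or np.any(bse > 200):
        offender = res.params.index[int(np.argmax(np.abs(params)))]
        raise FitError(f"{model}: diverging coefficient for {offender!r} (separation)")


def _result(res, model: str, n: int, n_events: int, interaction: bool) -> RegressionResult:
    beta = float(res.params["fi10"])
    se = float(res.bse["fi10"])
    ci = (beta - Z95 * se, beta + Z95 * se)
    covs = {
        name: (float(res.params[name]), float(res.bse[name]))
        for name in res.params.index
        if name not in ("fi10", "female_x_fi10")
    }
    inter = None
    if interaction:
        b = float(res.params["female_x_fi10"])
        s = float(res.bse["female_x_fi10"])
        inter = InteractionTerm(beta=b, se=s, p=float(2 * sps.norm.sf(abs(b / s))))
    return RegressionResult(
        model=model,
        beta=beta,
        se=se,
        ci95=ci,
        effect=float(np.exp(beta)),
        n=n,
        n_events=n_events,
        covariates=covs,
        interaction=inter,
    )


def fit_poisson_sae(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    quadratic: bool = False,
    interaction: bool = False,
) -> RegressionResult:
    """Poisson regression of the first-SAE indicator with a log
    observation-time offset; the ``fi10`` coefficient is the log IRR per
    0.1-unit FI.  The offset's time unit cancels from the IRR.

    ``data`` needs columns fi, sae_event, observation_time, plus age_years
    and sex when adjusted.
    """
    y = data["sae_event"].astype(float)
    n_events = int(y.sum())
    if n_events == 0:
        raise FitError("Poisson SAE model requires at least one event")
    t = data["observation_time"].astype(float)
    if (t <= 0).any():
        raise DataError("observation_time must be strictly positive")
    X = _design(data, covariates, quadratic, interaction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(t)).fit()
    _check_fit(res, "poisson_sae")
    return _result(res, "poisson_sae", n=len(y), n_events=n_events, interaction=interaction)


def fit_logistic_attrition(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    quadratic: bool = False,
    interaction: bool = False,
) -> RegressionResult:
    """Logistic regression of trial attrition; the ``fi10`` coefficient is
    the log OR per 0.1-unit FI.

    ``data`` needs columns fi, attrition, plus age_years and sex when
    adjusted.  Separation (diverging coefficients) raises
    :class:`FitError` naming the covariate.
    """
    y = data["attrition"].astype(float)
    n_events = int(y.sum())
    if y.nunique() < 2:
        raise FitError("attrition model requires both outcomes to be present")
    X = _design(data, covariates, quadratic, interaction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    _check_fit(res, "logistic_attrition")
    return _result(
        res, "logistic_attrition", n=len(y), n_events=n_events, interaction=interaction
    )


def fit_interaction(
    model: str,
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
) -> RegressionResult:
    """Refit an outcome model with a sex x FI product term and its Wald p."""
    if model == "poisson_sae":
        return fit_poisson_sae(data, covariates=covariates, interaction=True)
    if model == "logistic_attrition":
        return fit_logistic_attrition(data, covariates=covariates, interaction=True)
    raise FitError(f"unknown model {model!r}; expected 'poisson_sae' or 'logistic_attrition'")
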