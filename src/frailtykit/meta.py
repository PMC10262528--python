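"""Random-effects pooling of per-trial log-scale coefficients.

Per-trial log IRRs / log ORs and their standard errors are pooled with the
DerSimonian–Laird estimator: with fixed-effect weights ``w_i = 1/se_i**2``
and fixed-effect mean ``b_FE``, the heterogeneity statistic is
``Q = sum w_i (b_i - b_FE)**2`` and

    tau2 = max(0, (Q - (k - 1)) / (sum w - sum w**2 / sum w))

after which studies are re-weighted by ``w*_i = 1/(se_i**2 + tau2)``.
Paule–Mandel (``method="pm"``), which solves Q(tau2) = k - 1, is available
as an alternative.  Confidence intervals use the normal 1.96 quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

Z95 = 1.96


@dataclass(frozen=True)
class StudyRow:
    study: str
    beta: float
    se: float
    weight: float  # random-effects weight, percent


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    ci95: tuple[float, float]
    effect: float
    tau2: float
    q: float
    i2: float
    k: int
    method: str
    rows: tuple[StudyRow, ...]

    @property
    def effect_ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))


def _normalise(estimates) -> tuple[list[str], np.ndarray, np.ndarray]:
    names, betas, ses = [], [], []
    for i, est in enumerate(estimates):
        if len(est) == 3:
            name, b, s = est
        else:
            b, s = est
            name = f"study {i + 1}"
        names.append(str(name))
        betas.append(float(b))
        ses.append(float(s))
    return names, np.asarray(betas), np.asarray(ses)


def _pm_tau2(b: np.ndarray, v: np.ndarray, k: int) -> float:
    """Paule–Mandel tau2: the root of Q(tau2) = k - 1 (0 if none exists)."""

    def q_of(t: float) -> float:
        w = 1.0 / (v + t)
        mu = np.sum(w * b) / np.sum(w)
        return float(np.sum(w * (b - mu) ** 2))

    if q_of(0.0) <= k - 1:
        return 0.0
    lo, hi = 0.0, 10.0 * (np.var(b) + np.max(v))
    while q_of(hi) > k - 1:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if q_of(mid) > k - 1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pool_random_effects(
    estimates: Sequence, method: str = "dl"
) -> MetaResult:
    """Pool per-study (beta, se) pairs in a random-effects meta-analysis.

    ``estimates`` is a sequence of ``(beta, se)`` or ``(study, beta, se)``
    tuples.  With a single study the pooled estimate equals that study's.
    """
    if method not in ("dl", "pm"):
        raise DataError(f"unknown method {method!r}; expected 'dl' or 'pm'")
    names, b, se = _normalise(estimates)
    k = len(b)
    if k == 0:
        raise DataError("meta-analysis requires at least one study")
    if np.any(se <= 0):
        raise DataError("all standard errors must be strictly positive")
    v = se**2
    w = 1.0 / v
    b_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fe) ** 2))
    if k == 1:
        tau2 = 0.0
    elif method == "dl":
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = _pm_tau2(b, v, k)
    w_re = 1.0 / (v + tau2)
    beta = float(np.sum(w_re * b) / np.sum(w_re))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_re)))
    ci = (beta - Z95 * se_pooled, beta + Z95 * se_pooled)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    weights = 100.0 * w_re / np.sum(w_re)
    rows = tuple(
        StudyRow(study=n, beta=float(bi), se=float(si), weight=float(wi))
        for n, bi, si, wi in zip(names, b, se, weights)
    )
    return MetaResult(
        beta=beta,
        se=se_pooled,
        ci95=ci,
        effect=float(np.exp(beta)),
        tau2=float(tau2),
        q=q,
        i2=i2,
        k=k,
        method=method,
        rows=rows,
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Per-study and pooled rows, exponentiated, ready for forest plotting.

    Study weights are random-effects weights summing to 100%.
    """
    records = [
        {
            "study": r.study,
            "beta": r.beta,
            "se": r.se,
            "effect": float(np.exp(r.beta)),
            "ci_lo": float(np.exp(r.beta - Z95 * r.se)),
            "ci_hi": float(np.exp(r.beta + Z95 * r.se)),
            "weight_pct": r.weight,
            "pooled": False,
        }
        for r in meta.rows
    ]
    records.append(
        {
            "study": f"pooled (random effects, {meta.method.upper()})",
            "beta": meta.beta,
            "se": meta.se,
            "effect": meta.effect,
            "ci_lo": meta.effect_ci95[0],
            "ci_hi": meta.effect_ci95[1],
            "weight_pct": 100.0,
            "pooled": True,
        }
    )
    return pd.DataFrame.from_records(records)
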