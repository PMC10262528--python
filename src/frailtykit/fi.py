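"""Frailty index construction.

The frailty index (FI) of a participant is the ratio of deficits
accumulated to deficits considered.  Individual deficits are scored on
[0, 1]: binary deficits score 0 (absent) or 1 (present), ordinal deficits
are scaled onto an equally spaced grid (0, 0.25, 0.5, 0.75, 1 for five
levels), and continuous raw variables are dichotomised at a cut-point.
A deficit with missing data is removed from both numerator and denominator;
participants missing strictly more than 20% of the deficits in an index are
excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    DeficitCatalog,
    DeficitDefinition,
    MedicationConditionMap,
    map_medications,
    parse_medications,
    polypharmacy_score,
)
from .errors import ConfigurationError, DataError, EmptySampleError

logger = logging.getLogger(__name__)

MISSING = float("nan")

#: Strictly-greater-than exclusion threshold on the missing fraction.
MAX_MISSING_FRACTION = 0.20

#: eFI-style category boundaries (robust <= 0.12 < mild <= 0.24 < moderate <= 0.36 < severe).
DEFAULT_BOUNDARIES = (0.12, 0.24, 0.36)
CATEGORIES = ("robust", "mild", "moderate", "severe")

#: Column holding semicolon-delimited medication codes in baseline tables.
MEDICATIONS_COLUMN = "medications"


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and x != x:
        return True
    if isinstance(x, str) and not x.strip():
        return True
    return False


def score_deficit(raw_value, definition: DeficitDefinition) -> float:
    """Map one raw value to a deficit score in [0, 1] (NaN if missing).

    Binary -> {0, 1}; ordinal level ``k`` of ``n`` levels -> ``k / (n - 1)``;
    threshold -> 1 when the raw value lies at or beyond the cut-point in the
    deficit direction, else 0.
    """
    if _is_missing(raw_value):
        return MISSING
    kind = definition.kind
    if kind == "binary":
        v = float(raw_value)
        if v not in (0.0, 1.0):
            raise DataError(f"deficit {definition.id!r}: binary value must be 0 or 1, got {raw_value!r}")
        return v
    if kind == "ordinal":
        v = float(raw_value)
        n = int(definition.n_levels)  # type: ignore[arg-type]
        if not v.is_integer() or not (0 <= v <= n - 1):
            raise DataError(
                f"deficit {definition.id!r}: ordinal level must be an integer in "
                f"[0, {n - 1}], got {raw_value!r}"
            )
        return v / (n - 1)
    # threshold
    v = float(raw_value)
    cut = float(definition.threshold)  # type: ignore[arg-type]
    if definition.direction == "above":
        return float(v >= cut)
    return float(v <= cut)


def _score_column(values: pd.Series, definition: DeficitDefinition) -> np.ndarray:
    """Vectorised :func:`score_deficit` over one baseline column."""
    v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    if definition.kind == "binary":
        bad = ok & ~np.isin(v, (0.0, 1.0))
        if bad.any():
            idx = values.index[bad][0]
            raise DataError(
                f"deficit {definition.id!r}: binary value must be 0 or 1 "
                f"(participant {idx!r}: {values.loc[idx]!r})"
            )
        out[ok] = v[ok]
    elif definition.kind == "ordinal":
        n = int(definition.n_levels)  # type: ignore[arg-type]
        bad = ok & ((v != np.floor(v)) | (v < 0) | (v > n - 1))
        if bad.any():
            idx = values.index[bad][0]
            raise DataError(
                f"deficit {definition.id!r}: ordinal level out of range "
                f"(participant {idx!r}: {values.loc[idx]!r}, levels 0..{n - 1})"
            )
        out[ok] = v[ok] / (n - 1)
    else:
        cut = float(definition.threshold)  # type: ignore[arg-type]
        if definition.direction == "above":
            out[ok] = (v[ok] >= cut).astype(float)
        else:
            out[ok] = (v[ok] <= cut).astype(float)
    return out


def score_matrix(
    baseline: pd.DataFrame,
    catalog: DeficitCatalog,
    med_map: MedicationConditionMap | None = None,
    deficits: Sequence[DeficitDefinition] | None = None,
) -> pd.DataFrame:
    """Participants x deficits score matrix (NaN marks missing deficits).

    Deficits resolve, by ``source``, from a same-named baseline column, from
    the medication list via the condition map, or from the distinct
    medication count (polypharmacy).  Unresolvable deficits raise
    :class:`ConfigurationError` before any scoring.  ``deficits`` restricts
    scoring to a subset (e.g. one variant) of the catalog.
    """
    med_map = med_map if med_map is not None else catalog.medication_map
    deficits = tuple(deficits) if deficits is not None else catalog.deficits
    needs_meds = [d for d in deficits if d.source in ("medication", "polypharmacy")]
    unresolved = [
        d.id for d in deficits if d.source == "column" and d.id not in baseline.columns
    ]
    if needs_meds and MEDICATIONS_COLUMN not in baseline.columns:
        unresolved += [d.id for d in needs_meds]
    if any(d.source == "medication" for d in deficits) and med_map is None:
        raise ConfigurationError(
            "catalog contains medication-inferred deficits but no medication map was supplied"
        )
    if unresolved:
        raise ConfigurationError(f"deficits unresolvable from baseline table: {sorted(set(unresolved))}")

    index = (
        baseline["participant_id"] if "participant_id" in baseline.columns else baseline.index
    )
    scores = pd.DataFrame(index=pd.Index(index, name="participant_id"))
    med_lists = None
    conditions = None
    if needs_meds:
        med_lists = [parse_medications(c) for c in baseline[MEDICATIONS_COLUMN]]
        conditions = [map_medications(m, med_map) for m in med_lists]
    base = baseline.set_index(scores.index)
    for d in deficits:
        if d.source == "column":
            scores[d.id] = _score_column(base[d.id], d)
        elif d.source == "medication":
            scores[d.id] = [float(d.id in c) for c in conditions]  # type: ignore[union-attr]
        else:  # polypharmacy
            scores[d.id] = [float(polypharmacy_score(m)) for m in med_lists]  # type: ignore[union-attr]
    return scores


@dataclass(frozen=True)
class FrailtyResult:
    """Per-participant frailty index for one variant.

    ``fi`` is None when the participant is excluded (more than 20% of the
    variant's deficits missing); otherwise it is the ratio of the summed
    available scores to the number of available deficits.
    """

    participant_id: object
    variant: str
    n_total: int
    n_available: int
    fi: float | None

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_available / self.n_total

    @property
    def excluded(self) -> bool:
        return self.fi is None


def compute_fi(
    scores: Mapping[str, float] | pd.Series,
    variant_ids: Sequence[str],
    participant_id: object = None,
    variant: str = "physical",
) -> FrailtyResult:
    """Frailty index of one participant over the deficits of one variant.

    Missing deficits are dropped from numerator and denominator; the
    participant is excluded iff the missing fraction strictly exceeds 20%
    (exactly 20% missing is retained).  The exclusion test uses integer
    arithmetic (``5 * n_missing > n_total``) so the boundary is exact.
    """
    if len(variant_ids) == 0:
        raise ConfigurationError("variant deficit set is empty")
    vals = np.asarray([float(scores[i]) for i in variant_ids], dtype=float)
    n_total = len(vals)
    avail = ~np.isnan(vals)
    n_available = int(avail.sum())
    n_missing = n_total - n_available
    if 5 * n_missing > n_total:
        fi = None
    else:
        fi = float(vals[avail].sum() / n_available)
    return FrailtyResult(
        participant_id=participant_id,
        variant=variant,
        n_total=n_total,
        n_available=n_available,
        fi=fi,
    )


def build_fi_table(
    baseline: pd.DataFrame,
    catalog: DeficitCatalog,
    variant: str = "physical",
    med_map: MedicationConditionMap | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Frailty index for every participant in a baseline table.

    Returns a DataFrame with columns participant_id, variant, n_total,
    n_available, missing_fraction, excluded, fi (NaN when excluded).  Pass
    a precomputed ``scores`` matrix to reuse scoring across variants.
    """
    if scores is None:
        scores = score_matrix(
            baseline, catalog, med_map=med_map,
            deficits=catalog.variant_deficits(variant),
        )
    ids = catalog.variant_ids(variant)
    missing_cols = [i for i in ids if i not in scores.columns]
    if missing_cols:
        raise ConfigurationError(f"score matrix lacks deficits {missing_cols}")
    sub = scores[ids].to_numpy(dtype=float)
    n_total = sub.shape[1]
    n_available = (~np.isnan(sub)).sum(axis=1)
    n_missing = n_total - n_available
    excluded = 5 * n_missing > n_total
    with np.errstate(invalid="ignore"):
        fi = np.nansum(sub, axis=1) / np.where(n_available > 0, n_available, 1)
    fi = np.where(excluded, np.nan, fi)
    out = pd.DataFrame(
        {
            "participant_id": scores.index,
            "variant": variant,
            "n_total": n_total,
            "n_available": n_available,
            "missing_fraction": n_missing / n_total,
            "excluded": excluded,
            "fi": fi,
        }
    )
    n_excl = int(excluded.sum())
    if n_excl:
        logger.info(
            "build_fi_table: %d/%d participants excluded (>20%% of %s deficits missing)",
            n_excl, len(out), variant,
        )
    return out


def categorize(fi, boundaries: Sequence[float] = DEFAULT_BOUNDARIES):
    """Assign eFI-style frailty categories.

    Half-open convention: robust <= b1 < mild <= b2 < moderate <= b3 < severe,
    with default boundaries (0.12, 0.24, 0.36), so a prevalence of
    ``FI > 0.24`` is exactly moderate + severe.
    """
    arr = np.asarray(fi, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DataError("frailty index values must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(boundaries, dtype=float), arr, side="left")
    labels = np.asarray(CATEGORIES, dtype=object)[idx]
    if np.isscalar(fi) or arr.ndim == 0:
        return str(labels if arr.ndim == 0 else labels[0])
    return labels


def _extract_values(results) -> np.ndarray:
    """Accept an array of FI values or a build_fi_table frame; drop exclusions."""
    if isinstance(results, pd.DataFrame) and "fi" in results.columns:
        vals = results.loc[~results["excluded"].astype(bool), "fi"].to_numpy(dtype=float)
    else:
        vals = np.asarray(results, dtype=float)
        vals = vals[~np.isnan(vals)]
    return vals


def summarize_fi(
    results,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    centile: float = 0.99,
) -> dict:
    """Descriptive summary of an FI sample: mean, SD, empirical 99th centile
    and eFI category prevalences (percent, summing to 100 up to rounding).

    The centile is the linear-interpolation empirical quantile.  Excluded
    participants are omitted; fewer than two values raises
    :class:`EmptySampleError`.
    """
    vals = _extract_values(results)
    if len(vals) < 2:
        raise EmptySampleError("need at least 2 non-excluded frailty index values")
    cats = categorize(vals, boundaries)
    prevalence = {c: 100.0 * float(np.mean(cats == c)) for c in CATEGORIES}
    return {
        "n": int(len(vals)),
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)),
        "p99": float(np.quantile(vals, centile)),
        "prevalence": prevalence,
    }


def prevalence_over_threshold(
    data,
    threshold: float = 0.24,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> float:
    """Percentage of participants with FI strictly above ``threshold``.

    Accepts either raw FI values, or a mapping of category -> prevalence
    percent (as printed in a descriptive table).  For category input the
    threshold must coincide with a category boundary, in which case the
    result is the sum of the prevalences of the categories above it (e.g.
    moderate + severe for threshold 0.24).
    """
    if isinstance(data, Mapping):
        bounds = [float(b) for b in boundaries]
        if threshold not in bounds:
            raise DataError(
                f"threshold {threshold} is not a category boundary {bounds}; "
                "raw FI values are required"
            )
        above = CATEGORIES[bounds.index(threshold) + 1 :]
        return float(sum(float(data[c]) for c in above))
    vals = _extract_values(data)
    if len(vals) == 0:
        raise EmptySampleError("no frailty index values supplied")
    return 100.0 * float(np.mean(vals > threshold))
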