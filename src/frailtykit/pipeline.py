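"""End-to-end orchestration: catalog -> FI -> distribution -> models -> meta.

Runs the full retrospective frailty analysis over one or more trials and
emits a report bundle: per trial x variant a descriptive FI summary
(mean/SD, 99th centile, eFI category prevalences), parametric distribution
fits, and the SAE / attrition regressions; across trials the random-effects
pools and forest tables; plus a machine-readable manifest.  Every number in
the rendered table is a rounded copy of a field in the machine-readable
results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import DeficitCatalog, load_catalog
from .dist import model_summary, select_best_fit
from .errors import ConfigurationError, FitError, FrailtykitError
from .fi import (
    DEFAULT_BOUNDARIES,
    build_fi_table,
    prevalence_over_threshold,
    score_matrix,
    summarize_fi,
)
from .meta import forest_table, pool_random_effects
from .models import fit_logistic_attrition, fit_poisson_sae, prepare_outcomes

logger = logging.getLogger(__name__)

OUTCOME_MODELS = ("poisson_sae", "logistic_attrition")


@dataclass(frozen=True)
class TrialSpec:
    name: str
    baseline: str | Path
    outcomes: str | Path
    follow_up_days: float


@dataclass(frozen=True)
class RunConfig:
    trials: tuple[TrialSpec, ...]
    catalog_path: str | Path
    variants: tuple[str, ...] = ("physical", "physical_cognitive")
    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    threshold: float = 0.24
    out_dir: str | Path | None = None
    strict_catalog: bool = True

    def validate(self) -> None:
        if not self.trials:
            raise ConfigurationError("run config needs at least one trial")
        missing = [
            str(p)
            for t in self.trials
            for p in (t.baseline, t.outcomes)
            if not Path(p).exists()
        ]
        if not Path(self.catalog_path).exists():
            missing.append(str(self.catalog_path))
        if missing:
            raise ConfigurationError(f"input files not found: {missing}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a run configuration from YAML (paths relative to the file)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    base = path.parent
    trials = tuple(
        TrialSpec(
            name=t["name"],
            baseline=base / t["baseline"],
            outcomes=base / t["outcomes"],
            follow_up_days=float(t["follow_up_days"]),
        )
        for t in data["trials"]
    )
    return RunConfig(
        trials=trials,
        catalog_path=base / data["catalog"],
        variants=tuple(data.get("variants", ("physical", "physical_cognitive"))),
        boundaries=tuple(data.get("boundaries", DEFAULT_BOUNDARIES)),
        threshold=float(data.get("threshold", 0.24)),
        out_dir=data.get("out_dir"),
    )


def _regression_record(res) -> dict:
    return {
        "model": res.model,
        "beta": res.beta,
        "se": res.se,
        "effect": res.effect,
        "effect_ci95": list(res.effect_ci95),
        "n": res.n,
        "n_events": res.n_events,
        "covariates": {k: list(v) for k, v in res.covariates.items()},
    }


def analyse_trial(
    name: str,
    baseline: pd.DataFrame,
    outcomes: pd.DataFrame,
    follow_up_days: float,
    catalog: DeficitCatalog,
    variants: Sequence[str] = ("physical", "physical_cognitive"),
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    threshold: float = 0.24,
) -> dict:
    """Full single-trial analysis; returns a nested result dict."""
    scores = score_matrix(baseline, catalog)
    prepared = prepare_outcomes(outcomes, follow_up=follow_up_days)
    out: dict = {"trial": name, "n": len(baseline), "variants": {}}
    for variant in variants:
        fi_table = build_fi_table(baseline, catalog, variant, scores=scores)
        kept = fi_table.loc[~fi_table["excluded"]]
        summary = summarize_fi(fi_table, boundaries=boundaries)
        summary["prevalence_over_threshold"] = prevalence_over_threshold(
            fi_table, threshold=threshold, boundaries=boundaries
        )
        n_deficits = len(catalog.variant_ids(variant))
        best, fits = select_best_fit(kept["fi"].to_numpy(), n_deficits=n_deficits)
        dist_record = {
            "selected": best.family,
            "fits": {
                fam: {
                    "params": dict(f.params),
                    "loglik": f.loglik,
                    "ks": f.ks,
                    "converged": f.converged,
                }
                for fam, f in fits.items()
            },
            "model_summary": model_summary(best, boundaries=boundaries),
        }
        merged = kept.merge(prepared, on="participant_id").merge(
            baseline[["participant_id", "age_years", "sex"]], on="participant_id"
        )
        regressions = {}
        for model, fit in (
            ("poisson_sae", fit_poisson_sae),
            ("logistic_attrition", fit_logistic_attrition),
        ):
            try:
                regressions[model] = _regression_record(fit(merged))
            except FitError as exc:
                raise FitError(f"{name}/{variant}/{model}: {exc}") from exc
        out["variants"][variant] = {
            "n_excluded": int(fi_table["excluded"].sum()),
            "fi_table": fi_table,
            "summary": summary,
            "distribution": dist_record,
            "regressions": regressions,
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the analysis across all configured trials and pool the estimates.

    Returns the report bundle as a dict; when ``config.out_dir`` is set the
    bundle is also written out as CSV/JSON files plus a rendered
    descriptive table and a manifest.
    """
    config.validate()
    catalog = load_catalog(config.catalog_path, strict=config.strict_catalog)
    trial_results = []
    for t in config.trials:
        baseline = pd.read_csv(t.baseline)
        outcomes = pd.read_csv(t.outcomes)
        try:
            trial_results.append(
                analyse_trial(
                    t.name, baseline, outcomes, t.follow_up_days, catalog,
                    variants=config.variants, boundaries=config.boundaries,
                    threshold=config.threshold,
                )
            )
        except FrailtykitError as exc:
            raise type(exc)(f"trial {t.name!r}: {exc}") from exc

    meta_results: dict = {}
    for variant in config.variants:
        for model in OUTCOME_MODELS:
            estimates = [
                (
                    tr["trial"],
                    tr["variants"][variant]["regressions"][model]["beta"],
                    tr["variants"][variant]["regressions"][model]["se"],
                )
                for tr in trial_results
            ]
            meta_results[f"{model}/{variant}"] = pool_random_effects(estimates)

    report = {
        "version": __version__,
        "catalog": {"name": catalog.name, "version": catalog.version},
        "threshold": config.threshold,
        "boundaries": list(config.boundaries),
        "trials": trial_results,
        "meta": meta_results,
    }
    if config.out_dir is not None:
        _write_bundle(report, Path(config.out_dir), config)
    return report


def _json_safe(obj):
    if isinstance(obj, Mapping):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def _write_bundle(report: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries, associations, exclusions = [], [], {}
    for tr in report["trials"]:
        for variant, res in tr["variants"].items():
            res["fi_table"].to_csv(
                out_dir / f"fi_{tr['trial']}_{variant}.csv", index=False, float_format="%.6f"
            )
            summaries.append({"trial": tr["trial"], "variant": variant, **res["summary"]})
            for model, rec in res["regressions"].items():
                associations.append({"trial": tr["trial"], "variant": variant, **rec})
            exclusions[f"{tr['trial']}/{variant}"] = res["n_excluded"]
    (out_dir / "summaries.json").write_text(json.dumps(_json_safe(summaries), indent=2))
    (out_dir / "associations.json").write_text(json.dumps(_json_safe(associations), indent=2))
    dist_records = [
        {"trial": tr["trial"], "variant": v, **res["distribution"]}
        for tr in report["trials"]
        for v, res in tr["variants"].items()
    ]
    (out_dir / "distributions.json").write_text(json.dumps(_json_safe(dist_records), indent=2))
    meta_records = {}
    for key, m in report["meta"].items():
        forest_table(m).to_csv(
            out_dir / f"forest_{key.replace('/', '_')}.csv", index=False, float_format="%.6f"
        )
        meta_records[key] = {
            "beta": m.beta, "se": m.se, "effect": m.effect,
            "effect_ci95": list(m.effect_ci95), "tau2": m.tau2, "q": m.q,
            "i2": m.i2, "k": m.k, "method": m.method,
        }
    (out_dir / "meta.json").write_text(json.dumps(_json_safe(meta_records), indent=2))
    (out_dir / "table2.txt").write_text(report_table2(summaries))
    manifest = {
        "frailtykit_version": report["version"],
        "catalog": report["catalog"],
        "threshold": report["threshold"],
        "boundaries": report["boundaries"],
        "trials": [
            {"name": t.name, "baseline": str(t.baseline), "outcomes": str(t.outcomes),
             "follow_up_days": t.follow_up_days}
            for t in config.trials
        ],
        "n_excluded": exclusions,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("report bundle written to %s (exclusions: %s)", out_dir, exclusions)


def _r1(x: float) -> str:
    """Round half-up to one decimal, as in printed tables."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _r2(x: float) -> str:
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def report_table2(summaries: Sequence[Mapping]) -> str:
    """Render descriptive FI statistics, one row per trial x variant.

    Columns: trial, variant, mean (SD), 99th centile, and the four eFI
    category prevalences as percentages to one decimal.  All values are
    rounded copies of fields in the summary dicts (no arithmetic here).
    """
    if not summaries:
        raise ConfigurationError("no summaries to render")
    header = (
        f"{'trial':<14}{'variant':<22}{'mean (SD)':<14}{'p99':<7}"
        f"{'robust%':>9}{'mild%':>8}{'moderate%':>11}{'severe%':>9}"
    )
    lines = [header, "-" * len(header)]
    for s in summaries:
        if s.get("n", 0) == 0:
            logger.warning("omitting empty variant row: %s", s)
            continue
        prev = s["prevalence"]
        lines.append(
            f"{s.get('trial', '-'):<14}{s.get('variant', '-'):<22}"
            f"{_r2(s['mean']) + ' (' + _r2(s['sd']) + ')':<14}"
            f"{_r2(s['p99']):<7}"
            f"{_r1(prev['robust']):>9}{_r1(prev['mild']):>8}"
            f"{_r1(prev['moderate']):>11}{_r1(prev['severe']):>9}"
        )
    return "\n".join(lines) + "\n"
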