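"""Deficit catalogs: declarative descriptions of age-related health deficits.

A frailty index is a ratio of accumulated health deficits to deficits
considered.  Which deficits go in is not fixed by the method — any
health-related item that increases in prevalence with age and does not
saturate too early qualifies — so the catalog is user-supplied config.
This module defines the catalog types, validation (a physical index should
contain at least 30 deficits spanning several physiological systems),
YAML/JSON (de)serialization, and the medication-based comorbidity mapping
used when medical history is only observable through concomitant
medications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import CatalogError

logger = logging.getLogger(__name__)

VALID_KINDS = ("binary", "ordinal", "threshold")
VALID_VARIANT_CLASSES = ("physical", "cognitive")
VALID_SOURCES = ("column", "medication", "polypharmacy")
#: Variant names accepted throughout the package.
VARIANTS = ("physical", "physical_cognitive")

#: Minimum physical-deficit count enforced in strict validation mode.
MIN_PHYSICAL_DEFICITS = 30
#: Minimum number of distinct physiological-system tags.
MIN_SYSTEMS = 5
#: Concurrent-medication count defining polypharmacy.
POLYPHARMACY_THRESHOLD = 5


@dataclass(frozen=True)
class DeficitDefinition:
    """One age-related health deficit and how raw data maps to a [0, 1] score.

    Parameters
    ----------
    id : short stable identifier, unique within a catalog.
    label : human-readable name.
    system : physiological-system tag (cardiovascular, laboratory, ...).
    kind : ``binary`` (present/absent), ``ordinal`` (graded severity on an
        equally spaced 0..1 grid) or ``threshold`` (continuous raw value
        dichotomised at a cut-point).
    variant_class : ``physical`` or ``cognitive``; the physical frailty
        index uses only the former, the combined index uses both.
    n_levels : number of ordinal levels (ordinal only, >= 2).
    threshold, direction : cut-point and the side counted as deficient
        (threshold only; ``above`` scores 1 when raw >= threshold,
        ``below`` when raw <= threshold).
    source : where the raw value comes from: a baseline-table ``column``
        named after the deficit id, the ``medication`` list (condition
        inferred from concomitant medication classes), or the
        ``polypharmacy`` count of distinct medications.
    """

    id: str
    label: str
    system: str
    kind: str
    variant_class: str
    n_levels: int | None = None
    threshold: float | None = None
    direction: str | None = None
    source: str = "column"

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogError("deficit id must be a non-empty string")
        if self.kind not in VALID_KINDS:
            raise CatalogError(
                f"deficit {self.id!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if self.variant_class not in VALID_VARIANT_CLASSES:
            raise CatalogError(
                f"deficit {self.id!r}: variant_class must be one of "
                f"{VALID_VARIANT_CLASSES}, got {self.variant_class!r}"
            )
        if self.source not in VALID_SOURCES:
            raise CatalogError(
                f"deficit {self.id!r}: source must be one of {VALID_SOURCES}, got {self.source!r}"
            )
        if self.kind == "ordinal":
            if self.n_levels is None or int(self.n_levels) < 2:
                raise CatalogError(f"deficit {self.id!r}: ordinal kind requires n_levels >= 2")
        if self.kind == "threshold":
            if self.threshold is None or not _finite(self.threshold):
                raise CatalogError(f"deficit {self.id!r}: threshold kind requires a finite cut-point")
            if self.direction not in ("above", "below"):
                raise CatalogError(
                    f"deficit {self.id!r}: threshold kind requires direction 'above' or 'below'"
                )
        if self.source == "polypharmacy" and self.kind != "binary":
            raise CatalogError(f"deficit {self.id!r}: polypharmacy source must be binary")

    def to_dict(self) -> dict:
        out: dict = {
            "id": self.id,
            "label": self.label,
            "system": self.system,
            "kind": self.kind,
            "variant_class": self.variant_class,
        }
        if self.source != "column":
            out["source"] = self.source
        if self.kind == "ordinal":
            out["n_levels"] = int(self.n_levels)  # type: ignore[arg-type]
        if self.kind == "threshold":
            out["threshold"] = float(self.threshold)  # type: ignore[arg-type]
            out["direction"] = self.direction
        return out


def _finite(x) -> bool:
    try:
        return abs(float(x)) < float("inf")
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class MedicationConditionMap:
    """Rules mapping medication-class codes to condition deficit ids.

    Codes are an ATC-like flat string vocabulary.  Each rule maps one
    medication class to exactly one condition; several classes may map to
    the same condition.  Matching uses set semantics: duplicated codes add
    nothing, and unknown codes are counted and ignored.
    """

    rules: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rules", {str(k).strip().lower(): str(v) for k, v in dict(self.rules).items()}
        )

    @property
    def condition_ids(self) -> set[str]:
        return set(self.rules.values())

    def validate_against(self, catalog: "DeficitCatalog") -> None:
        known = set(catalog.ids())
        missing = sorted(self.condition_ids - known)
        if missing:
            raise CatalogError(
                f"medication map targets unknown condition deficit ids: {missing}"
            )


@dataclass(frozen=True)
class DeficitCatalog:
    """Ordered collection of deficit definitions plus an optional medication map."""

    name: str
    version: str
    deficits: tuple[DeficitDefinition, ...]
    medication_map: MedicationConditionMap | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "deficits", tuple(self.deficits))
        seen: dict[str, int] = {}
        for d in self.deficits:
            seen[d.id] = seen.get(d.id, 0) + 1
        dupes = sorted(k for k, v in seen.items() if v > 1)
        if dupes:
            raise CatalogError(f"duplicate deficit ids: {dupes}")
        if self.medication_map is not None:
            self.medication_map.validate_against(self)

    # -- lookup ----------------------------------------------------------
    def ids(self) -> list[str]:
        return [d.id for d in self.deficits]

    def get(self, deficit_id: str) -> DeficitDefinition:
        for d in self.deficits:
            if d.id == deficit_id:
                return d
        raise KeyError(deficit_id)

    def subset(self, variant_class: str) -> tuple[DeficitDefinition, ...]:
        return tuple(d for d in self.deficits if d.variant_class == variant_class)

    def variant_deficits(self, variant: str) -> tuple[DeficitDefinition, ...]:
        """Deficits belonging to a frailty-index variant.

        ``physical`` -> physical deficits only; ``physical_cognitive`` ->
        physical plus cognitive deficits.
        """
        if variant == "physical":
            return self.subset("physical")
        if variant == "physical_cognitive":
            return self.deficits
        raise CatalogError(f"unknown variant {variant!r}; expected one of {VARIANTS}")

    def variant_ids(self, variant: str) -> list[str]:
        return [d.id for d in self.variant_deficits(variant)]

    # -- validation ------------------------------------------------------
    def validate(
        self,
        strict: bool = True,
        min_physical: int = MIN_PHYSICAL_DEFICITS,
        expected_cognitive: int | None = None,
        min_systems: int = MIN_SYSTEMS,
    ) -> list[str]:
        """Check catalog-level frailty-index criteria.

        Returns the list of problems found.  In strict mode problems raise
        :class:`CatalogError`; in permissive mode they are logged as
        warnings (small catalogs are legitimate in unit tests).
        """
        problems: list[str] = []
        n_physical = len(self.subset("physical"))
        if n_physical < min_physical:
            problems.append(
                f"physical variant has {n_physical} deficits; a frailty index "
                f"requires a minimum of {min_physical}"
            )
        if expected_cognitive is not None:
            n_cog = len(self.subset("cognitive"))
            if n_cog != expected_cognitive:
                problems.append(
                    f"cognitive subset has {n_cog} deficits; expected {expected_cognitive}"
                )
        systems = {d.system for d in self.deficits}
        if len(systems) < min_systems:
            problems.append(
                f"deficits span {len(systems)} systems ({sorted(systems)}); "
                f"need at least {min_systems} to cover a range of physiological systems"
            )
        if problems:
            if strict:
                raise CatalogError("; ".join(problems))
            for p in problems:
                logger.warning("catalog %s: %s", self.name, p)
        return problems

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "version": self.version,
            "deficits": [d.to_dict() for d in self.deficits],
        }
        if self.medication_map is not None:
            out["medication_map"] = dict(self.medication_map.rules)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "DeficitCatalog":
        if not isinstance(data, Mapping):
            raise CatalogError("catalog document must be a mapping")
        for fld in ("name", "version", "deficits"):
            if fld not in data:
                raise CatalogError(f"catalog missing required field {fld!r}")
        if not isinstance(data["deficits"], (list, tuple)) or not data["deficits"]:
            raise CatalogError("field 'deficits' must be a non-empty list")
        deficits = []
        allowed = {
            "id", "label", "system", "kind", "variant_class",
            "n_levels", "threshold", "direction", "source",
        }
        for i, entry in enumerate(data["deficits"]):
            if not isinstance(entry, Mapping):
                raise CatalogError(f"deficits[{i}] must be a mapping")
            unknown = set(entry) - allowed
            if unknown:
                raise CatalogError(f"deficits[{i}]: unknown fields {sorted(unknown)}")
            for fld in ("id", "label", "system", "kind", "variant_class"):
                if fld not in entry:
                    raise CatalogError(f"deficits[{i}] missing required field {fld!r}")
            deficits.append(DeficitDefinition(**entry))
        med_map = None
        if data.get("medication_map"):
            if not isinstance(data["medication_map"], Mapping):
                raise CatalogError("field 'medication_map' must be a mapping of code -> deficit id")
            med_map = MedicationConditionMap(rules=dict(data["medication_map"]))
        return cls(
            name=str(data["name"]),
            version=str(data["version"]),
            deficits=tuple(deficits),
            medication_map=med_map,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def with_medication_map(self, med_map: MedicationConditionMap) -> "DeficitCatalog":
        return replace(self, medication_map=med_map)


def load_catalog(
    path: str | Path,
    strict: bool = True,
    expected_cognitive: int | None = None,
) -> DeficitCatalog:
    """Load and validate a deficit catalog from a YAML or JSON file.

    The document structure is published in ``frailtykit/data/catalog.schema.json``.
    In strict mode the frailty-index criteria (>= 30 physical deficits
    spanning >= 5 systems) are enforced as errors; in permissive mode they
    are warnings only.
    """
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise CatalogError(f"could not parse catalog {path}: {exc}") from exc
    catalog = DeficitCatalog.from_dict(data)
    catalog.validate(strict=strict, expected_cognitive=expected_cognitive)
    return catalog


def default_catalog_path() -> Path:
    """Path of the bundled synthetic dementia/MCI catalog."""
    return Path(resources.files("frailtykit.data") / "default_catalog.yaml")


def load_default_catalog() -> DeficitCatalog:
    return load_catalog(default_catalog_path(), strict=True, expected_cognitive=5)


# ---------------------------------------------------------------------------
# medication handling
# ---------------------------------------------------------------------------

def parse_medications(cell) -> list[str]:
    """Split a semicolon-delimited medication-code cell into clean codes."""
    if cell is None or (isinstance(cell, float) and cell != cell):
        return []
    return [c.strip().lower() for c in str(cell).split(";") if c.strip()]


def map_medications(
    meds: Iterable[str], med_map: MedicationConditionMap
) -> set[str]:
    """Infer condition deficit ids from medication-class codes.

    Set semantics: duplicated codes are idempotent and adding codes can
    only add conditions.  Unknown codes are ignored with a logged count.
    """
    conditions: set[str] = set()
    unknown = 0
    for code in meds:
        key = str(code).strip().lower()
        if key in med_map.rules:
            conditions.add(med_map.rules[key])
        else:
            unknown += 1
    if unknown:
        logger.debug("map_medications: ignored %d unknown medication codes", unknown)
    return conditions


def polypharmacy_score(meds: Iterable[str], threshold: int = POLYPHARMACY_THRESHOLD) -> int:
    """1 if the participant takes ``threshold`` (default 5) or more distinct medications."""
    distinct = {str(c).strip().lower() for c in meds if str(c).strip()}
    return int(len(distinct) >= threshold)
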