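"""Data-driven severity-score definitions.

Each of the seven scoring systems (REMS, MEWS, PEDS, SEYMOUR, APACHE2,
APACHE3, SAPS2) is described by a packaged YAML file: banded point tables
over physiologic variables, categorical points (age bands, chronic health,
admission type), special rules (oxygenation branch, acute-renal-failure
creatinine handling, ventilation-conditional PaO2/FiO2), and an optional
published mortality transform. The scoring engine in :mod:`sevscore.engine`
interprets these definitions; nothing about a particular score is hard-coded
there.

Band tables are ordered lists of half-open intervals ``[lo, hi) -> points``.
Validation enforces that the intervals tile the real line without gap or
overlap, that points are non-negative integers, and that the zero-point band
contains the variable's declared normal reference value (so that imputing a
missing value as normal contributes exactly zero points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

SCORE_NAMES = ("REMS", "MEWS", "PEDS", "SEYMOUR", "APACHE2", "APACHE3", "SAPS2")
ED_SCORES = ("REMS", "MEWS", "PEDS", "SEYMOUR")
ICU_SCORES = ("APACHE2", "APACHE3", "SAPS2")

#: snapshot variables replaced by their normal reference value when missing;
#: absent chronic-health flags are likewise treated as false.
MISSING_NORMAL_VARIABLES = frozenset({"albumin", "bilirubin", "ph", "pco2"})

#: normal reference for derived quantities that are not snapshot fields
_DERIVED_NORMALS = {"pf_ratio": 95.0 / 0.21}
_DERIVED_BOUNDS = {"pf_ratio": (0.0, 3500.0)}


class DefinitionError(ValueError):
    """A score definition failed validation (gap, overlap, bad points...)."""


@dataclass(frozen=True)
class VariableSpec:
    """Registry entry for one physiologic variable."""

    name: str
    units: str
    normal: float
    lo: float
    hi: float
    effect: float = 0.0
    p_high: float = 1.0
    noise_sd: float = 0.0
    integer: bool = False


@dataclass(frozen=True)
class BandTable:
    """Piecewise-constant mapping from a variable's value to integer points.

    Intervals are half-open ``[lo, hi)``, stored in increasing order and
    tiling ``(-inf, inf)``.
    """

    variable: str
    los: np.ndarray
    his: np.ndarray
    points: np.ndarray

    @classmethod
    def from_rows(cls, variable: str, rows: Iterable[Iterable[float]]) -> "BandTable":
        rows = [tuple(r) for r in rows]
        if not rows:
            raise DefinitionError(f"{variable}: empty band table")
        rows.sort(key=lambda r: r[0])
        los = np.array([r[0] for r in rows], dtype=float)
        his = np.array([r[1] for r in rows], dtype=float)
        pts = [r[2] for r in rows]
        for lo, hi, p in rows:
            if not (lo < hi):
                raise DefinitionError(f"{variable}: empty interval [{lo}, {hi})")
            if p < 0 or float(p) != int(p):
                raise DefinitionError(
                    f"{variable}: points must be non-negative integers, got {p} "
                    f"on [{lo}, {hi})"
                )
        if not math.isinf(los[0]) or not math.isinf(his[-1]):
            raise DefinitionError(
                f"{variable}: band table must span the whole plausibility range "
                f"(first lo and last hi must be infinite)"
            )
        for i in range(len(rows) - 1):
            if his[i] < los[i + 1]:
                raise DefinitionError(
                    f"{variable}: gap between [{los[i]}, {his[i]}) and "
                    f"[{los[i + 1]}, {his[i + 1]})"
                )
            if his[i] > los[i + 1]:
                raise DefinitionError(
                    f"{variable}: overlap between [{los[i]}, {his[i]}) and "
                    f"[{los[i + 1]}, {his[i + 1]})"
                )
        return cls(variable, los, his, np.array(pts, dtype=int))

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Points for each value; NaN values map to 0 points."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.his[:-1], v, side="right")
        pts = self.points[np.clip(idx, 0, len(self.points) - 1)]
        return np.where(np.isnan(v), 0, pts)

    @property
    def max_points(self) -> int:
        return int(self.points.max())

    def zero_band(self) -> tuple[float, float]:
        i = int(np.argmin(self.points))
        if self.points[i] != 0:
            raise DefinitionError(f"{self.variable}: no zero-point band")
        return float(self.los[i]), float(self.his[i])


@dataclass(frozen=True)
class ScoreDefinition:
    """One scoring system: banded point tables plus categorical weights."""

    name: str
    family: str  # 'ed' or 'icu'
    default_window: str
    provenance: str
    band_tables: Mapping[str, BandTable]
    age_bands: BandTable | None = None
    chronic_health: Mapping | None = None
    chronic_flag_points: Mapping[str, int] = field(default_factory=dict)
    chronic_flag_mode: str = "sum"  # 'sum' or 'max'
    chronic_flag_excluded_categories: frozenset = frozenset()
    admission_type_points: Mapping[str, int] | None = None
    special: Mapping = field(default_factory=dict)
    mortality_transform: Mapping[str, float] | None = None
    required_variables: frozenset = frozenset()
    impute_normal_variables: frozenset = frozenset()

    @property
    def has_mortality_transform(self) -> bool:
        return self.mortality_transform is not None

    @property
    def max_score(self) -> int:
        """Maximum attainable total under this definition."""
        total = 0
        ox = self.special.get("oxygenation")
        for var, table in self.band_tables.items():
            if ox and var in ("pao2", "aa_gradient"):
                continue  # mutually exclusive branch, count once below
            if var == "creatinine_arf":
                continue
            if var == "creatinine" and self.special.get("creatinine_arf") == "double":
                total += 2 * table.max_points
                continue
            if var == "creatinine" and self.special.get("creatinine_arf") == "switch":
                total += max(table.max_points,
                             self.band_tables["creatinine_arf"].max_points)
                continue
            total += table.max_points
        if ox:
            total += max(self.band_tables["pao2"].max_points,
                         self.band_tables["aa_gradient"].max_points)
        if self.age_bands is not None:
            total += self.age_bands.max_points
        if self.chronic_health:
            total += max(self.chronic_health["points_by_admission_category"].values())
        if self.chronic_flag_points:
            vals = list(self.chronic_flag_points.values())
            total += max(vals) if self.chronic_flag_mode == "max" else sum(vals)
        if self.admission_type_points:
            total += max(self.admission_type_points.values())
        return total

    def scored_variables(self) -> frozenset:
        """Snapshot variables this definition can award points for."""
        return frozenset(v for v in self.band_tables
                         if v not in ("creatinine_arf", "pf_ratio"))


def _packaged(name: str) -> Path:
    return Path(resources.files("sevscore").joinpath("definitions", name))


def load_variable_registry(path: str | Path | None = None) -> dict[str, VariableSpec]:
    """Load the physiologic-variable registry (units, bounds, normals)."""
    path = Path(path) if path is not None else _packaged("variables.yaml")
    raw = yaml.safe_load(path.read_text())["variables"]
    return {name: VariableSpec(name=name, **spec) for name, spec in raw.items()}


def _validate_definition(d: ScoreDefinition,
                         registry: Mapping[str, VariableSpec]) -> None:
    for var, table in d.band_tables.items():
        base = "creatinine" if var == "creatinine_arf" else var
        if base in registry:
            normal = registry[base].normal
        elif base in _DERIVED_NORMALS:
            normal = _DERIVED_NORMALS[base]
        else:
            raise DefinitionError(f"{d.name}: unknown variable '{var}'")
        if var == "pf_ratio":
            # conditional component (ventilated only): scores >0 by design
            continue
        lo, hi = table.zero_band()
        if not (lo <= normal < hi):
            raise DefinitionError(
                f"{d.name}/{var}: zero-point band [{lo}, {hi}) does not contain "
                f"the normal reference value {normal}"
            )
    for var in d.required_variables | d.impute_normal_variables:
        if var not in registry:
            raise DefinitionError(f"{d.name}: unknown variable '{var}'")
    if not d.impute_normal_variables <= MISSING_NORMAL_VARIABLES:
        extra = d.impute_normal_variables - MISSING_NORMAL_VARIABLES
        raise DefinitionError(
            f"{d.name}: {sorted(extra)} are not in the missing-as-normal policy"
        )
    if d.family not in ("ed", "icu"):
        raise DefinitionError(f"{d.name}: family must be 'ed' or 'icu'")


def _parse_definition(raw: Mapping, registry: Mapping[str, VariableSpec]) -> ScoreDefinition:
    name = raw["name"]
    tables = {v: BandTable.from_rows(v, rows)
              for v, rows in raw.get("band_tables", {}).items()}
    age = raw.get("age_bands")
    d = ScoreDefinition(
        name=name,
        family=raw["family"],
        default_window=raw["default_window"],
        provenance=raw.get("provenance", "transcribed"),
        band_tables=tables,
        age_bands=BandTable.from_rows("age", age) if age else None,
        chronic_health=raw.get("chronic_health"),
        chronic_flag_points=raw.get("chronic_flag_points", {}) or {},
        chronic_flag_mode=raw.get("chronic_flag_mode", "sum"),
        chronic_flag_excluded_categories=frozenset(
            raw.get("chronic_flag_excluded_categories", [])),
        admission_type_points=raw.get("admission_type_points"),
        special=raw.get("special", {}) or {},
        mortality_transform=raw.get("mortality_transform"),
        required_variables=frozenset(raw.get("required_variables", [])),
        impute_normal_variables=frozenset(raw.get("impute_normal_variables", [])),
    )
    _validate_definition(d, registry)
    return d


def load_score_definitions(
    config_path: str | Path | None = None,
    registry: Mapping[str, VariableSpec] | None = None,
) -> dict[str, ScoreDefinition]:
    """Load all score definitions from a directory of YAML files.

    Parameters
    ----------
    config_path
        Directory holding ``<score>.yaml`` files plus ``variables.yaml``.
        Defaults to the definitions packaged with sevscore.
    registry
        Pre-loaded variable registry; loaded from ``config_path`` if omitted.

    Returns
    -------
    dict mapping score name to validated :class:`ScoreDefinition`.
    """
    base = Path(config_path) if config_path is not None else _packaged("")
    if registry is None:
        reg_path = base / "variables.yaml"
        registry = load_variable_registry(reg_path if reg_path.exists() else None)
    defs: dict[str, ScoreDefinition] = {}
    for fname in sorted(p.name for p in base.glob("*.yaml")):
        if fname == "variables.yaml":
            continue
        raw = yaml.safe_load((base / fname).read_text())
        d = _parse_definition(raw, registry)
        defs[d.name] = d
    missing = set(SCORE_NAMES) - set(defs)
    if config_path is None and missing:
        raise DefinitionError(f"packaged definitions incomplete: missing {missing}")
    return defs
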