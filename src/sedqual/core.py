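"""Domain types and aggregation for sediment heavy-metal concentration data.

All concentrations are mg/kg dry weight throughout the package; there is no
unit-conversion layer. The central objects are:

* :class:`FractionRecord` — one site/metal/period observation resolved into
  the five operationally defined Tessier fractions (exchangeable,
  carbonate-bound, Fe-Mn-oxide-bound, organic-bound, residual).
* :class:`ConcentrationRecord` — a total concentration observation, either
  measured directly or obtained as the sum of the five fractions.
* :class:`GuidelineTable` — per-metal threshold / probable / severe effect
  levels (TEL < PEL; SEL optional) against which hazard quotients are formed.
* :class:`ConstantTables` — background (crustal reference) concentrations and
  Hakanson toxic-response factors for the classical indices.
* :class:`ConcentrationMatrix` — the aggregated site x metal concentration
  table that every index consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ValidationError(ValueError):
    """A value violates a domain invariant (concentration < 0, TEL >= PEL, ...)."""


class SchemaError(ValidationError):
    """An input table is missing required columns or has a malformed header."""


class MissingDataError(ValidationError):
    """A required (site, metal) cell has no observations."""


#: Element symbols accepted without warning in guideline / constants tables.
KNOWN_ELEMENTS = frozenset(
    "Ag Al As B Ba Be Bi Ca Cd Ce Co Cr Cs Cu Fe Ga Hg K La Li Mg Mn Mo Na Nb "
    "Ni P Pb Rb Sb Sc Se Sn Sr Th Ti Tl U V W Y Zn Zr".split()
)


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class FractionRecord:
    """One sequential-extraction observation: five fractions, mg/kg dry wt."""

    site: str
    metal: str
    period: str
    f1: float  # exchangeable
    f2: float  # carbonate bound
    f3: float  # Fe-Mn oxides bound
    f4: float  # organic bound
    f5: float  # residual

    def __post_init__(self) -> None:
        if not str(self.metal).strip():
            raise ValidationError("metal symbol must be nonempty")
        for name in ("f1", "f2", "f3", "f4", "f5"):
            object.__setattr__(self, name, _check_nonneg(name, getattr(self, name)))

    @property
    def fractions(self) -> tuple[float, float, float, float, float]:
        return (self.f1, self.f2, self.f3, self.f4, self.f5)

    @property
    def total(self) -> float:
        """Total metal concentration F1+F2+F3+F4+F5."""
        return self.f1 + self.f2 + self.f3 + self.f4 + self.f5


@dataclass(frozen=True)
class ConcentrationRecord:
    """A total-concentration observation, optionally with a standard deviation."""

    site: str
    metal: str
    period: str
    c: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if not str(self.metal).strip():
            raise ValidationError("metal symbol must be nonempty")
        object.__setattr__(self, "c", _check_nonneg("c", self.c))
        if self.sd is not None:
            object.__setattr__(self, "sd", _check_nonneg("sd", self.sd))


def total_concentration(rec: FractionRecord) -> ConcentrationRecord:
    """Collapse a fraction record to its total concentration (sum of F1..F5)."""
    return ConcentrationRecord(site=rec.site, metal=rec.metal, period=rec.period, c=rec.total)


@dataclass(frozen=True)
class GuidelineEntry:
    """Effect levels for one metal: 0 < TEL < PEL; SEL > 0 or absent."""

    tel: float
    pel: float
    sel: float | None = None

    def __post_init__(self) -> None:
        for name in ("tel", "pel"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a positive finite number, got {v!r}")
            object.__setattr__(self, name, v)
        if self.tel >= self.pel:
            raise ValidationError(f"TEL ({self.tel}) must be < PEL ({self.pel})")
        if self.sel is not None:
            v = float(self.sel)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"sel must be positive, got {v!r}")
            object.__setattr__(self, "sel", v)

    @property
    def levels(self) -> dict[str, float]:
        """Present effect levels by name (tel/pel and sel when available)."""
        out = {"tel": self.tel, "pel": self.pel}
        if self.sel is not None:
            out["sel"] = self.sel
        return out


@dataclass(frozen=True)
class GuidelineTable:
    """Per-metal effect-level entries; metals appear at most once."""

    entries: Mapping[str, GuidelineEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for metal in self.entries:
            if metal not in KNOWN_ELEMENTS:
                warnings.warn(f"unrecognised metal symbol {metal!r} in guideline table")

    def __getitem__(self, metal: str) -> GuidelineEntry:
        try:
            return self.entries[metal]
        except KeyError:
            raise MissingDataError(f"no guideline entry for metal {metal!r}") from None

    def __contains__(self, metal: str) -> bool:
        return metal in self.entries

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(self.entries)


@dataclass(frozen=True)
class ConstantTables:
    """Backgrounds B_i (mg/kg) and toxic-response factors Tr (dimensionless)."""

    background: Mapping[str, float]
    toxic_response: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in ("background", "toxic_response"):
            table = dict(getattr(self, name))
            for metal, value in table.items():
                v = float(value)
                if not (math.isfinite(v) and v > 0):
                    raise ValidationError(f"{name}[{metal!r}] must be positive, got {value!r}")
                table[metal] = v
            object.__setattr__(self, name, table)


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Aggregated site x metal concentrations with the aggregation method tag.

    ``values`` is a DataFrame indexed by site with one column per metal.
    Unless ``allow_missing`` was requested at construction, every cell holds a
    finite nonnegative number.
    """

    values: pd.DataFrame
    method: str = "mean"

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        if (df.fillna(0.0) < 0).any().any():
            raise ValidationError("concentration matrix contains negative values")
        object.__setattr__(self, "values", df)

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def __getitem__(self, key: tuple[str, str]) -> float:
        site, metal = key
        return float(self.values.at[site, metal])

    def site_series(self, site: str) -> pd.Series:
        return self.values.loc[site]


_AGGREGATORS = {"mean": "mean", "median": "median"}


def aggregate_concentrations(
    records: Iterable[ConcentrationRecord],
    method: str = "mean",
    allow_missing: bool = False,
) -> ConcentrationMatrix:
    """Aggregate per-period records to one concentration per (site, metal).

    ``method`` is ``"mean"`` (default, the annual mean over the periods
    present) or ``"median"``. Sites and metals keep first-appearance order.
    Unless ``allow_missing`` is set, a (site, metal) pair with no record
    raises :class:`MissingDataError` naming every empty cell.
    """
    if method not in _AGGREGATORS:
        raise ValidationError(f"unknown aggregation method {method!r}; use mean or median")
    records = list(records)
    if not records:
        raise ValidationError("no concentration records to aggregate")
    df = pd.DataFrame(
        {"site": r.site, "metal": r.metal, "c": r.c} for r in records
    )
    sites = list(dict.fromkeys(df["site"]))
    metals = list(dict.fromkeys(df["metal"]))
    wide = (
        df.groupby(["site", "metal"], sort=False)["c"]
        .agg(_AGGREGATORS[method])
        .unstack("metal")
        .reindex(index=sites, columns=metals)
    )
    if wide.isna().any().any() and not allow_missing:
        missing = [
            (site, metal)
            for site in sites
            for metal in metals
            if pd.isna(wide.at[site, metal])
        ]
        raise MissingDataError(f"no observations for cells: {missing}")
    return ConcentrationMatrix(values=wide, method=method)
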