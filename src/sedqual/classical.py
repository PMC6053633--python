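"""Classical sediment contamination indices used as the comparison suite.

Closed-form indices with long-standing use in sediment quality assessment:

* CF — contamination factor, C / background.
* %DC — each metal's percentage contribution to the degree of contamination
  (the CF sum) at a site.
* mCd — modified degree of contamination, mean CF over the metals.
* PLI — pollution load index, geometric mean CF.
* Er / RI — Hakanson per-metal ecological risk (Tr x CF) and its site sum,
  with %Ri the percentage contribution of each metal to RI.
* RAC — risk assessment code, the bioavailable (exchangeable + carbonate)
  share of the total metal, in percent.
* ICF — individual contamination factor, non-residual over residual metal.
* HQ — a plain effect-level quotient C / level for a chosen guideline level.

Indices whose formulas are defined only in external work (CSI, mRAC, PCI)
are deliberately not computed here; the report layer accepts externally
computed columns for them instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConcentrationMatrix,
    ConstantTables,
    FractionRecord,
    GuidelineTable,
    MissingDataError,
    ValidationError,
)


def contamination_factor(c: float, background: float) -> float:
    """CF = measured concentration over crustal/background reference."""
    if not (math.isfinite(background) and background > 0):
        raise ValidationError(f"background must be positive, got {background!r}")
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c!r}")
    return c / background


def percent_dc(cfs: Mapping[str, float]) -> dict[str, float]:
    """Percentage contribution of each metal's CF to the site CF sum."""
    total = sum(cfs.values())
    if total <= 0:
        raise ValidationError("cannot form %DC: contamination factors sum to zero")
    return {metal: 100.0 * cf / total for metal, cf in cfs.items()}


def modified_degree_of_contamination(cfs: Mapping[str, float]) -> float:
    """mCd = arithmetic mean of the contamination factors."""
    if not cfs:
        raise ValidationError("mCd requires at least one contamination factor")
    return sum(cfs.values()) / len(cfs)


def pollution_load_index(cfs: Mapping[str, float]) -> float:
    """PLI = geometric mean of the contamination factors (all must be > 0)."""
    if not cfs:
        raise ValidationError("PLI requires at least one contamination factor")
    values = np.asarray(list(cfs.values()), dtype=float)
    if (values <= 0).any():
        bad = [m for m, v in cfs.items() if v <= 0]
        raise ValidationError(f"PLI undefined for nonpositive CF of {bad}")
    return float(np.exp(np.mean(np.log(values))))


@dataclass(frozen=True)
class PeriResult:
    """Hakanson potential ecological risk decomposition for one site."""

    er: Mapping[str, float]      # per-metal risk factor Tr x CF
    ri: float                    # site risk index, sum of Er
    percent_ri: Mapping[str, float]  # per-metal % contribution to RI


def potential_ecological_risk(
    cfs: Mapping[str, float], toxic_response: Mapping[str, float]
) -> PeriResult:
    """Er_i = Tr_i x CF_i; RI = sum Er; %Ri = 100 Er / RI."""
    missing = [m for m in cfs if m not in toxic_response]
    if missing:
        raise MissingDataError(f"no toxic-response factor for metal(s) {missing}")
    er = {m: toxic_response[m] * cf for m, cf in cfs.items()}
    ri = sum(er.values())
    if ri <= 0:
        raise ValidationError("risk index RI is zero; %Ri undefined")
    pct = {m: 100.0 * v / ri for m, v in er.items()}
    return PeriResult(er=er, ri=ri, percent_ri=pct)


@dataclass(frozen=True)
class SpeciationResult:
    """Fraction-based mobility indices for one record."""

    rac: float          # % of total metal in F1+F2 (bioavailable pool)
    icf: float | None   # (F1+F2+F3+F4)/F5; None when F5 == 0


def speciation_indices(rec: FractionRecord) -> SpeciationResult:
    """RAC and ICF from one five-fraction record.

    ICF is undefined when the residual fraction is zero; it is reported as
    ``None`` rather than raising, since a fully mobile metal is a legitimate
    (if extreme) observation.
    """
    total = rec.total
    if total <= 0:
        raise ValidationError("speciation indices undefined for zero total metal")
    rac = 100.0 * (rec.f1 + rec.f2) / total
    icf = None if rec.f5 == 0 else (rec.f1 + rec.f2 + rec.f3 + rec.f4) / rec.f5
    return SpeciationResult(rac=rac, icf=icf)


def effect_level_quotient(c: float, level: float) -> float:
    """Plain hazard quotient C / level for a chosen effect level."""
    if not (math.isfinite(level) and level > 0):
        raise ValidationError(f"effect level must be positive, got {level!r}")
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c!r}")
    return c / level


#: index names understood by :func:`index_table` --set selection
INDEX_NAMES = ("cf", "dc", "mcd", "pli", "peri", "rac", "icf", "hq")


def index_table(
    matrix: ConcentrationMatrix,
    constants: ConstantTables,
    guidelines: GuidelineTable | None = None,
    fraction_records: Sequence[FractionRecord] | None = None,
    which: Sequence[str] = INDEX_NAMES,
    hq_level: str = "tel",
) -> pd.DataFrame:
    """Long-format table of index values, one row per (index, site, metal).

    Aggregate indices (mCd, PLI, RI) carry metal ``"ALL"``. The speciation
    indices (RAC, ICF) need ``fraction_records`` and are averaged over the
    periods present for each (site, metal).
    """
    which = [w.lower() for w in which]
    unknown = [w for w in which if w not in INDEX_NAMES]
    if unknown:
        raise ValidationError(f"unknown index selection {unknown}; choose from {INDEX_NAMES}")
    rows: list[dict] = []

    def add(index: str, site: str, metal: str, value: float) -> None:
        rows.append({"index": index, "site": site, "metal": metal, "value": value})

    needs_cf = {"cf", "dc", "mcd", "pli", "peri"} & set(which)
    for site in matrix.sites:
        if needs_cf:
            cfs = {
                m: contamination_factor(matrix[site, m], constants.background[m])
                for m in matrix.metals
                if m in constants.background
            }
            missing = [m for m in matrix.metals if m not in constants.background]
            if missing:
                raise MissingDataError(f"no background for metal(s) {missing}")
            if "cf" in which:
                for m, v in cfs.items():
                    add("cf", site, m, v)
            if "dc" in which:
                for m, v in percent_dc(cfs).items():
                    add("dc", site, m, v)
            if "mcd" in which:
                add("mcd", site, "ALL", modified_degree_of_contamination(cfs))
            if "pli" in which:
                add("pli", site, "ALL", pollution_load_index(cfs))
            if "peri" in which:
                peri = potential_ecological_risk(cfs, constants.toxic_response)
                for m, v in peri.er.items():
                    add("er", site, m, v)
                add("ri", site, "ALL", peri.ri)
                for m, v in peri.percent_ri.items():
                    add("pct_ri", site, m, v)
        if "hq" in which:
            if guidelines is None:
                raise ValidationError("HQ selection requires a guideline table")
            for m in matrix.metals:
                if m in guidelines:
                    level = guidelines[m].levels[hq_level]
                    add(f"hq_{hq_level}", site, m, effect_level_quotient(matrix[site, m], level))

    if {"rac", "icf"} & set(which):
        if fraction_records is None:
            raise ValidationError("RAC/ICF selection requires fraction records")
        spec = pd.DataFrame(
            {
                "site": r.site,
                "metal": r.metal,
                "rac": speciation_indices(r).rac,
                "icf": speciation_indices(r).icf,
            }
            for r in fraction_records
        )
        grouped = spec.groupby(["site", "metal"], sort=False).mean(numeric_only=True)
        for (site, metal), row in grouped.iterrows():
            if "rac" in which:
                add("rac", site, metal, row["rac"])
            if "icf" in which:
                add("icf", site, metal, row["icf"])

    return pd.DataFrame(rows, columns=["index", "site", "metal", "value"])
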