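"""Modified hazard quotient (mHQ) and ecological contamination index (ECI).

The mHQ compares a metal's sediment concentration C_i with the three
effect-level guidelines simultaneously::

    mHQ_i = sqrt( C_i * (1/TEL_i + 1/PEL_i + 1/SEL_i) )

The square root acts as a drawdown so that the index grows with the square
root of concentration rather than linearly, compressing the upper range for
ranking purposes. A site's ECI aggregates the per-metal quotients with a
weight derived from a correlation PCA of the metal concentrations::

    ECI = B_n * sum_i mHQ_i,   B_n = 1 / lambda   (reciprocal eigenvalue)

where lambda is by convention the first (anthropogenic-source) eigenvalue of
the site's metals-only correlation PCA — see :mod:`sedqual.pca`.

Both indices map onto ordinal severity scales via left-closed intervals
(each boundary belongs to the class above it).
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import ConcentrationMatrix, GuidelineEntry, GuidelineTable, ValidationError

#: Severity class boundaries and labels for the modified hazard quotient.
MHQ_EDGES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
MHQ_LABELS: tuple[str, ...] = (
    "Nil to very low severity of contamination",
    "Very low severity of contamination",
    "Low severity of contamination",
    "Moderate severity of contamination",
    "Considerable severity of contamination",
    "High severity of contamination",
    "Very high severity of contamination",
    "Extreme severity of contamination",
)

#: Contamination class boundaries and labels for the ECI.
ECI_EDGES: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
ECI_LABELS: tuple[str, ...] = (
    "Uncontaminated",
    "Uncontaminated to slightly contaminated",
    "Slightly to moderately contaminated",
    "Moderately to considerably contaminated",
    "Considerably to highly contaminated",
    "Highly contaminated",
    "Extremely contaminated",
)


def classify_mhq(mhq: float) -> str:
    """Severity label for an mHQ value (left-closed intervals)."""
    if not (math.isfinite(mhq) and mhq >= 0):
        raise ValidationError(f"mHQ must be a finite nonnegative number, got {mhq!r}")
    return MHQ_LABELS[bisect_right(MHQ_EDGES, mhq)]


def classify_eci(eci: float) -> str:
    """Contamination label for an ECI value (left-closed intervals)."""
    if not (math.isfinite(eci) and eci >= 0):
        raise ValidationError(f"ECI must be a finite nonnegative number, got {eci!r}")
    return ECI_LABELS[bisect_right(ECI_EDGES, eci)]


@dataclass(frozen=True)
class MhqResult:
    site: str
    metal: str
    mhq: float
    severity_class: str
    #: True when the guideline entry lacked SEL and the quotient used only
    #: the TEL and PEL reciprocal terms (changes the scale of the index).
    partial: bool = False


@dataclass(frozen=True)
class EciResult:
    site: str
    eci: float
    bn: float
    #: per-metal percentage contribution to the mHQ sum (sums to 100)
    contributions: Mapping[str, float]
    contamination_class: str
    #: metals excluded for lack of data or guidelines at this site
    excluded: tuple[str, ...] = ()


def compute_mhq(c: float, guideline: GuidelineEntry) -> float:
    """Evaluate mHQ = sqrt(C * (1/TEL + 1/PEL + 1/SEL)) for one metal.

    When the entry has no SEL the quotient is formed from the available
    reciprocal terms only (callers should flag this — see
    :func:`mhq_results`).
    """
    c = float(c)
    if not (math.isfinite(c) and c >= 0):
        raise ValidationError(f"concentration must be finite and >= 0, got {c!r}")
    recip = sum(1.0 / level for level in guideline.levels.values())
    return math.sqrt(c * recip)


def mhq_results(
    matrix: ConcentrationMatrix, guidelines: GuidelineTable
) -> list[MhqResult]:
    """Per-metal mHQ with severity classes for every site in the matrix.

    Metals without a guideline entry are skipped with a warning; entries
    lacking SEL produce results flagged ``partial``.
    """
    out: list[MhqResult] = []
    missing = [m for m in matrix.metals if m not in guidelines]
    if missing:
        warnings.warn(f"no guideline entry for {missing}; mHQ not computed for them")
    for site in matrix.sites:
        for metal in matrix.metals:
            if metal not in guidelines:
                continue
            entry = guidelines[metal]
            value = compute_mhq(matrix[site, metal], entry)
            out.append(
                MhqResult(
                    site=site,
                    metal=metal,
                    mhq=value,
                    severity_class=classify_mhq(value),
                    partial=entry.sel is None,
                )
            )
    return out


def compute_eci(mhqs: Sequence[MhqResult], bn: float) -> EciResult:
    """Aggregate one site's mHQ values into an ECI.

    ``bn`` is the reciprocal-eigenvalue weight (see
    :func:`sedqual.pca.bn_weight`). Contributions are each metal's share of
    the mHQ sum in percent; when every mHQ is zero they are reported uniform
    with a warning since the shares are then undefined.
    """
    mhqs = list(mhqs)
    if not mhqs:
        raise ValidationError("cannot compute ECI from an empty mHQ collection")
    sites = {r.site for r in mhqs}
    if len(sites) > 1:
        raise ValidationError(f"mHQ collection spans multiple sites: {sorted(sites)}")
    bn = float(bn)
    if not (math.isfinite(bn) and bn > 0):
        raise ValidationError(f"B_n must be positive and finite, got {bn!r}")
    total = sum(r.mhq for r in mhqs)
    eci = bn * total
    if total > 0:
        contributions = {r.metal: 100.0 * r.mhq / total for r in mhqs}
    else:
        warnings.warn("all mHQ values are zero; contributions reported as uniform")
        contributions = {r.metal: 100.0 / len(mhqs) for r in mhqs}
    return EciResult(
        site=sites.pop(),
        eci=eci,
        bn=bn,
        contributions=contributions,
        contamination_class=classify_eci(eci),
    )


@dataclass(frozen=True)
class MetalRanking:
    """Descending severity order with tie bookkeeping."""

    order: tuple[str, ...]
    #: groups of metals whose index values were exactly equal
    ties: tuple[tuple[str, ...], ...] = ()

    @property
    def tied(self) -> bool:
        return bool(self.ties)


def rank_metals_by_mhq(results: Sequence[MhqResult]) -> MetalRanking:
    """Order one site's metals by descending mHQ, ties broken alphabetically."""
    if not results:
        raise ValidationError("no mHQ results to rank")
    ranked = sorted(results, key=lambda r: (-r.mhq, r.metal))
    groups: dict[float, list[str]] = {}
    for r in ranked:
        groups.setdefault(r.mhq, []).append(r.metal)
    ties = tuple(tuple(ms) for ms in groups.values() if len(ms) > 1)
    return MetalRanking(order=tuple(r.metal for r in ranked), ties=ties)
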