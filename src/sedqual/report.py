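"""End-to-end pipeline: indices, classification, rankings, concordance.

``run_pipeline`` ties the modules together: aggregate the per-period
records, compute mHQ per (site, metal) and ECI per site, the classical
comparison suite, a per-site correlation PCA (or externally supplied
eigenvalues, e.g. the published two-component summaries), and a
trend-concordance report comparing the metal severity orderings of the
different indices. Externally computed index columns (e.g. CSI, mRAC, PCI,
whose formulas live in other work) can be merged into the concordance via
``extra_orderings``.

Everything is deterministic given the inputs; the manifest records every
numeric constant used so a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classical import index_table
from .core import (
    ConcentrationMatrix,
    ConcentrationRecord,
    ConstantTables,
    FractionRecord,
    GuidelineTable,
    ValidationError,
    aggregate_concentrations,
)
from .new_indices import (
    EciResult,
    MetalRanking,
    MhqResult,
    compute_eci,
    mhq_results,
    rank_metals_by_mhq,
)
from .pca import FactorModel, bn_weight, fit_pca, retain_components, rotate_model


@dataclass(frozen=True)
class PipelineConfig:
    """Switches for every genuinely open analysis choice.

    * ``aggregation`` — per-site C_i as mean (default) or median over periods.
    * ``bn_component`` — which eigenvalue's reciprocal forms B_n (1 = PC1).
    * ``bn_source`` — ``"computed"`` fits a per-site correlation PCA on the
      period x metal matrix; ``"provided"`` uses eigenvalues passed to
      :func:`run_pipeline` (e.g. published values).
    * ``retention`` — Kaiser (eigenvalue > 1) or fixed-k component retention.
    * ``rotate`` — varimax-rotate the retained loadings in the report. B_n
      always uses the pre-rotation eigenvalue.
    * ``indices`` — classical-index selection for the comparison table.
    * ``precision`` — significant digits for text output.
    """

    aggregation: str = "mean"
    bn_component: int = 1
    bn_source: str = "computed"
    retention: str = "kaiser"
    retention_k: int = 2
    rotate: bool = True
    indices: tuple[str, ...] = ("cf", "dc", "mcd", "pli", "peri", "hq")
    hq_level: str = "tel"
    precision: int = 4

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "indices" in raw and isinstance(raw["indices"], str):
            raw = {**raw, "indices": tuple(s.strip() for s in raw["indices"].split(","))}
        elif "indices" in raw:
            raw = {**raw, "indices": tuple(raw["indices"])}
        return cls(**raw)


@dataclass(frozen=True)
class SiteRanking:
    order: tuple[str, ...]
    ties: tuple[tuple[str, ...], ...] = ()

    @property
    def tied(self) -> bool:
        return bool(self.ties)


def rank_sites_by_eci(results: Mapping[str, EciResult] | Sequence[EciResult]) -> SiteRanking:
    """Sites in descending ECI order; exact ties keep input order, flagged."""
    if not isinstance(results, Mapping):
        results = {r.site: r for r in results}
    if not results:
        raise ValidationError("no ECI results to rank")
    items = list(results.items())
    order = [site for site, _ in sorted(items, key=lambda kv: -kv[1].eci)]
    groups: dict[float, list[str]] = {}
    for site, r in items:
        groups.setdefault(r.eci, []).append(site)
    ties = tuple(tuple(g) for g in groups.values() if len(g) > 1)
    return SiteRanking(order=tuple(order), ties=ties)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between the metal severity orderings of different indices."""

    orderings: Mapping[str, Mapping[str, tuple[str, ...]]]  # index -> site -> order
    exact_match: pd.DataFrame       # rows (index_a, index_b, site), bool
    spearman: pd.DataFrame          # rows (index_a, index_b, site), rho

    def all_consistent(self) -> bool:
        return bool(self.exact_match["match"].all())


def _ordering_ranks(order: Sequence[str], metals: Sequence[str]) -> np.ndarray:
    pos = {m: i + 1 for i, m in enumerate(order)}
    return np.array([pos[m] for m in metals], dtype=float)


def concordance(
    orderings: Mapping[str, Mapping[str, Sequence[str]]]
) -> ConcordanceReport:
    """Pairwise exact-match flags and Spearman rho between index orderings.

    Every index must supply, per site, a permutation of the same metal set.
    """
    if len(orderings) < 2:
        raise ValidationError("concordance needs at least two indices")
    names = list(orderings)
    sites = list(orderings[names[0]])
    reference = None
    for name in names:
        if list(orderings[name]) != sites:
            raise ValidationError(f"index {name!r} covers different sites")
        for site in sites:
            metals = frozenset(orderings[name][site])
            if reference is None:
                reference = metals
            if metals != reference:
                raise ValidationError(
                    f"ordering of {name!r} at {site!r} is over a different metal set"
                )
    metals = sorted(reference)
    match_rows, rho_rows = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for site in sites:
                oa, ob = tuple(orderings[a][site]), tuple(orderings[b][site])
                ra, rb = _ordering_ranks(oa, metals), _ordering_ranks(ob, metals)
                rho = float(stats.spearmanr(ra, rb).statistic)
                match_rows.append({"index_a": a, "index_b": b, "site": site, "match": oa == ob})
                rho_rows.append({"index_a": a, "index_b": b, "site": site, "rho": rho})
    frozen = {k: {s: tuple(v[s]) for s in v} for k, v in orderings.items()}
    return ConcordanceReport(
        orderings=frozen,
        exact_match=pd.DataFrame(match_rows),
        spearman=pd.DataFrame(rho_rows),
    )


@dataclass(frozen=True)
class PipelineResult:
    matrix: ConcentrationMatrix
    mhq: tuple[MhqResult, ...]
    eci: Mapping[str, EciResult]
    factor_models: Mapping[str, FactorModel]
    classical: pd.DataFrame
    metal_rankings: Mapping[str, Mapping[str, MetalRanking]]  # index -> site -> ranking
    site_ranking: SiteRanking
    concordance: ConcordanceReport
    manifest: Mapping


def _per_site_matrix(records: Sequence[ConcentrationRecord], site: str) -> pd.DataFrame:
    df = pd.DataFrame({"metal": r.metal, "period": r.period, "c": r.c}
                      for r in records if r.site == site)
    return df.pivot_table(index="period", columns="metal", values="c", sort=False)


def _rankings_from_values(values: Mapping[str, Mapping[str, float]]) -> dict[str, MetalRanking]:
    """Descending-value orderings per site from a site -> metal -> value map."""
    out: dict[str, MetalRanking] = {}
    for site, metal_values in values.items():
        ranked = sorted(metal_values.items(), key=lambda kv: (-kv[1], kv[0]))
        groups: dict[float, list[str]] = {}
        for metal, v in ranked:
            groups.setdefault(v, []).append(metal)
        ties = tuple(tuple(g) for g in groups.values() if len(g) > 1)
        out[site] = MetalRanking(order=tuple(m for m, _ in ranked), ties=ties)
    return out


def run_pipeline(
    records: Sequence[ConcentrationRecord],
    guidelines: GuidelineTable,
    constants: ConstantTables,
    config: PipelineConfig = PipelineConfig(),
    fraction_records: Sequence[FractionRecord] | None = None,
    provided_eigenvalues: Mapping[str, float] | None = None,
    extra_orderings: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> PipelineResult:
    """Compute every index, classification and ranking from totals records."""
    if not records:
        raise ValidationError("pipeline: no concentration records supplied")
    matrix = aggregate_concentrations(records, method=config.aggregation)

    # stage: per-site factor models / B_n
    factor_models: dict[str, FactorModel] = {}
    bn: dict[str, float] = {}
    if config.bn_source == "provided":
        if provided_eigenvalues is None:
            raise ValidationError("bn_source='provided' needs provided_eigenvalues")
        missing = [s for s in matrix.sites if s not in provided_eigenvalues]
        if missing:
            raise ValidationError(f"no provided eigenvalue for site(s) {missing}")
        bn = {s: bn_weight(provided_eigenvalues[s]) for s in matrix.sites}
    elif config.bn_source == "computed":
        for site in matrix.sites:
            model = fit_pca(_per_site_matrix(records, site))
            retained = retain_components(
                model, rule=config.retention,
                k=config.retention_k if config.retention == "fixed" else None,
            )
            factor_models[site] = (
                rotate_model(retained) if config.rotate and retained.n_components >= 2
                else retained
            )
            bn[site] = bn_weight(model, component=config.bn_component)
    else:
        raise ValidationError(f"unknown bn_source {config.bn_source!r}")

    # stage: new indices
    mhq = mhq_results(matrix, guidelines)
    eci: dict[str, EciResult] = {}
    for site in matrix.sites:
        site_mhqs = [r for r in mhq if r.site == site]
        eci[site] = compute_eci(site_mhqs, bn[site])

    # stage: classical comparison suite
    classical = index_table(
        matrix, constants, guidelines=guidelines,
        fraction_records=fraction_records,
        which=config.indices, hq_level=config.hq_level,
    )

    # stage: orderings and concordance
    mhq_values = {
        site: {r.metal: r.mhq for r in mhq if r.site == site} for site in matrix.sites
    }
    orderings_values: dict[str, dict[str, dict[str, float]]] = {"mhq": mhq_values}
    orderings_values["eci_contribution"] = {
        site: dict(eci[site].contributions) for site in matrix.sites
    }
    per_metal = classical[~classical["metal"].eq("ALL")]
    for name, grp in per_metal.groupby("index", sort=False):
        orderings_values[name] = {
            site: dict(zip(sub["metal"], sub["value"]))
            for site, sub in grp.groupby("site", sort=False)
        }
    metal_rankings = {
        name: _rankings_from_values(values) for name, values in orderings_values.items()
    }
    orderings = {
        name: {site: rk.order for site, rk in per_site.items()}
        for name, per_site in metal_rankings.items()
    }
    if extra_orderings:
        for name, per_site in extra_orderings.items():
            orderings[name] = {s: tuple(o) for s, o in per_site.items()}
    report = concordance(orderings)

    manifest = {
        "config": {
            "aggregation": config.aggregation,
            "bn_component": config.bn_component,
            "bn_source": config.bn_source,
            "retention": config.retention,
            "rotate": config.rotate,
            "indices": list(config.indices),
            "hq_level": config.hq_level,
            "precision": config.precision,
        },
        "guidelines": {
            m: guidelines[m].levels for m in guidelines.metals
        },
        "background": dict(constants.background),
        "toxic_response": dict(constants.toxic_response),
        "bn": dict(bn),
        "sites": list(matrix.sites),
        "metals": list(matrix.metals),
    }
    return PipelineResult(
        matrix=matrix,
        mhq=tuple(mhq),
        eci=eci,
        factor_models=factor_models,
        classical=classical,
        metal_rankings=metal_rankings,
        site_ranking=rank_sites_by_eci(eci),
        concordance=report,
        manifest=manifest,
    )
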