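"""Bundled study fixtures and a seeded synthetic fraction-data generator.

Two plain-text fixture tables ship with the package (checksummed on load):

* the 5-site x 5-metal x 6-month monthly mean (+/- s.d.) total
  concentrations of Cd, Cr, Cu, Ni and Pb in benthic sediments of five
  Equatorial Atlantic coastal ecosystems, and
* the per-site two-component correlation-PCA summaries (rotated loadings,
  eigenvalues, variability) whose PC1 eigenvalues supply the published ECI
  weights.

The generator emulates data of the same shape: per (site, metal, period) a
lognormal total concentration with configurable mean/CV and per-site
contamination multiplier, split across the five Tessier fractions by a
Dirichlet draw around target proportions. Draws are i.i.d. across periods
(no seasonality or spatial autocorrelation) and fully determined by the
seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ConcentrationRecord, FractionRecord, ValidationError
from .pca import FactorModel

_TABLE1 = "table1_monthly_concentrations.csv"
_TABLE2 = "table2_pca_loadings.csv"

#: sha256 of the bundled fixture files; verified on every load so silent
#: edits of the study constants are caught.
_CHECKSUMS = {
    _TABLE1: "4a7cc624a70deb4a4f16759be65dcf61d809426a90cac8577ed53e5200a65252",
    _TABLE2: "b187519f92902c2c29cddacafe27bc83539c57bd5b6a63aaa9a9ece0917505e8",
}

SITES = ("QUE", "DOU", "STB", "OKT", "QUR")
METALS = ("Cd", "Cr", "Cu", "Ni", "Pb")
PERIODS = ("Jun", "Jul", "Aug", "Nov", "Dec", "Jan")


def _fixture_path(name: str) -> Path:
    path = Path(str(resources.files("sedqual").joinpath("data", name)))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValidationError(
            f"fixture {name} checksum mismatch ({digest}); the bundled study "
            "constants appear to have been modified"
        )
    return path


def monthly_concentration_records() -> list[ConcentrationRecord]:
    """The 150 bundled monthly mean +/- s.d. total-concentration records."""
    df = pd.read_csv(_fixture_path(_TABLE1), comment="#")
    return [
        ConcentrationRecord(
            site=row.site, metal=row.metal, period=row.period,
            c=float(row.c), sd=float(row.sd),
        )
        for row in df.itertuples(index=False)
    ]


def reference_factor_models() -> dict[str, FactorModel]:
    """The bundled per-site two-component PCA summaries, as printed.

    These are the published post-rotation constants, not a re-fit; PC1's
    eigenvalue is the conventional source of the ECI weight B_n.
    """
    df = pd.read_csv(_fixture_path(_TABLE2), comment="#")
    models: dict[str, FactorModel] = {}
    for site, grp in df.groupby("site", sort=False):
        grp = grp.sort_values("component")
        metals = tuple(c.removeprefix("load_") for c in grp.columns if c.startswith("load_"))
        loadings = grp[[f"load_{m}" for m in metals]].to_numpy(dtype=float).T
        models[site] = FactorModel(
            metals=metals,
            eigenvalues=grp["eigenvalue"].to_numpy(dtype=float),
            loadings=loadings,
            variability_pct=grp["variability_pct"].to_numpy(dtype=float),
            cumulative_pct=grp["cumulative_pct"].to_numpy(dtype=float),
            rotation="varimax",
            n_variables=len(metals),
        )
    return models


def reference_pc1_eigenvalues() -> dict[str, float]:
    """PC1 eigenvalue per site from the bundled PCA summaries."""
    return {site: float(m.eigenvalues[0]) for site, m in reference_factor_models().items()}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic multi-site fraction dataset.

    ``mean`` and ``cv`` describe each metal's baseline lognormal total
    (mg/kg dry weight, coefficient of variation); ``site_multipliers`` scale
    the means per site (the contamination gradient); ``proportions`` give
    each metal's target F1..F5 split (summing to 1); ``dirichlet_precision``
    is the concentration parameter of the Dirichlet noise around those
    proportions (``inf`` for an exact split).
    """

    metals: tuple[str, ...]
    mean: Mapping[str, float]
    cv: Mapping[str, float]
    proportions: Mapping[str, tuple[float, float, float, float, float]]
    site_multipliers: Mapping[str, float]
    periods: int = 6
    dirichlet_precision: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metals:
            raise ValidationError("scenario needs at least one metal")
        for m in self.metals:
            if m not in self.mean or self.mean[m] <= 0:
                raise ValidationError(f"metal {m!r} needs a positive mean concentration")
            if self.cv.get(m, 0.0) < 0:
                raise ValidationError(f"metal {m!r} has negative CV")
            props = np.asarray(self.proportions[m], dtype=float)
            if props.shape != (5,) or (props < 0).any():
                raise ValidationError(f"metal {m!r} needs 5 nonnegative fraction proportions")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"fraction proportions of {m!r} sum to {props.sum()!r}, expected 1"
                )
        for site, mult in self.site_multipliers.items():
            if mult <= 0:
                raise ValidationError(f"site {site!r} multiplier must be > 0")
        if self.periods < 1:
            raise ValidationError("periods must be >= 1")
        if not self.dirichlet_precision > 0:
            raise ValidationError("dirichlet_precision must be > 0 (or inf)")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            metals=tuple(raw["metals"]),
            mean={k: float(v) for k, v in raw["mean"].items()},
            cv={k: float(v) for k, v in raw["cv"].items()},
            proportions={k: tuple(map(float, v)) for k, v in raw["proportions"].items()},
            site_multipliers={k: float(v) for k, v in raw["site_multipliers"].items()},
            periods=int(raw.get("periods", 6)),
            dirichlet_precision=float(raw.get("dirichlet_precision", 200.0)),
            seed=int(raw.get("seed", 0)),
        )


def generate_dataset(spec: ScenarioSpec, seed: int | None = None) -> list[FractionRecord]:
    """Draw a synthetic fraction dataset; identical seeds give identical data.

    Totals are lognormal with the spec's mean (times the site multiplier)
    and CV: sigma^2 = ln(1 + CV^2), mu = ln(mean) - sigma^2/2, so the
    arithmetic mean of the draws converges to the target. CV = 0 collapses
    to the exact mean. Fractions are total x Dirichlet(precision x
    proportions); infinite precision uses the exact proportions.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[FractionRecord] = []
    for site, mult in spec.site_multipliers.items():
        for metal in spec.metals:
            target = spec.mean[metal] * mult
            cv = spec.cv.get(metal, 0.0)
            props = np.asarray(spec.proportions[metal], dtype=float)
            for t in range(spec.periods):
                if cv == 0:
                    total = target
                else:
                    sigma2 = math.log1p(cv**2)
                    mu = math.log(target) - sigma2 / 2.0
                    total = float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))
                if math.isinf(spec.dirichlet_precision):
                    split = props
                else:
                    alpha = np.where(props > 0, props * spec.dirichlet_precision, 0.0)
                    split = np.zeros(5)
                    pos = alpha > 0
                    split[pos] = rng.dirichlet(alpha[pos])
                f = total * split
                records.append(
                    FractionRecord(
                        site=site, metal=metal, period=f"P{t + 1}",
                        f1=f[0], f2=f[1], f3=f[2], f4=f[3], f5=f[4],
                    )
                )
    return records
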