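# Methods

## Model and procedure

The package computes composite contamination indices from per-period,
per-site, per-metal sediment concentrations (mg/kg dry weight throughout;
there is no unit-conversion layer).

**Aggregation.** Indices are computed from one concentration C_i per
(site, metal). The default is the arithmetic mean over all sampling
periods (the annual mean of monthly means for the bundled dataset); a
median option and per-period computation are exposed because the
aggregation level is a genuinely open choice — summary tables of this
kind do not say whether site indices were formed from averaged
concentrations or from per-period indices averaged afterwards. Both paths
are switchable in `PipelineConfig`/the CLI.

**Modified hazard quotient.** mHQ_i = sqrt(C_i (1/TEL_i + 1/PEL_i +
1/SEL_i)). The reciprocal-sum term pools the three effect levels into a
single scale factor; the square root compresses the index (×4
concentration → ×2 index), which stabilises cross-metal rankings. If a
guideline entry lacks SEL the quotient is formed from the available
reciprocal terms and the result is flagged `partial`, because dropping a
term changes the scale of the index.

**Severity classes.** Both classification tables are implemented as
left-closed intervals: a ≤ x < b, with each printed boundary (0.5 … 3.5
for mHQ; 2 … 7 for ECI) belonging to the class above it. The top classes
are printed with strict inequalities ("> 3.5", "> 7"), which would leave
the boundary values unassigned; assigning boundaries upward keeps the
partition total and is consistent with the other rows.

**ECI.** ECI = B_n Σ mHQ_i over the n metals with a computed mHQ at the
site; metals without data or guidelines are excluded and listed rather
than silently rescaling the sum. B_n is the reciprocal of the "derived
eigenvalue" of the site's metals-only correlation PCA. Which eigenvalue
that is, is a design choice: the default is the first (largest)
pre-rotation eigenvalue, because PC1 carries the anthropogenic-source
interpretation that motivates the weight. The component index and the
eigenvalue source (`computed` per-site PCA vs `provided` external/
published values) are configurable. On the bundled dataset the two routes
agree closely — the self-computed PC1 eigenvalue for DOU is 1.704 against
the published 1.705 — and the computed route reproduces the published
site severity sequence DOU > QUE > QUR > STB > OKT exactly, while the
published-eigenvalue route swaps QUE and QUR by ~0.25 index units
(within the tolerance implied by the unprinted guideline constants).

**PCA.** Correlation-matrix PCA: columns are z-scored with the sample
standard deviation (ddof = 1), so eigenvalues sum to the number of
variables p and variability% = eigenvalue/p × 100. The decomposition is
scikit-learn's SVD-based PCA on the z-scores; tests verify equivalence to
a dense eigendecomposition of the explicit correlation matrix at 1e-10.
Loadings use the factor convention eigenvector × sqrt(eigenvalue), so
with no discarded components L·Lᵀ reproduces the correlation matrix.
Column signs are normalised so each component's largest-magnitude loading
is positive (printed loading signs are convention-dependent). With fewer
than p+1 observations the correlation matrix is rank-deficient; trailing
eigenvalues are reported as zero and excluded from Kaiser retention
(eigenvalue > 1; a fixed-k rule is also available). Varimax rotation uses
the standard SVD fixed-point iteration with Kaiser row-normalisation by
default (toggleable, matching the common default of desktop statistics
packages); rotation preserves communalities and never decreases the
varimax criterion, and B_n always uses the pre-rotation eigenvalue.

## Bundled constants

Effect levels are not part of the index definitions and must be pinned
for reproducibility. The bundled defaults (`data/default_guidelines.csv`,
overridable) take TEL/PEL from the widely used sediment-quality-guideline
compilations — coastal/estuarine values for Cd (0.68/4.21), Cr
(52.3/160.4), Cu (18.7/108.2), Ni (15.9/42.8) and the Canadian freshwater
pair for Pb (35/91.3) — and SEL from the Ontario provincial severe-effect
levels (10, 110, 110, 75, 250). `data/default_constants.csv` carries
average-shale backgrounds and the Hakanson toxic-response factors for the
classical indices. CSI, mRAC and PCI, whose formulas are defined in
external work, are not computed; externally computed orderings can be
merged into the concordance report via `extra_orderings`.

## Synthetic data generator

`ScenarioSpec`/`generate_dataset` emulate multi-site five-fraction
monitoring data: per (site, metal, period) a lognormal total with
configurable mean and CV (σ² = ln(1+CV²), μ = ln(mean) − σ²/2, so the
arithmetic mean of draws converges to the target), scaled by a per-site
contamination multiplier, and split across F1–F5 by a Dirichlet draw
around target proportions (precision parameter; ∞ gives an exact split).
Draws are i.i.d. across periods and sites given the seed — the generator
has no seasonality, spatial autocorrelation, censoring at detection
limits, or analytical error structure. Tests passing on generated data
therefore demonstrate correct index arithmetic and ranking recovery under
lognormal noise, not robustness to those real-data features.

## Numerical choices

- Ranking ties (equal index values) are broken alphabetically and
  flagged, never silently.
- All-zero mHQ sums make percentage contributions undefined; they are
  reported uniform with a warning.
- ICF with a zero residual fraction is undefined and reported as missing
  rather than raising.
- Text output uses 4 significant digits by default (configurable);
  round-tripping fraction tables through the writers is exact because
  floats are written at `repr` precision.
- Fixture tables are checksummed (SHA-256) on load so silent edits of the
  study constants are caught.

## Problem sizes

The bundled validation dataset is 5 sites × 5 metals × 6 periods (150
records); per-site PCAs are 6 × 5. Property tests use random 6×5–10×4
matrices, and generator-recovery tests use 800–1000 periods, which keeps
the Monte-Carlo sampling error (≈ CV/√N) well inside the asserted 3·CV/√N
band.

## Known limitations

- The ECI weight makes the index scale-dependent on the PCA input: sites
  with weakly correlated metals get larger λ₁⁻¹ only through the
  correlation structure, not through concentrations, so ECIs from
  different observation windows are comparable only if the PCA inputs
  are.
- Uncertainty in the ± s.d. columns is carried through IO but not
  propagated into the indices (point estimates only).
- No oblique rotations, factor scores, or bootstrap intervals on
  loadings; no enrichment factor or geoaccumulation index.
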