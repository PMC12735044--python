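# Methods

## Scope and model

`labscreen` turns replicate bioassay readings on a panel of candidate
strains into a ranked short-list. Three layers:

1. **Assay quantification** — raw readings → indicator values.
2. **Entropy-weight TOPSIS** — strain × indicator matrix → objective weights
   → relative-closeness ranking.
3. **PCA quadrant screen** — an orthogonal, geometry-based cross-check of
   the ranking.

The modelling surface is a `StrainScreening` model over an
`IndicatorMatrix`; `fit()` returns a `ScreeningResults` carrying the full
decomposition (E<sub>j</sub>/D<sub>j</sub>/W<sub>j</sub> per indicator,
D<sup>±</sup>/C<sub>i</sub>/rank per strain, PCA scores/loadings/variance,
the quadrant-selected strains and an agreement flag). The decomposition is
deterministic — there is no stochastic uncertainty to report; `summary()`
prints the decomposition itself.

## Assay arithmetic

* **Scavenging/chelation percent**: `[1 − (As − Ab)/Ac] × 100` from a
  sample/blank/control absorbance triplet; shared by DPPH, ABTS⁺, ·OH,
  ·O₂⁻ and FICC. The FICC blank/control roles mirror the radical assays;
  replicates are reduced as mean-of-percentages (each replicate is converted
  first, then averaged), not percentage-of-means. Values are **never
  clamped** to [0, 100]: pro-oxidant (negative) or super-stoichiometric
  readings are returned as-is with a `QualityWarning`, because clamping
  hides data errors.
* **Standard curves**: ordinary least squares (scipy) on
  (concentration, absorbance) pairs; r² is the squared Pearson correlation.
  Inversion is `(A − intercept)/slope`; negative concentrations are flagged,
  not clamped. The glucose curve for exopolysaccharide quantification
  (slope 0.0039, intercept 0.0033 absorbance, R² 0.9994, mg L⁻¹) ships as a
  constant. No published FeSO₄ curve exists for FRAP, so analyses must
  supply their own; `SYNTHETIC_FRAP_CURVE` is a labelled synthetic
  placeholder for tests only.
* **Titratable acidity**: `c_NaOH × V_NaOH × 90.08 / V_sample` in g L⁻¹
  lactic-acid equivalent. The titrimetric conversion formula is the standard
  one for a monoprotic acid; the lactic-acid molar mass is fixed at
  90.08 g mol⁻¹.
* **Inhibition zones**: recorded as the full measured diameter including the
  9 mm agar well (matching how such panels report 10–30 mm zones); a
  `net_zones` toggle subtracts the well for halo-only comparisons.
  Zero encodes "no inhibition".

## Entropy weighting and TOPSIS

Formulation (the canonical one; it regenerates the published
D<sub>j</sub> = 1 − E<sub>j</sub> relation and closeness values exactly):

* proportions per column: p<sub>ij</sub> = x<sub>ij</sub>/Σ<sub>i</sub> x<sub>ij</sub>;
* entropy E<sub>j</sub> = −(1/ln n) Σ<sub>i</sub> p<sub>ij</sub> ln p<sub>ij</sub>,
  natural log, with 0·ln 0 := 0 (required for E<sub>j</sub> ∈ [0, 1]);
* utility D<sub>j</sub> = 1 − E<sub>j</sub>; weights W<sub>j</sub> = D<sub>j</sub>/Σ D<sub>j</sub>;
* vector normalization r<sub>ij</sub> = x<sub>ij</sub>/√(Σ<sub>i</sub> x<sub>ij</sub>²),
  weighted matrix v<sub>ij</sub> = W<sub>j</sub> r<sub>ij</sub>;
* ideal best V<sub>j</sub>⁺ = max<sub>i</sub> v<sub>ij</sub> for benefit
  indicators (min for cost), ideal worst mirrored; Euclidean distances
  D<sub>i</sub><sup>±</sup>; closeness C<sub>i</sub> = D⁻/(D⁺ + D⁻).

Both normalizations are ratio-based, so every output is invariant to
positive rescaling of any indicator column — the property that makes the
method usable on percent / mg L⁻¹ / µmol L⁻¹ / mm columns simultaneously.
Correctness is certified against an independently written naive
implementation (explicit loops, written before the vectorized path) to
1e-12 on hundreds of random matrices, plus closure against a published
distance table.

Numerical/degenerate conventions:

* entropy requires non-negativity; `shift_positive` moves any column with a
  minimum ≤ 0 by `−min + ε` (default ε = 1e-6, small against every
  indicator scale in use). ε = 0 leaves zeros, legal but flagged.
* a constant column has E<sub>j</sub> = 1 and weight 0; all columns constant
  is a degenerate-weights error.
* all strains identical → D⁺ = D⁻ = 0; every C<sub>i</sub> is defined as 0.5
  with tied ranks.
* ranking is competition-style (ties share the best rank); report order is
  descending C<sub>i</sub> with lexicographic tie-break — deterministic and
  audit-friendly. Display rounding is 3 decimals; reports always carry full
  precision alongside.
* the published weight column of the reference screen is *not* recovered
  from its published entropies: the entropies are printed at 2 decimals and
  the weight normalization amplifies that rounding by roughly 0.1–0.25
  percentage points (e.g. 17.37% recomputed vs 17.29% printed). Likewise one
  printed closeness value (0.417) disagrees at the last digit with the value
  its own printed distances give (0.41769 → 0.418), because it was rounded
  from unrounded distances. Both are upstream-rounding artifacts, not
  method discrepancies; tests assert exactly where exactness is
  arithmetically attainable and within propagated input-rounding bounds
  where it is not.

No AHP/CRITIC/fuzzy variants and no rank-reversal mitigation are
implemented; TOPSIS with vector normalization is known to permit rank
reversal when alternatives are added or removed, which is out of scope for
a fixed panel.

## PCA quadrant screen

Correlation-matrix PCA: columns are z-scored (sample SD; mandatory given the
mixed scales), the centered standardized matrix is decomposed by SVD, scores
are U·S and loadings the right singular vectors. Signs are fixed
deterministically (each component's largest-|loading| entry is made
positive). Quadrants use the (PC1, PC2) sign convention (+,+)=1, (−,+)=2,
(−,−)=3, (+,−)=4; points exactly on an axis belong to no quadrant.
Selection returns the strains strictly inside the quadrant holding the most
benefit-indicator loadings, ties broken toward quadrant 1. Preconditions:
≥ 3 strains, ≥ 2 indicators, no constant column.

**Known limitation.** The quadrant heuristic is genuinely two-dimensional.
On a panel whose indicators are all strongly positively correlated (e.g. a
strict dominance order), the first component's loading vector approaches the
uniform positive direction, so by orthogonality the second component's
loading entries sum to ≈ 0: the benefit loadings split almost evenly between
the upper and lower half-planes, and a top strain's PC2 coordinate is noise.
In that regime the quadrant selection degenerates to a coin flip on PC2 and
can exclude the overall-best strain; the entropy-TOPSIS ranking, which does
not involve a planar projection, remains exact there. The two selectors
should be read as the ranking (primary) plus a geometric corroboration that
is informative only when the panel has real second-axis structure. The
variance percentages of any particular published biplot depend on that
study's full raw matrix and are not reproduced here; PCA correctness is
certified by conservation and limit properties (variance fractions sum
to 1, collinear data give a single component) and by recovery on panels
with constructed two-factor geometry.

## Synthetic panels

The generator emulates a triplicate-assayed LAB screening panel:

* per-indicator true means drawn uniformly on realistic scales — percent
  indicators in [10, 99], FRAP in [35, 275] µmol L⁻¹, EPS in
  [330, 1100] mg L⁻¹, lactic acid in [31, 77] g L⁻¹, inhibition zones in
  [10, 30] mm (defaults mirror observed screening ranges);
* dominance profiles: `none`; `total-order` (strain k strictly beats
  strain k+1 on every benefit indicator, minimum gap 1% of the indicator
  range, enforced by compressing sorted uniforms into the remaining slack);
  `single-dominant` (first strain beats all others);
* replicates = true mean × (1 + N(0, cv)), default cv 0.02 and 3 replicates
  (typical of triplicate spectrophotometric assays), truncated at zero
  rather than redrawn (bias negligible at cv 0.02). Multiplicative noise is
  used because replicate SDs in such panels scale roughly with the mean
  across indicators of very different magnitude;
* fully reproducible from an integer seed (bit-identical records).

What the generator does **not** emulate: correlation structure between
indicators beyond the imposed dominance (real antioxidant indicators
co-vary through shared chemistry), heteroscedasticity beyond a constant CV,
plate/batch effects, or detection limits. Recovery results on synthetic
panels therefore demonstrate the pipeline's arithmetic and its behavior
under clean dominance, not robustness to real-data pathologies.

## Problem sizes

Default test and acceptance runs use panels of 7 strains × 10 indicators
(the screening geometry the generator models), random matrices of 3–6
strains × 2–5 indicators for oracle equivalence (200 draws), and 50 seeds
for recovery experiments — sizes chosen to exercise every code path with
immediate feedback.
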