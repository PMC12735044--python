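"""PCA quadrant screening.

Cross-check for the entropy-TOPSIS ranking: strains (scores) and indicators
(loadings) are projected onto the first two principal components of the
z-score-standardized matrix, and the strains co-located with the bulk of the
benefit-indicator loadings are selected. Standardization is mandatory because
panel indicators span percentages, mg L⁻¹ and µmol L⁻¹ scales; it makes the
projection invariant to positive rescaling of any column (correlation-matrix
PCA).

Quadrants follow the sign convention (PC1, PC2): (+,+) = 1, (−,+) = 2,
(−,−) = 3, (+,−) = 4. Points lying exactly on an axis belong to no quadrant
(strict inequalities — deterministic strictness beats floating-point
ambiguity). Component signs are fixed deterministically: each component's
largest-|loading| entry is made positive, so results do not depend on the
SVD backend's sign choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import IndicatorMatrix

__all__ = ["PcaResult", "pca_project", "quadrant_select", "quadrant_of_point"]


def quadrant_of_point(x: float, y: float) -> "int | None":
    """Quadrant 1–4 of a planar point; None on an axis."""
    if x > 0 and y > 0:
        return 1
    if x < 0 and y > 0:
        return 2
    if x < 0 and y < 0:
        return 3
    if x > 0 and y < 0:
        return 4
    return None


@dataclass(frozen=True)
class PcaResult:
    """Projection of a panel onto its principal components.

    ``strain_scores`` and ``indicator_loadings`` hold all components
    (columns PC1, PC2, ...); quadrant logic uses the first two.
    ``variance_explained`` covers every component and sums to 1.
    """

    strain_scores: pd.DataFrame
    indicator_loadings: pd.DataFrame
    variance_explained: np.ndarray
    benefit_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def quadrant_of(self, label) -> "int | None":
        """Quadrant (1–4, or None on an axis) of a strain or indicator."""
        for table in (self.strain_scores, self.indicator_loadings):
            if label in table.index:
                x, y = table.loc[label, ["PC1", "PC2"]]
                return quadrant_of_point(float(x), float(y))
        raise ValidationError(f"unknown strain or indicator {label!r}")


def pca_project(m: IndicatorMatrix) -> PcaResult:
    """Correlation-matrix PCA of the panel via SVD.

    Columns are z-scored (sample SD); the centered standardized matrix is
    decomposed by singular values, scores are ``U·S`` and loadings the right
    singular vectors. Requires >= 3 strains, >= 2 indicators, and no constant
    column (z-scoring would divide by zero).
    """
    X = m.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("PCA needs >= 3 strains")
    if p < 2:
        raise ValidationError("PCA needs >= 2 indicators")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [m.indicators[j] for j in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant indicator column(s), cannot standardize: {bad}")
    Z = (X - X.mean(axis=0)) / sd

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic orientation: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    total = (S**2).sum()
    var = S**2 / total if total > 0 else np.zeros_like(S)
    comps = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=m.values.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=m.values.columns, columns=comps)
    return PcaResult(scores, loadings, var, benefit_mask=m.benefit_mask.copy())


def quadrant_select(p: PcaResult) -> list:
    """Strains co-located with the benefit-indicator loadings.

    The target quadrant is the one holding the most benefit-indicator
    loadings (axis-sitting loadings count for none); ties are broken toward
    quadrant 1, then the lowest quadrant number. Returned strains lie
    strictly inside that quadrant, in panel order.
    """
    benefit = (
        p.benefit_mask
        if p.benefit_mask is not None
        else np.ones(len(p.indicator_loadings), dtype=bool)
    )
    counts = {q: 0 for q in (1, 2, 3, 4)}
    for (label, row), is_benefit in zip(p.indicator_loadings.iterrows(), benefit):
        if not is_benefit:
            continue
        q = quadrant_of_point(float(row["PC1"]), float(row["PC2"]))
        if q is not None:
            counts[q] += 1
    best = max(counts.values())
    # tie-break toward quadrant 1, then ascending quadrant number
    target = min(q for q, c in counts.items() if c == best)

    selected = []
    for label, row in p.strain_scores.iterrows():
        if quadrant_of_point(float(row["PC1"]), float(row["PC2"])) == target:
            selected.append(label)
    return selected


def plot_biplot(p: PcaResult, path, loading_scale: "float | None" = None) -> None:
    """Render a PC1/PC2 biplot (strains as points, loadings as arrows) to an
    SVG/PNG file. Coordinates come straight from the result tables, so the
    figure is a pure rendering concern and is never asserted on in tests."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if loading_scale is None:
        span = np.abs(p.strain_scores[["PC1", "PC2"]].to_numpy()).max()
        lmax = np.abs(p.indicator_loadings[["PC1", "PC2"]].to_numpy()).max()
        loading_scale = 0.9 * span / lmax if lmax > 0 else 1.0

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.scatter(p.strain_scores["PC1"], p.strain_scores["PC2"], color="tab:blue")
    for label, row in p.strain_scores.iterrows():
        ax.annotate(str(label), (row["PC1"], row["PC2"]), fontsize=9,
                    xytext=(3, 3), textcoords="offset points")
    for label, row in p.indicator_loadings.iterrows():
        ax.annotate(
            "", xy=(row["PC1"] * loading_scale, row["PC2"] * loading_scale),
            xytext=(0, 0), arrowprops=dict(arrowstyle="->", color="tab:red", lw=1),
        )
        ax.annotate(str(label), (row["PC1"] * loading_scale, row["PC2"] * loading_scale),
                    color="tab:red", fontsize=8)
    ax.set_xlabel(f"PC1 ({p.variance_explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({p.variance_explained[1] * 100:.1f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
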