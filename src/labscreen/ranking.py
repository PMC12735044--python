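"""Entropy weighting and TOPSIS relative-closeness ranking (EW-TOPSIS).

Shannon-entropy weights measure how much each indicator discriminates among
strains: with column proportions ``p_ij = x_ij / Σ_i x_ij``, the entropy

    E_j = −(1/ln n) Σ_i p_ij ln p_ij      (0·ln 0 := 0)

lies in [0, 1]; a constant column has maximal entropy (E_j = 1, no
information). The information utility D_j = 1 − E_j is normalized into
weights W_j = D_j / Σ_j D_j.

TOPSIS then ranks strains by closeness to an ideal: the matrix is
vector-normalized per column (r_ij = x_ij / sqrt(Σ_i x_ij²)), weighted
(v_ij = W_j r_ij), and each strain's Euclidean distances D⁺/D⁻ to the
ideal-best/ideal-worst points yield the relative closeness
C_i = D⁻/(D⁺ + D⁻) ∈ [0, 1]; higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateError, ValidationError
from .matrix import IndicatorMatrix

__all__ = [
    "EntropyWeights",
    "TopsisScores",
    "entropy_weights",
    "topsis_scores",
    "closeness",
    "scores_from_distances",
    "rank_strains",
]


@dataclass(frozen=True)
class EntropyWeights:
    """Per-indicator entropy E_j, utility D_j = 1 − E_j, and weight W_j.

    Invariants: all E_j ∈ [0, 1], D_j = 1 − E_j exactly, Σ W_j = 1.
    """

    entropy: pd.Series  # E_j
    utility: pd.Series  # D_j
    weight: pd.Series  # W_j

    @property
    def indicators(self) -> list:
        return list(self.weight.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Ej": self.entropy, "Dj": self.utility, "Wj": self.weight}
        )


@dataclass(frozen=True)
class TopsisScores:
    """Per-strain distances to ideal-best (D⁺) / ideal-worst (D⁻), relative
    closeness C_i, and competition rank (1 = best, ties share the best rank).
    """

    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series
    rank: pd.Series

    @property
    def strains(self) -> list:
        return list(self.closeness.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "D+": self.d_plus,
                "D-": self.d_minus,
                "Ci": self.closeness,
                "rank": self.rank,
            }
        )


def entropy_weights(m: IndicatorMatrix) -> EntropyWeights:
    """Objective indicator weights from Shannon entropy of column proportions.

    Requires a non-negative matrix (apply :func:`~labscreen.matrix.shift_positive`
    first if needed) and >= 2 strains. Zeros are tolerated under the
    0·ln 0 := 0 convention. Raises :class:`DegenerateError` if every column is
    constant (all utilities zero — no indicator discriminates).
    """
    m.require_rankable()
    x = m.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError(
            "entropy weighting needs a non-negative matrix; apply shift_positive"
        )
    n = x.shape[0]
    colsum = x.sum(axis=0)
    if (colsum == 0).any():
        bad = [m.indicators[j] for j in np.flatnonzero(colsum == 0)]
        raise DegenerateError(f"all-zero indicator columns: {bad}")
    p = x / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ej = -plogp.sum(axis=0) / np.log(n)
    ej = np.clip(ej, 0.0, 1.0)
    dj = 1.0 - ej
    total = dj.sum()
    if total == 0:
        raise DegenerateError(
            "every indicator column is constant: entropy weights undefined"
        )
    wj = dj / total
    idx = m.values.columns
    return EntropyWeights(
        pd.Series(ej, index=idx, name="Ej"),
        pd.Series(dj, index=idx, name="Dj"),
        pd.Series(wj, index=idx, name="Wj"),
    )


def closeness(d_plus: float, d_minus: float) -> float:
    """Relative closeness C = D⁻/(D⁺ + D⁻).

    Both distances must be non-negative; both zero is degenerate (the strain
    coincides with best and worst ideals simultaneously — only possible when
    all strains are identical, handled in :func:`topsis_scores`).
    """
    if d_plus < 0 or d_minus < 0:
        raise ValidationError("distances must be >= 0")
    total = d_plus + d_minus
    if total == 0:
        raise DegenerateError("D+ + D- = 0: closeness undefined")
    return d_minus / total


def scores_from_distances(
    d_plus: "pd.Series", d_minus: "pd.Series"
) -> TopsisScores:
    """Build :class:`TopsisScores` from externally supplied D⁺/D⁻ pairs
    (e.g. a published distance table), recomputing closeness and ranks."""
    d_plus = pd.Series(d_plus, dtype=float)
    d_minus = pd.Series(d_minus, dtype=float).reindex(d_plus.index)
    if d_minus.isna().any():
        raise ValidationError("d_plus and d_minus must share strain labels")
    ci = pd.Series(
        [closeness(p, m) for p, m in zip(d_plus, d_minus)],
        index=d_plus.index,
        name="Ci",
    )
    rank = ci.rank(method="min", ascending=False).astype(int).rename("rank")
    return TopsisScores(d_plus.rename("D+"), d_minus.rename("D-"), ci, rank)


def topsis_scores(
    m: IndicatorMatrix, weights: "EntropyWeights | pd.Series | np.ndarray"
) -> TopsisScores:
    """Weighted-normalized TOPSIS scores against ideal-best/worst points.

    Benefit indicators take their ideal-best at the column maximum, cost
    indicators at the minimum (mirrored for ideal-worst). When all strains
    are identical both distances vanish; by convention every C_i is then 0.5
    with tied ranks.
    """
    m.require_rankable()
    x = m.values.to_numpy(dtype=float)
    if isinstance(weights, EntropyWeights):
        w = weights.weight.reindex(m.values.columns).to_numpy(dtype=float)
    else:
        w = np.asarray(pd.Series(weights).reindex(m.values.columns).to_numpy()
                       if isinstance(weights, pd.Series) else weights, dtype=float)
    if w.shape != (x.shape[1],):
        raise ValidationError("weight vector length differs from indicator count")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValidationError("weights must be finite and >= 0")

    norms = np.sqrt((x**2).sum(axis=0))
    if (norms == 0).any():
        bad = [m.indicators[j] for j in np.flatnonzero(norms == 0)]
        raise DegenerateError(f"all-zero columns cannot be vector-normalized: {bad}")
    v = w * (x / norms)

    benefit = m.benefit_mask
    v_best = np.where(benefit, v.max(axis=0), v.min(axis=0))
    v_worst = np.where(benefit, v.min(axis=0), v.max(axis=0))
    d_plus = np.sqrt(((v - v_best) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - v_worst) ** 2).sum(axis=1))

    total = d_plus + d_minus
    ci = np.where(total > 0, d_minus / np.where(total > 0, total, 1.0), 0.5)

    idx = m.values.index
    ci_s = pd.Series(ci, index=idx, name="Ci")
    rank = ci_s.rank(method="min", ascending=False).astype(int)
    return TopsisScores(
        pd.Series(d_plus, index=idx, name="D+"),
        pd.Series(d_minus, index=idx, name="D-"),
        ci_s,
        rank.rename("rank"),
    )


def rank_strains(scores: TopsisScores, digits: int = 3) -> pd.DataFrame:
    """Ordered ranking report: descending C_i, ties share the best
    (competition) rank and are listed lexicographically by strain label.

    Returns full-precision columns plus display-rounded ``*_rounded``
    companions (default 3 decimals).
    """
    df = scores.to_frame().copy()
    df.index.name = "strain"
    df = df.reset_index()
    df["_label"] = df["strain"].astype(str)
    df = df.sort_values(["Ci", "_label"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns="_label").reset_index(drop=True)
    for col in ("D+", "D-", "Ci"):
        df[f"{col}_rounded"] = df[col].round(digits)
    return df
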