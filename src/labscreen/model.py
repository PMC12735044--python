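"""Model/Results interface over the screening pipeline.

:class:`StrainScreening` is constructed from an :class:`IndicatorMatrix`
(or a DataFrame); ``fit()`` runs entropy weighting, TOPSIS and the PCA
quadrant screen and returns a :class:`ScreeningResults` whose ``summary()``
prints the full decomposition — per-indicator Ej/Dj/Wj, per-strain D±/Ci/rank,
variance explained, the PCA-selected strains, and whether the two selectors
agree on the top strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .matrix import IndicatorMatrix, IndicatorSpec, shift_positive
from .pca import PcaResult, pca_project, quadrant_select
from .ranking import (
    EntropyWeights,
    TopsisScores,
    entropy_weights,
    rank_strains,
    topsis_scores,
)

__all__ = ["StrainScreening", "ScreeningResults"]


class StrainScreening:
    """Multi-criteria strain screening model.

    Parameters
    ----------
    matrix
        The strain × indicator decision matrix (means; optional SDs).
    epsilon
        Shift applied to non-positive columns before entropy weighting
        (must be > 0 at fit time).

    Examples
    --------
    >>> from labscreen.datasets import table1_fixture
    >>> res = StrainScreening(table1_fixture()).fit()
    >>> res.ranking["strain"].iloc[0]
    'Lac. lactis W3C'
    """

    def __init__(self, matrix: IndicatorMatrix, epsilon: float = 1e-6):
        if epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        matrix.require_rankable()
        self.matrix = matrix
        self.epsilon = epsilon

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        orientations: "dict[str, str] | None" = None,
        epsilon: float = 1e-6,
    ) -> "StrainScreening":
        """Build from a strains-indexed DataFrame of indicator means."""
        orientations = orientations or {}
        specs = [IndicatorSpec(str(c), orientations.get(str(c), "benefit"))
                 for c in df.columns]
        return cls(IndicatorMatrix(df, specs), epsilon=epsilon)

    def fit(
        self,
        weights: "pd.Series | None" = None,
        run_pca: bool = True,
        digits: int = 3,
    ) -> "ScreeningResults":
        """Run the pipeline.

        ``weights`` overrides entropy weighting with user-supplied weights
        (they are normalized to sum to 1). PCA is skipped when the matrix
        is too small for it only if ``run_pca`` is False; otherwise its
        preconditions are enforced.
        """
        positive = shift_positive(self.matrix, self.epsilon)
        if weights is None:
            w = entropy_weights(positive)
        else:
            wv = pd.Series(weights, dtype=float).reindex(positive.values.columns)
            if wv.isna().any():
                raise ValidationError(
                    f"user weights missing indicators: {list(wv.index[wv.isna()])}"
                )
            if (wv < 0).any() or wv.sum() <= 0:
                raise ValidationError("user weights must be >= 0 with a positive sum")
            wv = wv / wv.sum()
            w = EntropyWeights(
                entropy=pd.Series(np.nan, index=wv.index, name="Ej"),
                utility=pd.Series(np.nan, index=wv.index, name="Dj"),
                weight=wv.rename("Wj"),
            )
        scores = topsis_scores(positive, w)
        ranking = rank_strains(scores, digits=digits)

        pca_res = pca_project(self.matrix) if run_pca else None
        selected = quadrant_select(pca_res) if pca_res is not None else []
        top = ranking["strain"].iloc[0]
        agreement = (top in selected) if pca_res is not None else None
        return ScreeningResults(
            model=self,
            weights=w,
            scores=scores,
            ranking=ranking,
            pca=pca_res,
            pca_selected=selected,
            agreement=agreement,
            digits=digits,
        )


@dataclass
class ScreeningResults:
    """Fitted screening decomposition.

    Attributes
    ----------
    weights : EntropyWeights
        Per-indicator entropy, utility and weight (Ej/Dj are NaN when
        user-supplied weights were used).
    scores : TopsisScores
        Per-strain D⁺/D⁻/Ci and competition rank.
    ranking : DataFrame
        Report-ordered table with full-precision and display-rounded columns.
    pca : PcaResult or None
    pca_selected : list
        Strains in the benefit-loading quadrant.
    agreement : bool or None
        Whether the TOPSIS top strain is among the PCA-selected strains.
    """

    model: StrainScreening
    weights: EntropyWeights
    scores: TopsisScores
    ranking: pd.DataFrame
    pca: "PcaResult | None"
    pca_selected: list
    agreement: "bool | None"
    digits: int = 3

    @property
    def best_strain(self):
        return self.ranking["strain"].iloc[0]

    def summary(self) -> str:
        d = self.digits
        lines = [
            "Strain screening (entropy-weight TOPSIS + PCA quadrant check)",
            "=" * 62,
            f"strains: {self.model.matrix.shape[0]}   "
            f"indicators: {self.model.matrix.shape[1]}   "
            f"labscreen {__version__}",
            "",
            "Indicator weights",
            "-" * 40,
            self.weights.to_frame().round(4).to_string(),
            "",
            "TOPSIS ranking (Ci = D-/(D+ + D-), higher is better)",
            "-" * 52,
            self.ranking[["strain", "D+", "D-", "Ci", "rank"]]
            .assign(**{c: self.ranking[c].round(d) for c in ("D+", "D-", "Ci")})
            .to_string(index=False),
        ]
        if self.pca is not None:
            ve = self.pca.variance_explained
            lines += [
                "",
                f"PCA: PC1 {ve[0] * 100:.1f}%, PC2 {ve[1] * 100:.1f}% "
                f"(first two components {sum(ve[:2]) * 100:.1f}%)",
                f"quadrant-selected strains: "
                f"{', '.join(map(str, self.pca_selected)) or '(none)'}",
                f"TOPSIS top strain in PCA selection: {self.agreement}",
            ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable report with full-precision and rounded fields."""
        d = self.digits
        report = {
            "tool": {"name": "labscreen", "version": __version__},
            "n_strains": int(self.model.matrix.shape[0]),
            "n_indicators": int(self.model.matrix.shape[1]),
            "weights": {
                str(j): {
                    "Ej": _f(self.weights.entropy[j]),
                    "Dj": _f(self.weights.utility[j]),
                    "Wj": _f(self.weights.weight[j]),
                }
                for j in self.weights.indicators
            },
            "scores": {
                str(s): {
                    "d_plus": _f(self.scores.d_plus[s]),
                    "d_minus": _f(self.scores.d_minus[s]),
                    "closeness": _f(self.scores.closeness[s]),
                    "closeness_rounded": round(float(self.scores.closeness[s]), d),
                    "rank": int(self.scores.rank[s]),
                }
                for s in self.scores.strains
            },
            "ranking": [str(s) for s in self.ranking["strain"]],
            "best_strain": str(self.best_strain),
        }
        if self.pca is not None:
            report["pca"] = {
                "variance_explained": [_f(v) for v in self.pca.variance_explained],
                "strain_scores": {
                    str(s): [_f(v) for v in row[["PC1", "PC2"]]]
                    for s, row in self.pca.strain_scores.iterrows()
                },
                "indicator_loadings": {
                    str(i): [_f(v) for v in row[["PC1", "PC2"]]]
                    for i, row in self.pca.indicator_loadings.iterrows()
                },
                "selected": [str(s) for s in self.pca_selected],
                "agreement_with_topsis": self.agreement,
            }
        return report


def _f(v) -> "float | None":
    v = float(v)
    return None if np.isnan(v) else v
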