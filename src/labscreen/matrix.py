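"""The strain × indicator decision matrix.

A screening panel is a small dense matrix: rows are candidate strains, columns
are oriented indicators (all ten of the study's ranking indicators are
benefit-type — higher is better — but cost orientation is supported). The
matrix carries replicate means, optional SDs, and per-indicator metadata, and
is the single input type for entropy weighting, TOPSIS and PCA.

Missing cells are a hard error at assembly: with a handful of strains,
silent imputation would be worse than failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QualityWarning, ValidationError

__all__ = [
    "IndicatorSpec",
    "IndicatorMatrix",
    "build_matrix",
    "column_summary",
    "shift_positive",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator column: name, optimization direction, unit."""

    name: str
    orientation: str = "benefit"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("benefit", "cost"):
            raise ValidationError(
                f"indicator {self.name!r}: orientation must be 'benefit' or "
                f"'cost', got {self.orientation!r}"
            )


class IndicatorMatrix:
    """Strains × oriented indicators with optional replicate SDs.

    Parameters
    ----------
    values
        DataFrame indexed by strain label, one column per indicator.
    specs
        Ordered indicator specs; defaults to all-benefit, unitless.
    sds
        Optional DataFrame of replicate standard deviations, same shape.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        specs: "list[IndicatorSpec] | None" = None,
        sds: "pd.DataFrame | None" = None,
    ):
        values = values.astype(float)
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError("matrix needs >= 1 strain and >= 1 indicator")
        if not np.isfinite(values.to_numpy()).all():
            bad = values.columns[~np.isfinite(values.to_numpy()).all(axis=0)]
            raise ValidationError(f"non-finite values in columns {list(bad)}")
        if values.index.duplicated().any():
            raise ValidationError("duplicate strain labels")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate indicator names")
        if specs is None:
            specs = [IndicatorSpec(str(c)) for c in values.columns]
        if [s.name for s in specs] != list(values.columns):
            raise ValidationError("indicator specs do not match matrix columns")
        if sds is not None:
            sds = sds.astype(float)
            if sds.shape != values.shape:
                raise ValidationError("sds shape differs from values shape")
            sds = sds.set_axis(values.index, axis=0).set_axis(values.columns, axis=1)
        values.index.name = "strain"
        values.columns.name = None
        if sds is not None:
            sds.index.name = "strain"
            sds.columns.name = None
        self.values = values
        self.specs = list(specs)
        self.sds = sds

    # -- introspection ------------------------------------------------------

    @property
    def strains(self) -> list:
        return list(self.values.index)

    @property
    def indicators(self) -> list:
        return list(self.values.columns)

    @property
    def benefit_mask(self) -> np.ndarray:
        """Boolean array, True where the indicator is benefit-oriented."""
        return np.array([s.orientation == "benefit" for s in self.specs])

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def spec_of(self, indicator: str) -> IndicatorSpec:
        for s in self.specs:
            if s.name == indicator:
                return s
        raise ValidationError(f"unknown indicator {indicator!r}")

    def require_rankable(self) -> None:
        """Gate applied before weighting/ranking/PCA: >= 2 strains."""
        if self.shape[0] < 2:
            raise ValidationError("ranking requires >= 2 strains")

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(
        cls, path, orientations: "dict[str, str] | None" = None
    ) -> "IndicatorMatrix":
        """Read the matrix dialect: first column ``strain``, one column per
        indicator, optional paired ``<indicator>_sd`` columns."""
        df = pd.read_csv(path)
        if df.columns[0] != "strain":
            raise ValidationError("matrix CSV must start with a 'strain' column")
        df = df.set_index("strain")
        sd_cols = [c for c in df.columns if c.endswith("_sd")]
        val_cols = [c for c in df.columns if not c.endswith("_sd")]
        values = df[val_cols]
        sds = None
        if sd_cols:
            sds = pd.DataFrame(
                {c[:-3]: df[c] for c in sd_cols}, index=df.index
            ).reindex(columns=val_cols, fill_value=0.0)
        orientations = orientations or {}
        specs = [
            IndicatorSpec(c, orientations.get(c, "benefit")) for c in val_cols
        ]
        return cls(values, specs, sds)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        if self.sds is not None:
            for c in self.values.columns:
                out[f"{c}_sd"] = self.sds[c]
        out.index.name = "strain"
        out.to_csv(path)

    def with_values(self, values: pd.DataFrame) -> "IndicatorMatrix":
        """Same specs/SDs, new cell values (used by column shifts)."""
        return IndicatorMatrix(values, self.specs, self.sds)

    def __repr__(self) -> str:
        return (
            f"IndicatorMatrix({self.shape[0]} strains x {self.shape[1]} "
            f"indicators: {', '.join(map(str, self.indicators))})"
        )


def build_matrix(
    records: pd.DataFrame,
    strain_order: "list | None" = None,
    indicator_order: "list | None" = None,
    orientations: "dict[str, str] | None" = None,
) -> IndicatorMatrix:
    """Assemble an :class:`IndicatorMatrix` from tidy per-strain rows.

    ``records`` needs columns ``strain, indicator, mean`` (optional ``sd``).
    Every (strain, indicator) pair must appear exactly once. Row order is the
    declared ``strain_order`` (default: first appearance in the input) and
    likewise for columns, so the result is invariant to record shuffling
    whenever the orders are declared.
    """
    required = {"strain", "indicator", "mean"}
    if not required <= set(records.columns):
        raise ValidationError(
            f"records missing columns: {sorted(required - set(records.columns))}"
        )
    if records.empty:
        raise ValidationError("empty record set")
    if strain_order is None:
        strain_order = list(dict.fromkeys(records["strain"]))
    if indicator_order is None:
        indicator_order = list(dict.fromkeys(records["indicator"]))

    dup = records.duplicated(subset=["strain", "indicator"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, records.loc[dup, ["strain", "indicator"]].values)))
        raise ValidationError(f"duplicate (strain, indicator) cells: {pairs}")

    values = records.pivot(index="strain", columns="indicator", values="mean")
    try:
        values = values.loc[strain_order, indicator_order]
    except KeyError as e:
        raise ValidationError(f"declared order references absent label: {e}") from e
    if values.isna().any().any():
        missing = [
            (s, i)
            for s in values.index
            for i in values.columns
            if pd.isna(values.at[s, i])
        ]
        raise ValidationError(f"missing (strain, indicator) cells: {missing}")

    sds = None
    if "sd" in records.columns:
        sds = records.pivot(index="strain", columns="indicator", values="sd").loc[
            strain_order, indicator_order
        ].fillna(0.0)
    orientations = orientations or {}
    specs = [IndicatorSpec(i, orientations.get(i, "benefit")) for i in indicator_order]
    return IndicatorMatrix(values, specs, sds)


def column_summary(m: IndicatorMatrix, indicator: str, stat: str) -> float:
    """Exact extremum or range over one indicator's column of means."""
    if indicator not in m.values.columns:
        raise ValidationError(f"unknown indicator {indicator!r}")
    col = m.values[indicator]
    if stat == "min":
        return float(col.min())
    if stat == "max":
        return float(col.max())
    if stat == "range":
        return float(col.max() - col.min())
    raise ValidationError(f"unknown stat {stat!r}; expected min|max|range")


def shift_positive(m: IndicatorMatrix, epsilon: float = 1e-6) -> IndicatorMatrix:
    """Shift any column containing values <= 0 by ``-min + epsilon``.

    Entropy weighting needs strictly positive proportions; columns that are
    already positive are returned bit-identical. With ``epsilon == 0`` a zero
    minimum survives the shift — legal under the 0·ln 0 := 0 convention but
    flagged with a :class:`QualityWarning` as entropy-unsafe.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    values = m.values.copy()
    shifted_zero = False
    for c in values.columns:
        mn = values[c].min()
        if mn <= 0:
            values[c] = values[c] + (-mn + epsilon)
            if epsilon == 0:
                shifted_zero = True
    if shifted_zero:
        warnings.warn(
            "shift_positive with epsilon=0 leaves zeros in the matrix "
            "(entropy-unsafe: a zero proportion contributes 0 by convention)",
            QualityWarning,
            stacklevel=2,
        )
    return m.with_values(values)
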