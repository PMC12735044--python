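"""Reduction of raw bioassay readings to panel indicators.

The screening panel aggregates six antioxidant readouts (DPPH, ABTS+, ·OH and
·O2− radical scavenging, ferrous-ion chelating capacity, FRAP), metabolite
production (exopolysaccharide via a glucose standard curve, titratable acidity
via NaOH titration) and agar-well inhibition zones. Every scavenging/chelation
assay shares one arithmetic: a sample/blank/control absorbance triplet
(As, Ab, Ac) reduced to an inhibition percentage ``[1 − (As − Ab)/Ac] × 100``.

Percentages and concentrations are never clamped: pro-oxidant readings
(negative percent) and below-intercept absorbances (negative concentration)
are returned as-is with a :class:`~labscreen.errors.QualityWarning`, because
clamping would hide data-entry or chemistry errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, QualityWarning, ValidationError

__all__ = [
    "SCAVENGING_ASSAYS",
    "LACTIC_ACID_MOLAR_MASS",
    "DEFAULT_WELL_DIAMETER_MM",
    "AbsorbanceTriplet",
    "LinearStandardCurve",
    "TitrationRecord",
    "ZoneMeasurement",
    "scavenging_percent",
    "fit_standard_curve",
    "invert_standard_curve",
    "frap_equivalent",
    "titratable_acidity",
    "net_zone_diameter",
    "quantify_records",
]

#: Assays quantified by the shared inhibition-percentage formula.
SCAVENGING_ASSAYS = frozenset({"DPPH", "ABTS", "OH", "O2", "FICC"})

#: Molar mass of lactic acid, g mol^-1 (titration results are expressed as
#: lactic acid equivalent).
LACTIC_ACID_MOLAR_MASS = 90.08

#: Agar wells are punched at 9 mm; reported zone diameters include the well.
DEFAULT_WELL_DIAMETER_MM = 9.0


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """One scavenging-assay reading set.

    Parameters
    ----------
    sample_abs, blank_abs, control_abs
        Absorbance of the sample group (As), blank group (Ab) and control
        group (Ac). Ac must be strictly positive.
    assay_kind
        One of ``DPPH | ABTS | OH | O2 | FICC``.
    wavelength
        Detection wavelength in nm (informational only).
    """

    sample_abs: float
    blank_abs: float
    control_abs: float
    assay_kind: str = "DPPH"
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.assay_kind not in SCAVENGING_ASSAYS:
            raise ValidationError(
                f"unknown scavenging assay {self.assay_kind!r}; "
                f"expected one of {sorted(SCAVENGING_ASSAYS)}"
            )
        for name in ("sample_abs", "blank_abs", "control_abs"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.assay_kind}: {name}={v!r} must be finite and >= 0"
                )


@dataclass(frozen=True)
class LinearStandardCurve:
    """Linear calibration ``absorbance = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    concentration_unit: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DegenerateError("standard curve has zero slope")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError(f"r_squared={self.r_squared} outside [0, 1]")

    def forward(self, concentration: float) -> float:
        """Predicted absorbance at a concentration."""
        return self.slope * concentration + self.intercept


#: Glucose standard curve for exopolysaccharide quantification (phenol-
#: sulfuric acid method, 490 nm): y = 0.0039 x + 0.0033, R^2 = 0.9994.
EPS_GLUCOSE_CURVE = LinearStandardCurve(0.0039, 0.0033, 0.9994, "mg L^-1")

#: Synthetic FeSO4 calibration used only as a documented test placeholder;
#: real FRAP analyses must supply the instrument's own curve.
SYNTHETIC_FRAP_CURVE = LinearStandardCurve(0.002, 0.05, 1.0, "umol L^-1")


@dataclass(frozen=True)
class TitrationRecord:
    """One NaOH titration of culture supernatant."""

    naoh_concentration: float  # mol L^-1
    naoh_volume: float  # mL
    sample_volume: float  # mL

    def __post_init__(self) -> None:
        if self.naoh_concentration <= 0:
            raise ValidationError("naoh_concentration must be > 0")
        if self.naoh_volume < 0:
            raise ValidationError("naoh_volume must be >= 0")
        if self.sample_volume <= 0:
            raise DegenerateError("sample_volume must be > 0")


@dataclass(frozen=True)
class ZoneMeasurement:
    """Inhibition-zone diameter from an agar well diffusion assay.

    ``zone_diameter`` is the full measured diameter including the well;
    0 encodes no inhibition.
    """

    pathogen: str
    zone_diameter: float
    well_diameter: float = DEFAULT_WELL_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.zone_diameter != 0 and self.zone_diameter < self.well_diameter:
            raise ValidationError(
                f"zone_diameter {self.zone_diameter} mm is below the "
                f"{self.well_diameter} mm well but not zero"
            )


def scavenging_percent(t: AbsorbanceTriplet) -> float:
    """Inhibition percentage ``[1 − (As − Ab)/Ac] × 100``.

    May be negative (pro-oxidant reading) or exceed 100; such values are
    returned unclamped with a :class:`QualityWarning`.
    """
    if t.control_abs == 0:
        raise DegenerateError(
            f"{t.assay_kind}: control absorbance is zero, percentage undefined"
        )
    pct = (1.0 - (t.sample_abs - t.blank_abs) / t.control_abs) * 100.0
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"{t.assay_kind}: scavenging percentage {pct:.2f} outside [0, 100]",
            QualityWarning,
            stacklevel=2,
        )
    return pct


def fit_standard_curve(
    points: "list[tuple[float, float]] | np.ndarray",
    concentration_unit: str = "",
) -> LinearStandardCurve:
    """Ordinary least-squares calibration from (concentration, absorbance) pairs.

    Requires at least two distinct concentrations; r² is the squared Pearson
    correlation (defined as 1.0 for a perfect two-point fit).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need >= 2 (concentration, absorbance) pairs")
    conc, absb = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise DegenerateError("all standard concentrations identical")
    res = stats.linregress(conc, absb)
    # rvalue is nan when absorbances are constant (horizontal line): r^2 := 0
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue) ** 2
    # guard against fp overshoot on collinear points
    r2 = min(r2, 1.0)
    return LinearStandardCurve(float(res.slope), float(res.intercept), r2, concentration_unit)


def invert_standard_curve(c: LinearStandardCurve, absorbance: float) -> float:
    """Concentration ``(absorbance − intercept)/slope``.

    Negative concentrations are returned with a :class:`QualityWarning`,
    never clamped.
    """
    conc = (absorbance - c.intercept) / c.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance} below curve intercept: negative "
            f"concentration {conc:.4g} {c.concentration_unit}".rstrip(),
            QualityWarning,
            stacklevel=2,
        )
    return conc


def frap_equivalent(absorbance: float, curve: LinearStandardCurve) -> float:
    """Ferric-reducing power as FeSO4 equivalent (µmol L⁻¹) from a FeSO4
    calibration curve. Same contract as :func:`invert_standard_curve`."""
    return invert_standard_curve(curve, absorbance)


def titratable_acidity(t: TitrationRecord) -> float:
    """Titratable acidity in g L⁻¹ lactic acid equivalent.

    mmol NaOH consumed equals mmol lactic acid neutralized (monoprotic);
    ``c_NaOH [mol/L] × V_NaOH [mL] = mmol``, × 90.08 mg/mmol, ÷ sample
    volume [mL] gives mg/mL ≡ g/L.
    """
    return t.naoh_concentration * t.naoh_volume * LACTIC_ACID_MOLAR_MASS / t.sample_volume


def net_zone_diameter(z: ZoneMeasurement) -> float:
    """Halo net of the well (diameter − well), 0 for no inhibition."""
    if z.zone_diameter == 0:
        return 0.0
    return z.zone_diameter - z.well_diameter


# ---------------------------------------------------------------------------
# long-format record reduction


def _triplet_rows(group: pd.DataFrame, assay: str, strain: str) -> AbsorbanceTriplet:
    by_role = {}
    for role in ("sample", "blank", "control"):
        vals = group.loc[group["role"] == role, "value"]
        if vals.empty:
            raise ValidationError(
                f"({strain}, {assay}): missing {role!r} absorbance row"
            )
        by_role[role] = float(vals.mean())
    return AbsorbanceTriplet(
        by_role["sample"], by_role["blank"], by_role["control"], assay_kind=assay
    )


def quantify_records(
    records: pd.DataFrame,
    curves: "dict[str, LinearStandardCurve] | None" = None,
    titration: "dict[str, float] | None" = None,
    net_zones: bool = False,
) -> pd.DataFrame:
    """Reduce a long-format replicate table to per-strain indicator means ± SD.

    Parameters
    ----------
    records
        Columns ``strain, assay, replicate, role, value`` (and optionally
        ``concentration`` on ``role == "standard"`` rows for curve fitting).
        Scavenging assays (DPPH/ABTS/OH/O2/FICC) need sample, blank and
        control roles per replicate; the control may be shared across strains
        (rows with an empty strain field). ``EPS`` and ``FRAP`` rows carry
        sample absorbances; ``ACID`` rows carry NaOH volumes (mL); any other
        assay name is treated as an inhibition-zone diameter in mm.
    curves
        Calibration per concentration assay, e.g. ``{"EPS": ..., "FRAP": ...}``.
        If absent, a curve is fitted from that assay's ``standard`` rows.
    titration
        ``{"naoh_concentration": mol/L, "sample_volume": mL}`` for ACID rows.
    net_zones
        If true, report zone diameters net of the 9 mm well.

    Returns
    -------
    DataFrame with columns ``strain, indicator, mean, sd, n, flag``;
    replicates are reduced by arithmetic mean of the per-replicate derived
    values (mean-of-percentages, not percentage-of-means).
    """
    required = {"strain", "assay", "replicate", "role", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    records = records.copy()
    records["strain"] = records["strain"].fillna("")
    curves = dict(curves or {})
    titration = titration or {}

    out_rows = []
    for assay, adf in records.groupby("assay", sort=False):
        if assay in SCAVENGING_ASSAYS:
            shared_controls = adf[(adf["role"] == "control") & (adf["strain"] == "")]
            for strain, sdf in adf[adf["strain"] != ""].groupby("strain", sort=False):
                pcts = []
                for _, rdf in sdf.groupby("replicate", sort=False):
                    if (rdf["role"] == "control").any() or shared_controls.empty:
                        triplet = _triplet_rows(rdf, assay, strain)
                    else:
                        aug = pd.concat([rdf, shared_controls], ignore_index=True)
                        triplet = _triplet_rows(aug, assay, strain)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", QualityWarning)
                        pcts.append(scavenging_percent(triplet))
                out_rows.append(_summary_row(strain, assay, pcts, percent=True))
        elif assay in ("EPS", "FRAP"):
            curve = curves.get(assay)
            if curve is None:
                std = adf[adf["role"] == "standard"]
                if std.empty or "concentration" not in std.columns:
                    raise ValidationError(
                        f"{assay}: no calibration curve supplied and no "
                        f"standard rows with a 'concentration' column"
                    )
                curve = fit_standard_curve(
                    list(zip(std["concentration"].astype(float), std["value"].astype(float)))
                )
            for strain, sdf in adf[(adf["role"] == "sample") & (adf["strain"] != "")].groupby(
                "strain", sort=False
            ):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", QualityWarning)
                    concs = [invert_standard_curve(curve, float(v)) for v in sdf["value"]]
                flag = "negative_concentration" if min(concs) < 0 else ""
                out_rows.append(_summary_row(strain, assay, concs, flag=flag))
        elif assay == "ACID":
            c = float(titration.get("naoh_concentration", 0.1))
            vs = float(titration.get("sample_volume", 10.0))
            for strain, sdf in adf[(adf["role"] == "sample") & (adf["strain"] != "")].groupby(
                "strain", sort=False
            ):
                acid = [
                    titratable_acidity(TitrationRecord(c, float(v), vs))
                    for v in sdf["value"]
                ]
                out_rows.append(_summary_row(strain, assay, acid))
        else:  # inhibition-zone assay, one column per pathogen label
            for strain, sdf in adf[(adf["role"] == "sample") & (adf["strain"] != "")].groupby(
                "strain", sort=False
            ):
                zones = [
                    net_zone_diameter(ZoneMeasurement(assay, float(v)))
                    if net_zones
                    else float(v)
                    for v in sdf["value"]
                ]
                out_rows.append(_summary_row(strain, assay, zones))
    if not out_rows:
        raise ValidationError("no quantifiable records found")
    return pd.DataFrame(out_rows, columns=["strain", "indicator", "mean", "sd", "n", "flag"])


def _summary_row(strain, indicator, values, percent=False, flag=""):
    arr = np.asarray(values, dtype=float)
    if percent and not flag and (arr.min() < 0 or arr.max() > 100):
        flag = "out_of_range_percent"
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "strain": strain,
        "indicator": indicator,
        "mean": float(arr.mean()),
        "sd": sd,
        "n": int(arr.size),
        "flag": flag,
    }
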