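"""Published reference tables packaged for tests and worked examples.

The study behind this package screened seven lactic acid bacteria isolated
from traditional cheese. Its antioxidant panel (six indicators, triplicate
means ± SD), the entropy-weight decomposition of its ten-indicator matrix,
and the EW-TOPSIS ranking are transcribed here verbatim, strain labels
included. Note the published tables label strain W3F *E. durans* while the
study's abstract calls it *E. lactis*; the labels are stored exactly as each
table prints them rather than resolving the inconsistency.
"""

from __future__ import annotations

import pandas as pd

from .matrix import IndicatorMatrix, IndicatorSpec

__all__ = ["table1_fixture", "table2_fixture", "table3_fixture"]

# strain: (·OH, ABTS, DPPH, ·O2−, FICC) in %, FRAP in µmol L⁻¹; (mean, sd)
_TABLE1 = {
    "Lac. lactis W3A": [(92.69, 0.96), (98.67, 0.75), (44.78, 1.43),
                        (15.99, 1.17), (28.49, 1.17), (65.11, 0.76)],
    "S. lutetiensis W3B": [(95.26, 0.38), (96.43, 0.14), (46.26, 0.60),
                           (17.24, 1.23), (25.15, 0.95), (35.56, 1.42)],
    "Lac. lactis W3C": [(87.56, 0.22), (95.86, 0.30), (51.76, 0.38),
                        (11.88, 1.27), (54.70, 1.24), (266.83, 1.57)],
    "E. durans W3D": [(86.06, 0.09), (96.81, 0.29), (50.64, 1.35),
                      (20.26, 1.40), (25.78, 1.16), (273.14, 1.36)],
    "Leu. mesenteroides W3E": [(93.94, 0.19), (98.09, 0.53), (37.72, 0.58),
                               (24.41, 1.33), (23.98, 1.10), (98.66, 0.17)],
    "E. durans W3F": [(93.05, 0.03), (96.67, 0.34), (53.13, 0.36),
                      (31.30, 0.41), (38.81, 1.60), (79.53, 0.03)],
    "Leu. lactis W3J": [(94.44, 0.08), (96.94, 0.65), (52.13, 1.45),
                        (22.00, 1.06), (39.44, 1.38), (141.53, 0.62)],
}

_TABLE1_SPECS = [
    IndicatorSpec("OH", "benefit", "%"),
    IndicatorSpec("ABTS", "benefit", "%"),
    IndicatorSpec("DPPH", "benefit", "%"),
    IndicatorSpec("O2", "benefit", "%"),
    IndicatorSpec("FICC", "benefit", "%"),
    IndicatorSpec("FRAP", "benefit", "umol L^-1"),
]

# indicator: (Ej, Dj, Wj as a fraction)
_TABLE2 = {
    "OH": (0.88, 0.12, 0.0741),
    "ABTS": (0.84, 0.16, 0.0946),
    "DPPH": (0.90, 0.10, 0.0576),
    "FRAP": (0.79, 0.21, 0.1243),
    "FICC": (0.71, 0.29, 0.1729),
    "O2": (0.86, 0.14, 0.0841),
    "EPS": (0.83, 0.17, 0.1035),
    "Lactic acid": (0.86, 0.14, 0.0846),
    "Anti-S. aureus": (0.81, 0.19, 0.1133),
    "Anti-E. coli": (0.85, 0.15, 0.0912),
}

# strain: (D+, D−, Ci, rank) of the published ten-indicator ranking
_TABLE3 = {
    "Lac. lactis W3A": (0.592, 0.478, 0.447, 4),
    "S. lutetiensis W3B": (0.682, 0.44, 0.392, 6),
    "Lac. lactis W3C": (0.662, 0.58, 0.467, 3),
    "E. durans W3D": (0.619, 0.444, 0.417, 5),
    "Leu. mesenteroides W3E": (0.706, 0.361, 0.338, 7),
    "E. durans W3F": (0.496, 0.558, 0.53, 2),
    "Leu. lactis W3J": (0.406, 0.597, 0.595, 1),
}


def table1_fixture() -> IndicatorMatrix:
    """The published 7 × 6 antioxidant panel (means and SDs of triplicates)."""
    strains = list(_TABLE1)
    cols = [s.name for s in _TABLE1_SPECS]
    values = pd.DataFrame(
        [[cell[0] for cell in _TABLE1[s]] for s in strains], index=strains, columns=cols
    )
    sds = pd.DataFrame(
        [[cell[1] for cell in _TABLE1[s]] for s in strains], index=strains, columns=cols
    )
    return IndicatorMatrix(values, list(_TABLE1_SPECS), sds)


def table2_fixture() -> pd.DataFrame:
    """Published entropy-weight decomposition of the ten-indicator matrix:
    columns Ej, Dj, Wj (Wj as a fraction, e.g. 0.1729 for 17.29%)."""
    df = pd.DataFrame.from_dict(_TABLE2, orient="index", columns=["Ej", "Dj", "Wj"])
    df.index.name = "indicator"
    return df


def table3_fixture() -> pd.DataFrame:
    """Published EW-TOPSIS result: columns D+, D-, Ci, rank per strain."""
    df = pd.DataFrame.from_dict(
        _TABLE3, orient="index", columns=["D+", "D-", "Ci", "rank"]
    )
    df.index.name = "strain"
    return df
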