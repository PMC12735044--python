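import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from labscreen.assays import (
    EPS_GLUCOSE_CURVE,
    AbsorbanceTriplet,
    LinearStandardCurve,
    TitrationRecord,
    ZoneMeasurement,
    fit_standard_curve,
    frap_equivalent,
    invert_standard_curve,
    net_zone_diameter,
    quantify_records,
    scavenging_percent,
    titratable_acidity,
)
from labscreen.errors import DegenerateError, QualityWarning, ValidationError

finite_abs = st.floats(0.0, 5.0, allow_nan=False)


class TestScavengingPercent:
    @pytest.mark.parametrize(
        "a_s, a_b, a_c, expected",
        [
            (0.3, 0.3, 0.7, 100.0),  # zero numerator
            (0.9, 0.1, 0.8, 0.0),  # full signal
            (0.5, 0.1, 0.8, 50.0),  # hand arithmetic: (1 - 0.4/0.8) * 100
        ],
    )
    def test_formula(self, a_s, a_b, a_c, expected):
        t = AbsorbanceTriplet(a_s, a_b, a_c, "DPPH")
        assert scavenging_percent(t) == pytest.approx(expected, abs=1e-12)

    def test_zero_control_names_assay(self):
        t = AbsorbanceTriplet(0.5, 0.1, 0.0, "FICC")
        with pytest.raises(DegenerateError, match="FICC"):
            scavenging_percent(t)

    def test_pro_oxidant_reading_unclamped_but_flagged(self):
        t = AbsorbanceTriplet(2.0, 0.1, 0.5, "ABTS")
        with pytest.warns(QualityWarning):
            pct = scavenging_percent(t)
        assert pct < 0  # never clamped to [0, 100]

    @given(
        a_s=finite_abs,
        a_b=finite_abs,
        a_c=st.floats(0.01, 5.0),
        k=st.floats(0.01, 100.0),
    )
    def test_affine_invariance_under_common_scaling(self, a_s, a_b, a_c, k):
        """Scaling As−Ab and Ac by the same factor leaves the percent fixed."""
        base = AbsorbanceTriplet(a_s, a_b, a_c, "OH")
        scaled = AbsorbanceTriplet(k * a_s, k * a_b, k * a_c, "OH")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QualityWarning)
            assert scavenging_percent(scaled) == pytest.approx(
                scavenging_percent(base), rel=1e-9, abs=1e-9
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            AbsorbanceTriplet(0.5, -0.1, 0.8, "DPPH")
        with pytest.raises(ValidationError):
            AbsorbanceTriplet(0.5, 0.1, 0.8, "XYZ")


class TestStandardCurve:
    def test_eps_curve_inversion(self):
        # published glucose curve: y = 0.0039 x + 0.0033
        assert invert_standard_curve(EPS_GLUCOSE_CURVE, 0.0033) == pytest.approx(0.0)
        assert invert_standard_curve(EPS_GLUCOSE_CURVE, 0.3933) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_identity_scale_case(self):
        c = LinearStandardCurve(2.0, 0.0)
        assert invert_standard_curve(c, 1.0) == pytest.approx(0.5)

    def test_negative_concentration_warns_not_clamps(self):
        with pytest.warns(QualityWarning):
            conc = invert_standard_curve(EPS_GLUCOSE_CURVE, 0.001)
        assert conc < 0

    def test_zero_slope_degenerate(self):
        with pytest.raises(DegenerateError):
            LinearStandardCurve(0.0, 0.1)

    def test_fit_recovers_exact_line(self):
        xs = [0.0, 25.0, 50.0, 100.0, 200.0]
        pts = [(x, 0.0039 * x + 0.0033) for x in xs]
        c = fit_standard_curve(pts, "mg L^-1")
        assert c.slope == pytest.approx(0.0039, abs=1e-12)
        assert c.intercept == pytest.approx(0.0033, abs=1e-12)
        assert c.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_two_points_define_the_line(self):
        c = fit_standard_curve([(1.0, 0.2), (3.0, 0.8)])
        assert c.r_squared == pytest.approx(1.0, abs=1e-12)
        assert c.slope == pytest.approx(0.3)

    def test_symmetric_noise_preserves_slope(self):
        # +d, -d, +d, -d around y = 2x + 1 at equally spaced x: OLS slope
        # unchanged (closed form: symmetric residuals are slope-orthogonal)
        d = 0.05
        pts = [(1.0, 3.0 + d), (2.0, 5.0 - d), (3.0, 7.0 + d), (4.0, 9.0 - d)]
        c = fit_standard_curve(pts)
        # closed-form OLS on these points: slope = 2 - 0.2 d / 1 ... compute directly
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        expected = np.polyfit(xs, ys, 1)[0]
        assert c.slope == pytest.approx(expected, abs=1e-12)

    def test_identical_concentrations_degenerate(self):
        with pytest.raises(DegenerateError):
            fit_standard_curve([(1.0, 0.2), (1.0, 0.4)])

    @given(
        slope=st.floats(0.001, 10.0),
        intercept=st.floats(-1.0, 1.0),
        conc=st.floats(0.0, 1000.0),
    )
    def test_inversion_roundtrip(self, slope, intercept, conc):
        """invert ∘ forward is the identity on concentrations."""
        import warnings

        c = LinearStandardCurve(slope, intercept)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QualityWarning)
            back = invert_standard_curve(c, c.forward(conc))
        assert back == pytest.approx(conc, rel=1e-9, abs=1e-9)


class TestFrap:
    def test_hand_arithmetic(self):
        c = LinearStandardCurve(0.002, 0.05, concentration_unit="umol L^-1")
        assert frap_equivalent(0.596, c) == pytest.approx(273.0, abs=1e-9)
        assert frap_equivalent(0.05, c) == pytest.approx(0.0, abs=1e-12)


class TestTitratableAcidity:
    def test_no_titrant_no_acid(self):
        assert titratable_acidity(TitrationRecord(0.1, 0.0, 10.0)) == 0.0

    def test_hand_arithmetic(self):
        # 0.1 mol/L x 10 mL = 1 mmol lactic acid; x 90.08 mg/mmol / 10 mL
        assert titratable_acidity(TitrationRecord(0.1, 10.0, 10.0)) == pytest.approx(
            9.008
        )

    @given(
        c=st.floats(0.01, 1.0),
        v=st.floats(0.0, 50.0),
        vs=st.floats(0.1, 50.0),
        k=st.floats(0.1, 10.0),
    )
    def test_linearity(self, c, v, vs, k):
        base = titratable_acidity(TitrationRecord(c, v, vs))
        assert titratable_acidity(TitrationRecord(c, k * v, vs)) == pytest.approx(
            k * base, rel=1e-9, abs=1e-9
        )
        assert titratable_acidity(TitrationRecord(c, v, k * vs)) == pytest.approx(
            base / k, rel=1e-9, abs=1e-9
        )

    def test_zero_sample_volume_degenerate(self):
        with pytest.raises(DegenerateError):
            TitrationRecord(0.1, 5.0, 0.0)


class TestZones:
    def test_net_halo_toggle(self):
        z = ZoneMeasurement("S. aureus", 15.0)
        assert net_zone_diameter(z) == pytest.approx(6.0)
        assert net_zone_diameter(ZoneMeasurement("E. coli", 0.0)) == 0.0

    def test_sub_well_diameter_rejected(self):
        with pytest.raises(ValidationError):
            ZoneMeasurement("E. coli", 5.0)


class TestQuantifyRecords:
    def _long_records(self):
        rows = []
        # DPPH for two strains, 2 replicates, shared control rows
        for rep in (1, 2):
            rows.append(("", "DPPH", rep, "control", 0.8))
            for strain, a_s in (("A", 0.5), ("B", 0.3)):
                rows.append((strain, "DPPH", rep, "sample", a_s))
                rows.append((strain, "DPPH", rep, "blank", 0.1))
        # EPS absorbances (published glucose curve supplied via standards)
        for conc, absb in [(0.0, 0.0033), (100.0, 0.3933), (200.0, 0.7833)]:
            rows.append(("", "EPS", 1, "standard", absb))
        rows.append(("A", "EPS", 1, "sample", 0.3933))
        rows.append(("A", "EPS", 2, "sample", 0.3933))
        # acid titration volumes
        rows.append(("A", "ACID", 1, "sample", 10.0))
        # one inhibition-zone assay
        rows.append(("A", "Anti-S. aureus", 1, "sample", 15.0))
        df = pd.DataFrame(
            rows, columns=["strain", "assay", "replicate", "role", "value"]
        )
        df["concentration"] = np.nan
        df.loc[(df["role"] == "standard") & (df["value"] == 0.0033), "concentration"] = 0.0
        df.loc[(df["role"] == "standard") & (df["value"] == 0.3933), "concentration"] = 100.0
        df.loc[(df["role"] == "standard") & (df["value"] == 0.7833), "concentration"] = 200.0
        return df

    def test_end_to_end_reduction(self):
        tidy = quantify_records(
            self._long_records(),
            titration={"naoh_concentration": 0.1, "sample_volume": 10.0},
        )
        tidy = tidy.set_index(["strain", "indicator"])
        assert tidy.loc[("A", "DPPH"), "mean"] == pytest.approx(50.0)
        assert tidy.loc[("B", "DPPH"), "mean"] == pytest.approx(75.0)
        assert tidy.loc[("A", "EPS"), "mean"] == pytest.approx(100.0, abs=1e-6)
        assert tidy.loc[("A", "ACID"), "mean"] == pytest.approx(9.008)
        assert tidy.loc[("A", "Anti-S. aureus"), "mean"] == pytest.approx(15.0)

    def test_net_zone_option(self):
        tidy = quantify_records(self._long_records(), net_zones=True)
        tidy = tidy.set_index(["strain", "indicator"])
        assert tidy.loc[("A", "Anti-S. aureus"), "mean"] == pytest.approx(6.0)

    def test_missing_role_raises(self):
        df = pd.DataFrame(
            [("A", "DPPH", 1, "sample", 0.5)],
            columns=["strain", "assay", "replicate", "role", "value"],
        )
        with pytest.raises(ValidationError, match="blank"):
            quantify_records(df)
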