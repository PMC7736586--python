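import json

import numpy as np
import pytest

import gdosim as g


class TestChronicDose:
    def test_one_year_unit_intake(self, coeffs):
        assert g.dose_chronic_from_intake(1.0, 365.0, coeffs) == pytest.approx(365 * 5.5e-5)

    def test_zero_and_linearity(self, coeffs):
        assert g.dose_chronic_from_intake(0.0, 100.0, coeffs) == 0.0
        assert g.dose_chronic_from_intake(2.0, 50.0, coeffs) == pytest.approx(
            2 * g.dose_chronic_from_intake(1.0, 50.0, coeffs)
        )

    @pytest.mark.parametrize("t", [1.0, 30.0, 365.0])
    def test_tracer_burden_identity(self, scenario_5y, gd146, gd148, params, coeffs, t):
        """Feeding back the model tracer burden for a unit Gd-148 intake
        reproduces the direct intake dose (algebraic round trip)."""
        k = g.k_factor(scenario_5y, gd146, t, params)
        q148 = g.whole_body_q(t, gd148, params, environmental_decay=True)
        res = g.dose_chronic_from_tracer_burden(
            q148 / k, gd146, t, scenario_5y, params, coeffs
        )
        assert res.committed_dose == pytest.approx(
            g.dose_chronic_from_intake(1.0, t, coeffs), rel=1e-9
        )

    def test_mda_level_burden_one_day(self, scenario_5y, gd146, params, coeffs):
        """A 6.3-Bq Gd-146 burden one day post release corresponds to 0.017 uSv."""
        res = g.dose_chronic_from_tracer_burden(6.3, gd146, 1.0, scenario_5y, params, coeffs)
        assert res.committed_dose == pytest.approx(1.7e-5, rel=0.03)

    def test_zero_burden(self, scenario_5y, gd146, params, coeffs):
        res = g.dose_chronic_from_tracer_burden(0.0, gd146, 10.0, scenario_5y, params, coeffs)
        assert res.committed_dose == 0.0

    def test_chain_record_reproduces_dose(self, scenario_5y, gd153, params, coeffs):
        res = g.dose_chronic_from_tracer_burden(5.0, gd153, 30.0, scenario_5y, params, coeffs)
        rebuilt = (
            res.chain["e_ing_msv_per_bq"] * res.chain["k"] * 5.0 * 30.0 / res.chain["q148"]
        )
        assert rebuilt == pytest.approx(res.committed_dose, rel=1e-12)
        assert json.loads(res.to_json())["pathway"] == "ingestion"


class TestInhalationDose:
    def test_unit_intake_coefficient(self, scenario_5y, gd146, hrtm, coeffs):
        """A burden consistent with a 1-Bq intake at t=0 commits 1.26e-2 mSv."""
        q = 21.0 * g.retention_whole_body(0.0, hrtm)
        res = g.dose_inhalation_from_tracer_burden(q, gd146, 0.0, scenario_5y, hrtm, coeffs)
        assert res.intake == pytest.approx(1.0, rel=1e-12)
        assert res.committed_dose == pytest.approx(1.26e-2, rel=1e-12)

    def test_zero_burden(self, scenario_5y, gd146, hrtm, coeffs):
        res = g.dose_inhalation_from_tracer_burden(0.0, gd146, 5.0, scenario_5y, hrtm, coeffs)
        assert res.committed_dose == 0.0

    def test_mda_level_one_day(self, scenario_5y, gd146, hrtm, detector, coeffs):
        """MDA-level Gd-146 signal at 1 d maps to ~0.022 mSv (the published
        1-d inhalation MDD cell, reproduced within 5%)."""
        q = detector.lung_geometry_mda(115.4)  # minimum detectable burden
        res = g.dose_inhalation_from_tracer_burden(q, gd146, 1.0, scenario_5y, hrtm, coeffs)
        assert res.committed_dose == pytest.approx(0.022, rel=0.05)


class TestDoseShare:
    def test_origin_value_is_coefficient_weighted_ratio(self, scenario_5y, coeffs):
        e = coeffs.ingestion
        expected = e["Gd-148"] / (
            e["Gd-148"] + 21.0 * e["Gd-146"] + 13.4 * e["Gd-153"]
        )
        assert g.dose_share_gd148(scenario_5y, 0.0, coeffs) == pytest.approx(expected, rel=1e-12)

    def test_one_year_share(self, scenario_5y, coeffs):
        """Gd-148 carries ~89% of the cumulative dose after one year."""
        share = g.dose_share_gd148(scenario_5y, 365.0, coeffs)
        assert 0.85 < share < 0.93

    def test_monotonically_increasing(self, scenario_5y, coeffs):
        ts = [0.0, 10.0, 50.0, 150.0, 365.0, 700.0]
        shares = [g.dose_share_gd148(scenario_5y, t, coeffs) for t in ts]
        assert all(b > a for a, b in zip(shares, shares[1:]))
        assert all(0 < s < 1 for s in shares)
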