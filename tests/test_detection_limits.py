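import numpy as np
import pytest

import gdosim as g


class TestMDAIngestion:
    def test_at_release_from_published_line_mdas(self, scenario_5y, detector):
        """6.3/12 Bq tracer line MDAs over a(t0)=21 give 0.30/0.57 Bq."""
        assert g.mda_ingestion_gd148(0.0, 115.4, scenario_5y, detector) == pytest.approx(0.30, rel=1e-3)
        assert g.mda_ingestion_gd148(0.0, 154.6, scenario_5y, detector) == pytest.approx(12 / 21.0, rel=1e-9)

    @pytest.mark.parametrize(
        "t, line, expected",
        [(1.0, 115.4, 0.306), (7.0, 115.4, 0.334), (30.0, 115.4, 0.464), (1.0, 154.6, 0.582)],
    )
    def test_published_five_year_cells(self, scenario_5y, detector, t, line, expected):
        got = g.mda_ingestion_gd148(t, line, scenario_5y, detector)
        assert got == pytest.approx(expected, rel=0.03)

    def test_tracer_decay_scaling_law(self, scenario_5y, detector, catalogue):
        """MDA(t2)/MDA(t1) follows pure tracer decay (Gd-148 correction ~1)."""
        for line, tracer in ((115.4, "Gd-146"), (97.4, "Gd-153")):
            t_half = catalogue[tracer].half_life
            m1 = g.mda_ingestion_gd148(10.0, line, scenario_5y, detector)
            m2 = g.mda_ingestion_gd148(110.0, line, scenario_5y, detector)
            assert m2 / m1 == pytest.approx(2 ** (100.0 / t_half), rel=0.01)

    def test_unknown_line_rejected(self, scenario_5y, detector):
        with pytest.raises(g.InvalidInputError):
            g.mda_ingestion_gd148(1.0, 200.0, scenario_5y, detector)


class TestMDDIngestion:
    @pytest.mark.parametrize(
        "t, line, scenario_name, expected_usv",
        [
            (1.0, 115.4, "5y", 0.0168),
            (7.0, 115.4, "5y", 0.0857),
            (30.0, 115.4, "5y", 0.513),
            (30.0, 97.4, "5y", 1.68),
        ],
    )
    def test_published_cells(
        self, scenario_5y, scenario_1y, detector, params, coeffs, t, line, scenario_name, expected_usv
    ):
        scenario = scenario_5y if scenario_name == "5y" else scenario_1y
        got = 1e3 * g.mdd_ingestion_gd148(t, line, scenario, detector, params, coeffs)
        assert got == pytest.approx(expected_usv, rel=0.03)


class TestInhalationLimits:
    def test_lung_geometry_rescaling(self, detector):
        """Lung counting costs a factor abdominal/lung ~ 3.2 in line MDA."""
        assert detector.lung_geometry_mda(115.4) == pytest.approx(6.3 * 2.1 / 0.66)
        assert detector.lung_geometry_mda(115.4) == pytest.approx(20.0, rel=0.01)

    def test_one_day_cell(self, scenario_5y, detector, hrtm):
        got = g.mda_inhalation_gd148(1.0, 115.4, scenario_5y, detector, hrtm)
        assert got == pytest.approx(1.74, rel=0.05)

    def test_monotone_in_time(self, scenario_5y, detector, hrtm):
        ts = [0.0, 1.0, 7.0, 30.0, 120.0]
        ms = [g.mda_inhalation_gd148(t, 115.4, scenario_5y, detector, hrtm) for t in ts]
        assert all(b > a for a, b in zip(ms, ms[1:]))

    def test_mdd_to_mda_ratio_is_inhalation_coefficient(
        self, scenario_5y, detector, hrtm, coeffs
    ):
        for t in (0.0, 1.0, 30.0, 365.0):
            mda = g.mda_inhalation_gd148(t, 115.4, scenario_5y, detector, hrtm)
            mdd = g.mdd_inhalation_gd148(t, 115.4, scenario_5y, detector, hrtm, coeffs)
            assert mdd / mda == pytest.approx(1.26e-2, rel=1e-12)


class TestCrossover:
    def test_gd153_line_beats_gd146_between_one_and_twelve_months(
        self, scenario_5y, detector
    ):
        """The longer-lived Gd-153 eventually yields the lower Gd-148 MDA."""
        ts = np.linspace(30.0, 365.0, 336)
        m146 = np.array([g.mda_ingestion_gd148(float(t), 115.4, scenario_5y, detector) for t in ts])
        m153 = np.array([g.mda_ingestion_gd148(float(t), 97.4, scenario_5y, detector) for t in ts])
        assert m146[0] < m153[0]          # Gd-146 wins early
        assert m146[-1] > m153[-1]        # Gd-153 wins at one year
        crossing = ts[np.argmax(m153 < m146)]
        assert 30.0 < crossing < 365.0


class TestLimitTable:
    def test_default_grid_shape(self, detector):
        table = g.build_limit_table()
        # 4 times x 2 scenarios x 4 lines
        assert len(table) == 32
        assert set(table.columns) >= {
            "time_d", "op_years", "tracer", "line_keV",
            "mda_ing_bq", "mdd_ing_usv", "mda_inh_bq", "mdd_inh_usv",
        }
        assert (table[["mda_ing_bq", "mdd_ing_usv", "mda_inh_bq", "mdd_inh_usv"]] > 0).all().all()

    def test_single_time_single_scenario(self, scenario_5y):
        table = g.build_limit_table([1.0], {5.0: scenario_5y})
        assert len(table) == 4

    def test_mda_columns_non_decreasing_in_time(self):
        table = g.build_limit_table()
        for _, grp in table.groupby(["op_years", "tracer", "line_keV"]):
            grp = grp.sort_values("time_d")
            assert grp["mda_ing_bq"].is_monotonic_increasing
            assert grp["mda_inh_bq"].is_monotonic_increasing

    def test_late_gd146_limits_explode(self):
        table = g.build_limit_table()
        sel = table[(table.tracer == "Gd-146") & (table.line_keV == 115.4) & (table.op_years == 5.0)]
        assert sel[sel.time_d == 365.0].mda_ing_bq.iloc[0] > 50 * sel[sel.time_d == 1.0].mda_ing_bq.iloc[0]

    def test_empty_times_rejected(self):
        with pytest.raises(g.InvalidInputError):
            g.build_limit_table([])


class TestDeviationReport:
    def test_known_inconsistent_cells_are_flagged(self):
        """The published 1-y chronic-ingestion MDD rows and late inhalation
        cells are internally inconsistent with the documented model; the
        report must flag them while leaving the early ingestion cells clean."""
        report = g.deviation_report(g.build_limit_table())
        assert len(report) == 32 * 4
        key = report.set_index(["time_d", "op_years", "tracer", "line_keV", "quantity"])
        flagged = key["flagged"]
        assert flagged.loc[(365.0, 5.0, "Gd-146", 115.4, "mdd_ing_usv")]
        assert flagged.loc[(365.0, 5.0, "Gd-146", 115.4, "mda_inh_bq")]
        # early chronic-ingestion cells reproduce well within 10%
        assert not flagged.loc[(1.0, 5.0, "Gd-146", 115.4, "mda_ing_bq")]
        assert not flagged.loc[(30.0, 5.0, "Gd-153", 97.4, "mdd_ing_usv")]

    def test_reference_table_loads(self):
        ref = g.load_reference_limits()
        assert len(ref) == 32
        assert ref.loc[
            (ref.time_d == 1) & (ref.op_years == 5) & (ref.line_keV == 115.4), "mda_ing_bq"
        ].iloc[0] == pytest.approx(0.306)
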