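import math

import numpy as np
import pytest

from cookfield.errors import FormatError, RecordValidationError
from cookfield.survey_io import (
    GridMeasurement,
    GridSummary,
    HouseholdDevice,
    QuestionnaireResponse,
    load_reference_grid_summary,
    read_grid_csv,
    read_questionnaire_csv,
    read_summary_csv,
    summarize_grid,
    write_grid_csv,
    write_questionnaire_csv,
    write_summary_csv,
)

GRID_HEADER = (
    "household_id,h_cm,d_cm,b_ut,wattage_w,cookware_diameter_cm,"
    "hob_offset_cm,table_height_cm\n"
)


def _write(path, text):
    path.write_text(text)
    return path


class TestGridCsv:
    def test_two_rows_one_household(self, tmp_path):
        p = _write(
            tmp_path / "g.csv",
            GRID_HEADER + "A,0,0,3.5,3000,24,23.9,85\nA,0,30,0.2,3000,24,23.9,85\n",
        )
        measurements, devices = read_grid_csv(p)
        assert len(measurements) == 2
        assert len(devices) == 1
        dev = devices[0]
        assert dev.wattage_w == 3000
        assert dev.cookware_diameter_m == pytest.approx(0.24)
        assert dev.hob_offset_m == pytest.approx(0.239)

    def test_negative_flux_cites_row(self, tmp_path):
        p = _write(
            tmp_path / "g.csv",
            GRID_HEADER + "A,0,0,3.5,3000,24,23.9,85\nA,0,10,-1.0,3000,24,23.9,85\n",
        )
        with pytest.raises(RecordValidationError, match="row 3"):
            read_grid_csv(p)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path / "g.csv", "household_id,h_cm,d_cm\nA,0,0\n")
        with pytest.raises(FormatError, match="b_ut"):
            read_grid_csv(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = _write(tmp_path / "g.csv", "")
        with pytest.raises(FormatError):
            read_grid_csv(p)

    def test_non_canonical_grid_warns(self, tmp_path):
        p = _write(tmp_path / "g.csv", GRID_HEADER + "A,5,0,1.0,3000,24,23.9,85\n")
        with pytest.warns(UserWarning, match="non-canonical"):
            read_grid_csv(p)

    def test_round_trip_identity(self, tmp_path):
        devices = [
            HouseholdDevice("A", 3000.0, 0.24, 0.239, 0.85),
            HouseholdDevice("B", 1500.0, 0.18, 0.21, 0.862),
        ]
        measurements = [
            GridMeasurement("A", 0.0, 0.0, 3.864),
            GridMeasurement("A", -20.0, 30.0, 0.198),
            GridMeasurement("B", 10.0, 10.0, 0.81),
        ]
        p = tmp_path / "g.csv"
        write_grid_csv(p, measurements, devices)
        m2, d2 = read_grid_csv(p)
        assert m2 == measurements
        for a, b in zip(sorted(d2, key=lambda d: d.household_id), devices):
            assert a.household_id == b.household_id
            assert a.wattage_w == pytest.approx(b.wattage_w, rel=1e-12)
            assert a.cookware_diameter_m == pytest.approx(b.cookware_diameter_m, rel=1e-12)
            assert a.hob_offset_m == pytest.approx(b.hob_offset_m, rel=1e-12)
            assert a.table_height_m == pytest.approx(b.table_height_m, rel=1e-12)


class TestQuestionnaireCsv:
    def test_optionals_are_none_not_zero(self, tmp_path):
        p = _write(
            tmp_path / "q.csv",
            "subject_id,stature_cm,dh_center_cm,d_edge_cm,cookware_diameter_cm,"
            "wattage_w,measured_b_ut\nS1,158.3,35,,,,\n",
        )
        (r,) = read_questionnaire_csv(p)
        assert r.dh_center_cm == 35
        assert r.d_edge_cm is None
        assert r.wattage_w is None
        assert r.measured_b_ut is None

    def test_no_distance_rejected(self):
        with pytest.raises(RecordValidationError, match="distance|dh_center"):
            QuestionnaireResponse("S1", 158.3)

    def test_round_trip(self, tmp_path):
        responses = [
            QuestionnaireResponse("S1", 158.3, dh_center_cm=35.0, wattage_w=3000.0,
                                  cookware_diameter_cm=24.0, measured_b_ut=1.2),
            QuestionnaireResponse("S2", 162.0, d_edge_cm=10.0),
        ]
        p = tmp_path / "q.csv"
        write_questionnaire_csv(p, responses)
        assert read_questionnaire_csv(p) == responses


class TestSummarizeGrid:
    @staticmethod
    def _cell(values, h=0.0, d=0.0):
        return [GridMeasurement("A", h, d, v) for v in values]

    def test_constant_cell(self):
        (s,) = summarize_grid(self._cell([2.0, 2.0, 2.0]))
        assert s.mean_ut == pytest.approx(2.0)
        assert s.sd_ut == pytest.approx(0.0)
        assert s.gm_ut == pytest.approx(2.0)
        assert s.gsd == pytest.approx(1.0)

    def test_two_value_cell_hand_arithmetic(self):
        (s,) = summarize_grid(self._cell([1.0, 4.0]))
        assert s.mean_ut == pytest.approx(2.5)
        assert s.gm_ut == pytest.approx(2.0)  # sqrt(1*4)

    def test_zero_reading_undefines_gm(self):
        with pytest.warns(UserWarning, match="zero"):
            (s,) = summarize_grid(self._cell([0.0, 1.0]))
        assert math.isnan(s.gm_ut) and math.isnan(s.gsd)
        assert s.mean_ut == pytest.approx(0.5)

    def test_cells_reported_in_campaign_order(self):
        measurements = (
            self._cell([1.0], h=-20, d=0)
            + self._cell([1.0], h=20, d=30)
            + self._cell([1.0], h=20, d=0)
        )
        cells = [(s.h_cm, s.d_cm) for s in summarize_grid(measurements)]
        assert cells == [(20, 0), (20, 30), (-20, 0)]

    def test_lognormal_gm_gsd_recovery(self):
        """GM/GSD estimate exp(mu) and exp(sigma) of a lognormal cell.

        Stochastic check at n = 10^4 with a 3-standard-error tolerance.
        """
        rng = np.random.default_rng(42)
        mu, sigma, n = math.log(0.9), math.log(2.0), 10_000
        values = rng.lognormal(mu, sigma, n)
        (s,) = summarize_grid(self._cell(values))
        se_mu = sigma / math.sqrt(n)
        se_sigma = sigma / math.sqrt(2 * n)
        assert abs(math.log(s.gm_ut) - mu) < 3 * se_mu
        assert abs(math.log(s.gsd) - sigma) < 3 * se_sigma

    def test_summary_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        measurements = [
            GridMeasurement("A", h, d, float(b))
            for h in (0.0, 10.0)
            for d in (0.0, 30.0)
            for b in rng.lognormal(0, 0.5, 5)
        ]
        summaries = summarize_grid(measurements)
        p = tmp_path / "s.csv"
        write_summary_csv(p, summaries)
        back = read_summary_csv(p)
        for a, b in zip(back, summaries):
            for field in ("h_cm", "d_cm", "n", "mean_ut", "sd_ut", "gm_ut",
                          "gsd", "q1_ut", "median_ut", "q3_ut"):
                assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)


class TestReferenceSummary:
    def test_shape_and_known_cells(self):
        rows = load_reference_grid_summary()
        assert len(rows) == 20
        by_cell = {(r.h_cm, r.d_cm): r for r in rows}
        assert by_cell[(0, 30)].mean_ut == 0.23
        assert by_cell[(0, 30)].sd_ut == 0.13
        assert by_cell[(0, 0)].mean_ut == 3.86
        assert by_cell[(0, 0)].sd_ut == 3.31
        assert all(r.n == 45 for r in rows)

    def test_field_decays_with_distance_at_every_height(self):
        rows = load_reference_grid_summary()
        by_cell = {(r.h_cm, r.d_cm): r for r in rows}
        for h in (-20, -10, 0, 10, 20):
            means = [by_cell[(h, d)].mean_ut for d in (0, 10, 20, 30)]
            assert means == sorted(means, reverse=True)


def test_grid_summary_invariants_enforced():
    with pytest.raises(RecordValidationError, match="GM"):
        GridSummary(0, 0, 5, mean_ut=1.0, sd_ut=0.1, gm_ut=1.5, gsd=1.2,
                    q1_ut=0.8, median_ut=1.0, q3_ut=1.2)
    with pytest.raises(RecordValidationError, match="GSD"):
        GridSummary(0, 0, 5, mean_ut=1.0, sd_ut=0.1, gm_ut=0.9, gsd=0.8,
                    q1_ut=0.8, median_ut=1.0, q3_ut=1.2)
    with pytest.raises(RecordValidationError, match="quartile"):
        GridSummary(0, 0, 5, mean_ut=1.0, sd_ut=0.1, gm_ut=0.9, gsd=1.2,
                    q1_ut=1.1, median_ut=1.0, q3_ut=1.2)
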