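"""Deviation-matrix sweep, binning, summaries, and figure series."""

import numpy as np
import pytest

from hipcal.catalog import make_catalog
from hipcal.matrix import (
    ScenarioConfig,
    bin_label,
    build_matrix,
    figure_series,
    make_error_grid,
    round_half_away,
    scenario,
    summarize,
)

from conftest import brute_force_snap


class TestErrorGrid:
    def test_symmetric_with_zero(self):
        g = make_error_grid(12, 1)
        assert len(g.values) == 25
        assert 0 in g.values
        assert g.values == tuple(sorted(g.values))
        assert tuple(-v for v in reversed(g.values)) == g.values
        assert len(g.positive()) == 13

    @pytest.mark.parametrize("max_abs, step", [(12, 5), (10, -1), (10, 0)])
    def test_invalid_grid_rejected(self, max_abs, step):
        with pytest.raises(ValueError):
            make_error_grid(max_abs, step)


class TestBuildMatrix:
    @pytest.mark.parametrize(
        "name, side, shape",
        [
            ("group1", "both", (12, 25)),
            ("group1", "positive_only", (12, 13)),
            ("group2", "both", (18, 49)),
            ("group2", "positive_only", (18, 25)),
        ],
    )
    def test_grid_cardinalities(self, name, side, shape):
        m = build_matrix(scenario(name, report_side=side))
        assert m.shape == shape

    def test_zero_error_column_identically_zero(self, group1_scenario):
        m = build_matrix(group1_scenario)
        assert (m.deviation_mm[0.0] == 0).all()
        assert (m.deviation_steps[0.0] == 0).all()

    def test_worked_example_cell(self, group1_scenario):
        m = build_matrix(group1_scenario)
        assert m.deviation_mm.at[52.0, 8.0] == pytest.approx(4.0)
        assert m.deviation_steps.at[52.0, 8.0] == 2
        assert m.bins.at[52.0, 8.0] == "2"

    def test_every_cell_matches_brute_force_oracle(self, group2_scenario):
        m = build_matrix(group2_scenario)
        cat = group2_scenario.catalog
        for s in m.sizes:
            for e in m.errors:
                projected = s * (100 + e) / 100
                expected = brute_force_snap(projected, cat, "toward_true", s)
                assert m.deviation_mm.at[s, e] == pytest.approx(expected - s)

    @pytest.mark.parametrize("name", ["group1", "group2"])
    def test_snapped_deviation_symmetric_in_error_sign(self, name):
        m = build_matrix(scenario(name, report_side="both"))
        for s in m.sizes:
            for e in m.errors:
                if e <= 0:
                    continue
                # skip exact snapping midpoints, where the tie rule may
                # break the mirror symmetry
                if abs((s * e / 100) % m.config.catalog.increment - 1.0) < 1e-9:
                    continue
                assert abs(m.deviation_mm.at[s, e]) == pytest.approx(
                    abs(m.deviation_mm.at[s, -e])
                )

    def test_row_monotone_in_error_magnitude(self, group2_scenario):
        m = build_matrix(group2_scenario)
        steps = m.deviation_steps.abs()
        for s in m.sizes:
            row = steps.loc[s].to_numpy()
            assert (np.diff(row) >= 0).all()

    def test_presnap_column_strictly_grows_with_size(self, group2_scenario):
        m = build_matrix(group2_scenario)
        for e in m.errors:
            if e == 0:
                continue
            col = m.presnap_mm[e].abs().to_numpy()
            assert (np.diff(col) > 0).all()

    def test_signed_bins_in_two_sided_report(self):
        m = build_matrix(scenario("group2", report_side="both"))
        labels = set(m.bins.to_numpy().ravel())
        assert "-3" in labels
        assert ">8" in labels and "<-8" in labels


class TestBinLabel:
    @pytest.mark.parametrize(
        "steps, expected", [(0, "0"), (5, "5"), (-5, "5"), (8, "8"), (9, ">8"), (-12, ">8")]
    )
    def test_unsigned_labels(self, steps, expected):
        assert bin_label(steps) == expected

    @pytest.mark.parametrize(
        "steps, expected", [(-5, "-5"), (5, "5"), (-9, "<-8"), (9, ">8")]
    )
    def test_signed_labels(self, steps, expected):
        assert bin_label(steps, signed=True) == expected

    def test_overflow_bin_only_in_large_sample(self):
        m1 = build_matrix(scenario("group1"))
        m2 = build_matrix(scenario("group2"))
        assert ">8" not in set(m1.bins.to_numpy().ravel())
        assert ">8" in set(m2.bins.to_numpy().ravel())


class TestSummarize:
    def test_common_sample_maxima(self, group1_scenario):
        s = summarize(build_matrix(group1_scenario))
        assert s.max_abs_presnap_mm == 7.9  # 66 mm * 12%, one decimal
        assert s.max_abs_steps == 4

    def test_large_sample_maxima(self, group2_scenario):
        s = summarize(build_matrix(group2_scenario))
        assert s.max_abs_presnap_mm == 17.3  # 72 mm * 24%
        assert s.max_abs_snapped_mm == 18.0
        assert s.max_abs_steps == 9

    def test_degenerate_single_cell(self):
        cfg = ScenarioConfig(
            catalog=make_catalog(52, 54, 2), grid=make_error_grid(0)
        )
        s = summarize(build_matrix(cfg))
        assert (s.max_abs_presnap_mm, s.max_abs_snapped_mm, s.max_abs_steps) == (0, 0, 0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(7.92) == 7.9
        assert round_half_away(0.25) == 0.3
        assert round_half_away(-0.25) == -0.3
        assert round_half_away(1.05) == 1.1


class TestFigureSeries:
    def test_one_line_per_size_with_exact_endpoints(self, group1_scenario):
        series = figure_series(group1_scenario)
        assert len(series) == 12
        pts = dict(series[66.0])
        assert pts[-12.0] == pytest.approx(58.08)
        assert pts[12.0] == pytest.approx(73.92)
        assert pts[0.0] == pytest.approx(66.0)

    def test_full_error_axis_even_when_report_is_one_sided(self, group2_scenario):
        series = figure_series(group2_scenario)
        assert len(series) == 18
        assert len(series[38.0]) == 49
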