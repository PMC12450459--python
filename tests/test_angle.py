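"""Aligned-angle model: lengths, angles, uncertainty propagation, schematic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from desmomap.angle import (
    DEFAULT_ISOFORMS,
    IsoformSpec,
    angle_of_alignment,
    isoform_length,
    monte_carlo_angle_sd,
    propagate_angle_sd,
    rod_length_from_total,
    solve_isoform,
    to_scale_model,
)
from desmomap.errors import DataError, GeometryError


class TestLengths:
    def test_rod_length_from_rotary_shadowing_dimensions(self):
        assert rod_length_from_total(162, 16, 16) == 130.0

    @pytest.mark.parametrize("total,head,tail", [(32, 16, 16), (100, 60, 60)])
    def test_non_positive_rod_rejected(self, total, head, tail):
        with pytest.raises(GeometryError):
            rod_length_from_total(total, head, tail)

    def test_isoform_lengths_from_rod_residue_counts(self):
        assert isoform_length(DEFAULT_ISOFORMS["DPI"]) == pytest.approx(162.0)
        assert isoform_length(DEFAULT_ISOFORMS["DPIa"]) == pytest.approx(97.59, abs=0.01)
        assert isoform_length(DEFAULT_ISOFORMS["DPII"]) == pytest.approx(74.46, abs=0.01)

    def test_zero_rod_is_head_plus_tail(self):
        assert isoform_length(IsoformSpec("stub", rod_aa=0)) == 32.0


class TestAngleOfAlignment:
    @pytest.mark.parametrize(
        "tail,head,length,expected",
        [(192, 70, 162, 22.1), (143, 60, 97, 25.3), (118, 65, 75, 20.7)],
    )
    def test_observed_isoform_angles(self, tail, head, length, expected):
        res = angle_of_alignment(tail, head, length)
        assert res.theta == pytest.approx(expected, abs=0.05)
        assert round(res.theta) == round(expected)

    def test_equal_ptp_gives_zero_angle(self):
        assert angle_of_alignment(100, 100, 75).theta == 0.0

    def test_offset_beyond_length_infeasible(self):
        with pytest.raises(GeometryError):
            angle_of_alignment(192, 70, 60)  # needs 61 nm from a 60 nm protein

    def test_tail_inside_head_rejected(self):
        with pytest.raises(GeometryError):
            angle_of_alignment(60, 70, 162)

    @given(
        head=st.floats(0, 150),
        offset=st.floats(0.5, 120),
        length=st.floats(125, 300),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_reconstructs_tail_ptp(self, head, offset, length):
        tail = head + 2 * offset
        res = angle_of_alignment(tail, head, length)
        back = 2 * length * math.sin(math.radians(res.theta)) + head
        assert back == pytest.approx(tail, rel=1e-9)

    def test_theta_monotone_in_tail_and_length(self):
        base = angle_of_alignment(150, 70, 100).theta
        assert angle_of_alignment(160, 70, 100).theta > base
        assert angle_of_alignment(150, 70, 120).theta < base


class TestUncertainty:
    def test_delta_method_value(self):
        theta = angle_of_alignment(192, 70, 162).theta
        sd = propagate_angle_sd(26, 12, theta, 162)
        assert sd == pytest.approx(5.5, abs=0.1)

    def test_zero_input_sds_give_zero(self):
        assert propagate_angle_sd(0, 0, 45, 100) == 0.0

    def test_ninety_degrees_rejected(self):
        with pytest.raises(GeometryError):
            propagate_angle_sd(5, 5, 90, 100)

    @pytest.mark.parametrize(
        "tail,head,sd_t,sd_h,length",
        [(192, 70, 26, 12, 162), (143, 60, 18, 13, 97.59), (118, 65, 14, 15, 74.46)],
    )
    def test_delta_method_agrees_with_monte_carlo(self, tail, head, sd_t, sd_h, length):
        theta = angle_of_alignment(tail, head, length).theta
        delta = propagate_angle_sd(sd_t, sd_h, theta, length)
        mc = monte_carlo_angle_sd(tail, head, sd_t, sd_h, length, n_draws=100_000, seed=1)
        assert delta == pytest.approx(mc, rel=0.05)


class TestScaleModel:
    def test_tail_transverse_coordinate_is_half_ptp(self):
        res = solve_isoform(DEFAULT_ISOFORMS["DPI"], 192, 70)
        df = to_scale_model([DEFAULT_ISOFORMS["DPI"]], [res])
        up = df[df["side"] == 1].iloc[0]
        assert up["tail_y_nm"] == pytest.approx(96.0)
        assert up["head_y_nm"] == pytest.approx(35.0)
        # segment length consistency: dx² + dy² = L²
        dx = up["tail_x_nm"] - up["head_x_nm"]
        dy = up["tail_y_nm"] - up["head_y_nm"]
        assert math.hypot(dx, dy) == pytest.approx(up["length_nm"])

    def test_zero_angle_keeps_equal_transverse_offset(self):
        res = angle_of_alignment(100, 100, 75)
        df = to_scale_model([IsoformSpec("flat", 290)], [res])
        assert (df["tail_y_nm"].abs() == df["head_y_nm"].abs()).all()

    def test_three_isoforms_mirrored_rows(self):
        specs = [DEFAULT_ISOFORMS[k] for k in ("DPI", "DPIa", "DPII")]
        results = [
            solve_isoform(s, t, h)
            for s, (t, h) in zip(specs, [(192, 70), (143, 60), (118, 65)])
        ]
        df = to_scale_model(specs, results)
        assert len(df) == 6
        assert set(df["side"]) == {1, -1}
        # mirror symmetry across the midline
        for iso, g in df.groupby("isoform"):
            assert g["tail_y_nm"].sum() == pytest.approx(0.0)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(DataError):
            to_scale_model([DEFAULT_ISOFORMS["DPI"]], [])
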