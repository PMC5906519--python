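import numpy as np
import pytest

from bidomainuq.features import (
    classify_values,
    ellipse_angle,
    extract_features,
    extremum_angle,
)
from bidomainuq.solver import EPD
from bidomainuq.synthetic import GaussianBlob, make_synthetic_epd


def _single_well():
    return make_synthetic_epd([GaussianBlob(0.0, 0.0, -1.0, 1.0, 1.0)], n=161)


class TestClassification:
    @pytest.mark.parametrize(
        "cmin,omin,cmax,expected",
        [
            # the three published pattern definitions
            (-1.37, -0.9, -0.1, "depression_type1"),
            (-0.75, -0.95, -0.07, "depression_type2"),
            (-0.5, -0.8, 1.04, "elevation"),
            # boundary behaviour: elevation wins whenever cmaxV > 0
            (-2.0, -1.0, 0.001, "elevation"),
            (-1.0, -1.0, -0.5, "depression_type1"),
        ],
    )
    def test_pattern_partition(self, cmin, omin, cmax, expected):
        assert classify_values(cmin, omin, cmax) == expected


class TestExtractFeatures:
    def test_single_central_well(self):
        epd, truth = _single_well()
        fs = extract_features(epd)
        assert fs.cminV == pytest.approx(-1.0, abs=1e-6)
        assert abs(fs.cmaxV) < 0.02
        # outside minimum sits right on the footprint border; the test grid
        # (0.1 cm) samples it slightly further out than the 0.05 cm oracle
        assert fs.ominV == pytest.approx(truth.ominV, abs=0.02)
        assert fs.epd_type == "depression_type1"

    def test_tripole_matches_brute_force_oracle(self):
        blobs = [
            GaussianBlob(0.0, 0.0, -0.8, 1.0, 1.0),
            GaussianBlob(3 * np.cos(np.deg2rad(70)), 3 * np.sin(np.deg2rad(70)), -1.2, 0.8, 0.8),
            GaussianBlob(-3 * np.cos(np.deg2rad(70)), -3 * np.sin(np.deg2rad(70)), -1.2, 0.8, 0.8),
        ]
        epd, truth = make_synthetic_epd(blobs, n=161)
        fs = extract_features(epd)
        assert truth.epd_type == "depression_type2"
        assert fs.epd_type == "depression_type2"
        assert fs.ominV < fs.cminV < 0
        assert fs.cminV == pytest.approx(truth.cminV, abs=0.02)
        assert fs.ominV == pytest.approx(truth.ominV, abs=0.02)
        assert fs.angmin == pytest.approx(70.0, abs=2.0)
        assert fs.angmin == pytest.approx(truth.angmin, abs=2.0)

    def test_constant_shift_moves_potentials_not_angles(self):
        blobs = [
            GaussianBlob(0.0, 0.0, -0.8, 1.4, 1.0, angle=30.0),
            GaussianBlob(2.4, 2.4, -1.2, 0.8, 0.8),
            GaussianBlob(-2.4, -2.4, -1.2, 0.8, 0.8),
        ]
        epd, _ = make_synthetic_epd(blobs, n=121)
        shifted = EPD(values=epd.values - 0.37, x=epd.x, y=epd.y)
        a, b = extract_features(epd), extract_features(shifted)
        assert b.cminV == pytest.approx(a.cminV - 0.37, abs=1e-12)
        assert b.cmaxV == pytest.approx(a.cmaxV - 0.37, abs=1e-12)
        assert b.ominV == pytest.approx(a.ominV - 0.37, abs=1e-12)
        # extremum angles are shift-invariant (the ellipse orientation is
        # not, since its contour level is referenced to zero potential)
        assert b.angmin == pytest.approx(a.angmin, abs=1e-9)

    def test_empty_mask_rejected(self):
        axis = np.linspace(3.0, 8.0, 11)  # grid entirely outside the footprint
        epd = EPD(values=np.zeros((11, 11)), x=axis, y=axis)
        with pytest.raises(ValueError):
            extract_features(epd)


class TestExtremumAngle:
    @pytest.mark.parametrize(
        "x0,y0,expected", [(0.0, 3.0, 90.0), (-2.2, 2.2, 135.0), (3.0, 3.0, 45.0)]
    )
    def test_known_positions(self, x0, y0, expected):
        epd, _ = make_synthetic_epd(
            [GaussianBlob(x0, y0, -1.0, 0.7, 0.7),
             GaussianBlob(-x0, -y0, -1.0, 0.7, 0.7)], n=161,
        )
        assert extremum_angle(epd, "min", "outside") == pytest.approx(expected, abs=1.5)

    def test_point_symmetric_partner_has_equal_depth(self):
        epd, _ = make_synthetic_epd(
            [GaussianBlob(1.5, 2.8, -1.0, 0.7, 0.7),
             GaussianBlob(-1.5, -2.8, -1.0, 0.7, 0.7)], n=161,
        )
        v = epd.values
        assert np.max(np.abs(v - v[::-1, ::-1])) < 1e-12

    def test_no_qualifying_extremum_returns_none(self):
        epd, _ = _single_well()
        assert extremum_angle(epd, "min", "outside") is None


class TestEllipseAngle:
    def test_axis_aligned_well(self):
        epd, _ = make_synthetic_epd([GaussianBlob(0, 0, -1.0, 1.8, 0.9)], n=161)
        ang, ratio = ellipse_angle(epd)
        assert ang == pytest.approx(0.0, abs=2.0) or ang == pytest.approx(180.0, abs=2.0)
        assert ratio > 1.3

    def test_rotated_well_equivariance(self):
        # 58.2 degrees mirrors the published type-1 emulator mean orientation
        epd, _ = make_synthetic_epd([GaussianBlob(0, 0, -1.0, 1.8, 0.9, angle=58.2)], n=161)
        ang, _ = ellipse_angle(epd)
        assert ang == pytest.approx(58.2, abs=2.0)

    def test_circular_well_flags_degenerate_ratio(self):
        epd, _ = _single_well()
        ang, ratio = ellipse_angle(epd)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_undefined_for_nonnegative_field(self):
        epd, _ = make_synthetic_epd([GaussianBlob(0, 0, 1.0, 1.0, 1.0)], n=81)
        assert ellipse_angle(epd) is None

    @pytest.mark.parametrize("delta", [10.0, 20.0, 95.0])
    def test_rotation_equivariance_of_all_angles(self, delta):
        # deltas keep the flank wells away from the footprint corners, where
        # their tails would leak into the central region and move cminV
        def blobs(extra):
            th = np.deg2rad(70.0 + extra)
            return [
                GaussianBlob(0, 0, -0.8, 1.6, 0.9, angle=20.0 + extra),
                GaussianBlob(3 * np.cos(th), 3 * np.sin(th), -1.2, 0.8, 0.8),
                GaussianBlob(-3 * np.cos(th), -3 * np.sin(th), -1.2, 0.8, 0.8),
            ]

        base, _ = make_synthetic_epd(blobs(0.0), n=201)
        rot, _ = make_synthetic_epd(blobs(delta), n=201)
        fa, fb = extract_features(base), extract_features(rot)
        assert fb.angmin == pytest.approx((fa.angmin + delta) % 180.0, abs=2.0)
        assert fb.ellipse_angle == pytest.approx((fa.ellipse_angle + delta) % 180.0, abs=3.0)
        assert fb.cminV == pytest.approx(fa.cminV, abs=0.02)
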