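"""Active-disc energy, Green's-theorem evaluation, gradients, and fitting."""

import math

import numpy as np
import pytest

from activedisc import (
    ActiveDiscParams,
    FitOptions,
    SyntheticSpec,
    boundary_samples,
    circle_mask,
    disc_energy_direct,
    disc_energy_green,
    energy_gradient,
    fit_active_disc,
    generate_fundus_image,
    localize_disc,
    row_cumulative,
    segment_optic_disc,
)
from activedisc.errors import (
    DegenerateTemplateError,
    FitFailureError,
    InvalidArgumentError,
)
from activedisc.eval_metrics import confusion_counts, segmentation_metrics

from conftest import smooth_field

SQRT2 = math.sqrt(2.0)


def binary_disc_image(a, size, center=None):
    c = size // 2 if center is None else center
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return (((xx - c) ** 2 + (yy - c) ** 2) <= a * a).astype(float), float(c)


def shoelace(pts):
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestBoundarySamples:
    def test_quarter_angles_outer(self):
        pts = boundary_samples(ActiveDiscParams(1.0, 0.0, 0.0), "outer", 4)
        expected = {(0.0, 1.0), (-1.0, 0.0), (0.0, -1.0), (1.0, 0.0)}
        got = {(round(x, 12), round(y, 12)) for x, y in pts}
        assert got == expected

    def test_inner_radius_is_outer_over_sqrt2(self):
        pts = boundary_samples(ActiveDiscParams(2.0, 5.0, 5.0), "inner", 1000)
        d = np.hypot(pts[:, 0] - 5.0, pts[:, 1] - 5.0)
        assert np.abs(d - 2.0 / SQRT2).max() < 1e-12

    def test_polygon_area_converges_to_circle_area(self):
        R = 3.7
        pts = boundary_samples(ActiveDiscParams(R, 1.0, -2.0), "outer", 10_000)
        assert shoelace(pts) == pytest.approx(math.pi * R * R, rel=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            boundary_samples(ActiveDiscParams(1.0, 0.0, 0.0), "outer", 2)


class TestDiscEnergyDirect:
    def test_uniform_image_near_zero(self):
        # inner disc covers exactly half the outer area, so E ~ 0; at R=60 the
        # pixel-center count imbalance is well below the 1% bound
        img = np.full((161, 161), 0.7)
        E = disc_energy_direct(img, ActiveDiscParams(60.0, 80.0, 80.0))
        assert abs(E) <= 0.7 * 1e-2

    @pytest.mark.parametrize("a", [30, 50])
    def test_binary_disc_closed_form(self, a):
        """Aligned template on a unit binary disc: E -> -pi/2; annulus-only: +pi/2."""
        img, c = binary_disc_image(a, 4 * a + 41)
        E = disc_energy_direct(img, ActiveDiscParams(SQRT2 * a, c, c))
        assert E == pytest.approx(-math.pi / 2, rel=0.02)
        annulus = circle_mask_ring(a, SQRT2 * a, 4 * a + 41)
        E2 = disc_energy_direct(annulus, ActiveDiscParams(SQRT2 * a, c, c))
        assert E2 == pytest.approx(math.pi / 2, rel=0.02)

    def test_degenerate_radius_rejected(self):
        with pytest.raises(DegenerateTemplateError):
            disc_energy_direct(np.ones((10, 10)), ActiveDiscParams(0.5, 5.0, 5.0))


def circle_mask_ring(r_in, r_out, size):
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    d2 = (xx - c) ** 2 + (yy - c) ** 2
    return ((d2 > r_in * r_in) & (d2 <= r_out * r_out)).astype(float)


class TestDiscEnergyGreen:
    def test_uniform_image_zero(self):
        F = row_cumulative(np.full((101, 101), 0.7))
        E = disc_energy_green(F, ActiveDiscParams(30.0, 50.0, 50.0))
        assert abs(E) < 1e-12

    def test_matches_direct_oracle_on_smooth_images(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            h, w = int(rng.integers(110, 170)), int(rng.integers(110, 170))
            img = smooth_field(rng, (h, w), 2.0)
            p = ActiveDiscParams(float(rng.uniform(25, 0.35 * min(h, w))),
                                 float(rng.uniform(0.25 * w, 0.75 * w)),
                                 float(rng.uniform(0.25 * h, 0.75 * h)))
            Ed = disc_energy_direct(img, p)
            Eg = disc_energy_green(row_cumulative(img), p)
            assert abs(Eg - Ed) <= max(1e-3 * abs(Ed), 1e-2 * np.abs(img).max())

    def test_circle_outside_support_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        F = row_cumulative(rng.uniform(0, 1, (50, 50)))
        # fully below the image rows: F samples identically zero
        assert disc_energy_green(F, ActiveDiscParams(10.0, 25.0, 200.0)) == 0.0
        # fully to the left: same
        assert disc_energy_green(F, ActiveDiscParams(10.0, -100.0, 25.0)) == 0.0


class TestEnergyGradient:
    def test_uniform_image_zero_gradient(self):
        img = np.full((101, 101), 0.6)
        g = energy_gradient(img, ActiveDiscParams(25.0, 50.0, 50.0))
        assert max(abs(v) for v in g) < 1e-6 * 0.6 * 25.0

    def test_translation_gradient_vanishes_at_symmetric_optimum(self):
        img, c = binary_disc_image(30, 161)
        g = energy_gradient(img, ActiveDiscParams(SQRT2 * 30, c, c), n=4096)
        assert abs(g[1]) < 1e-3 and abs(g[2]) < 1e-3

    def test_matches_central_finite_differences(self):
        """Standard gradient check: ||g - fd||_inf <= 5% of ||fd||_inf."""
        rng = np.random.default_rng(7)
        n = 4096
        h_step = 0.1
        for _ in range(10):
            img = smooth_field(rng, (140, 150), 4.0, mean=0.5)
            p = ActiveDiscParams(float(rng.uniform(20, 40)),
                                 float(rng.uniform(50, 100)),
                                 float(rng.uniform(50, 90)))
            g = np.array(energy_gradient(img, p, n=n))
            F = row_cumulative(img)
            fd = np.empty(3)
            for k, (dR, dx, dy) in enumerate([(h_step, 0, 0), (0, h_step, 0), (0, 0, h_step)]):
                pp = ActiveDiscParams(p.R + dR, p.xc + dx, p.yc + dy)
                pm = ActiveDiscParams(p.R - dR, p.xc - dx, p.yc - dy)
                fd[k] = (disc_energy_green(F, pp, n) - disc_energy_green(F, pm, n)) / (2 * h_step)
            assert np.abs(g - fd).max() <= 0.05 * np.abs(fd).max()


class TestFitActiveDisc:
    def test_recovers_binary_disc(self):
        img, _ = binary_disc_image(30, 200, center=100)
        res = fit_active_disc(img, ActiveDiscParams(50.0, 90.0, 90.0))
        assert res.converged
        assert res.object_circle.r == pytest.approx(30.0, rel=0.05)
        assert math.hypot(res.object_circle.cx - 100, res.object_circle.cy - 100) <= 1.0

    def test_init_at_optimum_stays_put(self):
        img, _ = binary_disc_image(30, 200, center=100)
        res0 = fit_active_disc(img, ActiveDiscParams(50.0, 90.0, 90.0))
        res = fit_active_disc(img, res0.params)
        assert res.n_iterations <= 2
        assert res.params.R == pytest.approx(res0.params.R, abs=0.2)

    def test_uniform_image_fails_no_contrast(self):
        with pytest.raises(FitFailureError):
            fit_active_disc(np.full((101, 101), 0.5),
                            ActiveDiscParams(25.0, 50.0, 50.0))

    def test_energy_trace_monotone_without_momentum(self):
        img, _ = binary_disc_image(25, 150, center=75)
        res = fit_active_disc(img, ActiveDiscParams(45.0, 70.0, 70.0),
                              FitOptions(momentum=0.0))
        trace = np.array(res.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_result_energy_consistent_with_green_evaluation(self):
        img, _ = binary_disc_image(25, 150, center=75)
        res = fit_active_disc(img, ActiveDiscParams(45.0, 70.0, 70.0))
        E = disc_energy_green(row_cumulative(img), res.params)
        assert res.energy == pytest.approx(E, abs=1e-9)


def dice_vs_truth(circle, truth_mask):
    m = circle_mask(circle, truth_mask.shape[0], truth_mask.shape[1])
    return segmentation_metrics(confusion_counts(m, truth_mask))["dice"]


class TestSegmentOpticDisc:
    def test_synthetic_default_conditions(self, default_case_seed11):
        img, truth = default_case_seed11
        res = segment_optic_disc(img, localize_disc(img))
        assert dice_vs_truth(res.object_circle, truth.disc_mask) >= 0.95

    def test_noiseless_subpixel_accuracy(self, noiseless_case):
        img, truth = noiseless_case
        res = segment_optic_disc(img, localize_disc(img))
        oc = res.object_circle
        assert math.hypot(oc.cx - truth.disc.cx, oc.cy - truth.disc.cy) <= 1.0
        assert abs(oc.r - truth.disc.r) <= 0.03 * truth.disc.r

    def test_basin_tolerates_ten_pixel_offset(self, default_case_seed11):
        """Initialization 10 px off the true center still converges to truth."""
        from activedisc.localization import LocalizationResult

        img, truth = default_case_seed11
        fake = LocalizationResult(x_p=truth.disc.cx + 10.0, y_p=truth.disc.cy,
                                  peak_score=1.0, roi_box=(0, 0, 255, 255))
        res = segment_optic_disc(img, fake)
        oc = res.object_circle
        assert math.hypot(oc.cx - truth.disc.cx, oc.cy - truth.disc.cy) <= 2.0
        assert dice_vs_truth(oc, truth.disc_mask) >= 0.95
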