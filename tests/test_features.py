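import math

import numpy as np
import pytest
from skimage import measure

from chromaquant.features import (
    axis_ratio_from_pixels,
    distance_matrix,
    eccentricity_from_pixels,
    mean_area,
    mean_nearest_distance,
    px_to_um,
    summarize_cohort,
    summarize_image,
    total_area,
)
from chromaquant.segmentation import ChromatinRegion
from chromaquant.synthesis import rasterize_ellipse
from helpers_oracles import flat_loop_cohort_stats, flat_loop_image_stats


def fake_region(area, centroid, ecc=0.3, region_id=0):
    return ChromatinRegion(
        id=region_id,
        pixels=np.zeros((1, 2), dtype=np.int64),
        area_px=area,
        centroid=centroid,
        eccentricity=ecc,
        birth_level=1,
    )


class TestAreas:
    def test_total_area_sums(self):
        regions = [fake_region(9, (0, 0)), fake_region(16, (5, 5))]
        assert total_area(regions) == 25
        assert total_area([]) == 0

    def test_mean_area(self):
        assert mean_area([fake_region(10, (0, 0))]) == 10
        assert mean_area(
            [fake_region(4, (0, 0)), fake_region(8, (3, 3))]
        ) == 6
        assert math.isnan(mean_area([]))


class TestDistances:
    def test_3_4_5_triangle(self):
        regions = [fake_region(1, (0.0, 0.0)), fake_region(1, (3.0, 4.0))]
        d = distance_matrix(regions)
        assert d[0, 1] == pytest.approx(5.0)
        assert mean_nearest_distance(d) == pytest.approx(5.0)

    def test_single_region(self):
        d = distance_matrix([fake_region(1, (2.0, 2.0))])
        assert d.shape == (1, 1) and d[0, 0] == 0
        assert math.isnan(mean_nearest_distance(d))

    def test_collinear_three_points(self):
        regions = [
            fake_region(1, (0.0, x)) for x in (0.0, 1.0, 10.0)
        ]
        # per-region nearest distances are 1, 1, 9
        assert mean_nearest_distance(distance_matrix(regions)) == (
            pytest.approx(11 / 3)
        )

    def test_symmetry_and_zero_diagonal(self, rng):
        regions = [
            fake_region(1, tuple(rng.uniform(0, 100, 2))) for _ in range(10)
        ]
        d = distance_matrix(regions)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_matches_exhaustive_scan(self, rng):
        pts = rng.uniform(0, 50, size=(20, 2))
        regions = [fake_region(1, tuple(p)) for p in pts]
        got = mean_nearest_distance(distance_matrix(regions))
        mins = []
        for i in range(20):
            mins.append(
                min(
                    math.dist(pts[i], pts[j])
                    for j in range(20)
                    if j != i
                )
            )
        assert got == pytest.approx(sum(mins) / 20, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 50, size=(8, 2))
        base = mean_nearest_distance(
            distance_matrix([fake_region(1, tuple(p)) for p in pts])
        )
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)],
             [math.sin(theta), math.cos(theta)]]
        )
        moved = pts @ rot.T + np.array([13.0, -4.0])
        assert mean_nearest_distance(
            distance_matrix([fake_region(1, tuple(p)) for p in moved])
        ) == pytest.approx(base)


class TestEccentricity:
    def test_rasterized_disc_is_nearly_circular(self):
        coords = rasterize_ellipse(
            (30, 30), math.pi * 100, 0.0, 0.0, (61, 61)
        )
        assert eccentricity_from_pixels(coords) < 0.05

    def test_thin_bar_approaches_one(self):
        bar = np.column_stack(
            [np.zeros(20, dtype=int), np.arange(20)]
        )
        e = eccentricity_from_pixels(bar)
        assert 0.99 < e < 1.0

    def test_single_pixel_is_zero(self):
        assert eccentricity_from_pixels(np.array([[3, 4]])) == 0.0

    def test_10_to_5_ellipse_near_analytic_value(self):
        rr, cc = np.mgrid[0:41, 0:41]
        inside = ((rr - 20) / 10.0) ** 2 + ((cc - 20) / 5.0) ** 2 <= 1
        coords = np.column_stack(np.nonzero(inside))
        e = eccentricity_from_pixels(coords)
        assert e == pytest.approx(math.sqrt(1 - 25 / 100), abs=0.02)
        # independent moment computation from scikit-image
        assert e == pytest.approx(
            measure.regionprops(measure.label(inside))[0].eccentricity,
            abs=0.01,
        )

    def test_invariant_under_rotations_and_flips(self):
        rr, cc = np.mgrid[0:31, 0:31]
        inside = ((rr - 15) / 9.0) ** 2 + ((cc - 15) / 4.0) ** 2 <= 1
        base = eccentricity_from_pixels(np.column_stack(np.nonzero(inside)))
        for transform in (np.rot90, np.fliplr, np.flipud):
            coords = np.column_stack(np.nonzero(transform(inside)))
            assert eccentricity_from_pixels(coords) == pytest.approx(base)

    def test_axis_ratio_is_literal_alternative(self):
        rr, cc = np.mgrid[0:41, 0:41]
        inside = ((rr - 20) / 10.0) ** 2 + ((cc - 20) / 5.0) ** 2 <= 1
        coords = np.column_stack(np.nonzero(inside))
        assert axis_ratio_from_pixels(coords) == pytest.approx(2.0, abs=0.1)


class TestSummaries:
    def test_empty_region_list_all_undefined(self):
        s = summarize_image([], level=1, image_id="a")
        assert s.n == 0
        assert math.isnan(s.mean_area_px)
        assert math.isnan(s.mean_nn_dist_px)
        assert math.isnan(s.mean_eccentricity)

    def test_single_region_distance_undefined(self):
        s = summarize_image([fake_region(12, (1, 1), 0.4)], 1, "a")
        assert s.n == 1
        assert s.mean_area_px == 12
        assert math.isnan(s.mean_nn_dist_px)
        assert s.mean_eccentricity == pytest.approx(0.4)

    def test_pooled_cohort_mean_not_mean_of_means(self):
        """Two images, A = {10, 20}, n = {1, 4}: pooled 30/5 = 6."""
        im1 = summarize_image([fake_region(10, (0, 0))], 1, "im1")
        regs = [
            fake_region(5, (0, 0)),
            fake_region(5, (9, 0)),
            fake_region(5, (0, 9)),
            fake_region(5, (9, 9)),
        ]
        im2 = summarize_image(regs, 1, "im2")
        c = summarize_cohort([im1, im2], 1)
        assert c.overall_mean_area_px == pytest.approx(6.0)
        assert c.overall_mean_area_px != pytest.approx(7.5)

    def test_pooled_mean_between_min_and_max_image_means(self, rng):
        summaries = []
        for i in range(6):
            regs = [
                fake_region(int(rng.integers(5, 60)),
                            tuple(rng.uniform(0, 80, 2)),
                            float(rng.uniform(0.1, 0.8)))
                for _ in range(rng.integers(1, 9))
            ]
            summaries.append(summarize_image(regs, 2, f"im{i}"))
        c = summarize_cohort(summaries, 2)
        means = [s.mean_area_px for s in summaries]
        assert min(means) <= c.overall_mean_area_px <= max(means)

    def test_matches_flat_loop_oracle(self, rng):
        """Image and cohort statistics agree with plain-loop recomputation
        to 1e-9 on random synthetic region sets."""
        for _ in range(10):
            image_stats = []
            summaries = []
            for i in range(rng.integers(1, 7)):
                triples = [
                    (
                        float(rng.integers(1, 80)),
                        tuple(rng.uniform(0, 100, 2)),
                        float(rng.uniform(0, 0.95)),
                    )
                    for _ in range(rng.integers(0, 9))
                ]
                regs = [
                    fake_region(int(a), c, e, j)
                    for j, (a, c, e) in enumerate(triples)
                ]
                s = summarize_image(regs, 3, f"im{i}")
                o = flat_loop_image_stats(triples)
                assert s.n == o["n"]
                assert s.total_area_px == pytest.approx(
                    o["total_area"], abs=1e-9
                )
                for got, want in [
                    (s.mean_area_px, o["mean_area"]),
                    (s.mean_nn_dist_px, o["mean_nn"]),
                    (s.mean_eccentricity, o["mean_ecc"]),
                ]:
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-9)
                image_stats.append(o)
                summaries.append(s)
            c = summarize_cohort(summaries, 3)
            oc = flat_loop_cohort_stats(image_stats)
            assert c.total_regions == oc["total_regions"]
            assert c.total_area_px == pytest.approx(
                oc["total_area"], abs=1e-9
            )
            for got, want in [
                (c.overall_mean_area_px, oc["pooled_mean_area"]),
                (c.overall_mean_nn_dist_px, oc["mean_nn"]),
                (c.overall_mean_eccentricity, oc["mean_ecc"]),
            ]:
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-9)


class TestUnitConversion:
    def test_published_length_calibration(self):
        assert px_to_um(15.88, 0.032, "length") == pytest.approx(
            0.508, abs=0.001
        )

    def test_zero_maps_to_zero(self):
        assert px_to_um(0, 0.032, "length") == 0

    def test_area_uses_squared_pixel_size(self):
        assert px_to_um(4229.43, 0.0506, "area") == pytest.approx(
            10.83, abs=0.01
        )

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError):
            px_to_um(1.0, 0.0)
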