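import numpy as np
import pytest

from nucscreen.nuclear_metrics import (
    NucleusContour,
    contour_curvature,
    extract_contour,
    intensity_metrics,
    segment_nuclei,
    shape_metrics,
)
from nucscreen.synthdata import SyntheticNucleusSpec


def circle_contour(r=50.0, center=(100.0, 100.0), n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return NucleusContour(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    )


def ellipse_contour(a=40.0, b=20.0, n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return NucleusContour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


def disk_image(centers, r=30, size=(256, 256), value=1000.0):
    yy, xx = np.mgrid[: size[0], : size[1]]
    img = np.zeros(size)
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value
    return img


class TestSegmentation:
    def test_blank_image_yields_no_nuclei(self):
        assert segment_nuclei(np.zeros((128, 128))).max() == 0

    def test_constant_image_yields_no_nuclei(self):
        assert segment_nuclei(np.full((128, 128), 7.0)).max() == 0

    def test_three_disks_recovered_with_centroids(self):
        centers = [(60, 60), (180, 60), (120, 180)]
        img = disk_image(centers, r=30)
        mask = segment_nuclei(img, min_area=500, max_area=15000)
        assert mask.max() == 3
        found = []
        for lab in range(1, 4):
            ys, xs = np.nonzero(mask == lab)
            found.append((xs.mean(), ys.mean()))
        for cx, cy in centers:
            d = min(np.hypot(fx - cx, fy - cy) for fx, fy in found)
            assert d < 1.0

    def test_border_touching_nucleus_excluded(self):
        img = disk_image([(0, 128)], r=30)
        assert segment_nuclei(img).max() == 0

    def test_area_filter(self):
        img = disk_image([(128, 128)], r=8)  # area ~201 px < default min 500
        assert segment_nuclei(img).max() == 0


class TestContour:
    def test_disk_perimeter(self):
        img = disk_image([(128, 128)], r=50)
        mask = segment_nuclei(img)
        c = extract_contour(mask, 1)
        assert c.polygon.length == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_absent_label_raises(self):
        img = disk_image([(128, 128)], r=50)
        mask = segment_nuclei(img)
        with pytest.raises(KeyError):
            extract_contour(mask, 99)

    def test_ellipse_area(self):
        yy, xx = np.mgrid[:256, :256]
        img = np.where(
            ((xx - 128) / 40.0) ** 2 + ((yy - 128) / 20.0) ** 2 <= 1, 1000.0, 0.0
        )
        mask = segment_nuclei(img)
        c = extract_contour(mask, 1)
        assert c.polygon.area == pytest.approx(np.pi * 40 * 20, rel=0.02)

    def test_contour_is_counterclockwise(self):
        c = circle_contour()
        x, y = c.points[:, 0], c.points[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        k = contour_curvature(circle_contour(r=50))
        assert np.all(np.abs(k - 1 / 50) / (1 / 50) < 0.05)
        assert k.std() < 0.1 * k.mean()

    def test_ellipse_tip_curvatures(self):
        k = contour_curvature(ellipse_contour(a=40, b=20))
        assert k.max() == pytest.approx(40 / 20**2, rel=0.10)
        assert k.min() == pytest.approx(20 / 40**2, rel=0.10)

    def test_window_larger_than_contour_raises(self):
        small = circle_contour(r=2.0, n=10)
        with pytest.raises(ValueError, match="window"):
            contour_curvature(small, smoothing_window=99)


class TestShapeMetrics:
    def test_circle_reference_values(self):
        m = shape_metrics(circle_contour(r=50))
        assert m["Circularity"] == pytest.approx(1.0, abs=0.03)
        assert m["Eccentricity"] == pytest.approx(0.0, abs=0.05)
        assert m["Solidity"] == pytest.approx(1.0, abs=0.01)
        assert m["Invaginations"] == 0
        assert m["Std of Curvature"] < 0.1 * m["Mean Curvature"]
        assert m["Tortuosity"] == pytest.approx(1.0, abs=0.03)

    def test_square_circularity(self):
        s = np.linspace(0, 100, 101)[:-1]
        pts = np.vstack(
            [
                np.column_stack([s, np.zeros_like(s)]),
                np.column_stack([100 * np.ones_like(s), s]),
                np.column_stack([100 - s, 100 * np.ones_like(s)]),
                np.column_stack([np.zeros_like(s), 100 - s]),
            ]
        )
        m = shape_metrics(NucleusContour(pts))
        assert m["Circularity"] == pytest.approx(4 / np.pi, abs=0.05)

    def test_ellipse_axes_and_eccentricity(self):
        m = shape_metrics(ellipse_contour(a=40, b=20))
        assert m["Major Axis Length"] == pytest.approx(80, rel=0.02)
        assert m["Minor Axis Length"] == pytest.approx(40, rel=0.02)
        assert m["Eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), rel=0.02)
        assert m["Area"] == pytest.approx(np.pi * 800, rel=0.02)

    def test_blebbed_shape_counts_lobes(self):
        for m_lobes in (3, 4, 5):
            spec = SyntheticNucleusSpec(
                center=(0, 0), a=50, b=50, lobe_count=m_lobes, lobe_amplitude=0.25
            )
            metrics = shape_metrics(NucleusContour(spec.boundary_points()))
            assert metrics["Invaginations"] >= 1
            assert metrics["Mean Negative Curvature"] < 0
            assert abs(metrics["Invaginations"] - m_lobes) <= 1

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_scale_equivariance(self, s):
        base = shape_metrics(ellipse_contour(a=40, b=25))
        scaled = shape_metrics(
            NucleusContour(ellipse_contour(a=40, b=25).points * s)
        )
        assert scaled["Area"] == pytest.approx(base["Area"] * s**2, rel=0.02)
        assert scaled["Perimeter"] == pytest.approx(base["Perimeter"] * s, rel=0.02)
        assert scaled["Major Axis Length"] == pytest.approx(
            base["Major Axis Length"] * s, rel=0.02
        )
        assert scaled["Mean Curvature"] == pytest.approx(
            base["Mean Curvature"] / s, rel=0.02
        )
        for invariant in ("Circularity", "Eccentricity", "Solidity", "Tortuosity"):
            assert scaled[invariant] == pytest.approx(base[invariant], rel=0.02)
        assert scaled["Invaginations"] == base["Invaginations"]

    @pytest.mark.parametrize("deg", [30, 60, 90, 150])
    def test_rotation_invariance(self, deg):
        spec = SyntheticNucleusSpec(
            center=(0, 0), a=45, b=25, lobe_count=4, lobe_amplitude=0.15
        )
        pts = spec.boundary_points()
        th = np.radians(deg)
        rot = pts @ np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]).T
        base = shape_metrics(NucleusContour(pts))
        rotated = shape_metrics(NucleusContour(rot))
        for name, v in base.items():
            if name == "Invaginations":
                assert abs(rotated[name] - v) <= 1
            elif abs(v) > 1e-12:
                assert rotated[name] == pytest.approx(v, rel=0.02), name


class TestIntensityMetrics:
    def test_uniform_image(self):
        img = disk_image([(128, 128)], r=40, value=1.0)
        mask = (img > 0).astype(np.int32)
        channel = np.full_like(img, 17.0)
        m = intensity_metrics(mask, 1, channel)
        assert m["Mean Intensity"] == pytest.approx(17.0)
        assert m["Std of Intensity"] == pytest.approx(0.0, abs=1e-12)
        assert m["BP Intensity"] == pytest.approx(17.0)

    def test_boundary_band_value(self):
        """Ring image: interior 10, 2-px boundary band at 20."""
        from scipy import ndimage as ndi
        from skimage.morphology import disk as disk_fp

        img = disk_image([(100, 100)], r=40, value=1.0)
        region = img > 0
        mask = region.astype(np.int32)
        band = region & ~ndi.binary_erosion(region, disk_fp(2))
        channel = np.where(band, 20.0, np.where(region, 10.0, 0.0))
        m = intensity_metrics(mask, 1, channel)
        assert m["BP Intensity"] == pytest.approx(20.0, rel=0.05)
        # interior mean pulled up only by the band-area fraction (~10%)
        assert 10.0 <= m["Mean Intensity"] < 13.0

    def test_focus_increases_std(self):
        img = disk_image([(128, 128)], r=40, value=1.0)
        mask = (img > 0).astype(np.int32)
        flat = np.full_like(img, 10.0)
        focal = flat.copy()
        focal[125:131, 125:131] += 50.0
        assert (
            intensity_metrics(mask, 1, focal)["Std of Intensity"]
            > intensity_metrics(mask, 1, flat)["Std of Intensity"]
        )

    def test_dimension_mismatch_raises(self):
        mask = np.ones((10, 10), dtype=np.int32)
        with pytest.raises(ValueError, match="shape"):
            intensity_metrics(mask, 1, np.zeros((5, 5)))

    def test_invariant_to_other_labels(self, rng):
        img = disk_image([(60, 60), (180, 180)], r=30, value=1.0)
        mask = segment_nuclei(disk_image([(60, 60), (180, 180)], r=30))
        channel = rng.random(img.shape) * 100
        before = intensity_metrics(mask, 1, channel)
        relabeled = np.where(mask == 2, 7, mask)
        after = intensity_metrics(relabeled, 1, channel)
        assert before == after
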