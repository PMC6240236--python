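import numpy as np
import pandas as pd
import pytest

from nucscreen.boundary import (
    Boundary,
    boundary_angle,
    bootstrap_stability,
    group_importance,
    metric_importance,
    project_sample_shift,
    signed_distance,
    train_boundary,
)
from nucscreen.io_model import ChannelSpec, ContractError
from nucscreen.reference_cells import Normalization, fit_normalization
from nucscreen.synthdata import default_class_params, sample_two_class


def identity_norm(names):
    return Normalization(
        center=pd.Series(0.0, index=names), scale=pd.Series(1.0, index=names)
    )


@pytest.fixture()
def gaussian_2d(rng):
    h = pd.DataFrame(rng.normal([2.0, 0.0], 1.0, size=(300, 2)), columns=["m1", "m2"])
    p = pd.DataFrame(rng.normal([-2.0, 0.0], 1.0, size=(300, 2)), columns=["m1", "m2"])
    return h, p


class TestTrainBoundary:
    def test_symmetric_1d(self):
        h = pd.DataFrame({"m": [1.0, 1.0, 1.0]})
        p = pd.DataFrame({"m": [-1.0, -1.0, -1.0]})
        b = train_boundary(h, p, identity_norm(["m"]))
        assert b.w[0] == pytest.approx(1.0)
        assert b.b == pytest.approx(0.0, abs=1e-9)

    def test_informative_metric_dominates(self, gaussian_2d):
        h, p = gaussian_2d
        norm = fit_normalization(h, p, ["m1", "m2"])
        b = train_boundary(h, p, norm)
        assert abs(b.w[0]) > 0.95
        assert abs(b.w[1]) < 0.3

    def test_direction_close_to_lda(self, gaussian_2d):
        """Independent cross-check: the SVM normal should agree with the
        LDA discriminant direction to within 10 degrees."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        h, p = gaussian_2d
        norm = fit_normalization(h, p, ["m1", "m2"])
        b = train_boundary(h, p, norm)
        x = np.vstack([norm.apply(h), norm.apply(p)])
        y = np.r_[np.ones(len(h)), -np.ones(len(p))]
        lda = LinearDiscriminantAnalysis().fit(x, y)
        assert boundary_angle(b.w, lda.coef_.ravel()) < 10.0

    def test_label_swap_flips_boundary(self, gaussian_2d):
        h, p = gaussian_2d
        norm = fit_normalization(h, p, ["m1", "m2"])
        b1 = train_boundary(h, p, norm)
        b2 = train_boundary(p, h, norm)  # classes swapped
        # sign convention re-orients both to healthy-positive; the swapped
        # training must therefore produce the exact negated raw plane,
        # i.e. an identical stored boundary up to the convention flip
        np.testing.assert_allclose(b1.w, -b2.w, atol=1e-3)
        assert b1.b == pytest.approx(-b2.b, abs=1e-3)

    def test_degenerate_training_rejected(self):
        h = pd.DataFrame({"m": [1.0, 1.0]})
        p = pd.DataFrame({"m": [1.0, 1.0]})
        with pytest.raises(Exception):
            train_boundary(h, p, identity_norm(["m"]))

    def test_typical_healthy_core_scores_positive(self, channel_spec):
        """With separable classes virtually the whole healthy core lies on
        the positive side of the trained boundary."""
        params = default_class_params(channel_spec, strong_delta=4.0)
        healthy, progeria = sample_two_class(2000, params, 55)
        from nucscreen.reference_cells import select_typical

        th = select_typical(healthy, "progerin", 300, channel_spec)
        tp = select_typical(progeria, "progerin", 300, channel_spec)
        core_h = healthy.loc[th.cell_indices]
        core_p = progeria.loc[tp.cell_indices]
        metrics = list(channel_spec.metrics_of("progerin"))
        norm = fit_normalization(core_h, core_p, metrics)
        b = train_boundary(core_h, core_p, norm, channel="progerin")
        assert (b.signed_distances(core_h) > 0).mean() >= 0.99


class TestSignedDistance:
    def test_cell_on_boundary(self):
        b = Boundary(["m"], np.array([1.0]), 0.0, identity_norm(["m"]))
        assert signed_distance({"m": 0.0}, b) == pytest.approx(0.0)

    def test_1d_distance_value(self):
        b = Boundary(["m"], np.array([1.0]), 0.0, identity_norm(["m"]))
        assert signed_distance({"m": 3.0}, b) == pytest.approx(3.0)

    def test_reflection_antisymmetry(self, rng):
        names = ["a", "b", "c"]
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        b = Boundary(names, w, 0.3, identity_norm(names))
        for _ in range(20):
            x = rng.normal(size=3)
            d = signed_distance(dict(zip(names, x)), b)
            x_ref = x - 2 * (x @ b.w + b.b) * b.w
            d_ref = signed_distance(dict(zip(names, x_ref)), b)
            assert d_ref == pytest.approx(-d, abs=1e-9)

    def test_missing_metric_rejected(self):
        b = Boundary(["m"], np.array([1.0]), 0.0, identity_norm(["m"]))
        with pytest.raises(ContractError):
            signed_distance({"other": 1.0}, b)


class TestBoundaryAngle:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [
            ((1.0, 0.0), (1.0, 0.0), 0.0),
            ((1.0, 0.0), (0.0, 1.0), 90.0),
            ((1.0, 0.0), (1.0, 1.0), 45.0),
            ((1.0, 0.0), (-1.0, 0.0), 0.0),  # orientation flip folded away
        ],
    )
    def test_examples(self, v1, v2, expected):
        assert boundary_angle(np.array(v1), np.array(v2)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_subspace_restriction(self):
        w1 = {"a": 1.0, "b": 0.0, "c": 5.0}
        w2 = {"a": 1.0, "b": 1.0, "c": -5.0}
        # restricted to (a, b) the angle is 45 degrees regardless of c
        assert boundary_angle(w1, w2, subspace_metrics=["a", "b"]) == pytest.approx(45.0)

    def test_zero_restriction_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            boundary_angle({"a": 0.0, "b": 1.0}, {"a": 1.0, "b": 1.0},
                           subspace_metrics=["a"])


class TestImportance:
    def test_single_metric(self):
        b = Boundary(["a", "b", "c"], np.array([1.0, 0.0, 0.0]), 0.0,
                     identity_norm(["a", "b", "c"]))
        assert metric_importance(b) == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_group_shares(self):
        names = ["a1", "a2", "b1", "b2"]
        b = Boundary(names, np.array([0.5, 0.5, 0.5, 0.5]), 0.0, identity_norm(names))
        spec = ChannelSpec({"A": ("a1", "a2"), "B": ("b1", "b2")})
        shares = group_importance(b, spec)
        assert shares["A"] == pytest.approx(0.5)
        assert shares["B"] == pytest.approx(0.5)

    def test_shares_sum_to_one(self, rng):
        names = [f"m{i}" for i in range(7)]
        b = Boundary(names, rng.normal(size=7), 0.1, identity_norm(names))
        assert sum(metric_importance(b).values()) == pytest.approx(1.0)


class TestProjection:
    def test_mean_along_normal(self, rng):
        names = ["a", "b", "c"]
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        b = Boundary(names, w, 0.0, identity_norm(names))
        cells = pd.DataFrame([dict(zip(names, 2.5 * w))])
        perp, par = project_sample_shift(cells, b)
        assert perp == pytest.approx(2.5)
        assert par == pytest.approx(0.0, abs=1e-9)

    def test_mean_orthogonal_to_normal(self):
        names = ["a", "b"]
        b = Boundary(names, np.array([1.0, 0.0]), 0.0, identity_norm(names))
        cells = pd.DataFrame([{"a": 0.0, "b": 4.0}])
        perp, par = project_sample_shift(cells, b)
        assert perp == pytest.approx(0.0, abs=1e-12)
        assert par == pytest.approx(4.0)

    def test_pythagoras(self, rng):
        names = ["a", "b", "c", "d"]
        w = rng.normal(size=4)
        b = Boundary(names, w, 0.0, identity_norm(names))
        for _ in range(20):
            cells = pd.DataFrame(rng.normal(size=(5, 4)), columns=names)
            perp, par = project_sample_shift(cells, b)
            m = cells.mean().to_numpy()
            assert perp**2 + par**2 == pytest.approx(m @ m, abs=1e-9)


class TestBootstrapStability:
    def test_deterministic_under_seed(self, channel_spec, class_params):
        h, p = sample_two_class(500, class_params, 5)
        a = bootstrap_stability(h, p, channel_spec, "random", n_cells=100,
                                n_bootstrap=10, seed=11)
        b = bootstrap_stability(h, p, channel_spec, "random", n_cells=100,
                                n_bootstrap=10, seed=11)
        for ch in channel_spec.channel_names:
            np.testing.assert_array_equal(a.angles[ch], b.angles[ch])

    def test_angles_in_range(self, channel_spec, class_params):
        h, p = sample_two_class(500, class_params, 6)
        rep = bootstrap_stability(h, p, channel_spec, "typical", n_cells=100,
                                  n_bootstrap=10, seed=2)
        for ch, a in rep.angles.items():
            assert len(a) == 10
            assert np.all((a >= 0) & (a <= 90))

    def test_oversized_sample_rejected(self, channel_spec, class_params):
        h, p = sample_two_class(50, class_params, 7)
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_stability(h, p, channel_spec, "random", n_cells=100,
                                n_bootstrap=5)

    def test_point_mass_classes_give_zero_angles(self, channel_spec):
        names = list(channel_spec.metric_names)
        rngl = np.random.default_rng(0)
        # two tight, perfectly separated clusters: negligible sampling noise
        h = pd.DataFrame(
            1e-6 * rngl.normal(size=(200, len(names))) + 1.0, columns=names
        )
        p = pd.DataFrame(
            1e-6 * rngl.normal(size=(200, len(names))) - 1.0, columns=names
        )
        rep = bootstrap_stability(h, p, channel_spec, "random", n_cells=50,
                                  n_bootstrap=5, seed=3)
        for a in rep.angles.values():
            assert np.all(a < 1.0)


def test_boundary_json_roundtrip(tmp_path, gaussian_2d):
    h, p = gaussian_2d
    norm = fit_normalization(h, p, ["m1", "m2"])
    b = train_boundary(h, p, norm, channel="progerin")
    path = tmp_path / "b.json"
    b.to_json(path)
    back = Boundary.from_json(path)
    np.testing.assert_allclose(back.w, b.w)
    assert back.b == pytest.approx(b.b)
    cells = h.head(5)
    np.testing.assert_allclose(back.signed_distances(cells), b.signed_distances(cells))
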