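"""Superimposition geometry: centroid size, pairwise fits, GPA,
sliding, unbending and outlier flagging."""
import dataclasses

import numpy as np
import pytest

import gmrepro as g
from gmrepro.base import LandmarkScheme, ShapeDataset
from gmrepro.gpa import _rot


def _random_similarity(rng, coords):
    """Apply an independent random rotation/translation/scaling per row."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        theta = rng.uniform(-np.pi, np.pi)
        s = rng.uniform(0.2, 5.0)
        t = rng.uniform(-100, 100, size=2)
        out[i] = s * coords[i] @ _rot(theta).T + t
    return out


def _fixed_only_scheme(k):
    return LandmarkScheme(n_landmarks=k, fixed=frozenset(range(1, k + 1)),
                         semi=frozenset(), slide_neighbours={})


class TestCentroidSize:
    def test_unit_square(self):
        pts = np.array([(1, 1), (1, -1), (-1, 1), (-1, -1)], float)
        assert g.centroid_size(pts) == pytest.approx(2 * np.sqrt(2))

    def test_homogeneity(self, template):
        assert g.centroid_size(3.0 * template) == pytest.approx(3 * g.centroid_size(template))

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(22, 2))
        direct = np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum())
        assert g.centroid_size(pts) == pytest.approx(direct, rel=1e-12)

    def test_translation_rotation_invariant(self, rng, template):
        moved = template @ _rot(0.3).T + np.array([5.0, -2.0])
        assert g.centroid_size(moved) == pytest.approx(g.centroid_size(template))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            g.centroid_size(np.ones((5, 2)))


class TestFitPair:
    def test_recovers_pure_rotation(self, template):
        moving = template @ _rot(np.deg2rad(30)).T
        fit = g.fit_pair(moving, template)
        assert fit.angle_deg == pytest.approx(-30, abs=1e-9)
        assert fit.residual == pytest.approx(0, abs=1e-12)

    def test_identity_for_equal_configs(self, template):
        fit = g.fit_pair(template, template)
        assert fit.angle == pytest.approx(0, abs=1e-12)
        assert fit.scale == pytest.approx(1, abs=1e-12)
        np.testing.assert_allclose(fit.translation, 0, atol=1e-12)
        assert fit.residual == pytest.approx(0, abs=1e-12)

    def test_residual_matches_dense_rotation_grid(self, rng):
        """The returned residual equals the minimum over a 0.001-degree
        grid of rotations of the unit-size centred difference norm."""
        X = rng.normal(size=(10, 2))
        Y = rng.normal(size=(10, 2))
        fit = g.fit_pair(X, Y)
        Xc = (X - X.mean(0)) / g.centroid_size(X)
        Yc = (Y - Y.mean(0)) / g.centroid_size(Y)
        dot = (Xc * Yc).sum()
        cross = (Xc[:, 0] * Yc[:, 1] - Xc[:, 1] * Yc[:, 0]).sum()
        thetas = np.deg2rad(np.arange(0, 360, 0.001))
        # |Y - R(theta) X|^2 expands to 2 - 2(cos*dot + sin*cross)
        d2 = 2.0 - 2.0 * (np.cos(thetas) * dot + np.sin(thetas) * cross)
        assert fit.residual == pytest.approx(np.sqrt(d2.min()), abs=1e-7)

    def test_k_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            g.fit_pair(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))

    def test_full_similarity_recovered(self, rng, template):
        theta, s, t = 0.8, 2.5, np.array([3.0, -7.0])
        moving = (template - t) @ _rot(-theta).T / s
        fit = g.fit_pair(moving, template)
        recovered = fit.scale * moving @ fit.rotation.T + fit.translation
        np.testing.assert_allclose(recovered, template, atol=1e-9)


class TestProcrustesDistance:
    def test_zero_for_identical(self, template):
        assert g.procrustes_distance(template, template) == 0.0

    def test_three_four_five(self, template):
        b = template.copy()
        b[0] += (0.003, 0.004)
        assert g.procrustes_distance(template, b) == pytest.approx(0.005)

    def test_consistent_with_fit_pair_residual(self, rng):
        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=(8, 2))
        fit = g.fit_pair(X, Y)
        Xc = (X - X.mean(0)) / g.centroid_size(X)
        Yc = (Y - Y.mean(0)) / g.centroid_size(Y)
        aligned = Xc @ fit.rotation.T
        assert g.procrustes_distance(aligned, Yc) == pytest.approx(fit.residual, rel=1e-10)


class TestSliding:
    def test_tangential_displacement_removed(self, template, scheme):
        config = template.copy()
        s0 = scheme.semi0[0]
        tangent = template[scheme.next0[0]] - template[scheme.prev0[0]]
        tangent /= np.linalg.norm(tangent)
        config[s0] += 0.05 * tangent
        slid = g.slide_semilandmarks(config, template, scheme)
        assert np.linalg.norm(slid[s0] - template[s0]) < 1e-10

    def test_perpendicular_displacement_untouched(self, template, scheme):
        config = template.copy()
        s0 = scheme.semi0[0]
        tangent = template[scheme.next0[0]] - template[scheme.prev0[0]]
        tangent /= np.linalg.norm(tangent)
        normal = np.array([-tangent[1], tangent[0]])
        config[s0] += 0.05 * normal
        slid = g.slide_semilandmarks(config, template, scheme)
        np.testing.assert_allclose(slid[s0], config[s0], atol=1e-12)

    def test_random_displacement_matches_grid_minimum(self, rng, template, scheme):
        config = template + rng.normal(0, 0.01, size=template.shape)
        slid = g.slide_semilandmarks(config, template, scheme)
        for j, s0 in enumerate(scheme.semi0):
            tangent = config[scheme.next0[j]] - config[scheme.prev0[j]]
            tangent /= np.linalg.norm(tangent)
            ts = np.linspace(-0.1, 0.1, 20001)
            cand = config[s0][None] + ts[:, None] * tangent[None]
            d2 = ((cand - template[s0]) ** 2).sum(axis=1)
            best = np.sqrt(d2.min())
            ours = np.linalg.norm(slid[s0] - template[s0])
            assert ours <= best + 1e-9

    def test_fixed_landmarks_never_move(self, rng, template, scheme):
        config = template + rng.normal(0, 0.01, size=template.shape)
        slid = g.slide_semilandmarks(config, template, scheme)
        fixed0 = sorted(set(range(22)) - set(scheme.semi0))
        np.testing.assert_array_equal(slid[fixed0], config[fixed0])

    def test_coincident_neighbours_warn_and_skip(self, template, scheme, caplog):
        config = template.copy()
        config[scheme.prev0[0]] = config[scheme.next0[0]]
        with caplog.at_level("WARNING"):
            slid = g.slide_semilandmarks(config, template, scheme)
        assert "tangent" in caplog.text
        np.testing.assert_array_equal(slid[scheme.semi0[0]], config[scheme.semi0[0]])


class TestGPA:
    def test_copies_of_one_shape_align_exactly(self, rng, template, scheme):
        coords = np.repeat(template[None], 12, axis=0)
        coords = _random_similarity(rng, coords)
        import pandas as pd
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": [f"s{i}" for i in range(12)],
                          "group": "A", "operator": "Op.1", "trial": 1}),
            scheme,
        ).drop_excluded()
        fit = g.gpa(ds)
        d = fit.aligned - fit.aligned[0]
        assert np.sqrt((d ** 2).sum(axis=(1, 2))).max() < 1e-8

    def test_two_shape_consensus_is_equidistant(self, rng):
        scheme = _fixed_only_scheme(10)
        import pandas as pd
        coords = rng.normal(size=(2, 10, 2))
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": ["a", "b"], "group": "A",
                          "operator": "Op.1", "trial": 1}),
            scheme,
        )
        fit = g.gpa(ds)
        d0 = g.procrustes_distance(fit.aligned[0], fit.consensus)
        d1 = g.procrustes_distance(fit.aligned[1], fit.consensus)
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_slide_flag_is_noop_without_semis(self, rng):
        scheme = _fixed_only_scheme(8)
        import pandas as pd
        coords = rng.normal(size=(6, 8, 2))
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": [f"s{i}" for i in range(6)],
                          "group": "A", "operator": "Op.1", "trial": 1}),
            scheme,
        )
        a = g.gpa(ds, slide=True)
        b = g.gpa(ds, slide=False)
        np.testing.assert_allclose(a.aligned, b.aligned, atol=1e-12)

    def test_similarity_invariance(self, rng, small_data):
        """GPA output is invariant (1e-6) under arbitrary per-specimen
        similarity transforms of the input."""
        ds, _ = small_data
        sub = g.unbend(ds).drop_excluded().where(operator="Op.1", trial=1)
        transformed = ShapeDataset(
            _random_similarity(rng, sub.coords), sub.factors, sub.scheme
        )
        a = g.gpa(sub)
        b = g.gpa(transformed)
        assert np.abs(a.aligned - b.aligned).max() < 1e-6

    def test_mean_of_aligned_equals_consensus(self, rng):
        scheme = _fixed_only_scheme(12)
        import pandas as pd
        coords = rng.normal(size=(30, 12, 2))
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": [f"s{i}" for i in range(30)],
                          "group": "A", "operator": "Op.1", "trial": 1}),
            scheme,
        )
        fit = g.gpa(ds, slide=False)
        assert fit.converged
        np.testing.assert_allclose(fit.aligned.mean(axis=0), fit.consensus, atol=1e-8)
        assert g.centroid_size(fit.consensus) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(fit.aligned.mean(axis=1), 0, atol=1e-8)

    def test_centroid_sizes_in_original_units(self, rng, template, scheme):
        import pandas as pd
        coords = np.stack([2.0 * template, 5.0 * template])
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": ["a", "b"], "group": "A",
                          "operator": "Op.1", "trial": 1}),
            scheme,
        ).drop_excluded()
        fit = g.gpa(ds)
        kept = scheme.kept0
        np.testing.assert_allclose(
            fit.centroid_sizes,
            [2.0 * g.centroid_size(template[kept]), 5.0 * g.centroid_size(template[kept])],
            rtol=1e-12,
        )

    def test_needs_two_configurations(self, template, scheme):
        import pandas as pd
        ds = ShapeDataset(
            template[None],
            pd.DataFrame({"specimen_id": ["a"], "group": "A",
                          "operator": "Op.1", "trial": 1}),
            scheme,
        ).drop_excluded()
        with pytest.raises(ValueError, match="at least two"):
            g.gpa(ds)


class TestUnbend:
    def _dataset_from(self, coords, scheme):
        import pandas as pd
        n = coords.shape[0]
        return ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": [f"s{i}" for i in range(n)],
                          "group": "A", "operator": "Op.1", "trial": 1}),
            scheme,
        )

    def test_parabolic_references_become_collinear(self, template, scheme):
        # arch centred on the reference chord so the references lie on a
        # parabola in the frame the fit sees
        xc = 0.5 * (template[0, 0] + template[16, 0])
        arched = template.copy()
        arched[:, 1] += 0.3 * (arched[:, 0] - xc) ** 2
        ds = self._dataset_from(arched[None], scheme)
        out = g.unbend(ds)
        refs = out.coords[0][scheme.unbend0]
        # residual of the best line through the reference landmarks
        x, y = refs[:, 0], refs[:, 1]
        fit = np.polyfit(x, y, 1)
        assert np.abs(y - np.polyval(fit, x)).max() < 1e-10

    def test_straight_configuration_unchanged(self, template, scheme):
        rotated = template @ _rot(0.7).T + np.array([3.0, 4.0])
        ds = self._dataset_from(rotated[None], scheme)
        out = g.unbend(ds)
        assert np.abs(out.coords[0] - rotated).max() < 1e-10

    def test_recovers_unarched_truth(self):
        """On data generated with known quadratic arching (and no other
        error), unbending shrinks the distance to the truth by >= 90%."""
        spec = g.SyntheticSpec(
            n_per_group={"Spey": 10, "Oykel": 10}, n_replicate_per_group=2,
            operator_bias_magnitude=0.0, trial_noise_sd=0.0, seed=3,
        )
        ds, truth = g.simulate_dataset(spec)
        sub = ds.where(operator="Op.1", trial=1)
        unbent = g.unbend(sub)
        rows = sub.factors["specimen_id"].tolist()
        truth_shapes = {
            r["specimen_id"]: truth.true_shapes[i]
            for i, r in truth.specimens.iterrows()
        }
        before, after = [], []
        for i, sid in enumerate(rows):
            t = truth_shapes[sid]
            before.append(g.fit_pair(sub.coords[i], t).residual)
            after.append(g.fit_pair(unbent.coords[i], t).residual)
        before, after = np.array(before), np.array(after)
        assert np.sqrt((after ** 2).mean()) < 0.1 * np.sqrt((before ** 2).mean())

    def test_too_few_references(self, template):
        scheme = g.salmon_scheme()
        short = type(scheme)(
            n_landmarks=22, fixed=scheme.fixed, semi=scheme.semi,
            slide_neighbours=scheme.slide_neighbours, unbend=(1, 17),
            excluded=scheme.excluded,
        )
        ds = self._dataset_from(template[None], short)
        with pytest.raises(ValueError, match="reference"):
            g.unbend(ds)


class TestOutliers:
    def _fit(self, coords, scheme):
        import pandas as pd
        n = coords.shape[0]
        ds = ShapeDataset(
            coords,
            pd.DataFrame({"specimen_id": [f"s{i}" for i in range(n)],
                          "group": "A", "operator": "Op.1", "trial": 1}),
            scheme,
        )
        return g.gpa(ds, slide=False)

    def test_identical_configs_no_flags(self, template):
        scheme = _fixed_only_scheme(22)
        coords = np.repeat(template[None], 10, axis=0)
        rep = self._fit(coords, scheme).flag_outliers()
        assert rep.flagged.size == 0
        np.testing.assert_allclose(rep.distances, 0, atol=1e-12)

    def test_gross_displacement_is_flagged(self, rng, template):
        scheme = _fixed_only_scheme(22)
        coords = np.repeat(template[None], 100, axis=0)
        coords += rng.normal(0, 1e-4, size=coords.shape)
        coords[17, 0] += 10.0    # one landmark displaced by ~10 units
        rep = self._fit(coords, scheme).flag_outliers()
        assert 17 in rep.flagged

    def test_infinite_k_flags_nothing(self, rng, template):
        scheme = _fixed_only_scheme(22)
        coords = np.repeat(template[None], 20, axis=0)
        coords += rng.normal(0, 0.01, size=coords.shape)
        rep = self._fit(coords, scheme).flag_outliers(k_iqr=np.inf)
        assert rep.flagged.size == 0
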