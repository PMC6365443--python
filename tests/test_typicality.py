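import numpy as np
import pytest

from ctdm.errors import GroupError, UndefinedAxisError
from ctdm.pipeline import score_sample
from ctdm.superimposition import GPAResult, gpa
from ctdm.synthetic import simulate_two_group_sample, study1_preset
from ctdm.typicality import (
    ANCHOR_ORDER,
    TypicalityScores,
    composite_shape,
    ctdm_scores,
    dfim_scores,
    dfom_scores,
    group_means,
    select_composite_anchors,
    tps_deformation_grid,
)


def make_result(flat_configs, ids=None):
    """Wrap raw (n, k, 2) arrays as a GPAResult for direct score testing."""
    aligned = np.asarray(flat_configs, float)
    return GPAResult(
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=np.ones(len(aligned)),
        iterations=1,
        converged=True,
        specimen_ids=ids,
    )


@pytest.fixture
def two_group_result(rng):
    """Two clearly separated synthetic groups in a flat shape space."""
    base = rng.normal(size=(6, 2)) * 0.2
    offset = np.zeros((6, 2))
    offset[0, 0] = 0.05
    a = base + 0.01 * rng.normal(size=(20, 6, 2))
    b = base + offset + 0.01 * rng.normal(size=(20, 6, 2))
    labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
    return make_result(np.concatenate([a, b])), labels


class TestGroupMeans:
    def test_identical_shapes(self, rng):
        shape = rng.normal(size=(4, 2))
        res = make_result(np.stack([shape] * 3))
        means = group_means(res, ["g"] * 3)
        np.testing.assert_allclose(means["g"], shape)

    def test_two_specimens_midpoint(self, rng):
        a, b = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        res = make_result(np.stack([a, b]))
        means = group_means(res, ["g", "g"])
        np.testing.assert_allclose(means["g"], (a + b) / 2)

    def test_generative_mean_recovery(self):
        spec = study1_preset(seed=5)
        spec.n_per_group = (200, 200)
        sample, _ = simulate_two_group_sample(spec)
        res, scores = score_sample(sample, "CZ", "TR")
        # recovered separation within 3 standard errors of the truth
        d = spec.basis.shape[1]
        se = np.sqrt(sum(spec.noise_sd[g] ** 2 for g in spec.groups) / 200 * d)
        assert abs(scores.pdm - spec.delta) < 3 * se


class TestCTDMScores:
    def test_endpoint_property(self, two_group_result):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B")
        pdm = s.pdm
        flat_a, flat_b = s.mean_a.ravel(), s.mean_b.ravel()
        origin = s.origin.ravel()
        assert (flat_a - origin) @ s.direction == pytest.approx(-pdm / 2, abs=1e-10)
        assert (flat_b - origin) @ s.direction == pytest.approx(+pdm / 2, abs=1e-10)

    def test_origin_scores_zero(self, two_group_result):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B")
        assert float((s.origin.ravel() - s.origin.ravel()) @ s.direction) == 0.0

    def test_orthogonal_component_leaves_score_unchanged(self, two_group_result, rng):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B")
        v = rng.normal(size=s.direction.shape)
        v -= (v @ s.direction) * s.direction
        x = res.flat[3]
        score = (x - s.origin.ravel()) @ s.direction
        score_moved = (x + v - s.origin.ravel()) @ s.direction
        assert score_moved == pytest.approx(score, abs=1e-10)
        # while the distance from the outgroup mean does change
        d0 = np.linalg.norm(x - s.mean_b.ravel())
        d1 = np.linalg.norm(x + v - s.mean_b.ravel())
        assert d1 > d0

    def test_swap_negates_scores(self, two_group_result):
        res, labels = two_group_result
        s1 = ctdm_scores(res, labels, "A", "B")
        s2 = ctdm_scores(res, labels, "B", "A")
        np.testing.assert_allclose(s2.ctdm, -s1.ctdm, atol=1e-12)
        np.testing.assert_allclose(s2.dfom, s1.dfom, atol=1e-12)
        np.testing.assert_allclose(s2.dfim, s1.dfim, atol=1e-12)

    def test_coincident_means_error(self, rng):
        shape = rng.normal(size=(4, 2))
        res = make_result(np.stack([shape] * 4))
        with pytest.raises(UndefinedAxisError):
            ctdm_scores(res, ["A", "A", "B", "B"], "A", "B")

    def test_pooled_origin_option(self, two_group_result):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B", origin="pooled")
        np.testing.assert_allclose(s.origin, res.aligned.mean(axis=0))


class TestDistances:
    def test_outgroup_mean_scores_zero(self, two_group_result):
        res, labels = two_group_result
        means = group_means(res, labels)
        res.aligned[0] = means["B"]  # plant a specimen at the outgroup mean
        d = dfom_scores(res, labels, "B")
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_pythagorean_decomposition(self, two_group_result):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B")
        d = dfom_scores(res, labels, "B")
        ctdm_of_mean_b = s.pdm / 2
        for i in range(res.n_specimens):
            x = res.flat[i] - s.origin.ravel()
            along = x @ s.direction
            resid = x - along * s.direction - (s.mean_b.ravel() - s.origin.ravel() - ctdm_of_mean_b * s.direction)
            orth2 = np.linalg.norm(res.flat[i] - s.mean_b.ravel()) ** 2 - (along - ctdm_of_mean_b) ** 2
            assert d[i] ** 2 == pytest.approx((along - ctdm_of_mean_b) ** 2 + orth2, abs=1e-10)

    def test_metrics_agree_for_small_distances(self):
        spec = study1_preset(seed=11)
        sample, _ = simulate_two_group_sample(spec)
        res, _ = score_sample(sample, "CZ", "TR")
        labels = sample.groups
        te = dfom_scores(res, labels, "CZ", metric="tangent-euclidean")
        pr = dfom_scores(res, labels, "CZ", metric="procrustes")
        assert np.all(te < 0.1)
        np.testing.assert_allclose(te, pr, rtol=0.01)

    def test_dfim_zero_at_ingroup_mean(self, rng):
        # group built as {m, m+v, m-v} so specimen 0 sits exactly at the mean
        m = rng.normal(size=(4, 2))
        v = rng.normal(size=(4, 2))
        res = make_result(np.stack([m, m + v, m - v, m + 1.0]))
        labels = np.array(["A", "A", "A", "B"], dtype=object)
        d = dfim_scores(res, labels)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_dfim_consistent_with_disparity(self, two_group_result):
        from ctdm.inference import morphological_disparity

        res, labels = two_group_result
        d = dfim_scores(res, labels)
        disp = morphological_disparity(res, labels, n_perm=99, seed=0)
        for g in ("A", "B"):
            assert np.mean(d[labels == g] ** 2) == pytest.approx(disp.md[g], abs=1e-12)

    def test_unknown_outgroup_errors(self, two_group_result):
        res, labels = two_group_result
        with pytest.raises(GroupError):
            dfom_scores(res, labels, "Z")


class TestCompositeAnchors:
    def _scores(self, vals_a, vals_b):
        n = len(vals_a) + len(vals_b)
        ids = [f"a{i}" for i in range(len(vals_a))] + [f"b{i}" for i in range(len(vals_b))]
        return TypicalityScores(
            specimen_ids=ids,
            group=np.array(["A"] * len(vals_a) + ["B"] * len(vals_b), dtype=object),
            ctdm=np.array(vals_a + vals_b, float),
            dfom=np.zeros(n),
            dfim=np.zeros(n),
            mean_a=np.zeros((2, 2)),
            mean_b=np.ones((2, 2)),
            direction=np.array([0.5, 0.5, 0.5, 0.5]),
            origin=np.full((2, 2), 0.5),
            group_a="A",
            group_b="B",
        )

    def test_nearest_selection_brute_force_example(self):
        s = self._scores([-5, -4, -3, -2, -1], [1, 2, 3, 4, 5])
        sel = select_composite_anchors(s, k=2)
        # "A closest to B" anchors at max(A) = -1: nearest two are -1, -2
        assert sorted(s.ctdm[i] for i in sel["a_closest_to_b"]) == [-2, -1]
        # "B farthest from A" anchors at max(B) = 5: nearest two are 5, 4
        assert sorted(s.ctdm[i] for i in sel["b_farthest_from_a"]) == [4, 5]
        assert sorted(s.ctdm[i] for i in sel["a_farthest_from_b"]) == [-5, -4]
        assert sorted(s.ctdm[i] for i in sel["b_closest_to_a"]) == [1, 2]

    def test_k_equals_group_size_returns_whole_group(self):
        s = self._scores([-3, -2, -1], [1, 2, 3])
        sel = select_composite_anchors(s, k=3)
        for key in ANCHOR_ORDER[:3]:
            assert sorted(sel[key]) == [0, 1, 2]
        for key in ANCHOR_ORDER[3:]:
            assert sorted(sel[key]) == [3, 4, 5]

    def test_tie_breaks_lexicographically(self):
        # two specimens equidistant from the mean anchor (0): ids a0, a1, a2
        s = self._scores([-1.0, 0.0, 1.0], [1, 2, 3])
        sel = select_composite_anchors(s, k=2)
        picked_ids = sorted(s.specimen_ids[i] for i in sel["a_average"])
        assert picked_ids == ["a0", "a1"]  # a0 beats a2 at equal |delta|

    def test_group_too_small_errors(self):
        s = self._scores([-1, 0], [1, 2])
        with pytest.raises(GroupError):
            select_composite_anchors(s, k=3)


class TestCompositeShape:
    def test_singleton(self, two_group_result):
        res, _ = two_group_result
        np.testing.assert_allclose(composite_shape(res, [4]), res.aligned[4])

    def test_empty_set_errors(self, two_group_result):
        res, _ = two_group_result
        with pytest.raises(ValueError):
            composite_shape(res, [])

    def test_composite_score_is_mean_of_member_scores(self, two_group_result):
        res, labels = two_group_result
        s = ctdm_scores(res, labels, "A", "B")
        idx = [1, 3, 5, 7]
        comp = composite_shape(res, idx)
        comp_score = (comp.ravel() - s.origin.ravel()) @ s.direction
        assert comp_score == pytest.approx(np.mean(s.ctdm[idx]), abs=1e-12)

    def test_six_composites_ordered_along_axis(self):
        spec = study1_preset(seed=21)
        sample, _ = simulate_two_group_sample(spec)
        res, scores = score_sample(sample, "CZ", "TR")
        sel = select_composite_anchors(scores, k=6)
        anchors = {
            "a_farthest_from_b": scores.ctdm[scores.group == "CZ"].min(),
            "a_average": scores.ctdm[scores.group == "CZ"].mean(),
            "a_closest_to_b": scores.ctdm[scores.group == "CZ"].max(),
            "b_closest_to_a": scores.ctdm[scores.group == "TR"].min(),
            "b_average": scores.ctdm[scores.group == "TR"].mean(),
            "b_farthest_from_a": scores.ctdm[scores.group == "TR"].max(),
        }
        comp_scores = {}
        for key in ANCHOR_ORDER:
            comp = composite_shape(res, sel[key])
            comp_scores[key] = float((comp.ravel() - scores.origin.ravel()) @ scores.direction)
        # composite scores are ranked exactly as their anchor targets are
        by_anchor = sorted(ANCHOR_ORDER, key=lambda k: anchors[k])
        by_composite = sorted(ANCHOR_ORDER, key=lambda k: comp_scores[k])
        assert by_anchor == by_composite
        # and within each group the three categories are ordered along the axis
        assert comp_scores["a_farthest_from_b"] < comp_scores["a_average"] < comp_scores["a_closest_to_b"]
        assert comp_scores["b_closest_to_a"] < comp_scores["b_average"] < comp_scores["b_farthest_from_a"]


class TestDeformationGrid:
    def test_identity(self, rng):
        ref = rng.normal(size=(8, 2))
        pts, warped = tps_deformation_grid(ref, ref)
        np.testing.assert_allclose(warped, pts, atol=1e-12)

    def test_affine_target_keeps_grid_lines_straight(self, rng):
        ref = rng.normal(size=(8, 2))
        aff = ref @ np.array([[1.1, 0.2], [-0.05, 0.9]]) + [0.3, -0.2]
        # magnification 1 of an affine difference is itself affine
        pts, warped = tps_deformation_grid(ref, aff, magnification=1.0, grid=(10, 10))
        rows = warped.reshape(10, 10, 2)
        for r in range(10):
            p0, p1, p2 = rows[r, 0], rows[r, 4], rows[r, 9]
            cross = (p1 - p0)[0] * (p2 - p0)[1] - (p1 - p0)[1] * (p2 - p0)[0]
            assert abs(cross) < 1e-8

    def test_magnification_linearity(self, rng):
        ref = rng.normal(size=(8, 2))
        delta = 0.05 * rng.normal(size=(8, 2))
        pts1, w1 = tps_deformation_grid(ref, ref + delta, magnification=3.0)
        pts2, w2 = tps_deformation_grid(ref, ref + 3.0 * delta, magnification=1.0)
        np.testing.assert_allclose(w1, w2, atol=1e-10)
        np.testing.assert_allclose(pts1, pts2)
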