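import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import microconfig as mc
from microconfig.transforms import DistanceMatrix


def euclid_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)), "euclidean_2d")


class TestPcoa:
    def test_points_on_a_line_recovered_by_first_axis(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [5, 0]])
        res = mc.pcoa(euclid_dm(pts), k=2)
        pco1 = res.coordinates["PCo1"].to_numpy()
        spacing = np.diff(np.sort(pco1))
        assert np.allclose(spacing, [1, 1, 3], atol=1e-8)
        assert res.eigenvalues[1] < 1e-8  # second axis carries nothing

    def test_identical_samples_identical_coordinates(self):
        pts = np.array([[1.0, 2], [1, 2], [4, 0]])
        res = mc.pcoa(euclid_dm(pts), k=2)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9)

    def test_round_trip_reconstructs_distances(self, rng):
        pts = rng.normal(size=(15, 2))
        res = mc.pcoa(euclid_dm(pts), k=2)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rebuilt, squareform(pdist(pts)), atol=1e-8)

    def test_coordinates_are_centered(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        res = mc.pcoa(dm, k=2)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_explained_fractions_valid_with_negative_eigenvalues(self, small_cohort):
        # Bray-Curtis is non-Euclidean: negative eigenvalues appear
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        res = mc.pcoa(dm, k=3)
        assert (res.eigenvalues < 0).any()
        assert (res.proportion_explained >= 0).all()
        assert (res.proportion_explained <= 1).all()

    def test_k_truncated_with_warning(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        with pytest.warns(UserWarning, match="truncating"):
            res = mc.pcoa(euclid_dm(pts), k=3)
        assert res.coordinates.shape[1] < 3


class TestMedianCentroid:
    def test_single_reference_sample_distance_zero(self):
        pts = np.array([[0.0, 0], [3, 4], [1, 1]])
        res = mc.pcoa(euclid_dm(pts), k=2)
        groups = pd.Series(["ref", "x", "x"], index=res.sample_ids)
        cent = mc.median_centroid(res, "ref", groups)
        assert cent.distances.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_hand_median_and_pythagoras(self):
        coords = pd.DataFrame(
            [[1, 0], [-1, 0], [0, 1], [0, -1], [3, 4]],
            index=list("abcde"), columns=["PCo1", "PCo2"], dtype=float)
        res = mc.OrdinationResult(coords, np.ones(2), np.array([0.5, 0.5]))
        groups = pd.Series(["r", "r", "r", "r", "x"], index=coords.index)
        cent = mc.median_centroid(res, "r", groups)
        assert np.allclose(cent.centroid, [0.0, 0.0])
        assert cent.distances["e"] == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        coords = pd.DataFrame(rng.normal(size=(10, 2)),
                              index=[f"s{i}" for i in range(10)],
                              columns=["PCo1", "PCo2"])
        groups = pd.Series(["r"] * 4 + ["x"] * 6, index=coords.index)
        base = mc.OrdinationResult(coords, np.ones(2), np.array([0.5, 0.5]))
        shifted = mc.OrdinationResult(coords + 7.3, np.ones(2), np.array([0.5, 0.5]))
        d0 = mc.median_centroid(base, "r", groups).distances
        d1 = mc.median_centroid(shifted, "r", groups).distances
        assert np.allclose(d0, d1, atol=1e-9)

    def test_missing_reference_rejected(self):
        coords = pd.DataFrame([[0.0, 0], [1, 1]], index=["a", "b"],
                              columns=["PCo1", "PCo2"])
        res = mc.OrdinationResult(coords, np.ones(2), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="absent"):
            mc.median_centroid(res, "nope", pd.Series(["x", "x"], index=["a", "b"]))


class TestCentroidGroupTest:
    def test_identical_distances_p_one(self):
        dist = pd.Series([1.0] * 9, index=[f"s{i}" for i in range(9)])
        cent = mc.CentroidDistanceResult("r", np.zeros(2), dist)
        groups = pd.Series(np.repeat(["a", "b", "c"], 3), index=dist.index)
        omnibus, pairwise = mc.centroid_group_test(cent, groups)
        assert omnibus.p == 1.0
        assert all(r.p == 1.0 for r in pairwise)

    def test_shifted_group_detected(self, rng):
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                                 rng.normal(3, 1, 30)])
        ids = [f"s{i}" for i in range(90)]
        cent = mc.CentroidDistanceResult("r", np.zeros(2),
                                         pd.Series(np.abs(values), index=ids))
        groups = pd.Series(np.repeat(["a", "b", "c"], 30), index=ids)
        omnibus, pairwise = mc.centroid_group_test(cent, groups)
        assert omnibus.p < 0.05
        sig = [r for r in pairwise if "c" in r.comparison]
        assert all(r.q < 0.05 for r in sig)


class TestPermanova:
    def test_seeded_determinism(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        kw = dict(confounders=["study"], n_perm=99, seed=5)
        a = mc.permanova(dm, small_cohort.metadata, "group", **kw)
        b = mc.permanova(dm, small_cohort.metadata, "group", **kw)
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_term_ss_partition_sums_to_total(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        res = mc.permanova(dm, small_cohort.metadata, "group",
                           confounders=["study"], n_perm=99, seed=1)
        t = res.terms.set_index("term")
        parts = t.drop(index="total")["SS"].sum()
        assert parts == pytest.approx(t.loc["total", "SS"], abs=1e-9)
        assert ((t["R2"] >= -1e-12) & (t["R2"] <= 1 + 1e-12)).all()

    def test_planted_effect_reaches_permutation_floor(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        res = mc.permanova(dm, small_cohort.metadata, "group",
                           confounders=["study"], n_perm=199, seed=2)
        assert res.p == pytest.approx(1 / 200)

    def test_orthogonal_confounder_leaves_r2_unchanged(self, rng):
        # balanced 2x2 design: a confounder orthogonal to the grouping
        n = 40
        ids = [f"s{i}" for i in range(n)]
        group = np.tile(["a", "b"], n // 2)
        conf = np.repeat(["u", "v"], n // 2)
        pts = rng.normal(size=(n, 3)) + 2.0 * (group == "b")[:, None]
        dm = DistanceMatrix(ids, squareform(pdist(pts)), "euclidean_2d")
        meta = pd.DataFrame({"group": group, "conf": conf}, index=ids)
        without = mc.permanova(dm, meta, "group", confounders=None,
                               n_perm=99, seed=0)
        with_conf = mc.permanova(dm, meta, "group", confounders=["conf"],
                                 n_perm=99, seed=0)
        assert with_conf.r2("group") == pytest.approx(without.r2("group"), abs=1e-9)

    def test_single_level_term_rejected(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        meta = small_cohort.metadata.copy()
        meta["flat"] = "same"
        with pytest.raises(ValueError, match="single level"):
            mc.permanova(dm, meta, "flat", n_perm=99, seed=0)

    def test_saturating_confounder_demoted_to_stratum(self, small_cohort):
        # group is constant within patient: patient_id saturates the design
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        res = mc.permanova(dm, small_cohort.metadata, "group",
                           confounders=["study", "patient_id"], n_perm=99, seed=3)
        assert "patient_id" in res.strata
        assert "patient_id" not in list(res.terms["term"])

    def test_label_permutation_invariance(self, small_cohort):
        # renaming group levels must not change R2 or p
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        meta = small_cohort.metadata.copy()
        renamed = meta.copy()
        renamed["group"] = renamed["group"].map(
            {"control": "z_ctl", "CD": "a_cd", "HS": "m_hs"})
        r1 = mc.permanova(dm, meta, "group", confounders=["study"],
                          n_perm=99, seed=4)
        r2 = mc.permanova(dm, renamed, "group", confounders=["study"],
                          n_perm=99, seed=4)
        assert r1.r2("group") == pytest.approx(r2.r2("group"), abs=1e-12)
        assert r1.p == r2.p


class TestPairwisePermanova:
    def test_divergent_group_flagged_in_its_two_pairs(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        out = mc.pairwise_permanova(dm, small_cohort.metadata["group"],
                                    small_cohort.metadata, n_perm=199, seed=7)
        out = out.set_index("pair")
        # control vs CD communities are planted apart; HS is their mixture
        assert out.loc["CD vs control", "q"] < 0.05

    def test_input_order_invariance(self, small_cohort):
        dm = mc.bray_curtis(mc.to_relative(small_cohort.abundance))
        groups = small_cohort.metadata["group"]
        a = mc.pairwise_permanova(dm, groups, small_cohort.metadata,
                                  n_perm=99, seed=7)
        shuffled = groups.sample(frac=1.0, random_state=1)
        b = mc.pairwise_permanova(dm, shuffled, small_cohort.metadata,
                                  n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a, b)
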