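"""Module-atlas construction: centroids, BA lookup, hierarchy assignment."""

import numpy as np
import pandas as pd
import pytest

from modnet import (
    ModuleHierarchy,
    assign_brodmann,
    build_module_hierarchy,
    compute_parcel_centroids,
    internode_distance_report,
    module_members,
    split_anterior_posterior,
)
from modnet.atlas import NONE_LABEL, MemberSpec

from conftest import make_img


class TestCentroids:
    def test_single_voxel_label_maps_through_affine(self):
        data = np.zeros((4, 4, 4), dtype=int)
        data[1, 2, 3] = 7
        affine = np.array([[1, 0, 0, 9], [0, 1, 0, -22], [0, 0, 1, 27], [0, 0, 0, 1]],
                          dtype=float)
        nodes = compute_parcel_centroids(make_img(data, affine))
        assert len(nodes) == 1
        assert nodes.iloc[0]["node_id"] == 7
        np.testing.assert_allclose(nodes.iloc[0][["x", "y", "z"]].astype(float),
                                   [10, -20, 30])

    def test_two_voxel_label_yields_midpoint(self):
        data = np.zeros((4, 4, 4), dtype=int)
        data[[0, 2], 0, 0] = 5
        nodes = compute_parcel_centroids(make_img(data))
        np.testing.assert_allclose(nodes.iloc[0][["x", "y", "z"]].astype(float),
                                   [1, 0, 0])

    def test_multilabel_volume_matches_voxel_enumeration_oracle(self, rng):
        # brute force: average the affine image of each label's voxels directly
        data = np.zeros((8, 8, 8), dtype=int)
        data[rng.random((8, 8, 8)) < 0.6] = 1
        data[5:8, 5:8, 0:3] = 2
        data[0:2, 6:8, 6:8] = 3
        affine = np.array([[2, 0, 0, -8], [0, -2, 0, 8], [0, 0, 2, -8], [0, 0, 0, 1]],
                          dtype=float)
        nodes = compute_parcel_centroids(make_img(data, affine))
        for lab in (1, 2, 3):
            vox = np.argwhere(data == lab)
            mm = np.array([affine @ np.append(v, 1) for v in vox])[:, :3]
            got = nodes.loc[nodes["node_id"] == lab, ["x", "y", "z"]].to_numpy()[0]
            np.testing.assert_allclose(got.astype(float), mm.mean(axis=0))

    def test_empty_volume_and_singular_affine_are_errors(self):
        with pytest.raises(ValueError, match="no nonzero"):
            compute_parcel_centroids(make_img(np.zeros((3, 3, 3), dtype=int)))
        data = np.zeros((3, 3, 3), dtype=int)
        data[1, 1, 1] = 1
        bad = np.eye(4)
        bad[0, 0] = 0.0

        class Stub:  # nibabel refuses singular affines at construction
            affine = bad

            @staticmethod
            def get_fdata():
                return data.astype(float)

        with pytest.raises(ValueError, match="invertible"):
            compute_parcel_centroids(Stub())

    def test_hemisphere_from_centroid_sign_and_override(self):
        data = np.zeros((5, 3, 3), dtype=int)
        data[0, 1, 1] = 1   # x = -2
        data[4, 1, 1] = 2   # x = +2
        data[2, 1, 1] = 3   # x = 0, midline
        affine = np.eye(4)
        affine[0, 3] = -2
        with pytest.raises(ValueError, match="midline"):
            compute_parcel_centroids(make_img(data, affine), midline_tol_mm=0.5)
        nodes = compute_parcel_centroids(make_img(data, affine), midline_tol_mm=0.5,
                                         hemisphere_labels={3: "left"})
        assert nodes.set_index("node_id")["hemisphere"].to_dict() == {
            1: "left", 2: "right", 3: "left"}


class TestBrodmannLookup:
    def test_centroid_inside_region_gets_its_label(self):
        ba = np.zeros((6, 6, 6), dtype=int)
        ba[0:3] = 44
        nodes = pd.DataFrame({"node_id": [1], "x": [1.0], "y": [2.0], "z": [2.0],
                              "hemisphere": ["left"], "compartment": ["cortical"]})
        lab = assign_brodmann(nodes, make_img(ba), {44})
        assert lab.iloc[0]["ba"] == 44

    def test_unlabeled_or_excluded_territory_is_none(self):
        ba = np.zeros((6, 6, 6), dtype=int)
        ba[0:3] = 17  # a non-language area
        nodes = pd.DataFrame({"node_id": [1, 2], "x": [1.0, 4.0], "y": [2.0, 2.0],
                              "z": [2.0, 2.0], "hemisphere": ["left", "left"],
                              "compartment": ["cortical", "cortical"]})
        lab = assign_brodmann(nodes, make_img(ba), {44})
        assert lab["ba"].isna().all()

    def test_out_of_bounds_centroid_is_none_not_error(self):
        ba = np.full((4, 4, 4), 22, dtype=int)
        nodes = pd.DataFrame({"node_id": [1], "x": [99.0], "y": [0.0], "z": [0.0],
                              "hemisphere": ["right"], "compartment": ["cortical"]})
        lab = assign_brodmann(nodes, make_img(ba), {22})
        assert lab["ba"].isna().all()

    def test_two_cuboid_regions_match_point_in_cuboid_oracle(self, rng):
        ba = np.zeros((10, 10, 10), dtype=int)
        ba[0:5, 0:10, 0:10] = 20
        ba[5:10, 0:10, 0:10] = 41
        pts = rng.uniform(0.0, 9.0, size=(10, 3))
        nodes = pd.DataFrame({"node_id": np.arange(1, 11),
                              "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                              "hemisphere": "left", "compartment": "cortical"})
        lab = assign_brodmann(nodes, make_img(ba), {20, 41})
        for pt, got in zip(pts, lab["ba"]):
            expected = 20 if round(pt[0]) < 5 else 41
            assert got == expected


class TestAnteriorPosteriorSplit:
    @staticmethod
    def _nodes(ys, hemi="left"):
        x = -5.0 if hemi == "left" else 5.0
        return pd.DataFrame({"node_id": np.arange(1, len(ys) + 1),
                             "x": x, "y": ys, "z": 0.0,
                             "hemisphere": hemi, "compartment": "cortical"})

    @staticmethod
    def _labeling(n, ba=21):
        return pd.DataFrame({"node_id": np.arange(1, n + 1),
                             "ba": pd.array([ba] * n, dtype="Int64"),
                             "ap": "not_applicable"})

    def test_member_nodes_median_splits_strictly_greater(self):
        nodes = self._nodes([-30.0, -10.0, 10.0])
        lab = split_anterior_posterior(self._labeling(3), nodes, 21,
                                       reference="member_nodes")
        assert list(lab["ap"]) == ["posterior", "posterior", "anterior"]

    def test_all_equal_y_ties_to_posterior(self):
        nodes = self._nodes([4.0, 4.0, 4.0])
        lab = split_anterior_posterior(self._labeling(3), nodes, 21,
                                       reference="member_nodes")
        assert set(lab["ap"]) == {"posterior"}

    def test_mirrored_hemispheres_split_identically(self):
        ys = [-20.0, 0.0, 20.0]
        left = split_anterior_posterior(self._labeling(3), self._nodes(ys, "left"),
                                        21, reference="member_nodes")
        right = split_anterior_posterior(self._labeling(3), self._nodes(ys, "right"),
                                         21, reference="member_nodes")
        assert list(left["ap"]) == list(right["ap"])

    def test_map_voxel_reference_uses_per_hemisphere_voxel_median(self):
        # left BA21 voxels span y rows 0..5 (median mm -> between rows 2,3)
        ba = np.zeros((8, 6, 2), dtype=int)
        ba[0:3, 0:6, :] = 21
        affine = np.eye(4)
        affine[0, 3] = -4.0  # x: rows 0..2 -> -4..-2 (left)
        nodes = self._nodes([1.0, 3.0])  # voxel-median y = 2.5 -> 1.0 post, 3.0 ant
        nodes["x"] = -3.0
        lab = split_anterior_posterior(self._labeling(2), nodes, 21,
                                       reference="map_voxels",
                                       ba_img=make_img(ba, affine))
        assert list(lab["ap"]) == ["posterior", "anterior"]

    def test_empty_reference_set_is_error(self):
        nodes = self._nodes([0.0])
        with pytest.raises(ValueError):
            split_anterior_posterior(self._labeling(1), nodes, 21,
                                     reference="map_voxels",
                                     ba_img=make_img(np.zeros((3, 3, 3), dtype=int)))


class TestHierarchy:
    def test_module_counts_per_level(self, hierarchy):
        assert [hierarchy.module_count(lv) for lv in (1, 2, 3, 4)] == [10, 6, 2, 1]

    def test_level1_members_partition_the_language_bas(self, hierarchy):
        members = [m for mod in hierarchy.levels[1] for m in mod.members]
        assert len(members) == len(set(members))
        assert {m.ba for m in members} == set(hierarchy.language_bas)

    def test_invalid_specs_are_rejected(self, hierarchy):
        import copy
        spec = copy.deepcopy(hierarchy)
        spec.levels[1] = spec.levels[1][:-1]  # drop a module -> BAs uncovered
        with pytest.raises(ValueError):
            spec.validate()
        assert MemberSpec.parse("BA21:post") == MemberSpec(21, "post")
        with pytest.raises(ValueError):
            MemberSpec.parse("21")
        with pytest.raises(ValueError):
            MemberSpec.parse("BA21:middle")

    def test_other_domain_systems_expressible_as_config(self):
        """A somatosensory-motor system (BA1-4) is pure configuration."""
        sm = ModuleHierarchy.from_dict({
            "name": "somatosensory-motor",
            "language_bas": [1, 2, 3, 4],
            "split_bas": [],
            "levels": {
                1: [{"name": "Somatosensory-motor", "hemisphere": "each",
                     "members": ["BA1", "BA2", "BA3", "BA4"]}],
                2: [{"name": "Somatosensory-motor", "hemisphere": "each",
                     "level1": ["Somatosensory-motor"]}],
                3: [{"name": "Somatosensory-motor", "hemisphere": "each",
                     "level1": ["Somatosensory-motor"]}],
                4: [{"name": "Somatosensory-motor", "hemisphere": "both",
                     "level1": ["Somatosensory-motor"]}],
            },
        })
        assert [sm.module_count(lv) for lv in (1, 2, 3, 4)] == [2, 2, 2, 1]
        nodes = pd.DataFrame({"node_id": [1, 2], "x": [-30.0, 30.0],
                              "y": [-20.0, -20.0], "z": [50.0, 50.0],
                              "hemisphere": ["left", "right"],
                              "compartment": "cortical"})
        labeling = pd.DataFrame({"node_id": [1, 2],
                                 "ba": pd.array([3, 4], dtype="Int64"),
                                 "ap": "not_applicable"})
        assignment = build_module_hierarchy(labeling, nodes, sm)
        assert list(assignment["level1"]) == ["Somatosensory-motor L",
                                              "Somatosensory-motor R"]
        assert list(assignment["level4"]) == ["Somatosensory-motor"] * 2

    def test_full_assignment_on_synthetic_atlas(self, assigned_nodes, hierarchy):
        nodes, labeling, assignment = assigned_nodes
        # every level realizes its full module count on this complete atlas
        for lv, expect in ((1, 10), (2, 6), (3, 2), (4, 1)):
            col = f"level{lv}"
            names = set()
            for cell in assignment[col]:
                if cell != NONE_LABEL:
                    names.update(cell.split(";"))
            assert len(names) == expect

    def test_semantic_processing_feeds_two_level2_modules(self, assigned_nodes):
        nodes, labeling, assignment = assigned_nodes
        sem = assignment[assignment["level1"] == "Semantic processing L"]
        assert len(sem) > 0
        assert set(sem["level2"]) == {"Language sensory L;Word processing L"}
        assert set(sem["level3"]) == {"Language network L"}
        assert set(sem["level4"]) == {"Language network"}

    def test_level1_is_a_partition_and_nesting_is_monotone(self, assigned_nodes):
        nodes, labeling, assignment = assigned_nodes
        in_system = assignment[assignment["level1"] != NONE_LABEL]
        # partition: one level-1 module per node
        assert in_system["level1"].str.contains(";").sum() == 0
        # monotone nesting: level-3 membership is a superset of each level-1 module
        for mod in in_system["level1"].unique():
            l1 = set(module_members(assignment, mod, 1))
            suffix = mod.rsplit(" ", 1)[1]
            l3 = set(module_members(assignment, f"Language network {suffix}", 3))
            assert l1 <= l3

    def test_hemisphere_closure_at_levels_1_to_3(self, assigned_nodes):
        nodes, labeling, assignment = assigned_nodes
        merged = assignment.merge(nodes[["node_id", "hemisphere"]], on="node_id")
        for lv in (1, 2, 3):
            sub = merged[merged[f"level{lv}"] != NONE_LABEL]
            for name, grp in sub.groupby(f"level{lv}"):
                assert grp["hemisphere"].nunique() == 1

    def test_unlabeled_node_is_outside_at_every_level(self, hierarchy):
        nodes = pd.DataFrame({"node_id": [1], "x": [-5.0], "y": [0.0], "z": [0.0],
                              "hemisphere": ["left"], "compartment": ["cortical"]})
        labeling = pd.DataFrame({"node_id": [1], "ba": pd.array([None], dtype="Int64"),
                                 "ap": "not_applicable"})
        assignment = build_module_hierarchy(labeling, nodes, hierarchy)
        assert list(assignment.iloc[0][["level1", "level2", "level3", "level4"]]) == \
            [NONE_LABEL] * 4

    def test_assignment_is_deterministic(self, synthetic_atlas, hierarchy):
        parc, ba_img = synthetic_atlas
        runs = []
        for _ in range(2):
            nodes = compute_parcel_centroids(parc)
            labeling = assign_brodmann(nodes, ba_img, hierarchy.language_bas)
            for ba in sorted(hierarchy.split_bas):
                labeling = split_anterior_posterior(labeling, nodes, ba,
                                                    reference="map_voxels",
                                                    ba_img=ba_img)
            runs.append(build_module_hierarchy(labeling, nodes, hierarchy))
        pd.testing.assert_frame_equal(runs[0], runs[1])


class TestDistanceReport:
    def test_two_nodes_median_is_their_distance(self, hierarchy):
        nodes = pd.DataFrame({"node_id": [1, 2], "x": [-3.0, -3.0],
                              "y": [0.0, 5.0], "z": [0.0, 0.0],
                              "hemisphere": "left", "compartment": "cortical"})
        assignment = pd.DataFrame({"node_id": [1, 2],
                                   "level1": "Motoric language L",
                                   "level2": "Language motor L",
                                   "level3": "Language network L",
                                   "level4": "Language network"})
        rep = internode_distance_report(nodes, assignment, "Motoric language L")
        assert rep["median_mm"] == 5.0
        assert rep["frac_gt_40mm"] == 0.0

    def test_three_collinear_nodes_enumerated(self):
        nodes = pd.DataFrame({"node_id": [1, 2, 3], "x": [-3.0] * 3,
                              "y": [0.0, 30.0, 60.0], "z": [0.0] * 3,
                              "hemisphere": "left", "compartment": "cortical"})
        assignment = pd.DataFrame({"node_id": [1, 2, 3], "level1": "M",
                                   "level2": "M", "level3": "M", "level4": "M"})
        rep = internode_distance_report(nodes, assignment, "M")
        # pairwise distances {30, 30, 60}
        assert rep["median_mm"] == 30.0
        assert rep["frac_gt_40mm"] == pytest.approx(1 / 3)

    def test_single_node_module_is_an_error(self):
        nodes = pd.DataFrame({"node_id": [1], "x": [0.0], "y": [0.0], "z": [0.0],
                              "hemisphere": "left", "compartment": "cortical"})
        assignment = pd.DataFrame({"node_id": [1], "level1": "M", "level2": "M",
                                   "level3": "M", "level4": "M"})
        with pytest.raises(ValueError, match="fewer than 2"):
            internode_distance_report(nodes, assignment, "M")
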