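"""Skeleton morphometrics: analytic shapes, tree oracles, invariants."""

import numpy as np
import pytest

from gliavasc.cells import CellRecord, extract_single_cells, segment_somata
from gliavasc.morpho import (
    FEATURE_NAMES,
    SkeletonGraph,
    branch_stats,
    compute_features,
    hull_and_ramification,
    skeletonize_cell,
)
from gliavasc.synthetic import generate_fov
from oracles import branch_lengths_by_path_enumeration, random_skeleton_tree


def _line_mask(n=10):
    mask = np.zeros((5, n + 4), dtype=bool)
    mask[2, 2 : 2 + n] = True
    return mask


class TestSkeletonizeCell:
    def test_straight_line_is_a_path(self):
        sk = skeletonize_cell(_line_mask(), (1.0, 1.0), prune_um=0.0)
        stats = branch_stats(sk)
        assert stats.n_endpoints == 2
        assert stats.n_branchpoints == 0
        assert len(stats.branch_lengths) == 1

    def test_y_mask_has_three_endpoints_one_branchpoint(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 2:9] = True          # stem going left
        for i in range(1, 6):        # two diagonal arms
            mask[8 - i, 8 + i] = True
            mask[8 + i, 8 + i] = True
        mask[8, 8] = True
        sk = skeletonize_cell(mask, (1.0, 1.0), prune_um=0.0)
        stats = branch_stats(sk)
        assert stats.n_endpoints == 3
        assert stats.n_branchpoints == 1
        assert len(stats.branch_lengths) == 3

    def test_empty_and_disconnected_masks_are_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_cell(np.zeros((8, 8), dtype=bool), (1.0, 1.0))
        two = np.zeros((8, 8), dtype=bool)
        two[1, 1] = two[6, 6] = True
        with pytest.raises(ValueError, match="components"):
            skeletonize_cell(two, (1.0, 1.0))

    def test_skeleton_rotates_with_the_mask(self):
        mask = _line_mask()
        sk0 = skeletonize_cell(mask, (1.0, 1.0))
        sk90 = skeletonize_cell(np.rot90(mask), (1.0, 1.0))
        s0, s90 = branch_stats(sk0), branch_stats(sk90)
        assert s0.n_endpoints == s90.n_endpoints
        assert s0.branch_lengths == pytest.approx(s90.branch_lengths)

    def test_edge_list_export_roundtrips_lengths(self):
        sk = skeletonize_cell(_line_mask(), (1.0, 1.0), prune_um=0.0)
        nodes, edges = sk.to_edge_list()
        assert len(nodes) == sk.graph.number_of_nodes()
        assert edges["length_um"].sum() == pytest.approx(
            sum(d["length"] for _, _, d in sk.graph.edges(data=True))
        )

    def test_pruning_never_adds_endpoints(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 2:18] = True
        mask[8:10, 10] = True  # a 2-voxel spur
        short = branch_stats(skeletonize_cell(mask, (1.0, 1.0), prune_um=0.0))
        pruned = branch_stats(skeletonize_cell(mask, (1.0, 1.0), prune_um=3.0))
        assert pruned.n_endpoints <= short.n_endpoints


class TestBranchStats:
    def test_path_graph_single_branch(self):
        import networkx as nx

        g = nx.path_graph(7)
        nx.set_edge_attributes(g, 2.0, "length")
        stats = branch_stats(SkeletonGraph(graph=g, voxel_size=(1.0,)))
        assert stats.branch_lengths == pytest.approx([12.0])
        assert stats.max_branch_length == stats.total_branch_length == 12.0

    def test_star_graph_three_arms(self):
        import networkx as nx

        g = nx.Graph()
        for arm in range(3):
            prev = "hub"
            for i in range(5):
                node = (arm, i)
                g.add_edge(prev, node, length=1.0)
                prev = node
        stats = branch_stats(SkeletonGraph(graph=g, voxel_size=(1.0,)))
        assert stats.n_endpoints == 3
        assert stats.n_branchpoints == 1
        assert sorted(stats.branch_lengths) == pytest.approx([5.0, 5.0, 5.0])
        assert stats.max_branch_length == 5.0
        assert stats.total_branch_length == 15.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        g = random_skeleton_tree(rng, n_branches=int(rng.integers(3, 9)))
        stats = branch_stats(SkeletonGraph(graph=g, voxel_size=(1.0,)))
        assert sorted(stats.branch_lengths) == pytest.approx(
            branch_lengths_by_path_enumeration(g)
        )
        assert stats.n_endpoints == sum(1 for _, d in g.degree() if d == 1)


class TestHullAndRamification:
    def test_filled_cuboid_is_fully_convex(self):
        mask = np.ones((6, 9, 7), dtype=bool)
        cell, hull, ri = hull_and_ramification(mask, (1.0, 1.25, 1.25))
        assert ri >= 0.95
        assert ri == pytest.approx(1.0, abs=1e-9)

    def test_plus_sign_matches_analytic_hull(self):
        # five unit squares in a plus: area 5, hull = 3x3 square minus 4 corners = 7
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        mask[1:4, 2] = True
        cell, hull, ri = hull_and_ramification(mask, (1.0, 1.0))
        assert cell == pytest.approx(5.0)
        assert hull == pytest.approx(7.0)
        assert ri == pytest.approx(5.0 / 7.0)

    def test_index_is_bounded_by_one(self, rng):
        mask = rng.uniform(size=(12, 12)) > 0.5
        mask[5, 5] = True
        _, _, ri = hull_and_ramification(mask, (1.0, 1.0))
        assert 0.0 < ri <= 1.0


class TestComputeFeatures:
    @staticmethod
    def _soma_only_cell():
        yy, xx = np.mgrid[:41, :41]
        soma = (yy - 20.0) ** 2 + (xx - 20.0) ** 2 <= 15.0**2
        return CellRecord(
            cell_id=1, mask=soma.copy(), soma_mask=soma.copy(),
            soma_centroid_um=(10.0, 10.0), soma_size=float(soma.sum()),
            soma_footprint_um2=float(soma.sum()),
        )

    def test_soma_only_cell_has_no_branches(self):
        feats = compute_features(self._soma_only_cell(), (1.0, 1.0))
        assert feats.n_endpoints == 0
        assert feats.max_branch_length == 0.0
        # discretization shaves ~5% off a rasterized disc's solidity
        assert feats.ramification_index > 0.9

    def test_vector_has_eight_features(self):
        feats = compute_features(self._soma_only_cell(), (1.0, 1.0))
        assert feats.to_vector().shape == (8,)
        assert len(FEATURE_NAMES) == 8

    def test_ramified_archetype_scores_below_amoeboid(self, flat_config_2d):
        import dataclasses

        ramified = generate_fov(flat_config_2d, fov_index=0)
        amoeboid_cfg = dataclasses.replace(flat_config_2d, branches_per_cell=(0, 0))
        amoeboid = generate_fov(amoeboid_cfg, fov_index=0)

        def mean_ri(fov):
            cfg = fov.config
            seg = segment_somata(fov.clean_channels["iba1"], cfg.voxel_size)
            ex = extract_single_cells(fov.clean_channels["iba1"], seg, cfg.voxel_size)
            return np.mean(
                [compute_features(c, cfg.voxel_size).ramification_index for c in ex.cells]
            )

        assert mean_ri(ramified) < mean_ri(amoeboid)

    def test_recovers_generator_truth_on_separated_trees(self, flat_config_2d):
        import dataclasses

        from gliavasc.evaluate import match_somata_to_truth

        exact_endpoints = 0
        total = 0
        max_len_errors = []
        for idx in range(18):  # ~50 rendered cells
            cfg = dataclasses.replace(flat_config_2d, seed=100 + idx)
            fov = generate_fov(cfg, fov_index=idx)
            seg = segment_somata(fov.clean_channels["iba1"], cfg.voxel_size)
            ex = extract_single_cells(fov.clean_channels["iba1"], seg, cfg.voxel_size)
            match = match_somata_to_truth(seg.labels, fov.truth.cells, cfg.voxel_size)
            lookup = dict(zip(match["soma_label"], match["truth_index"]))
            for cell in ex.cells:
                truth = fov.truth.cells.loc[lookup[cell.cell_id]]
                feats = compute_features(cell, cfg.voxel_size)
                total += 1
                exact_endpoints += feats.n_endpoints == truth["n_endpoints"]
                max_len_errors.append(
                    abs(feats.max_branch_length - truth["max_branch_length"])
                    / truth["max_branch_length"]
                )
        assert total >= 40
        assert exact_endpoints / total >= 0.9
        assert np.median(max_len_errors) < 0.15
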