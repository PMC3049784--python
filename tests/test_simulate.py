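"""Planted-truth generator: exact membership, noise model, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from engraftlogic.designs import expression_replica_design, protein_replica_design
from engraftlogic.simulate import (
    PlantedDesign,
    RegionSpec,
    UP_G0,
    UP_G1,
    build_ground_truth,
    generate_expression,
    generate_ki67,
    generate_protein_table,
    plant_id_map,
)
from conftest import flipped


def region_counts(gt: pd.DataFrame) -> dict:
    return gt["label"].value_counts().to_dict()


class TestDesignValidation:
    def test_region_overflow_names_offender(self):
        with pytest.raises(ValueError, match="BM.*8"):
            PlantedDesign(n_features=5, regions=(RegionSpec((("BM", UP_G0),), 8),))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"effect_size": 0.0},
            {"effect_size": -1.0},
            {"noise_sd": -0.1},
            {"replicates_per_group": 1},
            {"n_features": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        params = {"n_features": 10} | kwargs
        with pytest.raises(ValueError):
            PlantedDesign(**params)

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec((("BM", 2),), 1)


class TestGroundTruth:
    def test_replica_region_sizes_are_exact(self):
        """Venn region sizes equal the design counts, feature for feature."""
        gt = build_ground_truth(expression_replica_design())
        de_bm = gt["effect_BM"] != 0
        de_mpb = gt["effect_MPB"] != 0
        de_ucb = gt["effect_UCB"] != 0
        assert de_bm.sum() == 10256
        assert de_mpb.sum() == 1705
        assert de_ucb.sum() == 2685
        assert (de_bm & de_mpb).sum() == 643
        assert (de_bm & de_mpb & de_ucb).sum() == 159
        assert (de_bm & de_mpb & ~de_ucb).sum() == 484
        counts = region_counts(gt)
        assert counts["engraftment_G0"] == 132
        assert counts["engraftment_G1"] == 207
        assert counts["discordant:BM_G0_MPB_G1"] == 54
        assert counts["discordant:BM_G1_MPB_G0"] == 91
        assert counts["cell_cycle"] == 159

    def test_replica_direction_margins(self):
        gt = build_ground_truth(expression_replica_design())
        for tissue, (up_g0, up_g1) in {
            "BM": (4522, 5734), "MPB": (840, 865), "UCB": (1432, 1253)
        }.items():
            assert (gt[f"effect_{tissue}"] > 0).sum() == up_g0
            assert (gt[f"effect_{tissue}"] < 0).sum() == up_g1

    def test_null_features_have_zero_effect_everywhere(self, tiny_design):
        gt = build_ground_truth(tiny_design)
        nulls = gt[gt["label"] == "null"]
        assert len(nulls) == 6
        assert (nulls[["effect_BM", "effect_MPB", "effect_UCB"]] == 0).all().all()

    def test_label_flip_swaps_directions_only(self, tiny_design):
        gt = build_ground_truth(tiny_design)
        gt_flip = build_ground_truth(flipped(tiny_design))
        for t in ("BM", "MPB", "UCB"):
            assert (gt_flip[f"effect_{t}"] == -gt[f"effect_{t}"]).all()
        swap = {"engraftment_G0": "engraftment_G1", "engraftment_G1": "engraftment_G0"}
        expected = gt["label"].map(lambda s: swap.get(s, s))
        assert (gt_flip["label"] == expected).all()


class TestGenerateExpression:
    def test_shape_and_sample_sheet(self, tiny_design):
        matrix, gt = generate_expression(tiny_design, seed=3)
        assert matrix.values.shape == (10, 18)
        assert (matrix.values.to_numpy() > 0).all()
        assert matrix.samples.groupby(["tissue", "phase"]).size().eq(3).all()
        assert list(gt.index) == list(matrix.values.index)

    def test_noise_free_ratio_matches_planted_effect(self, tiny_design):
        """With noise_sd=0, per-feature G0/G1 ratios equal 2**effect exactly."""
        matrix, gt = generate_expression(tiny_design, seed=0)
        for tissue in ("BM", "MPB", "UCB"):
            g0 = matrix.values[matrix.group_columns(tissue, "G0")].mean(axis=1)
            g1 = matrix.values[matrix.group_columns(tissue, "G1")].mean(axis=1)
            np.testing.assert_allclose(
                (g0 / g1).to_numpy(), np.exp2(gt[f"effect_{tissue}"]), rtol=1e-12
            )

    def test_reproducibility_bitwise(self, tiny_design):
        design = PlantedDesign(n_features=10, regions=tiny_design.regions, noise_sd=0.3)
        m1, g1 = generate_expression(design, seed=7)
        m2, g2 = generate_expression(design, seed=7)
        assert m1.values.equals(m2.values)
        assert g1.equals(g2)
        m3, _ = generate_expression(design, seed=8)
        assert not m1.values.equals(m3.values)

    def test_global_null_design(self):
        design = PlantedDesign(n_features=50, noise_sd=0.1)
        matrix, gt = generate_expression(design, seed=1)
        assert (gt["label"] == "null").all()
        assert matrix.values.shape == (50, 18)


class TestKi67:
    def test_reduction_is_exact(self):
        k = generate_ki67(0.93)
        np.testing.assert_allclose(k["G0"] / k["G1"], 0.07)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            generate_ki67(1.2)


class TestProteinTable:
    def test_replica_priority_structure(self):
        table, gt = generate_protein_table(protein_replica_design(), seed=2)
        assert table.n_features == 646
        p12 = gt["priority"].isin([1, 2])
        for tissue, n in {"BM": 25, "MPB": 12, "UCB": 22}.items():
            assert ((gt[f"effect_{tissue}"] != 0) & p12).sum() == n
        de_all = gt[["effect_BM", "effect_MPB", "effect_UCB"]] != 0
        assert (de_all.all(axis=1) & p12).sum() == 7
        assert (de_all["effect_BM"] & de_all["effect_MPB"] & p12).sum() == 11
        assert de_all["effect_BM"].sum() == 62  # all priorities
        assert gt["priority"].isin([1, 2, 3, 4]).all()

    def test_all_null_design_has_no_de(self):
        design = PlantedDesign(n_features=20, feature_prefix="P")
        table, gt = generate_protein_table(design, seed=0)
        assert (gt["label"] == "null").all()
        assert "priority" in table.feature_meta

    def test_missing_priority_rejected(self):
        design = PlantedDesign(
            n_features=5, regions=(RegionSpec((("BM", UP_G0),), 1),)
        )
        with pytest.raises(ValueError, match="priority"):
            generate_protein_table(design, seed=0)


class TestIdMap:
    def test_planted_match_count(self):
        gene_design = PlantedDesign(
            n_features=2000,
            regions=(
                RegionSpec((("BM", UP_G0), ("MPB", UP_G0)), 60),
                RegionSpec((("BM", UP_G1),), 40),
            ),
        )
        _, gene_gt = generate_expression(gene_design, seed=0)
        _, prot_gt = generate_protein_table(protein_replica_design(), seed=0)
        id_map = plant_id_map(prot_gt, gene_gt, n_matched=10, seed=5)
        de_prot = set(prot_gt.index[prot_gt["effect_BM"] != 0])
        de_gene = set(gene_gt.index[gene_gt["effect_BM"] != 0])
        mapping = dict(zip(id_map["protein_id"], id_map["gene_id"]))
        matched = [p for p in de_prot if mapping.get(p) in de_gene]
        assert len(matched) == 10

    def test_overplanting_rejected(self):
        _, prot_gt = generate_protein_table(protein_replica_design(), seed=0)
        small = PlantedDesign(n_features=5, regions=(RegionSpec((("BM", UP_G0),), 2),))
        gene_gt = build_ground_truth(small)
        with pytest.raises(ValueError, match="cannot plant"):
            plant_id_map(prot_gt, gene_gt, n_matched=10)
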