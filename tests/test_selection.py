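"""Node- and gene-selection rules and their monotonicity properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somtopo import selection as sel, som
from somtopo.io import AnnotationTable, DETable, SecretomeRecord, SecretomeTable
from somtopo.topography import Topography

SUBSTRATES = ("maltose", "avicel", "aspen", "pine", "wheat_straw")

# per-substrate node means for four secretion-hotspot-like nodes plus a
# quiet one; columns follow SUBSTRATES
NODE_MEANS = np.array(
    [
        [12.0, 15.0, 13.0, 13.0, 13.0],
        [7.0, 15.0, 14.0, 13.0, 13.0],
        [7.0, 12.0, 13.0, 12.0, 13.0],
        [7.0, 13.0, 12.0, 10.0, 9.0],
        [8.0, 8.0, 8.0, 8.0, 8.0],
    ]
)


def masks_from_means(means=NODE_MEANS, threshold=12.0):
    n = means.shape[0]
    return {
        s: Topography(means[:, i] > threshold, "high_mask", (n, 1), condition=s)
        for i, s in enumerate(SUBSTRATES)
    }


class TestSubstrateSpecificNodes:
    def test_high_on_control_excluded(self):
        masks = masks_from_means()
        # node 2 (7,15,14,13,13): high on avicel -> excluded for aspen
        nodes = sel.substrate_specific_nodes(masks, "aspen")
        assert 2 not in nodes
        # node 3 (7,12,13,12,13): avicel mean exactly 12 is NOT high
        assert 3 in nodes

    def test_exclusively_high_node_selected(self):
        means = np.array([[7.0, 7.0, 7.0, 13.0, 7.0]])
        masks = masks_from_means(means)
        assert sel.substrate_specific_nodes(masks, "pine") == {1}
        assert sel.substrate_specific_nodes(masks, "aspen") == set()

    def test_all_false_masks_empty(self):
        means = np.full((3, 5), 5.0)
        masks = masks_from_means(means)
        assert sel.substrate_specific_nodes(masks, "pine") == set()

    def test_control_substrate_rejected(self):
        with pytest.raises(ValueError, match="control"):
            sel.substrate_specific_nodes(masks_from_means(), "maltose")


class TestCommonNodes:
    def test_intersection(self):
        means = np.array(
            [
                [7, 7, 13, 13, 13],  # node 1: high on all three tests
                [7, 7, 13, 13, 7],   # node 2: aspen + pine only
                [7, 7, 7, 7, 13],    # node 3: wheat straw only
            ],
            dtype=float,
        )
        masks = masks_from_means(means)
        common = sel.common_nodes(masks, ["aspen", "pine", "wheat_straw"])
        assert common == {1}

    def test_disjoint_sets_empty(self):
        means = np.array([[7, 7, 13, 7, 7], [7, 7, 7, 13, 7]], dtype=float)
        masks = masks_from_means(means)
        assert sel.common_nodes(masks, ["aspen", "pine"]) == set()

    @given(st.integers(min_value=0, max_value=2**10 - 1),
           st.integers(min_value=0, max_value=2**10 - 1))
    @settings(max_examples=30, deadline=None)
    def test_contained_in_every_input(self, bits_a, bits_p):
        n = 10
        means = np.full((n, 5), 7.0)
        means[[b == "1" for b in f"{bits_a:010b}"], 2] = 13.0
        means[[b == "1" for b in f"{bits_p:010b}"], 3] = 13.0
        masks = masks_from_means(means)
        common = sel.common_nodes(masks, ["aspen", "pine"])
        assert common <= sel.substrate_specific_nodes(masks, "aspen")
        assert common <= sel.substrate_specific_nodes(masks, "pine")


def model_with_assignment(assignment, map_units=4):
    rows, cols = som.near_square_shape(map_units)
    return som.SomModel(
        config=som.SomConfig(map_units=map_units),
        grid_shape=(rows, cols),
        node_coords=som.hex_coordinates(rows, cols),
        codebook=np.zeros((map_units, 1)),
        assignment=np.asarray(assignment),
        gene_ids=[f"g{i}" for i in range(len(assignment))],
        feature_names=["f"],
    )


def de_table_from(entries):
    frame = pd.DataFrame(
        entries, columns=["gene_id", "log2fc", "pvalue", "padj"]
    ).set_index("gene_id")
    return DETable(frame)


class TestDeFilter:
    def test_strict_thresholds(self):
        model = model_with_assignment([1, 1, 1, 2])
        de = de_table_from(
            [
                ("g0", 1.0, 0.001, 0.01),  # lfc exactly 1 -> excluded
                ("g1", 2.3, 0.001, 0.01),  # passes
                ("g2", 2.3, 0.04, 0.05),   # padj exactly 0.05 -> excluded
                ("g3", 5.0, 0.001, 0.001),  # not in selected nodes
            ]
        )
        out = sel.de_filter({1}, model, de)
        assert out["gene_id"].tolist() == ["g1"]

    def test_gene_missing_from_de_warned(self):
        model = model_with_assignment([1, 1])
        de = de_table_from([("g0", 2.0, 0.001, 0.01)])
        with pytest.warns(UserWarning, match="no DE entry"):
            out = sel.de_filter({1}, model, de)
        assert out["gene_id"].tolist() == ["g0"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        model = model_with_assignment(rng.integers(1, 5, 50))
        de = de_table_from(
            [
                (f"g{i}", rng.normal(1, 1.5), 0.01, rng.random())
                for i in range(50)
            ]
        )
        sizes = []
        for lfc in (0.5, 1.0, 2.0):
            cfg = sel.SelectionConfig(lfc_threshold=lfc)
            sizes.append(len(sel.de_filter({1, 2, 3, 4}, model, de, cfg)))
        assert sizes == sorted(sizes, reverse=True)


class TestTopSecretionNodes:
    def make_topo(self, counts):
        return Topography(
            np.asarray(counts, dtype=float), "secretion_count",
            (len(counts), 1),
        )

    def test_tie_inclusion_extends_top_three_to_four(self):
        counts = np.full(230, 2.0)
        counts[119] = 26  # node 120
        counts[13] = 24   # node 14
        counts[34] = 23   # node 35
        counts[219] = 23  # node 220
        topo = Topography(counts, "secretion_count", (23, 10))
        assert sel.top_secretion_nodes(topo, k=3) == [120, 14, 35, 220]

    def test_all_zero_returns_full_grid_with_warning(self):
        topo = self.make_topo([0, 0, 0, 0])
        with pytest.warns(UserWarning, match="tied"):
            assert sel.top_secretion_nodes(topo, k=3) == [1, 2, 3, 4]

    def test_unique_maximum_singleton(self):
        assert sel.top_secretion_nodes(self.make_topo([1, 9, 3]), k=1) == [2]

    def test_counts_non_increasing_in_rank(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=20).astype(float)
        topo = self.make_topo(counts)
        ranked = sel.top_secretion_nodes(topo, k=5)
        values = [counts[n - 1] for n in ranked]
        assert values == sorted(values, reverse=True)

    def test_k_below_one_fails(self):
        with pytest.raises(ValueError, match="k"):
            sel.top_secretion_nodes(self.make_topo([1.0]), k=0)


class TestSummarizeSelection:
    def test_detected_over_predicted_percentage(self):
        result = sel.SelectionResult(
            nodes={"aspen": {1}},
            genes={
                "aspen": pd.DataFrame(
                    {
                        "gene_id": [f"g{i}" for i in range(10)],
                        "node_id": [1] * 10,
                        "log2fc": [2.0] * 10,
                        "pvalue": [0.001] * 10,
                        "padj": [0.01] * 10,
                    }
                )
            },
        )
        ann = AnnotationTable(
            labels={"g0": "GH7"},
            predicted_secreted={"g0", "g1", "g2", "g3"},
        )
        secretome = SecretomeTable(
            [SecretomeRecord("P0", "g0", "a"), SecretomeRecord("P1", "g1", "a")]
        )
        row = sel.summarize_selection(result, ann, secretome).iloc[0]
        assert row["secreted"] == "2/4 (50%)"
        assert row["genes"] == 10

    def test_empty_selection_zero_row(self):
        result = sel.SelectionResult(nodes={"pine": set()})
        row = sel.summarize_selection(result).iloc[0]
        assert row["nodes"] == 0 and row["genes"] == 0

    def test_cazyme_plus_unknown_bounded_by_genes(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(40)]
        result = sel.SelectionResult(
            nodes={"pine": {1}},
            genes={
                "pine": pd.DataFrame(
                    {
                        "gene_id": genes,
                        "node_id": [1] * 40,
                        "log2fc": [2.0] * 40,
                        "pvalue": [0.01] * 40,
                        "padj": [0.01] * 40,
                    }
                )
            },
        )
        for _ in range(10):
            ann = AnnotationTable(
                labels={g: "GH5" for g in genes if rng.random() < 0.4},
                predicted_secreted={g for g in genes if rng.random() < 0.5},
            )
            row = sel.summarize_selection(result, ann).iloc[0]
            assert row["cazymes"] + row["unknown"] <= row["genes"]
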