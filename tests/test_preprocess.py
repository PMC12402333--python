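"""Cell QC, normalization, gating, fractions, and pseudobulk."""

import numpy as np
import pandas as pd
import pytest

from libio.errors import ConfigError, IntegrityError
from libio.matrix import ExpressionMatrix
from libio.preprocess import (
    GateRule,
    cell_type_fractions,
    filter_genes,
    gate_cells,
    normalize_lognorm,
    pseudobulk_mean,
    qc_filter_cells,
)


def _ann(cell_ids, mito, ngenes, sample="s1"):
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample,
            "subject_id": sample,
            "time_point": "D9",
            "cell_type": "T",
            "mito_fraction": mito,
            "n_genes_detected": ngenes,
        }
    )


def _counts(n_genes, cell_ids, rng=None, values=None):
    if values is None:
        values = (rng or np.random.default_rng(0)).integers(
            0, 6, size=(n_genes, len(cell_ids))
        )
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cell_ids,
    )
    return ExpressionMatrix(df, "counts")


class TestQcFilter:
    def test_mito_and_gene_thresholds(self):
        cells = [f"c{i}" for i in range(5)]
        counts = _counts(4, cells)
        ann = _ann(cells, [0.10, 0.30, 0.20, 0.26, 0.00], [600, 700, 400, 800, 550])
        filt, ann_f, report = qc_filter_cells(counts, ann)
        assert filt.obs_ids == ["c0", "c4"]
        assert report["n_removed"] == 3
        assert report["n_high_mito"] == 2
        assert report["n_low_genes"] == 1

    def test_boundary_mito_exactly_quarter_kept(self):
        cells = ["c0"]
        filt, _, _ = qc_filter_cells(_counts(3, cells), _ann(cells, [0.25], [600]))
        assert filt.obs_ids == ["c0"]

    def test_all_passing_is_identity_and_idempotent(self):
        cells = [f"c{i}" for i in range(4)]
        counts = _counts(3, cells)
        ann = _ann(cells, [0.1] * 4, [900] * 4)
        once, ann1, _ = qc_filter_cells(counts, ann)
        twice, _, r2 = qc_filter_cells(once, ann1)
        assert once.obs_ids == counts.obs_ids == twice.obs_ids
        assert r2["n_removed"] == 0

    def test_annotation_mismatch_rejected(self):
        counts = _counts(3, ["c0", "c1"])
        with pytest.raises(IntegrityError):
            qc_filter_cells(counts, _ann(["c0"], [0.1], [600]))


class TestFilterGenes:
    @pytest.mark.parametrize("n_nonzero,kept", [(2, False), (3, True), (0, False)])
    def test_detection_threshold(self, n_nonzero, kept):
        values = np.zeros((1, 5))
        values[0, :n_nonzero] = 2.0
        counts = _counts(1, [f"c{i}" for i in range(5)], values=values)
        out = filter_genes(counts)
        assert ("g0" in out.gene_ids) is kept


class TestNormalize:
    def test_formula(self):
        counts = _counts(2, ["c0"], values=[[1.0], [3.0]])
        out = normalize_lognorm(counts)
        assert out.value_kind == "lognorm"
        assert out.values.loc["g0", "c0"] == pytest.approx(np.log1p(2500))
        assert out.values.loc["g1", "c0"] == pytest.approx(np.log1p(7500))

    def test_depth_invariance(self):
        a = _counts(3, ["c0"], values=[[1.0], [2.0], [3.0]])
        b = _counts(3, ["c0"], values=[[2.0], [4.0], [6.0]])
        assert np.allclose(
            normalize_lognorm(a).values.to_numpy(), normalize_lognorm(b).values.to_numpy()
        )

    def test_zero_total_cell_rejected(self):
        counts = _counts(2, ["c0", "c1"], values=[[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(IntegrityError, match="c1"):
            normalize_lognorm(counts)


CD8_RULE = GateRule("CD8T", ("Cd8a", "Cd8b1"), ("Cd4",))
CD4_RULE = GateRule("CD4T", ("Cd4",), ("Cd8a", "Cd8b1"))


class TestGating:
    def _lognorm(self, cd8a, cd8b1, cd4):
        df = pd.DataFrame(
            np.array([cd8a, cd8b1, cd4], dtype=float),
            index=["Cd8a", "Cd8b1", "Cd4"],
            columns=[f"c{i}" for i in range(len(cd8a))],
        )
        return ExpressionMatrix(df, "lognorm")

    def test_signature_assignment_and_conflicts(self):
        m = self._lognorm([1.2, 1.0, 0.0], [0.8, 0.0, 0.0], [0.0, 2.0, 0.0])
        labels = gate_cells(m, [CD8_RULE, CD4_RULE])
        # c0: Cd8a+,Cd8b1+,Cd4- -> CD8T; c1: Cd8a+Cd4+ conflict; c2: all zero
        assert labels.tolist() == ["CD8T", "unassigned", "unassigned"]

    def test_partition_no_double_labels(self, rng):
        m = self._lognorm(*(rng.integers(0, 2, 30).astype(float).reshape(3, 10)))
        labels = gate_cells(m, [CD8_RULE, CD4_RULE])
        assert set(labels) <= {"CD8T", "CD4T", "unassigned"}

    def test_missing_gate_gene_is_config_error(self):
        m = self._lognorm([1.0], [1.0], [0.0])
        with pytest.raises(ConfigError):
            gate_cells(m, [GateRule("X", ("Nope",))])


class TestFractions:
    def test_simple_fraction(self):
        ann = _ann([f"c{i}" for i in range(10)], [0.1] * 10, [600] * 10)
        ann.loc[:3, "cell_type"] = "B"
        fr = cell_type_fractions(ann)
        assert fr.loc["s1", "B"] == pytest.approx(0.4)
        assert fr.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_single_type(self):
        ann = _ann(["c0", "c1"], [0.1, 0.1], [600, 600])
        assert cell_type_fractions(ann).loc["s1", "T"] == pytest.approx(1.0)


class TestPseudobulk:
    def _lognorm_for(self, delogged_cols, samples):
        cells = [f"c{i}" for i in range(len(samples))]
        df = pd.DataFrame(
            np.log1p(np.array(delogged_cols, dtype=float)),
            index=["g0"],
            columns=cells,
        )
        m = ExpressionMatrix(df, "lognorm")
        ann = _ann(cells, [0.1] * len(cells), [600] * len(cells))
        ann["sample_id"] = samples
        return m, ann

    def test_delogged_mean(self):
        m, ann = self._lognorm_for([[2.0, 4.0]], ["sA", "sA"])
        pb = pseudobulk_mean(m, ann)
        assert pb.values.loc["g0", "sA"] == pytest.approx(3.0)
        assert pb.cell_counts["sA"] == 2
        assert pb.value_kind == "pseudobulk"

    def test_single_cell_sample_equals_cell(self):
        m, ann = self._lognorm_for([[5.0]], ["sA"])
        pb = pseudobulk_mean(m, ann)
        assert pb.values.loc["g0", "sA"] == pytest.approx(5.0)

    def test_cell_order_and_duplication_invariance(self, rng):
        vals = rng.uniform(0.5, 4.0, size=(1, 6))
        m, ann = self._lognorm_for(vals, ["sA"] * 3 + ["sB"] * 3)
        pb = pseudobulk_mean(m, ann)
        # permute cells
        perm = rng.permutation(6)
        m2 = m.subset_obs([m.obs_ids[i] for i in perm])
        pb2 = pseudobulk_mean(m2, ann)
        assert np.allclose(pb.values.to_numpy(), pb2.values.to_numpy())
        # duplicate the population
        dup_vals = np.concatenate([vals, vals], axis=1)
        cells = [f"c{i}" for i in range(12)]
        df = pd.DataFrame(np.log1p(dup_vals), index=["g0"], columns=cells)
        ann_dup = _ann(cells, [0.1] * 12, [600] * 12)
        ann_dup["sample_id"] = (["sA"] * 3 + ["sB"] * 3) * 2
        pb3 = pseudobulk_mean(ExpressionMatrix(df, "lognorm"), ann_dup)
        assert np.allclose(pb.values.to_numpy(), pb3.values.to_numpy())
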