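"""Clone sizes, expansion enrichment, and Simpson clonality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from libio.errors import InputError
from libio.repertoire import (
    clonality,
    clone_sizes,
    compare_clonality,
    expansion_enrichment,
    expansion_flags,
    unit_expansion_flags,
)
from libio.stats import ContingencyTable2x2, fisher_exact


def _records(keys, samples=None, types=None):
    n = len(keys)
    return pd.DataFrame(
        {
            "unit_id": [f"u{i}" for i in range(n)],
            "sample_id": samples or ["s1"] * n,
            "subject_id": "m1",
            "chain": "TRB",
            "cdr3_nt": keys,
            "clonotype_key": [f"TRB:{k}" for k in keys],
            "cell_type": types or ["T"] * n,
        }
    )


def test_clone_sizes_within_sample():
    sizes = clone_sizes(_records(["A", "A", "B"]))
    assert dict(zip(sizes["clonotype_key"], sizes["size"])) == {"TRB:A": 2, "TRB:B": 1}


def test_same_clone_counted_separately_per_sample():
    sizes = clone_sizes(_records(["A", "A", "A"], samples=["s1", "s1", "s2"]))
    by = sizes.set_index(["sample_id", "clonotype_key"])["size"]
    assert by[("s1", "TRB:A")] == 2
    assert by[("s2", "TRB:A")] == 1


def test_empty_group_empty_table():
    assert clone_sizes(_records([]).iloc[:0]).empty


@pytest.mark.parametrize("size,expanded", [(1, False), (2, True), (5, True)])
def test_expansion_threshold(size, expanded):
    sizes = pd.DataFrame({"sample_id": ["s1"], "clonotype_key": ["k"], "size": [size]})
    assert expansion_flags(sizes)["expanded"].iloc[0] is np.bool_(expanded)


def test_enrichment_matches_fisher_oracle():
    # Construct units yielding the table [[10,2],[3,9]] for Tem vs other
    keys, types = [], []
    def add(n, expanded_flag, t):
        for i in range(n):
            key = f"{t}_{expanded_flag}_{i}"
            keys.extend([key] * (2 if expanded_flag else 1))
            types.extend([t] * (2 if expanded_flag else 1))
    # a=10 expanded Tem units -> 5 clones of size 2 = 10 units
    recs = []
    uid = 0
    rows = []
    def units(n_units, expanded, cell_type):
        nonlocal uid
        added = 0
        ci = 0
        while added < n_units:
            size = 2 if expanded else 1
            key = f"{cell_type}{expanded}{ci}"
            ci += 1
            for _ in range(min(size, n_units - added)):
                rows.append((f"u{uid}", key, cell_type))
                uid += 1
                added += 1
    units(10, True, "Tem")
    units(2, False, "Tem")
    units(4, True, "other")   # 2 clones of size 2 -> 4 expanded units
    units(9, False, "other")
    df = pd.DataFrame(rows, columns=["unit_id", "cdr3_nt", "cell_type"])
    df["sample_id"] = "s1"
    df["subject_id"] = "m1"
    df["chain"] = "TRB"
    df["clonotype_key"] = "TRB:" + df["cdr3_nt"]
    flags = unit_expansion_flags(df)
    table, res = expansion_enrichment(flags, df["cell_type"] == "Tem")
    assert (table.a, table.b, table.c, table.d) == (10, 2, 4, 9)
    ref = fisher_exact(ContingencyTable2x2(10, 2, 4, 9))
    assert res.p == pytest.approx(ref.p)


def test_enrichment_degenerate_table_guarded():
    df = _records(["A", "A", "B", "C"], types=["Tem", "Tem", "other", "other"])
    flags = unit_expansion_flags(df)
    table, res = expansion_enrichment(flags, df["cell_type"] == "Tem")
    assert table.c == 0  # no expanded units outside Tem
    assert np.isfinite(res.or_sample)


class TestClonality:
    def test_hand_cases(self):
        sizes = clone_sizes(_records(["A", "A", "B"]))
        assert clonality(sizes)["simpson"].iloc[0] == pytest.approx(5 / 9)
        single = clone_sizes(_records(["A", "A", "A"]))
        assert clonality(single)["simpson"].iloc[0] == pytest.approx(1.0)
        uniform = clone_sizes(_records(["A", "B", "C", "D"]))
        assert clonality(uniform)["simpson"].iloc[0] == pytest.approx(0.25)

    def test_mean_clone_size_and_unit_totals(self):
        sizes = clone_sizes(_records(["A", "A", "B"]))
        row = clonality(sizes).iloc[0]
        assert row["mean_clone_size"] == pytest.approx(1.5)
        assert row["n_units"] == 3 == sizes["size"].sum()

    def test_scaled_variant_range(self):
        sizes = clone_sizes(_records(["A", "B", "C", "D"]))
        assert clonality(sizes, scaled=True)["simpson"].iloc[0] == pytest.approx(0.0)

    def test_merging_two_clones_increases_simpson_exhaustively(self):
        """Dominance strictly rises when two clones merge (n_units <= 8)."""
        for n_units in range(2, 9):
            for cuts in itertools.combinations(range(1, n_units), 2):
                sizes = np.diff([0, *cuts, n_units])
                if len(sizes) < 2:
                    continue
                p = sizes / n_units
                before = (p**2).sum()
                merged = np.array([sizes[0] + sizes[1], *sizes[2:]]) / n_units
                assert (merged**2).sum() > before + 1e-12

    def test_relabeling_invariance(self):
        s1 = clonality(clone_sizes(_records(["A", "A", "B"])))
        s2 = clonality(clone_sizes(_records(["X", "X", "Y"])))
        assert s1["simpson"].iloc[0] == s2["simpson"].iloc[0]


class TestCompareClonality:
    def _setup(self, resp_keys, non_keys):
        recs = []
        manifest_rows = []
        for i, keys in enumerate(resp_keys):
            s = f"r{i}"
            recs.append(_records(keys).assign(sample_id=s))
            manifest_rows.append((s, s, "responder", "sc", "post", "D9"))
        for i, keys in enumerate(non_keys):
            s = f"n{i}"
            recs.append(_records(keys).assign(sample_id=s))
            manifest_rows.append((s, s, "non_responder", "sc", "post", "D9"))
        manifest = pd.DataFrame(
            manifest_rows,
            columns=["sample_id", "subject_id", "response_label",
                     "modality", "timing", "time_point"],
        )
        clon = clonality(clone_sizes(pd.concat(recs, ignore_index=True)))
        return clon, manifest

    def test_identical_groups_not_significant(self):
        keys = [["A", "A", "B"], ["C", "C", "D"]]
        clon, manifest = self._setup(keys, keys)
        assert compare_clonality(clon, manifest, "D9").p >= 0.5

    def test_expanded_responders_low_p(self):
        resp = [["A"] * 5 + ["B"], ["C"] * 6] * 2
        non = [["A", "B", "C", "D", "E", "F"]] * 4
        clon, manifest = self._setup(resp, non)
        assert compare_clonality(clon, manifest, "D9").p < 0.05

    def test_missing_group_rejected(self):
        clon, manifest = self._setup([["A", "A"]], [])
        with pytest.raises(InputError):
            compare_clonality(clon, manifest, "D9")
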