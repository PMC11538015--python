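"""STRING edge lists, temporal split, and the annotation count filters."""

import numpy as np
import pandas as pd
import pytest

from gosel.data_io import (
    AnnotationTable,
    AttributeMatrix,
    EmptyLabelSpaceError,
    EvidenceNetwork,
    LabelMatrix,
    ProteinIndex,
    filter_attributes,
    filter_labels,
    onehot_labels,
    read_string_edges,
    temporal_split,
    write_string_edges,
)


@pytest.fixture()
def abc_index():
    return ProteinIndex(("A", "B", "C"))


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStringEdges:
    def test_zero_scores_are_not_edges(self, tmp_path, abc_index):
        p = _write(tmp_path, "A\tB\t700\nB\tC\t0\nA\tC\t150\n")
        net = read_string_edges(p, "experimental", abc_index)
        assert net.adjacency[0, 1] == 700
        assert net.adjacency[0, 2] == 150
        assert net.adjacency[1, 2] == 0

    def test_empty_file_gives_zero_adjacency(self, tmp_path, abc_index):
        p = _write(tmp_path, "")
        net = read_string_edges(p, "fusion", abc_index)
        assert net.adjacency.shape == (3, 3)
        assert not net.adjacency.any()

    def test_duplicate_pair_keeps_maximum(self, tmp_path, abc_index):
        p = _write(tmp_path, "A\tB\t700\nB\tA\t500\n")
        net = read_string_edges(p, "database", abc_index)
        assert net.adjacency[0, 1] == 700
        assert net.adjacency[1, 0] == 700

    def test_unknown_protein_is_rejected_with_identity(self, tmp_path, abc_index):
        p = _write(tmp_path, "A\tZ\t10\n")
        with pytest.raises(ValueError, match="Z"):
            read_string_edges(p, "fusion", abc_index)

    def test_malformed_score_is_rejected(self, tmp_path, abc_index):
        p = _write(tmp_path, "protein1\tprotein2\tscore\nA\tB\thigh\n")
        with pytest.raises(ValueError, match="malformed score"):
            read_string_edges(p, "fusion", abc_index)

    def test_roundtrip_write_read_exact(self, tmp_path, rng):
        ids = tuple(f"P{i}" for i in range(12))
        index = ProteinIndex(ids)
        w = np.triu(rng.random((12, 12)) * (rng.random((12, 12)) < 0.3), k=1)
        net = EvidenceNetwork("coexpression", w + w.T)
        path = tmp_path / "rt.tsv"
        write_string_edges(net, index, path)
        back = read_string_edges(path, "coexpression", index)
        np.testing.assert_array_equal(back.adjacency, net.adjacency)


class TestTemporalSplit:
    def _table(self, rows):
        return AnnotationTable(
            pd.DataFrame(rows, columns=["protein", "go_term", "evidence", "date", "aspect"])
        )

    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2017-12-31", "train"),
            ("2018-01-01", "train"),  # uncovered boundary day -> train
            ("2019-06-01", "val"),
            ("2021-03-01", "test"),
            ("2021-01-01", "test"),
        ],
    )
    def test_window_assignment(self, date, expected):
        t = self._table([("P1", "GO:1", "IDA", date, "BP")])
        assert temporal_split(t)["P1"] == expected

    def test_earliest_annotation_date_rules(self):
        t = self._table(
            [
                ("P1", "GO:1", "IDA", "2019-05-01", "BP"),
                ("P1", "GO:2", "IMP", "2016-01-01", "BP"),
            ]
        )
        assert temporal_split(t)["P1"] == "train"

    def test_unparseable_dates_warn_and_drop(self):
        t = self._table(
            [
                ("P1", "GO:1", "IDA", "not-a-date", "BP"),
                ("P2", "GO:1", "IDA", "2016-01-01", "BP"),
            ]
        )
        with pytest.warns(UserWarning, match="1"):
            s = temporal_split(t)
        assert list(s.index) == ["P2"]

    def test_partition_property(self, rng):
        rows = []
        for i in range(80):
            year = int(rng.integers(2014, 2023))
            rows.append(
                (f"P{i}", "GO:1", "IDA", f"{year}-06-15", "BP")
            )
        s = temporal_split(self._table(rows))
        assert len(s) == 80  # every dated protein assigned exactly once
        assert set(s.unique()) <= {"train", "val", "test"}


class TestOnehotLabels:
    def _table(self):
        rows = [
            ("A", "GO:X", "IDA", "2016-01-01", "BP"),
            ("A", "GO:X", "IDA", "2016-01-01", "BP"),  # duplicate
            ("B", "GO:X", "IEA", "2016-01-01", "BP"),  # not whitelisted
            ("C", "GO:Y", "IMP", "2016-01-01", "MF"),  # other aspect
        ]
        return AnnotationTable(
            pd.DataFrame(rows, columns=["protein", "go_term", "evidence", "date", "aspect"])
        )

    def test_whitelist_and_idempotence(self, abc_index):
        lm = onehot_labels(self._table(), abc_index, "BP")
        assert lm.terms == ("GO:X",)
        np.testing.assert_array_equal(lm.y["all"][:, 0], [1, 0, 0])

    def test_empty_whitelist_rejected(self, abc_index):
        with pytest.raises(ValueError):
            onehot_labels(self._table(), abc_index, "BP", evidence_whitelist=set())


def _label_matrix(counts, n_terms, rng, n_train=60, n_val=30, n_test=20):
    """Build a LabelMatrix with exact per-split positive counts per term."""
    splits = {
        "train": np.arange(n_train),
        "val": np.arange(n_train, n_train + n_val),
        "test": np.arange(n_train + n_val, n_train + n_val + n_test),
    }
    y = {}
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    for name, size in sizes.items():
        mat = np.zeros((size, n_terms), dtype=np.int8)
        for k in range(n_terms):
            pos = rng.choice(size, size=counts[name][k], replace=False)
            mat[pos, k] = 1
        y[name] = mat
    return LabelMatrix(y=y, terms=tuple(f"GO:{k}" for k in range(n_terms)), splits=splits)


class TestFilterLabels:
    def test_threshold_rules(self, rng):
        counts = {
            "train": [12, 9, 12, 30],
            "val": [6, 6, 6, 20],
            "test": [2, 2, 0, 10],
        }
        lm = _label_matrix(counts, 4, rng)
        # n_network=1000 -> cap 50: term 3 totals 60 and is dropped; term 1
        # fails train>=10; term 2 fails test>=1
        out = filter_labels(lm, n_network=1000)
        assert out.terms == ("GO:0",)

    def test_brute_force_recount_on_random_tables(self, rng):
        for _ in range(10):
            counts = {
                "train": rng.integers(0, 40, size=6).tolist(),
                "val": rng.integers(0, 20, size=6).tolist(),
                "test": rng.integers(0, 10, size=6).tolist(),
            }
            lm = _label_matrix(counts, 6, rng)
            n_network = 400
            try:
                out = filter_labels(lm, n_network)
            except EmptyLabelSpaceError:
                out = None
            expected = [
                k
                for k in range(6)
                if counts["train"][k] >= 10
                and counts["val"][k] >= 5
                and counts["test"][k] >= 1
                and counts["train"][k] + counts["val"][k] + counts["test"][k]
                <= 0.05 * n_network
            ]
            if out is None:
                assert expected == []
            else:
                assert out.terms == tuple(f"GO:{k}" for k in expected)

    def test_idempotent(self, rng):
        counts = {"train": [15, 11], "val": [7, 6], "test": [3, 2]}
        lm = _label_matrix(counts, 2, rng)
        once = filter_labels(lm, 2000)
        twice = filter_labels(once, 2000)
        assert once.terms == twice.terms
        np.testing.assert_array_equal(once.y["train"], twice.y["train"])

    def test_all_filtered_raises(self, rng):
        counts = {"train": [3], "val": [1], "test": [0]}
        lm = _label_matrix(counts, 1, rng)
        with pytest.raises(EmptyLabelSpaceError):
            filter_labels(lm, 1000)


class TestFilterAttributes:
    def test_support_boundary(self):
        x = np.zeros((10, 3))
        x[:6, 0] = 1  # support 6: kept
        x[:5, 1] = 1  # support 5: dropped
        attrs = AttributeMatrix(x=x, columns=("a", "b", "zero"))
        out = filter_attributes(attrs)
        assert out.columns == ("a",)
        assert out.x.shape == (10, 1)

    def test_zero_survivors_warns(self):
        attrs = AttributeMatrix(x=np.zeros((8, 2)), columns=("a", "b"))
        with pytest.warns(UserWarning):
            out = filter_attributes(attrs)
        assert out.x.shape == (8, 0)
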