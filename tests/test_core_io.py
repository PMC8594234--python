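import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gutnet as gn
from gutnet.errors import (
    EmptyResultError,
    IdentifierError,
    ReconciliationError,
    TableFormatError,
    UsageError,
)


class TestCountsIO:
    def test_round_trip_byte_identical(self, small_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        gn.write_counts(small_counts, path)
        first = path.read_bytes()
        again = gn.read_counts(path)
        assert again == small_counts
        gn.write_counts(again, path)
        assert path.read_bytes() == first

    def test_duplicate_sample_header_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon_id\ts1\ts1\ntA\t1\t2\n")
        with pytest.raises(IdentifierError, match="s1"):
            gn.read_counts(path)

    def test_duplicate_taxon_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon_id\ts1\ts2\ntA\t1\t2\ntA\t3\t4\n")
        with pytest.raises(IdentifierError, match="tA"):
            gn.read_counts(path)

    @pytest.mark.parametrize("bad,err", [("-2", "negative"), ("1.5", "non-integer")])
    def test_bad_cell_names_coordinates(self, tmp_path, bad, err):
        path = tmp_path / "bad.tsv"
        path.write_text(f"taxon_id\ts1\ts2\ntA\t1\t2\ntB\t{bad}\t4\n")
        with pytest.raises(TableFormatError) as exc:
            gn.read_counts(path)
        msg = str(exc.value)
        assert err in msg and "tB" in msg and "s1" in msg

    def test_invariants_enforced(self):
        with pytest.raises(UsageError):
            gn.CountMatrix(pd.DataFrame([[1]], index=["t"], columns=["s"]))


class TestDesignIO:
    def test_read_covers_counts(self, small_counts, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "sample_id\tdiet\tregion\n"
            "s1\tU\teso\ns2\tU\tsto\ns3\tG\teso\ns4\tG\tsto\n"
        )
        design = gn.read_design(path, small_counts)
        assert design.sample_ids == small_counts.sample_ids
        assert len(set(design.cells())) == 4

    def test_missing_sample_is_reconciliation_error(self, small_counts, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tdiet\tregion\ns1\tU\teso\ns2\tU\tsto\ns3\tG\teso\n")
        with pytest.raises(ReconciliationError, match="s4"):
            gn.read_design(path, small_counts)

    def test_extra_rows_strict_vs_lenient(self, small_counts, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "sample_id\tdiet\tregion\n"
            "s1\tU\teso\ns2\tU\tsto\ns3\tG\teso\ns4\tG\tsto\ns5\tG\tsto\n"
        )
        with pytest.raises(ReconciliationError, match="s5"):
            gn.read_design(path, small_counts, strict=True)
        design = gn.read_design(path, small_counts, strict=False)
        assert design.sample_ids == small_counts.sample_ids


class TestFilterTaxa:
    def make(self, rows, n_samples=20):
        table = pd.DataFrame(
            rows, index=[f"t{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(n_samples)],
        ).astype(np.int64)
        return gn.CountMatrix(table)

    def test_min_reads_rule(self):
        rows = [[1] * 4 + [0] * 16, [100] * 20]
        kept, report = gn.filter_taxa(self.make(rows))
        assert report.taxa_removed_min_reads == 1
        assert kept.taxon_ids == ["t1"]

    def test_occurrence_rule(self):
        # present in 1 of 20 samples (5%) but abundant
        rows = [[10000] + [0] * 19, [100] * 20]
        kept, report = gn.filter_taxa(self.make(rows))
        assert report.taxa_removed_occurrence == 1
        assert kept.taxon_ids == ["t1"]

    def test_prevalence_rule(self):
        # widespread but vanishing share of reads: occurrence ok, prevalence not
        rows = [[1] * 20, [100000] * 20]
        kept, report = gn.filter_taxa(self.make(rows), min_total_reads=5)
        assert report.taxa_removed_prevalence == 1
        assert kept.taxon_ids == ["t1"]

    def test_zero_thresholds_identity(self, small_counts):
        kept, report = gn.filter_taxa(small_counts, 0, 0.0, 0.0)
        assert kept == small_counts
        assert (report.taxa_removed_min_reads, report.taxa_removed_prevalence,
                report.taxa_removed_occurrence) == (0, 0, 0)

    def test_all_removed_raises(self):
        rows = [[1] + [0] * 19, [2] + [0] * 19]
        with pytest.raises(EmptyResultError):
            gn.filter_taxa(self.make(rows))

    def test_removal_precedence_single_counting(self):
        # taxon fails every rule; counted only under min_total_reads
        rows = [[1] + [0] * 19, [100] * 20]
        _, report = gn.filter_taxa(self.make(rows))
        assert report.taxa_removed_min_reads == 1
        assert report.taxa_removed_prevalence == 0
        assert report.taxa_removed_occurrence == 0

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=500), min_size=6, max_size=6),
            min_size=2,
            max_size=12,
        )
    )
    def test_partition_and_idempotence(self, rows):
        table = pd.DataFrame(
            rows, index=[f"t{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(6)],
        ).astype(np.int64)
        counts = gn.CountMatrix(table)
        try:
            kept, report = gn.filter_taxa(counts)
        except EmptyResultError:
            return
        assert report.taxa_input == len(rows)
        kept2, report2 = gn.filter_taxa(kept)
        assert kept2 == kept
        assert report2.taxa_retained == report.taxa_retained
        assert (report2.taxa_removed_min_reads, report2.taxa_removed_prevalence,
                report2.taxa_removed_occurrence) == (0, 0, 0)


class TestNetworkIO:
    def test_edgelist_round_trip(self, one_edge_network, tmp_path):
        path = tmp_path / "net.tsv"
        gn.write_network(one_edge_network, path, format="edgelist_tsv")
        lines = path.read_text().splitlines()
        assert sum(1 for ln in lines if not ln.startswith("#")) == 2  # header + 1 edge
        assert gn.read_network(path) == one_edge_network

    def test_graphml_round_trip(self, one_edge_network, tmp_path):
        path = tmp_path / "net.graphml"
        gn.write_network(one_edge_network, path, format="graphml")
        back = gn.read_network(path, format="graphml")
        assert back == one_edge_network

    def test_empty_network(self, tmp_path):
        net = gn.AssociationNetwork(
            ("a", "b"), pd.DataFrame(columns=["source", "target", "weight",
                                              "sign", "p_value"]),
        )
        for fmt, name in [("edgelist_tsv", "e.tsv"), ("graphml", "e.graphml")]:
            path = tmp_path / name
            gn.write_network(net, path, format=fmt)
            back = gn.read_network(path, format=fmt)
            assert back.n_edges == 0 and set(back.nodes) == {"a", "b"}

    def test_verbatim_sign_labels_preserved(self, tmp_path):
        edges = pd.DataFrame(
            [
                {"source": "a", "target": "b", "weight": 0.5, "sign": "+",
                 "p_value": 0.001},
                {"source": "b", "target": "c", "weight": -0.5, "sign": "-",
                 "p_value": 0.002},
            ]
        )
        net = gn.AssociationNetwork(("a", "b", "c"), edges)
        for fmt, name in [("edgelist_tsv", "s.tsv"), ("graphml", "s.graphml")]:
            path = tmp_path / name
            gn.write_network(net, path, format=fmt)
            back = gn.read_network(path, format=fmt)
            assert back.edge_signs() == {("a", "b"): "+", ("b", "c"): "-"}

    def test_unknown_format_rejected(self, one_edge_network, tmp_path):
        with pytest.raises(UsageError):
            gn.write_network(one_edge_network, tmp_path / "x", format="json")

    def test_self_edge_rejected(self):
        edges = pd.DataFrame(
            [{"source": "a", "target": "a", "weight": 0.5,
              "sign": "co-occurrence", "p_value": 0.01}]
        )
        with pytest.raises(UsageError, match="self-edge"):
            gn.AssociationNetwork(("a", "b"), edges)
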