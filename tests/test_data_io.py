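import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from planktonscape import data_io
from planktonscape.data_io import OTUTable, ValidationError


@pytest.fixture()
def toy_table():
    return OTUTable(
        otu_ids=["OTU_1", "OTU_2", "OTU_3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[3, 0], [1, 4], [0, 6]]),
        taxonomy={
            "OTU_1": {"kingdom": "Eukaryota", "phylum": "Ciliophora"},
            "OTU_2": {"kingdom": "Eukaryota", "phylum": "Chlorophyta"},
            "OTU_3": {"kingdom": "Eukaryota", "phylum": "Ciliophora"},
        },
    )


class TestOTUTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="nonnegative"):
            OTUTable(["a"], ["s1", "s2"], np.array([[1, -2]]))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            OTUTable(["a"], ["s1", "s2"], np.array([[1.0, 2.5]]))

    def test_duplicate_ids_named(self):
        with pytest.raises(ValidationError, match="s1"):
            OTUTable(["a"], ["s1", "s1"], np.array([[1, 2]]))
        with pytest.raises(ValidationError, match="a"):
            OTUTable(["a", "a"], ["s1"], np.array([[1], [2]]))

    def test_taxonomy_keys_must_be_otus(self):
        with pytest.raises(ValidationError, match="ghost"):
            OTUTable(["a"], ["s1"], np.array([[1]]), taxonomy={"ghost": {}})


class TestOTUTableIO:
    def test_tsv_round_trip_is_identity(self, toy_table, tmp_path):
        path = tmp_path / "otu.tsv"
        data_io.write_otu_table(toy_table, path)
        back = data_io.read_otu_table(path)
        assert back.otu_ids == toy_table.otu_ids
        assert back.sample_ids == toy_table.sample_ids
        np.testing.assert_array_equal(back.counts, toy_table.counts)

    def test_read_rejects_duplicate_sample_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\ts1\na\t1\t2\n")
        with pytest.raises(ValidationError, match="s1"):
            data_io.read_otu_table(path)

    def test_read_rejects_non_integer_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU_ID\ts1\na\t1.5\n")
        with pytest.raises(ValidationError):
            data_io.read_otu_table(path)

    def test_biom_json_sparse_and_dense(self, tmp_path):
        doc = {
            "format": "Biological Observation Matrix 1.0.0",
            "matrix_type": "sparse",
            "rows": [{"id": "a", "metadata": None}, {"id": "b", "metadata": None}],
            "columns": [{"id": "s1", "metadata": None}, {"id": "s2", "metadata": None}],
            "data": [[0, 0, 5], [1, 1, 7]],
        }
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(doc))
        t = data_io.read_otu_table(path, format="biom-json")
        np.testing.assert_array_equal(t.counts, [[5, 0], [0, 7]])
        doc["matrix_type"] = "dense"
        doc["data"] = [[5, 0], [0, 7]]
        path.write_text(json.dumps(doc))
        t2 = data_io.read_otu_table(path, format="biom-json")
        np.testing.assert_array_equal(t2.counts, t.counts)

    def test_taxonomy_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "tax.tsv"
        data_io.write_taxonomy(toy_table, path)
        assert data_io.read_taxonomy(path) == toy_table.taxonomy


class TestMetadataAndEnv:
    def test_reads_full_design(self, small_neutral_dataset, tmp_path):
        ds = small_neutral_dataset
        path = tmp_path / "meta.csv"
        ds.metadata.to_csv(path, index=False)
        meta = data_io.read_metadata(path, ds.table)
        assert len(meta) == 54
        assert set(meta["site"]) == {f"SP{i}" for i in range(1, 7)}

    def test_missing_column_listed(self, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"sample_id": ["s1"], "site": ["SP1"]}).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="season"):
            data_io.read_metadata(path)

    def test_latitude_out_of_range(self, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({
            "sample_id": ["s1"], "site": ["SP1"], "season": ["summer"],
            "replicate": [1], "latitude": [97.0], "longitude": [0.0],
        }).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="latitude"):
            data_io.read_metadata(path)

    def test_sample_id_mismatch_lists_difference(self, toy_table, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({
            "sample_id": ["s1"], "site": ["SP1"], "season": ["summer"],
            "replicate": [1], "latitude": [35.0], "longitude": [103.0],
        }).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="s2"):
            data_io.read_metadata(path, toy_table)

    def test_env_missing_variable_listed(self, tmp_path):
        path = tmp_path / "env.csv"
        pd.DataFrame({"sample_id": ["s1"], "WT": [15.0]}).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="Chl_a"):
            data_io.read_env(path)


class TestAggregateComposition:
    def _meta(self, sample_ids, sites):
        return pd.DataFrame(
            {"sample_id": sample_ids, "site": sites, "season": "summer"},
        ).set_index("sample_id", drop=False)

    def test_single_phylum_is_total(self):
        t = OTUTable(["a"], ["s1", "s2"], np.array([[4, 6]]),
                     taxonomy={"a": {"phylum": "Ciliophora"}})
        out = data_io.aggregate_composition(t, self._meta(["s1", "s2"], ["SP1", "SP1"]),
                                            top_k=3)
        assert out.loc["SP1", "Ciliophora"] == pytest.approx(1.0)
        assert out.loc["SP1", "Others"] == pytest.approx(0.0)

    def test_three_to_one_split(self):
        t = OTUTable(["a", "b"], ["s1"], np.array([[3], [1]]),
                     taxonomy={"a": {"phylum": "P1"}, "b": {"phylum": "P2"}})
        out = data_io.aggregate_composition(t, self._meta(["s1"], ["SP1"]), top_k=1)
        assert out.loc["SP1", "P1"] == pytest.approx(0.75)
        assert out.loc["SP1", "Others"] == pytest.approx(0.25)

    def test_others_matches_brute_force_sum(self, rng):
        # 12 phyla, k=10: "Others" must equal the direct sum of the two
        # least-abundant phyla's relative abundances
        n_otus, n_samples = 60, 8
        counts = rng.integers(0, 50, size=(n_otus, n_samples))
        counts[0] += 1  # avoid empty samples
        phyla = [f"P{i % 12}" for i in range(n_otus)]
        t = OTUTable(
            [f"o{i}" for i in range(n_otus)],
            [f"s{j}" for j in range(n_samples)],
            counts,
            taxonomy={f"o{i}": {"phylum": phyla[i]} for i in range(n_otus)},
        )
        meta = self._meta(t.sample_ids, ["SP1"] * 4 + ["SP2"] * 4)
        out = data_io.aggregate_composition(t, meta, top_k=10)
        rel = counts / counts.sum(axis=0)
        df = pd.DataFrame(rel, index=phyla, columns=t.sample_ids).groupby(level=0).sum()
        top10 = df.mean(axis=1).nlargest(10).index
        bottom = df.index.difference(top10)
        for grp, cols in (("SP1", t.sample_ids[:4]), ("SP2", t.sample_ids[4:])):
            expected_others = df.loc[bottom, cols].mean(axis=1).sum()
            assert out.loc[grp, "Others"] == pytest.approx(expected_others, abs=1e-12)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_sum_to_one(self, small_neutral_dataset):
        ds = small_neutral_dataset
        out = data_io.aggregate_composition(ds.table, ds.metadata, top_k=5,
                                            grouping="season")
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_absent_rank_errors(self, toy_table):
        meta = self._meta(["s1", "s2"], ["SP1", "SP1"])
        with pytest.raises(ValidationError, match="genus"):
            data_io.aggregate_composition(toy_table, meta, rank="genus")


class TestNetworkIO:
    def _toy_graph(self):
        g = nx.Graph()
        g.add_node("a", module=0, zi=0.1, pi=0.0, role="peripheral")
        g.add_node("b", module=0, zi=-0.1, pi=0.0, role="peripheral")
        g.add_node("c", module=1, zi=0.0, pi=0.5, role="peripheral")
        g.add_node("d", module=1, zi=0.0, pi=0.0, role="peripheral")
        g.add_edge("a", "b", rho=0.9, sign="positive", weight=0.9)
        g.add_edge("c", "d", rho=-0.7, sign="negative", weight=0.7)
        return g

    @pytest.mark.parametrize("fmt", ["graphml", "gexf"])
    def test_round_trip_preserves_counts_and_attrs(self, tmp_path, fmt):
        g = self._toy_graph()
        path = tmp_path / f"net.{fmt}"
        data_io.write_network(g, path, format=fmt)
        back = data_io.read_network(path, format=fmt)
        assert back.number_of_nodes() == 4
        assert back.number_of_edges() == 2
        assert back.edges["c", "d"]["sign"] == "negative"

    def test_empty_network_warns_but_writes(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            data_io.write_network(nx.Graph(), tmp_path / "empty.graphml")
        assert data_io.read_network(tmp_path / "empty.graphml").number_of_nodes() == 0
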