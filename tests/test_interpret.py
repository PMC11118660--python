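"""Attention aggregation, DGA ranking/classification, ORA and co-occurrence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hetdr.graph import HeteroGraph
from hetdr.interpret import (
    AttentionSummary,
    aggregate_attention,
    classify_associations,
    count_cooccurrences,
    ora_enrichment,
    rank_drug_genes,
)
from hetdr.model import AttentionTensor
from hetdr.preprocess import DTITable


def _graph(n=2, m=2, l=3):
    N = n + m + l
    return HeteroGraph(
        adjacency=np.zeros((N, N)),
        adc=np.zeros((n, m)),
        acg=np.zeros((m, l)),
        adg=np.zeros((n, l)),
        drug_ids=[f"D{i}" for i in range(n)],
        cell_ids=[f"C{i}" for i in range(m)],
        gene_ids=[f"G{i}" for i in range(l)],
    )


def _attn(rng, n_nodes, n_heads, density=0.5):
    mask = (rng.random((n_nodes, n_nodes)) < density)[:, :, None]
    weights = rng.random((n_nodes, n_nodes, n_heads)) * mask
    return AttentionTensor(weights=weights)


class TestAggregateAttention:
    def test_identical_heads_average_to_themselves(self):
        g = _graph()
        rng = np.random.default_rng(0)
        a = _attn(rng, g.n_nodes, 1)
        a5 = AttentionTensor(weights=np.repeat(a.weights, 5, axis=2))
        out = aggregate_attention([a5], g)
        assert np.allclose(out.aggregate, a.head_mean_dense())

    def test_two_layers_sum(self):
        g = _graph()
        rng = np.random.default_rng(1)
        a1, a2 = _attn(rng, g.n_nodes, 3), _attn(rng, g.n_nodes, 3)
        out = aggregate_attention([a1, a2], g)
        assert np.allclose(out.aggregate, a1.head_mean_dense() + a2.head_mean_dense())

    def test_matches_naive_loop_oracle(self):
        g = _graph(3, 2, 4)
        rng = np.random.default_rng(2)
        attns = [_attn(rng, g.n_nodes, 5) for _ in range(3)]
        out = aggregate_attention(attns, g)
        expected = np.zeros((g.n_nodes, g.n_nodes))
        for a in attns:
            for i in range(g.n_nodes):
                for j in range(g.n_nodes):
                    expected[i, j] += sum(
                        a.weights[i, j, h] for h in range(5)
                    ) / 5.0
        assert np.allclose(out.aggregate, expected, atol=1e-12)

    def test_head_count_mismatch_rejected(self):
        g = _graph()
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="head-count"):
            aggregate_attention([_attn(rng, g.n_nodes, 2), _attn(rng, g.n_nodes, 3)], g)

    def test_direction_switch_transposes_slice(self):
        g = _graph()
        rng = np.random.default_rng(4)
        a = _attn(rng, g.n_nodes, 2)
        fwd = aggregate_attention([a], g, direction="drug_receives").drug_gene_slice()
        rev = aggregate_attention([a], g, direction="gene_receives").drug_gene_slice()
        n, m = g.n_drugs, g.n_cells
        dense = a.head_mean_dense()
        assert np.allclose(fwd.to_numpy(), dense[:n, n + m:])
        assert np.allclose(rev.to_numpy(), dense[n + m:, :n].T)


class TestRankDrugGenes:
    @staticmethod
    def _summary(block):
        # the helper fills the drug-side slice, so read it back drug-side
        g = _graph(n=block.shape[0], m=1, l=block.shape[1])
        agg = np.zeros((g.n_nodes, g.n_nodes))
        agg[: g.n_drugs, g.n_drugs + 1 :] = block
        return AttentionSummary(aggregate=agg, graph=g, direction="drug_receives")

    def test_dominant_gene_ranks_first(self):
        s = self._summary(np.array([[0.1, 5.0, 0.2]]))
        out = rank_drug_genes(s, k=2)
        assert out.iloc[0]["gene_id"] == "G1" and out.iloc[0]["rank"] == 1

    def test_k_exceeding_connectivity_warns(self):
        s = self._summary(np.array([[0.0, 1.0, 0.0]]))
        with pytest.warns(UserWarning, match="touches only"):
            out = rank_drug_genes(s, k=3)
        assert len(out) == 1

    def test_ties_break_lexicographically(self):
        s = self._summary(np.array([[1.0, 1.0, 1.0]]))
        out = rank_drug_genes(s, k=3)
        assert list(out["gene_id"]) == ["G0", "G1", "G2"]

    def test_record_count_is_drugs_times_k(self):
        rng = np.random.default_rng(5)
        s = self._summary(rng.random((4, 6)) + 0.1)
        out = rank_drug_genes(s, k=5)
        assert len(out) == 4 * 5
        for _, grp in out.groupby("drug_id"):
            assert sorted(grp["rank"]) == [1, 2, 3, 4, 5]
            assert (grp.sort_values("rank")["score"].diff().dropna() <= 0).all()

    def test_rankings_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(6)
        block = rng.random((3, 5)) + 0.1
        r1 = rank_drug_genes(self._summary(block), k=3)
        r2 = rank_drug_genes(self._summary(block * 37.5), k=3)
        pd.testing.assert_frame_equal(
            r1[["drug_id", "gene_id", "rank"]], r2[["drug_id", "gene_id", "rank"]]
        )


class TestClassifyAssociations:
    def test_empty_dti_all_novel(self):
        dgas = pd.DataFrame(
            {"drug_id": ["D0"], "gene_id": ["G0"], "score": [1.0], "rank": [1]}
        )
        out, summary = classify_associations(dgas, DTITable())
        assert (out["status"] == "novel").all()
        assert summary["n_known"] == 0

    def test_exact_match_recovers_everything(self):
        dgas = pd.DataFrame(
            {
                "drug_id": ["D0", "D1"],
                "gene_id": ["G0", "G1"],
                "score": [1.0, 1.0],
                "rank": [1, 1],
            }
        )
        dti = DTITable(pairs={("D0", "G0"), ("D1", "G1")})
        out, summary = classify_associations(dgas, dti)
        assert (out["status"] == "known_dti").all()
        assert summary["dti_recovery_fraction"] == 1.0

    def test_recovery_matches_set_membership_oracle(self):
        rng = np.random.default_rng(7)
        drugs = [f"D{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(8)]
        records = [
            (d, g, rng.random(), r + 1)
            for d in drugs
            for r, g in enumerate(rng.choice(genes, size=3, replace=False))
        ]
        dgas = pd.DataFrame(records, columns=["drug_id", "gene_id", "score", "rank"])
        dti = DTITable(
            pairs={(rng.choice(drugs), rng.choice(genes)) for _ in range(10)}
        )
        _, summary = classify_associations(dgas, dti)
        ranked = set(zip(dgas["drug_id"], dgas["gene_id"]))
        oracle = {(d, g) for d, g in dti.pairs if (d, g) in ranked}
        assert summary["n_dti_recovered"] == len(oracle)


class TestORA:
    def test_hypergeometric_matches_exhaustive_enumeration(self):
        # universe of 10, one set of 5, query of 4 drawn genes, overlap 4:
        # p = C(5,4) C(5,0) / C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        gset = {f"g{i}" for i in range(5)}
        query = {"q": ["g0", "g1", "g2", "g3"]}
        out = ora_enrichment(query, {"s": gset}, universe)
        assert np.isclose(out["p_value"][0], 5 / 210)
        # independent oracle: enumerate all 4-subsets of the universe
        hits = total = 0
        for comb in itertools.combinations(sorted(universe), 4):
            total += 1
            if len(set(comb) & gset) >= 4:
                hits += 1
        assert np.isclose(out["p_value"][0], hits / total, atol=1e-12)

    def test_enumeration_oracle_on_random_small_universes(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            u_size = int(rng.integers(6, 13))
            universe = {f"g{i}" for i in range(u_size)}
            gset = set(rng.choice(sorted(universe), size=int(rng.integers(2, u_size)),
                                  replace=False))
            q = int(rng.integers(2, u_size))
            query = list(rng.choice(sorted(universe), size=q, replace=False))
            out = ora_enrichment({"d": query}, {"s": gset}, universe)
            k = len(set(query) & gset)
            hits = total = 0
            for comb in itertools.combinations(sorted(universe), q):
                total += 1
                if len(set(comb) & gset) >= k:
                    hits += 1
            assert np.isclose(out["p_value"][0], hits / total, atol=1e-12)

    def test_bh_closed_form(self):
        universe = {f"g{i}" for i in range(6)}
        # craft three sets to yield distinct raw p-values, then check the BH
        # step-up on the sorted values
        out = ora_enrichment(
            {"d": ["g0", "g1"]},
            {"a": {"g0", "g1"}, "b": {"g0", "g2"}, "c": {"g3", "g4"}},
            universe,
        )
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(out["adjusted_p"], expected)
        assert (out["adjusted_p"] >= out["p_value"] - 1e-15).all()
        assert (out["adjusted_p"] <= 1.0).all()

    def test_bh_textbook_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(np.array([0.01, 0.02, 0.03]), method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        out = ora_enrichment({"d": ["g0"]}, {"s": {"g5", "g6"}}, universe)
        assert out["p_value"][0] == 1.0

    def test_single_test_adjustment_is_identity(self):
        universe = {f"g{i}" for i in range(8)}
        out = ora_enrichment({"d": ["g0", "g5"]}, {"s": {"g5", "g6"}}, universe)
        assert np.isclose(out["adjusted_p"][0], out["p_value"][0])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ora_enrichment({"d": ["zzz"]}, {"s": {"g0"}}, {"g0", "g1"})

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment({}, {"s": {"g0"}}, {"g0"})
        with pytest.raises(ValueError):
            ora_enrichment({"d": ["g0"]}, {"s": {"g0"}}, set())


class TestCooccurrence:
    dgas = pd.DataFrame(
        {
            "drug_id": ["D0", "D0", "D1"],
            "gene_id": ["G0", "G1", "G0"],
            "score": [1.0, 0.5, 0.8],
            "rank": [1, 2, 1],
        }
    )

    def test_empty_index_all_zero(self):
        idx = pd.DataFrame(columns=["abstract_id", "drug_ids", "gene_ids"])
        out = count_cooccurrences(self.dgas, idx)
        assert (out["n_abstracts"] == 0).all()

    def test_single_abstract_single_pair(self):
        idx = pd.DataFrame(
            {"abstract_id": ["a1"], "drug_ids": ["D0"], "gene_ids": ["G0"]}
        )
        out = count_cooccurrences(self.dgas, idx)
        assert out.set_index(["drug_id", "gene_id"])["n_abstracts"].to_dict() == {
            ("D0", "G0"): 1, ("D0", "G1"): 0, ("D1", "G0"): 0,
        }

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        drugs = ["D0", "D1"]
        genes = ["G0", "G1"]
        rows = []
        for i in range(30):
            rows.append(
                {
                    "abstract_id": f"a{i}",
                    "drug_ids": ";".join(
                        rng.choice(drugs, size=rng.integers(0, 3), replace=False)
                    ),
                    "gene_ids": ";".join(
                        rng.choice(genes, size=rng.integers(0, 3), replace=False)
                    ),
                }
            )
        idx = pd.DataFrame(rows)
        out = count_cooccurrences(self.dgas, idx)
        for _, r in out.iterrows():
            expected = sum(
                1
                for _, a in idx.iterrows()
                if r["drug_id"] in a["drug_ids"].split(";")
                and r["gene_id"] in a["gene_ids"].split(";")
            )
            assert r["n_abstracts"] == expected
            assert np.isclose(r["log_abstracts"], math.log1p(expected))
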