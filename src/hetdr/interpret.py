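"""Attention-coefficient interpretation.

Turns the per-layer multi-head attention captured during an eval-mode forward
pass into ranked drug-gene associations: heads are averaged within each
layer, layers are summed, and the drug-gene slice of the aggregate is ranked
per drug. Associations are labeled known (present in the training DTI table)
or novel, optionally counted against an offline abstract co-mention index,
and the top genes per drug are tested for gene-set over-representation with
a hypergeometric test and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph import HeteroGraph
from .model import AttentionTensor
from .preprocess import DTITable

__all__ = [
    "AttentionSummary",
    "aggregate_attention",
    "rank_drug_genes",
    "classify_associations",
    "ora_enrichment",
    "count_cooccurrences",
]


@dataclass
class AttentionSummary:
    """Head-averaged, layer-summed (N x N) attention with a drug-gene view.

    ``aggregate[i, j]`` is the total attention node i pays to node j. The
    drug-gene slice follows the configured direction: ``gene_receives``
    (default) reads the attention gene nodes pay to drug sources, transposed
    to drugs x genes; ``drug_receives`` reads the attention drug nodes pay
    to gene sources. The gene-side view contrasts drugs within each gene's
    neighborhood and carries the cleaner mechanism signal in practice.
    """

    aggregate: np.ndarray
    graph: HeteroGraph
    direction: str = "gene_receives"

    def drug_gene_slice(self) -> pd.DataFrame:
        n, m, l = self.graph.n_drugs, self.graph.n_cells, self.graph.n_genes
        if self.direction == "drug_receives":
            block = self.aggregate[:n, n + m :]
        elif self.direction == "gene_receives":
            block = self.aggregate[n + m :, :n].T
        else:
            raise ValueError("direction must be 'drug_receives' or 'gene_receives'")
        return pd.DataFrame(
            block, index=self.graph.drug_ids, columns=self.graph.gene_ids
        )


def aggregate_attention(
    attns: list[AttentionTensor],
    graph: HeteroGraph,
    direction: str = "gene_receives",
) -> AttentionSummary:
    """Average heads within each layer, then sum the layer matrices."""
    if not attns:
        raise ValueError("need at least one attention tensor")
    heads = {a.n_heads for a in attns}
    if len(heads) != 1:
        raise ValueError(f"head-count mismatch across layers: {sorted(heads)}")
    nodes = {a.n_nodes for a in attns}
    if len(nodes) != 1 or nodes.pop() != graph.n_nodes:
        raise ValueError("attention tensors inconsistent with graph node count")
    aggregate = np.zeros((graph.n_nodes, graph.n_nodes))
    for a in attns:
        aggregate += a.head_mean_dense()
    return AttentionSummary(aggregate=aggregate, graph=graph, direction=direction)


def rank_drug_genes(summary: AttentionSummary, k: int = 5) -> pd.DataFrame:
    """Top-k genes per drug by aggregated attention.

    Ties are broken lexicographically by gene id; genes with zero attention
    (no connectivity) are never ranked. Returns a tidy frame with columns
    drug_id, gene_id, score, rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    slice_df = summary.drug_gene_slice()
    records = []
    for drug_id, row in slice_df.iterrows():
        nonzero = row[row > 0]
        if len(nonzero) < k:
            warnings.warn(
                f"drug {drug_id!r} touches only {len(nonzero)} genes (< k={k})",
                stacklevel=2,
            )
        ordered = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for rank, (gene_id, score) in enumerate(ordered, start=1):
            records.append((drug_id, gene_id, float(score), rank))
    return pd.DataFrame(records, columns=["drug_id", "gene_id", "score", "rank"])


def classify_associations(
    dgas: pd.DataFrame, dti: DTITable
) -> tuple[pd.DataFrame, dict]:
    """Label each ranked association known_dti or novel and summarize.

    The recovery fraction is the share of DTI pairs (restricted to drugs
    that appear in the ranking) found among the top-k associations.
    """
    out = dgas.copy()
    out["status"] = [
        "known_dti" if (d, g) in dti.pairs else "novel"
        for d, g in zip(out["drug_id"], out["gene_id"])
    ]
    ranked_pairs = set(zip(out["drug_id"], out["gene_id"]))
    ranked_drugs = set(out["drug_id"])
    relevant = {(d, g) for d, g in dti.pairs if d in ranked_drugs}
    recovered = relevant & ranked_pairs
    summary = {
        "n_total": int(len(out)),
        "n_known": int((out["status"] == "known_dti").sum()),
        "n_novel": int((out["status"] == "novel").sum()),
        "n_dti_relevant": len(relevant),
        "n_dti_recovered": len(recovered),
        "dti_recovery_fraction": (
            len(recovered) / len(relevant) if relevant else float("nan")
        ),
    }
    return out, summary


def ora_enrichment(
    query_genes: dict[str, list[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    bh_family: str = "per_drug",
) -> pd.DataFrame:
    """Hypergeometric over-representation of per-drug gene lists.

    For each (drug, gene set): with a universe of U genes, a set of K (after
    intersection with the universe), and a query of n genes, the p-value is
    the upper tail P(X >= overlap) of Hypergeometric(U, K, n). BH adjustment
    is applied within each drug's family of tested sets (``per_drug``) or
    across all tests (``global``); adjusted p < alpha flags significance.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query_genes:
        raise ValueError("empty query")
    trimmed_sets = {
        name: genes & universe for name, genes in gene_sets.items()
    }
    rows = []
    for drug_id in sorted(query_genes):
        query = set(query_genes[drug_id])
        if not query:
            raise ValueError(f"empty query gene list for drug {drug_id!r}")
        stray = query - universe
        if stray:
            raise ValueError(
                f"query genes outside the universe for drug {drug_id!r}: "
                f"{sorted(stray)[:5]}"
            )
        for name in sorted(trimmed_sets):
            members = trimmed_sets[name]
            overlap = len(query & members)
            # P(X >= overlap), X ~ Hypergeom(U, K, n)
            p = float(
                hypergeom.sf(overlap - 1, len(universe), len(members), len(query))
            )
            rows.append(
                {
                    "drug_id": drug_id,
                    "gene_set_name": name,
                    "overlap": overlap,
                    "set_size": len(members),
                    "query_size": len(query),
                    "universe_size": len(universe),
                    "p_value": min(p, 1.0),
                }
            )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = np.nan
    if bh_family == "per_drug":
        for drug_id, idx in df.groupby("drug_id").groups.items():
            df.loc[idx, "adjusted_p"] = multipletests(
                df.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    elif bh_family == "global":
        df["adjusted_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        raise ValueError("bh_family must be 'per_drug' or 'global'")
    df["significant"] = df["adjusted_p"] < alpha
    return df


def count_cooccurrences(
    dgas: pd.DataFrame, abstract_index: pd.DataFrame
) -> pd.DataFrame:
    """Count abstracts co-mentioning each ranked drug-gene pair.

    ``abstract_index`` has one row per abstract with columns ``abstract_id``,
    ``drug_ids`` and ``gene_ids`` (iterables or ';'-joined strings). Adds
    ``n_abstracts`` and its natural-log scale ``log_abstracts`` (log1p) to
    the association table.
    """

    def _as_set(x):
        if isinstance(x, str):
            return {t for t in x.split(";") if t}
        return set(x)

    counts: dict[tuple[str, str], int] = {}
    wanted = set(zip(dgas["drug_id"], dgas["gene_id"]))
    for _, row in abstract_index.iterrows():
        drugs = _as_set(row["drug_ids"])
        genes = _as_set(row["gene_ids"])
        for d in drugs:
            for g in genes:
                if (d, g) in wanted:
                    counts[(d, g)] = counts.get((d, g), 0) + 1
    out = dgas.copy()
    out["n_abstracts"] = [
        counts.get((d, g), 0) for d, g in zip(out["drug_id"], out["gene_id"])
    ]
    out["log_abstracts"] = np.log1p(out["n_abstracts"].to_numpy(dtype=float))
    return out
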