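"""End-to-end input preparation: raw tables -> model-ready matrices.

Chains the preprocessing operations in the canonical order (log10 +
percentile filter, margin binarization, variance-based gene selection,
similarity kernels, adjacency blocks) and returns the bundle the
training/evaluation loop consumes.
"""

from __future__ import annotations

import pandas as pd

from .evaluate import EvalInputs
from .graph import build_cell_gene_adjacency, build_drug_gene_adjacency
from .preprocess import (
    DTITable,
    ExpressionTable,
    FingerprintTable,
    binarize_response,
    preprocess_ic50,
    rbf_similarity,
    select_genes,
)

__all__ = ["prepare_inputs"]


def prepare_inputs(
    raw_response: pd.DataFrame,
    expression: ExpressionTable,
    fingerprints: FingerprintTable,
    dti: DTITable,
    top_fraction: float = 1.0,
    pad_mode: str = "zero",
    acg_axis: str = "gene",
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> EvalInputs:
    """Run the full matrix-building chain on raw tables.

    Drugs, cells and genes are ordered lexicographically; cell ids must
    agree between the response and expression tables. ``top_fraction``
    controls variance-based gene selection (1.0 keeps every gene, the
    screen-scale default here; large panels typically use 0.10), with DTI
    genes always retained.
    """
    drug_order = sorted(raw_response.index)
    cell_order = sorted(raw_response.columns)
    if set(cell_order) != set(expression.cell_ids):
        raise ValueError("response and expression tables disagree on cell ids")
    if list(raw_response.index) != drug_order or list(raw_response.columns) != cell_order:
        raw_response = raw_response.loc[drug_order, cell_order]

    table = binarize_response(
        preprocess_ic50(raw_response, lower_pct=lower_pct, upper_pct=upper_pct)
    )

    genes = select_genes(expression, top_fraction=top_fraction, dti_genes=dti.genes())
    expr_sel = ExpressionTable(values=expression.values.loc[cell_order, genes])

    fp = fingerprints.bits.loc[drug_order]
    Sd = rbf_similarity(fp, "drug").values.to_numpy()
    Sc = rbf_similarity(expr_sel.values, "cell").values.to_numpy()
    Sg = rbf_similarity(expr_sel.values.T, "gene").values.to_numpy()

    acg = build_cell_gene_adjacency(expr_sel, axis=acg_axis)
    adg = build_drug_gene_adjacency(dti, drug_order, genes, pad_mode=pad_mode)

    return EvalInputs(
        labels=table.labels,
        acg=acg,
        adg=adg,
        Sd=Sd,
        Sc=Sc,
        Sg=Sg,
        gene_ids=genes,
    )
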