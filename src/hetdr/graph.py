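"""Heterogeneous drug-cell-gene graph assembly.

The unified adjacency stacks three bipartite blocks symmetrically:

    A = [[ 0    Adc  Adg ]
         [ Adc' 0    Acg ]
         [ Adg' Acg' 0   ]]

where Adc is the binary sensitive-association block (masked for held-out
pairs), Acg carries positive expression z-scores (above-average expression),
and Adg carries known drug-target interactions over a zero or 0.5 pad.
Node indices are contiguous: drugs [0, n), cells [n, n+m), genes
[n+m, n+m+l).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DTITable, ExpressionTable

__all__ = [
    "MaskMatrix",
    "HeteroGraph",
    "build_cell_gene_adjacency",
    "build_drug_gene_adjacency",
    "assemble_graph",
]


@dataclass
class MaskMatrix:
    """Binary drugs x cells visibility mask: 0 hides a pair from training."""

    entries: np.ndarray

    def validate(self) -> None:
        if not np.isin(self.entries, [0, 1]).all():
            raise ValueError("mask entries must be 0/1")

    @staticmethod
    def all_visible(n_drugs: int, n_cells: int) -> "MaskMatrix":
        return MaskMatrix(np.ones((n_drugs, n_cells), dtype=np.int8))

    def hiding(self, pairs) -> "MaskMatrix":
        """Copy with the given (drug_idx, cell_idx) pairs additionally hidden."""
        out = self.entries.copy()
        for d, c in pairs:
            out[d, c] = 0
        return MaskMatrix(out)


@dataclass
class HeteroGraph:
    """Block adjacency plus index maps into the drug/cell/gene segments."""

    adjacency: np.ndarray
    adc: np.ndarray
    acg: np.ndarray
    adg: np.ndarray
    drug_ids: list[str]
    cell_ids: list[str]
    gene_ids: list[str]

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_cells + self.n_genes

    def drug_index(self, local: int) -> int:
        return local

    def cell_index(self, local: int) -> int:
        return self.n_drugs + local

    def gene_index(self, local: int) -> int:
        return self.n_drugs + self.n_cells + local

    @property
    def segments(self) -> dict[str, range]:
        n, m, l = self.n_drugs, self.n_cells, self.n_genes
        return {
            "drug": range(0, n),
            "cell": range(n, n + m),
            "gene": range(n + m, n + m + l),
        }

    def validate(self) -> None:
        A = self.adjacency
        n, m, l = self.n_drugs, self.n_cells, self.n_genes
        if A.shape != (n + m + l, n + m + l):
            raise ValueError("adjacency shape inconsistent with index maps")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A[:n, :n].any() or A[n : n + m, n : n + m].any() or A[n + m :, n + m :].any():
            raise ValueError("diagonal blocks must be zero")
        if not np.isin(self.adc, [0, 1]).all():
            raise ValueError("Adc entries must be 0/1")
        if (self.acg < 0).any():
            raise ValueError("Acg entries must be nonnegative")

    def edge_list(self) -> pd.DataFrame:
        """Directed weighted edges (both orientations) with typed labels."""
        n, m = self.n_drugs, self.n_cells
        rows = []
        for (block, roff, coff, etype) in (
            (self.adc, 0, n, "drug-cell"),
            (self.adg, 0, n + m, "drug-gene"),
            (self.acg, n, n + m, "cell-gene"),
        ):
            src, dst = np.nonzero(block)
            for s, d in zip(src, dst):
                w = float(block[s, d])
                rows.append((roff + s, coff + d, w, etype))
                rows.append((coff + d, roff + s, w, etype))
        return pd.DataFrame(rows, columns=["src", "dst", "weight", "edge_type"])


def build_cell_gene_adjacency(
    expr: ExpressionTable, axis: str = "gene", ddof: int = 1
) -> np.ndarray:
    """Positive part of the z-scored expression matrix (cells x genes).

    ``axis='gene'`` standardizes each gene across cell lines (default: the
    retained weights flag above-average expression of that gene);
    ``axis='cell'`` standardizes each cell line across genes. Zero-variance
    columns/rows z-score to 0 with a warning.
    """
    vals = expr.values.to_numpy(dtype=float)
    if axis == "gene":
        mu = vals.mean(axis=0, keepdims=True)
        sd = vals.std(axis=0, ddof=ddof, keepdims=True)
    elif axis == "cell":
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    else:
        raise ValueError("axis must be 'gene' or 'cell'")
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance {axis}(s); their z-scores set to 0",
            stacklevel=2,
        )
    z = np.where(zero, 0.0, (vals - mu) / np.where(zero, 1.0, sd))
    return np.maximum(z, 0.0)


def build_drug_gene_adjacency(
    dti: DTITable,
    drug_ids: list[str],
    gene_ids: list[str],
    pad_mode: str = "zero",
) -> np.ndarray:
    """Drugs x genes DTI block: known pairs 1, unknown pad 0 or 0.5.

    Zero padding treats unknown interactions as absent; soft padding (0.5)
    lets attention diffuse over unannotated drug-gene pairs, which is the
    default for interpretability runs.
    """
    if pad_mode not in ("zero", "soft"):
        raise ValueError("pad_mode must be 'zero' or 'soft'")
    pad = 0.0 if pad_mode == "zero" else 0.5
    return dti.matrix_form(drug_ids, gene_ids, pad_value=pad)


def assemble_graph(
    labels: pd.DataFrame,
    acg: np.ndarray,
    adg: np.ndarray,
    mask: MaskMatrix | None = None,
    gene_ids: list[str] | None = None,
) -> HeteroGraph:
    """Assemble the symmetric block adjacency from the three bipartite blocks.

    Adc gets an edge only for pairs labeled sensitive (1); resistant and
    uncertain pairs contribute no edge. The mask is applied as a Hadamard
    product (Adc * M), so hidden test pairs leave no trace in the graph.
    """
    drug_ids = list(labels.index)
    cell_ids = list(labels.columns)
    n, m = len(drug_ids), len(cell_ids)
    lab = labels.to_numpy(dtype=float)
    adc = (np.isfinite(lab) & (lab == 1.0)).astype(float)
    if mask is None:
        mask = MaskMatrix.all_visible(n, m)
    mask.validate()
    if mask.entries.shape != adc.shape:
        raise ValueError(
            f"mask shape {mask.entries.shape} != labels shape {adc.shape}"
        )
    adc = adc * mask.entries
    if acg.shape[0] != m:
        raise ValueError(f"Acg rows ({acg.shape[0]}) != number of cells ({m})")
    if adg.shape[0] != n:
        raise ValueError(f"Adg rows ({adg.shape[0]}) != number of drugs ({n})")
    if acg.shape[1] != adg.shape[1]:
        raise ValueError(
            f"Acg cols ({acg.shape[1]}) != Adg cols ({adg.shape[1]})"
        )
    l = acg.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(l)]
    if len(gene_ids) != l:
        raise ValueError("gene_ids length inconsistent with Acg/Adg columns")
    N = n + m + l
    A = np.zeros((N, N))
    A[:n, n : n + m] = adc
    A[n : n + m, :n] = adc.T
    A[:n, n + m :] = adg
    A[n + m :, :n] = adg.T
    A[n : n + m, n + m :] = acg
    A[n + m :, n : n + m] = acg.T
    graph = HeteroGraph(
        adjacency=A,
        adc=adc,
        acg=acg,
        adg=adg,
        drug_ids=drug_ids,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
    )
    graph.validate()
    return graph
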