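"""Preprocessing of raw pharmacogenomic tables.

Implements the chain that turns a continuous IC50 screen into binary
sensitivity labels — log10 transform, central-percentile filtering, per-drug
z-scoring and a one-standard-deviation margin rule — together with variance
based gene selection, Morgan fingerprinting of drug structures and RBF-kernel
similarity matrices for each entity type.

Conventions (configurable where noted):

* standard deviation is the sample standard deviation (``ddof=1``) everywhere;
* percentiles use numpy's linear interpolation, and the filtering band is
  inclusive (values equal to a bound survive);
* entity identifiers are sorted lexicographically at load time, and every
  matrix is indexed in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTable",
    "ExpressionTable",
    "DTITable",
    "FingerprintTable",
    "SimilarityMatrix",
    "preprocess_ic50",
    "binarize_response",
    "select_genes",
    "morgan_fingerprints",
    "rbf_similarity",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ResponseTable:
    """Drugs x cell lines response matrix.

    ``values`` holds log10 IC50s (NaN where filtered/missing); ``labels``
    holds the binarized classes: 1.0 sensitive, 0.0 resistant, NaN uncertain.
    """

    values: pd.DataFrame
    labels: pd.DataFrame | None = None

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.labels is not None:
            if self.labels.shape != self.values.shape:
                raise ValueError("labels and values shapes differ")
            lab = self.labels.to_numpy(dtype=float)
            finite = lab[np.isfinite(lab)]
            if not np.isin(finite, [0.0, 1.0]).all():
                raise ValueError("labels must be 0, 1 or NaN")


@dataclass
class ExpressionTable:
    """Cell lines x genes expression matrix (no missing entries)."""

    values: pd.DataFrame

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing entries")


@dataclass
class DTITable:
    """Known drug-target interaction pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def matrix_form(
        self, drug_ids: list[str], gene_ids: list[str], pad_value: float = 0.0
    ) -> np.ndarray:
        """Dense drugs x genes matrix: known pairs 1, the rest ``pad_value``."""
        out = np.full((len(drug_ids), len(gene_ids)), float(pad_value))
        d_idx = {d: i for i, d in enumerate(drug_ids)}
        g_idx = {g: j for j, g in enumerate(gene_ids)}
        for d, g in self.pairs:
            if d in d_idx and g in g_idx:
                out[d_idx[d], g_idx[g]] = 1.0
        return out


@dataclass
class FingerprintTable:
    """Drugs x bits binary fingerprint matrix."""

    bits: pd.DataFrame

    @property
    def drug_ids(self) -> list[str]:
        return list(self.bits.index)

    def validate(self) -> None:
        arr = self.bits.to_numpy()
        if not np.isin(arr, [0, 1]).all():
            raise ValueError("fingerprint entries must be 0/1")


@dataclass
class SimilarityMatrix:
    """Square symmetric RBF similarity in (0, 1], unit diagonal."""

    values: pd.DataFrame
    entity_kind: str = "drug"

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def validate(self, atol: float = 1e-10) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(arr, arr.T, atol=atol):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=atol):
            raise ValueError("similarity diagonal must be 1")
        if (arr <= 0).any() or (arr > 1 + atol).any():
            raise ValueError("similarity entries must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def preprocess_ic50(
    raw: pd.DataFrame, lower_pct: float = 2.5, upper_pct: float = 97.5
) -> ResponseTable:
    """log10-transform raw IC50s and keep only the central percentile band.

    Per drug (row), entries outside the inclusive ``[lower_pct, upper_pct]``
    percentile band (linear-interpolation percentiles over the finite entries)
    are set to NaN. Non-positive IC50s are rejected; an all-missing drug row
    passes through with a warning.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    arr = raw.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(arr) & (arr <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive IC50 at drug {raw.index[i]!r}, cell {raw.columns[j]!r}: "
            f"{arr[i, j]}"
        )
    logged = np.where(np.isfinite(arr), np.log10(np.where(arr > 0, arr, 1.0)), np.nan)
    out = logged.copy()
    for i in range(out.shape[0]):
        row = out[i]
        finite = row[np.isfinite(row)]
        if finite.size == 0:
            warnings.warn(f"drug {raw.index[i]!r} has no finite IC50s", stacklevel=2)
            continue
        lo, hi = np.percentile(finite, [lower_pct, upper_pct])
        outside = np.isfinite(row) & ((row < lo) | (row > hi))
        row[outside] = np.nan
    values = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return ResponseTable(values=values)


def binarize_response(table: ResponseTable, ddof: int = 1) -> ResponseTable:
    """Assign sensitive/resistant/uncertain labels by the mu +/- sigma margin.

    Per drug the (already log-scaled) values are z-scored; x < mu - sigma is
    sensitive (1), x > mu + sigma resistant (0), anything in between —
    including x == mu exactly — uncertain (NaN). A zero-variance drug yields
    an all-NaN row with a warning rather than an error.
    """
    vals = table.values.to_numpy(dtype=float)
    labels = np.full(vals.shape, np.nan)
    for i in range(vals.shape[0]):
        row = vals[i]
        finite = np.isfinite(row)
        if finite.sum() < 2:
            if finite.sum() > 0:
                warnings.warn(
                    f"drug {table.values.index[i]!r}: fewer than 2 finite values; "
                    "labels undefined",
                    stacklevel=2,
                )
            continue
        mu = row[finite].mean()
        sigma = row[finite].std(ddof=ddof)
        if sigma == 0:
            warnings.warn(
                f"drug {table.values.index[i]!r} has zero variance; labels undefined",
                stacklevel=2,
            )
            continue
        labels[i, finite & (row < mu - sigma)] = 1.0
        labels[i, finite & (row > mu + sigma)] = 0.0
    out = ResponseTable(
        values=table.values,
        labels=pd.DataFrame(labels, index=table.values.index, columns=table.values.columns),
    )
    out.validate()
    return out


def select_genes(
    expr: ExpressionTable,
    top_fraction: float = 0.10,
    dti_genes: set[str] | None = None,
    ddof: int = 1,
) -> list[str]:
    """Union of the most variable genes and the DTI genes present in ``expr``.

    Genes are ranked by per-gene sample standard deviation across cell lines;
    the top ``top_fraction`` (at least one gene) is kept and merged with any
    ``dti_genes`` that exist in the table. The result is deterministic:
    sorted lexicographically.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    stds = expr.values.std(axis=0, ddof=ddof)
    n_keep = max(1, int(round(top_fraction * len(stds))))
    # stable ranking: sd descending, gene id ascending on ties
    order = sorted(stds.index, key=lambda g: (-stds[g], g))
    selected = set(order[:n_keep])
    if dti_genes:
        present = set(expr.gene_ids)
        for g in sorted(dti_genes):
            if g in present:
                selected.add(g)
            else:
                warnings.warn(f"DTI gene {g!r} absent from expression; dropped", stacklevel=2)
    return sorted(selected)


def morgan_fingerprints(
    smiles: dict[str, str] | None = None,
    n_bits: int = 2048,
    radius: int = 2,
    precomputed: pd.DataFrame | None = None,
    on_invalid: str = "abort",
) -> FingerprintTable:
    """Morgan (circular, ECFP-like) fingerprints from SMILES via RDKit.

    ``precomputed`` bypasses RDKit entirely and is returned verbatim (used for
    synthetic cohorts). Unparseable SMILES are collected and either raise
    (``on_invalid='abort'``) or are dropped with a warning (``'drop'``).
    """
    if precomputed is not None:
        table = FingerprintTable(bits=precomputed.copy())
        table.validate()
        return table
    if smiles is None:
        raise ValueError("either smiles or precomputed must be given")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, ids, invalid = [], [], []
    for drug_id in sorted(smiles):
        mol = Chem.MolFromSmiles(smiles[drug_id])
        if mol is None:
            invalid.append(drug_id)
            continue
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.int8)
        for b in fp.GetOnBits():
            arr[b] = 1
        rows.append(arr)
        ids.append(drug_id)
    if invalid:
        msg = f"unparseable SMILES for drugs: {invalid}"
        if on_invalid == "abort":
            raise ValueError(msg)
        warnings.warn(msg + " (dropped)", stacklevel=2)
    return FingerprintTable(bits=pd.DataFrame(np.array(rows), index=ids))


def rbf_similarity(X: pd.DataFrame, entity_kind: str = "drug") -> SimilarityMatrix:
    """RBF-kernel similarity S_ij = exp(-gamma ||x_i - x_j||^2), gamma = 1/d.

    ``d`` is the feature count (row length). The result is symmetric with a
    unit diagonal by construction; missing entries are rejected.
    """
    arr = X.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty feature matrix")
    if not np.isfinite(arr).all():
        raise ValueError("feature matrix contains missing entries; impute first")
    gamma = 1.0 / arr.shape[1]
    sq_norms = (arr * arr).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (arr @ arr.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-gamma * d2)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(
        values=pd.DataFrame(S, index=X.index, columns=X.index), entity_kind=entity_kind
    )
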