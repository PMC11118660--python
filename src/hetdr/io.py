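"""Readers and writers for the delimited-text interchange formats.

All tables are TSV by default (CSV accepted on read via the ``sep``
argument): matrices carry row ids in the first column and a header of column
ids; pair lists are two-column; gene sets use GMT (set name, description,
member genes, tab-separated). Writers and readers round-trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DTITable, ExpressionTable, FingerprintTable
from .simulate import SyntheticCohort

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_pairs",
    "write_pairs",
    "read_smiles",
    "read_gmt",
    "write_gmt",
    "write_edge_list",
    "write_json",
    "read_json",
    "write_attention_triplets",
    "write_cohort",
    "load_cohort",
    "file_checksum",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Matrix with row ids in the first column; empty/NA cells become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup_rows = df.index[df.index.duplicated()].tolist()
    if dup_rows:
        raise ValueError(f"{path}: duplicate row ids {sorted(set(dup_rows))}")
    dup_cols = df.columns[df.columns.duplicated()].tolist()
    if dup_cols:
        raise ValueError(f"{path}: duplicate column ids {sorted(set(dup_cols))}")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path, sep))


def read_pairs(path, sep: str | None = None) -> DTITable:
    """Two-column (drug_id, gene_id) pair list."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug_id, gene_id)")
    return DTITable(pairs=set(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_pairs(dti: DTITable, path, sep: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sorted(dti.pairs), columns=["drug_id", "gene_id"])
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_smiles(path, sep: str | None = None) -> dict[str, str]:
    """Two-column (drug_id, SMILES) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug_id, smiles)")
    ids = df.iloc[:, 0]
    dups = ids[ids.duplicated()].tolist()
    if dups:
        raise ValueError(f"{path}: duplicate drug ids {sorted(set(dups))}")
    return dict(zip(ids, df.iloc[:, 1]))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sorted(gene_sets.items())
    ]
    path.write_text("\n".join(lines) + "\n")


def write_edge_list(edges: pd.DataFrame, path, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges.to_csv(path, sep=sep, index=False)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_attention_triplets(attns, path, sep: str = "\t") -> None:
    """Sparse attention export: layer, head, src, dst, weight."""
    rows = []
    for layer, a in enumerate(attns):
        for h, src, dst, w in a.triplets():
            rows.append((layer, h, src, dst, w))
    df = pd.DataFrame(rows, columns=["layer", "head", "src", "dst", "weight"])
    write_edge_list(df, path, sep=sep)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def save_checkpoint(model, path, index_maps: dict | None = None,
                    seed: int | None = None, checksums: dict | None = None) -> None:
    """Serialize a trained model (config + parameters + index maps) to one
    JSON file, with a manifest recording seed and input checksums."""
    state = model.state_dict()
    payload = {
        "config": state["config"],
        "dims": list(state["dims"]),
        "params": [p.tolist() for p in state["params"]],
        "index_maps": index_maps or {},
        "manifest": {"seed": seed, "checksums": checksums or {}},
    }
    write_json(payload, path)


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    from .model import DrugResponseGT, ModelConfig

    payload = read_json(path)
    config = ModelConfig(**payload["config"])
    n, m, l = payload["dims"]
    model = DrugResponseGT(n, m, l, config)
    model.load_state({"params": [np.asarray(p) for p in payload["params"]]})
    return model, payload


# ---------------------------------------------------------------------------
# Synthetic-cohort round trip
# ---------------------------------------------------------------------------

_COHORT_FILES = {
    "response": "response_ic50.tsv",
    "expression": "expression.tsv",
    "fingerprints": "fingerprints.tsv",
    "dti": "dti_known.tsv",
    "truth": "planted_truth.tsv",
    "params": "params.json",
}


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write a cohort as the exact file dialects the builder reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in _COHORT_FILES.items()}
    write_matrix(cohort.response, paths["response"])
    write_matrix(cohort.expression.values, paths["expression"])
    write_matrix(cohort.fingerprints.bits, paths["fingerprints"])
    write_pairs(cohort.dti_known, paths["dti"])
    write_pairs(DTITable(pairs=set(cohort.planted_truth)), paths["truth"])
    write_json({"params": cohort.params, "seed": cohort.seed}, paths["params"])
    return paths


def load_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    meta = read_json(indir / _COHORT_FILES["params"])
    fp = read_matrix(indir / _COHORT_FILES["fingerprints"])
    fp = fp.astype(np.int8)
    cohort = SyntheticCohort(
        response=read_matrix(indir / _COHORT_FILES["response"]),
        expression=ExpressionTable(values=read_matrix(indir / _COHORT_FILES["expression"])),
        fingerprints=FingerprintTable(bits=fp),
        dti_known=read_pairs(indir / _COHORT_FILES["dti"]),
        planted_truth=set(read_pairs(indir / _COHORT_FILES["truth"]).pairs),
        params=meta["params"],
        seed=meta["seed"],
    )
    cohort.validate()
    return cohort
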