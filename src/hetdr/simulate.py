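"""Seeded synthetic pharmacogenomic cohorts with a planted mechanism.

The generator emulates the input tables of a drug-sensitivity screen —
continuous IC50s, gene expression, drug fingerprints and a partially-visible
drug-target table — with a known causal chain: each drug belongs to a
mechanism group with dedicated target genes, a cell line's latent sensitivity
to a drug grows with its standardized expression of those targets, and the
observed IC50 is the exponentiated noisy negative of that latent score. The
log10 / percentile / z-score / margin preprocessing chain therefore runs on
synthetic input exactly as on a real screen, and every planted drug-target
pair is recorded so recovery can be scored exactly.

Mechanism groups also shape the fingerprints: drugs sharing targets share a
dedicated bit block (plus random background bits), giving cold-start
prediction a structure-to-mechanism path through drug similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    DTITable,
    ExpressionTable,
    FingerprintTable,
    binarize_response,
    preprocess_ic50,
)

__all__ = ["SyntheticCohort", "generate_cohort", "describe_truth"]


@dataclass
class SyntheticCohort:
    """Bundle of generated input tables plus the planted ground truth."""

    response: pd.DataFrame  # raw positive IC50s, drugs x cells
    expression: ExpressionTable
    fingerprints: FingerprintTable
    dti_known: DTITable
    planted_truth: set[tuple[str, str]]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.dti_known.pairs <= self.planted_truth:
            raise ValueError("dti_known must be a subset of planted_truth")
        if (self.response.to_numpy() <= 0).any():
            raise ValueError("synthetic IC50s must be strictly positive")


def generate_cohort(
    n_drugs: int = 40,
    n_cells: int = 30,
    n_genes: int = 200,
    targets_per_drug: int = 1,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    dti_visible_fraction: float = 0.5,
    n_mechanisms: int | None = None,
    n_bits: int = 2048,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort with a planted drug -> target-gene -> response chain.

    ``effect_size`` is the standardized mean shift: a cell one standard
    deviation above average in a drug's target expression has its latent
    sensitivity raised by ``effect_size`` (in log10 IC50 units, sign
    flipped). ``n_mechanisms`` groups drugs into mechanism-sharing sets
    (default ``n_drugs // 2``: pairs of drugs share targets and fingerprint
    blocks); each mechanism owns ``targets_per_drug`` distinct target genes.
    ``dti_visible_fraction`` of the planted pairs are exposed as the known
    DTI table.
    """
    if min(n_drugs, n_cells, n_genes, targets_per_drug) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 <= dti_visible_fraction <= 1:
        raise ValueError("dti_visible_fraction must be in [0, 1]")
    if targets_per_drug > n_genes:
        raise ValueError("targets_per_drug cannot exceed n_genes")
    if n_mechanisms is None:
        n_mechanisms = max(1, n_drugs // 2)
    if n_mechanisms * targets_per_drug > n_genes:
        raise ValueError("not enough genes for distinct mechanism targets")
    rng = np.random.default_rng(seed)

    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    cell_ids = [f"C{i:03d}" for i in range(n_cells)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]

    # expression: per-gene baseline mean and spread, Gaussian noise per cell
    gene_mu = rng.uniform(2.0, 8.0, size=n_genes)
    gene_sd = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    expr = gene_mu + gene_sd * rng.standard_normal((n_cells, n_genes))
    expression = ExpressionTable(
        values=pd.DataFrame(expr, index=cell_ids, columns=gene_ids)
    )

    # mechanisms: disjoint target-gene sets; drugs assigned round-robin
    target_pool = rng.choice(n_genes, size=n_mechanisms * targets_per_drug, replace=False)
    mech_targets = target_pool.reshape(n_mechanisms, targets_per_drug)
    drug_mech = np.arange(n_drugs) % n_mechanisms
    planted_truth = {
        (drug_ids[d], gene_ids[g])
        for d in range(n_drugs)
        for g in mech_targets[drug_mech[d]]
    }

    # latent sensitivity from standardized target expression
    z_expr = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    latent = np.empty((n_drugs, n_cells))
    for d in range(n_drugs):
        latent[d] = effect_size * z_expr[:, mech_targets[drug_mech[d]]].mean(axis=1)
    log_ic50 = -latent + noise_sd * rng.standard_normal((n_drugs, n_cells))
    response = pd.DataFrame(10.0 ** log_ic50, index=drug_ids, columns=cell_ids)

    # fingerprints: shared per-mechanism bit block + random background bits
    block = max(8, min(128, n_bits // max(n_mechanisms, 1)))
    n_background = max(4, block // 4)
    bits = np.zeros((n_drugs, n_bits), dtype=np.int8)
    for d in range(n_drugs):
        mech = drug_mech[d]
        start = (mech * block) % max(n_bits - block, 1)
        bits[d, start : start + block] = 1
        bg = rng.choice(n_bits, size=n_background, replace=False)
        bits[d, bg] = 1
    fingerprints = FingerprintTable(
        bits=pd.DataFrame(bits, index=drug_ids, columns=range(n_bits))
    )

    # visible DTI subset of the planted truth
    truth_sorted = sorted(planted_truth)
    n_visible = int(round(dti_visible_fraction * len(truth_sorted)))
    visible_idx = rng.choice(len(truth_sorted), size=n_visible, replace=False)
    dti_known = DTITable(pairs={truth_sorted[i] for i in visible_idx})

    cohort = SyntheticCohort(
        response=response,
        expression=expression,
        fingerprints=fingerprints,
        dti_known=dti_known,
        planted_truth=planted_truth,
        params={
            "n_drugs": n_drugs,
            "n_cells": n_cells,
            "n_genes": n_genes,
            "targets_per_drug": targets_per_drug,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
            "dti_visible_fraction": dti_visible_fraction,
            "n_mechanisms": n_mechanisms,
            "n_bits": n_bits,
        },
        seed=seed,
    )
    cohort.validate()
    return cohort


def describe_truth(cohort: SyntheticCohort) -> dict:
    """Reference report for recovery tests: planted pairs, visible subset,
    and the per-drug class balance after the standard binarization chain."""
    table = binarize_response(preprocess_ic50(cohort.response))
    lab = table.labels.to_numpy(dtype=float)
    balance = pd.DataFrame(
        {
            "n_sensitive": np.nansum(lab == 1.0, axis=1).astype(int),
            "n_resistant": np.nansum(lab == 0.0, axis=1).astype(int),
            "n_uncertain": np.isnan(lab).sum(axis=1).astype(int),
        },
        index=table.values.index,
    )
    return {
        "planted_truth": sorted(cohort.planted_truth),
        "dti_known": sorted(cohort.dti_known.pairs),
        "class_balance": balance,
        "params": dict(cohort.params),
        "seed": cohort.seed,
    }
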