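"""Config-driven hyperparameter grid search.

A deliberately small stand-in for a full search framework: enumerate the
Cartesian product of the supplied parameter lists, score each configuration
by k-fold random-mask validation, and return a ranked table. Intended for
desk-scale screens where a handful of configurations is affordable.
"""

from __future__ import annotations

import itertools
import time

import pandas as pd

from .evaluate import EvalInputs, run_test1
from .model import ModelConfig

__all__ = ["grid_search"]


def grid_search(
    inputs: EvalInputs,
    param_grid: dict[str, list],
    k: int = 5,
    seed: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """Score every combination in ``param_grid`` (ModelConfig field -> list of
    values) by mean k-fold AUROC; rows sorted best-first."""
    names = sorted(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        params = dict(zip(names, combo))
        config = ModelConfig(seed=seed, **params)
        t0 = time.time()
        report = run_test1(inputs, config, k=k, seed=seed)
        row = {
            **params,
            "auroc_mean": report.mean_auroc,
            "auroc_sd": report.sd_auroc,
            "aupr_mean": report.mean_aupr,
            "seconds": round(time.time() - t0, 1),
        }
        rows.append(row)
        if verbose:
            print(row)
    return (
        pd.DataFrame(rows)
        .sort_values("auroc_mean", ascending=False)
        .reset_index(drop=True)
    )
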