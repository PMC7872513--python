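"""Label-permutation false discovery rate over the association table.

Subject labels of the phenotype block (determinants and covariates together)
are shuffled against the indicator block B times; every association model is
re-fit on each permuted dataset.  For an observed p-value p the FDR estimate
is the average number of permuted p-values <= p across permutations, divided
by the number of real p-values <= p (capped at 1).  The significance
threshold for a target FDR is the largest observed p whose estimate is below
the target.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .associations import association_stats
from .config import DETERMINANTS, InputError

__all__ = [
    "PermutationFDRTable",
    "permute_and_fit",
    "fdr_at",
    "threshold_for_fdr",
    "compute_fdr",
]


def permute_and_fit(
    indicators: pd.DataFrame,
    cohort: pd.DataFrame,
    B: int,
    seed: int = 0,
    determinants=DETERMINANTS,
) -> np.ndarray:
    """P-value matrix (B x n_tests) from B whole-row phenotype permutations.

    Each permutation jointly shuffles the phenotype rows (determinant panel
    plus covariates) relative to the indicator rows, breaking every
    indicator-phenotype link while preserving the panel's internal
    correlation structure.  Deterministic given the seed.
    """
    if B < 1:
        raise InputError(f"number of permutations must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    indicators = indicators.reindex(cohort.index)
    out = np.empty((B, len(list(determinants)) * indicators.shape[1]))
    for b in range(B):
        perm = rng.permutation(n)
        shuffled = cohort.iloc[perm].set_index(cohort.index)
        _, _, tstat, dof, _ = association_stats(
            indicators, shuffled, determinants, on_constant="null"
        )
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))
        out[b] = np.clip(p, np.nextafter(0, 1), 1.0).ravel()
    return out


def fdr_at(p: float, real_p, perm_p) -> float:
    """Permutation FDR estimate at observed level ``p``.

    mean over permutations of #{perm <= p} divided by #{real <= p}, capped at
    1; if no real p-value is <= p the estimate is undefined and returned as 1.
    """
    real_p = np.asarray(real_p, dtype=float)
    perm_p = np.asarray(perm_p, dtype=float)
    if real_p.size == 0:
        raise InputError("real p-value list is empty")
    if perm_p.size == 0:
        raise InputError("permutation p-value matrix is empty")
    if not 0 < p <= 1:
        raise InputError(f"p must be in (0, 1], got {p}")
    n_real = int((real_p <= p).sum())
    if n_real == 0:
        return 1.0
    mean_perm = float((perm_p <= p).sum(axis=-1).mean())
    return float(min(mean_perm / n_real, 1.0))


def threshold_for_fdr(target: float, real_p, perm_p) -> float | None:
    """Largest observed real p with FDR estimate <= target; None if no
    observed p qualifies."""
    if not 0 < target < 1:
        raise InputError(f"target FDR must be in (0, 1), got {target}")
    real_p = np.asarray(real_p, dtype=float)
    if real_p.size == 0:
        raise InputError("real p-value list is empty")
    best = None
    for p in np.sort(np.unique(real_p)):
        if fdr_at(float(p), real_p, perm_p) <= target:
            best = float(p)
    return best


@dataclass
class PermutationFDRTable:
    n_permutations: int
    seed: int
    target_fdr: float
    real_p: np.ndarray
    perm_p: np.ndarray  # B x n_tests
    fdr: np.ndarray  # estimate at each observed p
    threshold: float | None

    def to_json(self, path: str | Path, include_perm_p: bool = False) -> None:
        d = {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "target_fdr": self.target_fdr,
            "real_p": self.real_p.tolist(),
            "fdr": self.fdr.tolist(),
            "threshold": self.threshold,
        }
        if include_perm_p:
            d["perm_p"] = self.perm_p.tolist()
        Path(path).write_text(json.dumps(d, indent=1))


def compute_fdr(
    indicators: pd.DataFrame,
    cohort: pd.DataFrame,
    real_p,
    B: int = 1000,
    seed: int = 0,
    target_fdr: float = 0.05,
    determinants=DETERMINANTS,
) -> PermutationFDRTable:
    """Permutation FDR table for an observed association p-value list."""
    real_p = np.asarray(real_p, dtype=float)
    perm_p = permute_and_fit(indicators, cohort, B, seed, determinants)
    fdr = np.array([fdr_at(float(p), real_p, perm_p) for p in real_p])
    thr = threshold_for_fdr(target_fdr, real_p, perm_p)
    return PermutationFDRTable(
        n_permutations=B,
        seed=int(seed),
        target_fdr=float(target_fdr),
        real_p=real_p,
        perm_p=perm_p,
        fdr=fdr,
        threshold=thr,
    )
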