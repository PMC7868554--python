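"""Gene-set permutation test of differential expression.

Individual genes in a co-expressed set are not independent observations, so
counting significant genes overstates set-level differential expression.
This test instead asks how extreme the set's *median absolute* DE statistic
is against random same-sized gene sets, separately in a control contrast
(e.g. untreated vs. scrambled siRNA) and a perturbation contrast (scrambled
vs. knockdown), and reports the ratio of the two exceedance percentages as a
fold-change in differential expression.  Because the same co-expression
structure is present in both contrasts, the ratio cancels it out.

Exceedance uses the add-one estimator 100*(k+1)/(n_perm+1) with a strict
inequality, so both percentages are positive and the ratio is always
defined.  Random sets are drawn without replacement within a draw and
independently across draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .syndata import DeStatTable

_CHUNK_CELLS = 20_000_000  # cap on random-key matrix size per chunk


@dataclass
class PermutationResult:
    set_size: int
    n_permutations: int
    observed_median_abs_control: float
    observed_median_abs_kd: float
    pct_control: float
    pct_kd: float
    fold_change: float
    seed: int


def median_abs_stat(
    stats: Sequence[float], genes: Sequence[str], gene_set: Iterable[str]
) -> float:
    """Median of |statistic| over a gene set (mean-of-middle-two for even sizes)."""
    index = {g: i for i, g in enumerate(genes)}
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise KeyError(f"genes absent from the statistic table: {missing[:5]}")
    values = np.abs(np.asarray(stats, float)[[index[g] for g in gene_set]])
    return float(np.median(values))


def exceedance_pct(
    stats: Sequence[float],
    set_size: int,
    observed: float,
    n_perm: int,
    seed: int | np.random.Generator,
) -> float:
    """Percentage of random same-size gene sets whose median |T| exceeds ``observed``.

    Strict inequality; add-one estimator 100*(k+1)/(n_perm+1).
    """
    values = np.abs(np.asarray(stats, float))
    n_genes = values.shape[0]
    if not 0 < set_size < n_genes:
        raise ValueError("set_size must be in (0, n_genes)")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chunk = max(1, _CHUNK_CELLS // n_genes)
    k = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_genes))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        medians = np.median(values[idx], axis=1)
        k += int((medians > observed).sum())
        done += m
    return 100.0 * (k + 1) / (n_perm + 1)


def de_fold_change(pct_control: float, pct_kd: float) -> float:
    """Fold-change in set-level differential expression.

    Ratio of the control-contrast exceedance percentage to the
    knockdown-contrast one: values above 1 mean the observed set is more
    extreme (harder for random sets to beat) in the knockdown contrast than
    in the control contrast.
    """
    if pct_control <= 0 or pct_kd <= 0:
        raise ValueError("exceedance percentages must be positive")
    return pct_control / pct_kd


def run_permde(
    table: DeStatTable,
    gene_set: Iterable[str],
    n_perm: int = 1_000_000,
    seed: int = 0,
) -> PermutationResult:
    """Full permutation analysis of one gene set over both contrasts."""
    gene_set = list(gene_set)
    obs_c = median_abs_stat(table.stat_control, table.genes, gene_set)
    obs_k = median_abs_stat(table.stat_kd, table.genes, gene_set)
    child_c, child_k = np.random.SeedSequence(seed).spawn(2)
    pct_c = exceedance_pct(
        table.stat_control, len(gene_set), obs_c, n_perm, np.random.default_rng(child_c)
    )
    pct_k = exceedance_pct(
        table.stat_kd, len(gene_set), obs_k, n_perm, np.random.default_rng(child_k)
    )
    return PermutationResult(
        set_size=len(gene_set),
        n_permutations=n_perm,
        observed_median_abs_control=obs_c,
        observed_median_abs_kd=obs_k,
        pct_control=pct_c,
        pct_kd=pct_k,
        fold_change=de_fold_change(pct_c, pct_k),
        seed=seed,
    )
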