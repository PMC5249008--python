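"""Contextualization: rescuing sparse genes by pooling with random context genes.

A gene with only a handful of non-zero cells cannot support a stable mixture
fit on its own.  Its non-zero log2CPM values are therefore pooled with the
non-zero values of several randomly selected context genes and the mixture is
fitted to the pooled sample; the target gene's cells inherit their calls from
that pooled fit.  The procedure is repeated with fresh random context genes
and the final per-cell call is the majority over repetitions, with ties
resolved conservatively to the smaller (low-expression) value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coactive.mixture import (
    EMConfig,
    InsufficientCellsError,
    classify_cells,
    fit_gamma_normal,
)


@dataclass(frozen=True)
class ContextConfig:
    """Controls for contextual fitting.

    ``n_context_genes`` genes are drawn per repetition from the eligible pool
    (by default every other gene with at least ``EMConfig.min_nonzero_cells``
    non-zero cells), ``n_repetitions`` times, each repetition with an
    independent draw.
    """

    n_context_genes: int = 10
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_context_genes < 1:
            raise ValueError("n_context_genes must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


def _eligible_pool(logexpr: pd.DataFrame, target: str, min_nonzero: int) -> list[str]:
    nonzero_counts = (logexpr.to_numpy() > 0).sum(axis=1)
    pool = [
        g
        for g, c in zip(logexpr.index, nonzero_counts)
        if g != target and c >= min_nonzero
    ]
    return pool


def contextual_fit(
    gene: str,
    logexpr: pd.DataFrame,
    em_config: EMConfig = EMConfig(),
    ctx_config: ContextConfig = ContextConfig(),
) -> pd.Series:
    """Ternary calls for one sparse gene via repeated pooled fits.

    Returns a Series over all cells: 0 where the gene's log2CPM is zero,
    1/2 by majority vote over repetitions (ties -> 1), NaN if every
    repetition's pool was still too small to fit.

    Raises ``ValueError`` if the gene is absent, has no non-zero cells, or no
    eligible context genes exist.
    """
    if gene not in logexpr.index:
        raise ValueError(f"gene {gene!r} not present")
    row = logexpr.loc[gene].to_numpy(dtype=float)
    nz_mask = row > 0
    if not nz_mask.any():
        raise ValueError(f"gene {gene!r} has no non-zero cells")

    pool = _eligible_pool(logexpr, gene, em_config.min_nonzero_cells)
    if not pool:
        raise ValueError("no eligible context genes")

    target_values = row[nz_mask]
    n_target = target_values.size
    rng = np.random.default_rng(ctx_config.seed)
    draw = min(ctx_config.n_context_genes, len(pool))

    votes = np.zeros((ctx_config.n_repetitions, n_target), dtype=float)
    for rep in range(ctx_config.n_repetitions):
        ctx_genes = rng.choice(len(pool), size=draw, replace=False)
        ctx_values = [
            v[v > 0]
            for v in (logexpr.loc[pool[j]].to_numpy(dtype=float) for j in ctx_genes)
        ]
        pooled = np.concatenate([target_values, *ctx_values])
        rep_seed = int(rng.integers(0, 2**31))
        rep_config = EMConfig(
            max_iter=em_config.max_iter,
            tol=em_config.tol,
            min_nonzero_cells=em_config.min_nonzero_cells,
            seed=rep_seed,
            z_call_threshold=em_config.z_call_threshold,
        )
        try:
            fit = fit_gamma_normal(pooled, rep_config)
        except InsufficientCellsError:
            votes[rep] = np.nan  # this repetition abstains
            continue
        # the target's values occupy the head of the pooled sample
        votes[rep] = classify_cells(fit, em_config.z_call_threshold)[:n_target]

    out = np.zeros(row.size, dtype=float)
    out[nz_mask] = majority_vote(votes)
    return pd.Series(out, index=logexpr.columns, name=gene)


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Final call per cell from a (repetitions x cells) array of 1/2 votes.

    NaN votes abstain.  Majority wins; an exact tie resolves conservatively
    to the smaller value (1); a cell with only abstentions is NaN.
    """
    votes = np.asarray(votes, dtype=float)
    n_high = (votes == 2).sum(axis=0)
    n_low = (votes == 1).sum(axis=0)
    calls = np.where(n_high > n_low, 2.0, 1.0)  # tie -> the smaller value
    calls[(n_high + n_low) == 0] = np.nan
    return calls


def contextualize_matrix(
    ternary: pd.DataFrame,
    logexpr: pd.DataFrame,
    em_config: EMConfig = EMConfig(),
    ctx_config: ContextConfig = ContextConfig(),
) -> pd.DataFrame:
    """Replace NA rows of a ternary matrix with contextual fits.

    Genes with any NA entry (too few non-zero cells for a direct fit) are
    re-called via ``contextual_fit``; all other rows pass through unchanged.
    Per-gene seeds are derived from ``ctx_config.seed`` for reproducibility.
    """
    result = ternary.copy()
    na_genes = ternary.index[ternary.isna().any(axis=1)]
    gene_seeds = np.random.SeedSequence(ctx_config.seed).generate_state(
        max(len(na_genes), 1)
    ) % 2**31
    for seed, gene in zip(gene_seeds, na_genes):
        cfg = ContextConfig(
            n_context_genes=ctx_config.n_context_genes,
            n_repetitions=ctx_config.n_repetitions,
            seed=int(seed),
        )
        try:
            result.loc[gene] = contextual_fit(gene, logexpr, em_config, cfg)
        except ValueError:
            continue  # no pool or no non-zero cells: leave as NA
    return result
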