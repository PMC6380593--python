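"""Fitness scoring and assembly of the synergistic network.

The three pair measures — synergy S, mean individual AUC M and absolute
Spearman correlation C — are each min–max normalized to [0, 1] over the
evaluated pair collection, and combined into a fitness

    F = -sqrt((1 - S̄)² + (1 - M̄)² + (1 - C̄)²),

the negative Euclidean distance to the ideal point (1, 1, 1).  F is 0 for a
pair attaining the maximum of all three measures and -sqrt(3) at the
anti-ideal point.  The network is the top-``n_links`` pairs by fitness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import ExpressionCompendium, GeneNetwork

logger = logging.getLogger("synet")

F_MIN = -np.sqrt(3.0)

MEASURES = ("S", "M", "C")
DEFAULT_N_LINKS = 50_000


def normalize_measures(scores: pd.DataFrame) -> pd.DataFrame:
    """Min–max normalize S, M, C over the supplied pair collection and
    attach the fitness F.

    Returns a DataFrame with gene_i, gene_j, S_bar, M_bar, C_bar, F.
    A measure constant across all pairs is degenerate; its normalized
    value is set to 1 for every pair (logged).
    """
    out = scores[["gene_i", "gene_j"]].copy()
    dist2 = np.zeros(len(scores))
    for m in MEASURES:
        x = scores[m].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("measure %s is constant; normalized to 1 "
                           "for all pairs", m)
            bar = np.ones_like(x)
        else:
            bar = (x - lo) / (hi - lo)
        out[f"{m}_bar"] = bar
        dist2 += (1.0 - bar) ** 2
    out["F"] = -np.sqrt(dist2)
    return out


def median_fitness(per_fold: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-pair median of F across folds (each fold already normalized
    within itself).  All folds must cover the identical canonical pair set."""
    if not per_fold:
        raise ValueError("no fold fitness tables supplied")
    ref = per_fold[0][["gene_i", "gene_j"]]
    stack = []
    for k, df in enumerate(per_fold):
        if len(df) != len(ref) or not (
                df["gene_i"].to_numpy() == ref["gene_i"].to_numpy()).all() or not (
                df["gene_j"].to_numpy() == ref["gene_j"].to_numpy()).all():
            raise ValueError(f"fold {k} does not cover the canonical pair "
                             "set of fold 0 (scan contract violation)")
        stack.append(df["F"].to_numpy(dtype=float))
    out = ref.copy()
    out["F"] = np.median(np.stack(stack), axis=0)
    return out


def build_synet(fitness: pd.DataFrame,
                n_links: int = DEFAULT_N_LINKS) -> GeneNetwork:
    """Top-``n_links`` pairs by fitness as a network.

    Edge weight is a rank score (rank from worst to best) / n_links in
    (0, 1], preserving fitness order — fitness itself is <= 0 while group
    construction downstream needs positive neighbor-priority weights.
    Ties break lexicographically on (gene_i, gene_j).
    """
    if n_links > len(fitness):
        raise ValueError(f"n_links = {n_links} exceeds {len(fitness)} "
                         "scored pairs")
    ranked = fitness.sort_values(["F", "gene_i", "gene_j"],
                                 ascending=[False, True, True],
                                 kind="stable").head(n_links)
    weight = (n_links - np.arange(n_links)) / n_links
    return GeneNetwork(pd.DataFrame({
        "gene_a": ranked["gene_i"].to_numpy(),
        "gene_b": ranked["gene_j"].to_numpy(),
        "weight": weight,
    }))


def build_corr_network(c: ExpressionCompendium,
                       n_links: int = DEFAULT_N_LINKS) -> GeneNetwork:
    """Co-expression network: absolute Spearman correlation on the given
    (training) samples, top ``n_links`` retained.

    Correlations involving a constant gene are set to 0.
    """
    if c.n_samples < 3:
        raise ValueError("correlation network requires >= 3 samples")
    genes = sorted(c.gene_ids)
    X = c.values[genes].to_numpy(dtype=float)
    R = scipy.stats.rankdata(X, axis=0)
    R -= R.mean(axis=0)
    nrm = np.sqrt((R * R).sum(axis=0))
    const = nrm == 0
    nrm[const] = 1.0
    R /= nrm
    rho = np.abs(R.T @ R)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    iu, ju = np.triu_indices(len(genes), k=1)
    gene_arr = np.array(genes)
    df = pd.DataFrame({"gene_i": gene_arr[iu], "gene_j": gene_arr[ju],
                       "F": np.clip(rho[iu, ju], 0.0, 1.0)})
    n_links = min(n_links, len(df))
    ranked = df.sort_values(["F", "gene_i", "gene_j"],
                            ascending=[False, True, True],
                            kind="stable").head(n_links)
    return GeneNetwork(pd.DataFrame({
        "gene_a": ranked["gene_i"].to_numpy(),
        "gene_b": ranked["gene_j"].to_numpy(),
        "weight": ranked["F"].to_numpy(),
    }))


def infer_synet(c: ExpressionCompendium, n_links: int,
                seed: int = 0, n_repeats: int = 5) -> GeneNetwork:
    """End-to-end network inference on a (training) compendium.

    Runs the full pair scan, normalizes measures over all scored pairs and
    keeps the top-``n_links`` pairs by fitness.  At full scale this is the
    median across inner leave-one-study-out folds; at package scale the
    scan itself already aggregates across those folds, so a single
    normalization pass is applied to its output.
    """
    from .pairscan import scan_pairs

    scores = scan_pairs(c, seed=seed, n_repeats=n_repeats)
    fit = normalize_measures(scores)
    return build_synet(fit, n_links=min(n_links, len(fit)))
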