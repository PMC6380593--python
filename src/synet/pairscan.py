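"""Per-gene and per-pair holdout AUCs, synergy and correlation.

The scan evaluates, for every canonical gene pair (i, j), how well a linear
meta-gene (OLS combination of the two z-scored genes) separates good from
poor outcome in held-out studies, compared to each gene alone.  Evaluation
follows a leave-one-study-out design: for each fold the training studies
are subsampled with replacement to 70%, the meta-gene and the two
single-gene orientations are fitted on the subsample, and AUCs are measured
on the held-out study.  The reported A_i, A_j, A_ij are medians over all
(fold x repeat) cells; C is the absolute Spearman correlation on the full
training partition, median over folds.

Synergy S = A_ij / max(A_i, A_j): a pair is synergistic (S > 1) when the
combination beats its best member.

The subsample drawn for a given (seed, fold, repeat) is keyed by a
counter-based RNG and is therefore identical for every gene and pair,
regardless of how the pair range is chunked across workers.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import ExpressionCompendium

logger = logging.getLogger("synet")

_RIDGE = 1e-8            # stabilizes the 2x2 OLS solve for collinear pairs
_BLOCK = 50_000          # pairs processed per memory block

DEFAULT_N_REPEATS = 5
DEFAULT_SUBSAMPLE = 0.7


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(score: Sequence[float], label: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC of "higher score => poor".

    ``label`` is 1/True for poor, 0/False for good; ties count 1/2.
    The orientation is fixed: no folding of values below 0.5.
    """
    y = np.asarray(label).astype(bool)
    s = np.asarray(score, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = scipy.stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_matrix(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Mann-Whitney AUC (higher => poor) with exact tie handling.

    Ranks come from a double argsort; columns containing ties (rare:
    constant genes) are re-ranked with average ranks.
    """
    n, _ = scores.shape
    n_pos = int(y.sum())
    n_neg = n - n_pos
    order = np.argsort(scores, axis=0, kind="stable")
    ranks = np.empty(scores.shape, dtype=np.float64)
    np.put_along_axis(ranks, order,
                      np.arange(1, n + 1, dtype=np.float64)[:, None], axis=0)
    srt = np.take_along_axis(scores, order, axis=0)
    tied = (srt[1:] == srt[:-1]).any(axis=0)
    if tied.any():
        for j in np.flatnonzero(tied):
            ranks[:, j] = scipy.stats.rankdata(scores[:, j])
    pos_sum = ranks[y.astype(bool)].sum(axis=0)
    return (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# meta-gene
# ---------------------------------------------------------------------------

def fit_metagene(x_i: Sequence[float], x_j: Sequence[float],
                 label: Sequence[int]) -> tuple[float, float, float]:
    """OLS of the 0/1 label on the two z-scored genes.

    Returns (w0, w_i, w_j); the meta-gene score of a sample is
    w0 + w_i * z(x_i) + w_j * z(x_j) with z-scoring parameters learned on
    the training samples.  A constant gene gets weight 0 (logged).
    """
    xi = np.asarray(x_i, dtype=float)
    xj = np.asarray(x_j, dtype=float)
    y = np.asarray(label, dtype=float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    zi, ok_i = _zscore(xi)
    zj, ok_j = _zscore(xj)
    if not (ok_i and ok_j):
        logger.info("constant gene in meta-gene fit; weight set to 0")
    yc = y - y.mean()
    b_i = float(zi @ yc / len(y))
    b_j = float(zj @ yc / len(y))
    r = float(zi @ zj / len(y))
    denom = (1 + _RIDGE) ** 2 - r ** 2
    w_i = ((1 + _RIDGE) * b_i - r * b_j) / denom
    w_j = ((1 + _RIDGE) * b_j - r * b_i) / denom
    return float(y.mean()), w_i, w_j


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x), False
    return (x - x.mean()) / sd, True


def synergy(A_ij: float, A_i: float, A_j: float) -> float:
    """S = A_ij / max(A_i, A_j)."""
    m = max(A_i, A_j)
    if m <= 0:
        raise ValueError("synergy undefined for max(A_i, A_j) <= 0")
    return A_ij / m


# ---------------------------------------------------------------------------
# canonical pair enumeration
# ---------------------------------------------------------------------------

def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n, 2)."""
    return n_genes * (n_genes - 1) // 2


def enumerate_pairs(genes: Sequence[str],
                    start: int = 0, stop: int | None = None
                    ) -> list[tuple[str, str]]:
    """Canonical pair list: genes sorted, all (i, j) with i < j in
    lexicographic order; optionally restricted to pair indices
    [start, stop)."""
    g = sorted(genes)
    ii, jj = _pair_indices(len(g), start, stop)
    return [(g[i], g[j]) for i, j in zip(ii, jj)]


def _pair_indices(n: int, start: int = 0, stop: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    total = pair_count(n)
    if stop is None:
        stop = total
    if not (0 <= start <= stop <= total):
        raise ValueError(f"invalid pair range [{start}, {stop}) for "
                         f"{total} pairs")
    if start == stop:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # offsets[i] = index of pair (i, i+1); row i covers [offsets[i], offsets[i+1])
    i_arange = np.arange(n, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(n - 1 - i_arange)])
    k = np.arange(start, stop, dtype=np.int64)
    ii = np.searchsorted(offsets, k, side="right") - 1
    jj = ii + 1 + (k - offsets[ii])
    return ii, jj


# ---------------------------------------------------------------------------
# cross-study scan engine
# ---------------------------------------------------------------------------

def subsample_indices(seed: int, fold: int, repeat: int, n_train: int,
                      fraction: float = DEFAULT_SUBSAMPLE) -> np.ndarray:
    """With-replacement draw of ceil(fraction * n_train) training indices,
    keyed by (seed, fold, repeat) only — identical for every gene and pair."""
    rng = np.random.default_rng([seed, fold, repeat])
    m = math.ceil(fraction * n_train)
    return rng.integers(0, n_train, size=m)


def _fold_contexts(c: ExpressionCompendium):
    """Yield (fold_index, X_train, y_train, X_test, y_test) over
    leave-one-study-out folds; excluded samples dropped; single-class
    held-out studies skipped with a log record."""
    lab = c.labelled()
    if len(lab.studies) < 2:
        raise ValueError("cross-study scan requires >= 2 studies")
    genes = sorted(lab.gene_ids)
    values = lab.values[genes].to_numpy(dtype=np.float32)
    y = lab.binary_labels().to_numpy()
    study = lab.annot["study"].to_numpy()
    for f, test_study in enumerate(lab.studies):
        te = study == test_study
        y_te = y[te]
        if y_te.min(initial=1) == y_te.max(initial=0) or len(y_te) == 0:
            logger.info("fold %d (study %s): single-class held-out study, "
                        "skipped", f, test_study)
            continue
        yield f, values[~te], y[~te], values[te], y_te


def scan_pairs(c: ExpressionCompendium,
               chunk: tuple[int, int] | None = None,
               seed: int = 0,
               n_repeats: int = DEFAULT_N_REPEATS,
               subsample: float = DEFAULT_SUBSAMPLE) -> pd.DataFrame:
    """Score a (chunk of the) canonical pair enumeration.

    Returns a DataFrame with columns gene_i, gene_j, A_i, A_j, A_ij,
    S, M, C, one row per pair, in canonical order.  Chunks are independent:
    concatenating the chunks of a partition equals a single full scan.
    """
    genes = sorted(c.gene_ids)
    n = len(genes)
    start, stop = chunk if chunk is not None else (0, pair_count(n))
    ii, jj = _pair_indices(n, start, stop)
    n_pairs = len(ii)

    single_cells: list[np.ndarray] = []   # per (fold, repeat): A per gene
    pair_cells: list[np.ndarray] = []     # per (fold, repeat): A per pair
    corr_folds: list[np.ndarray] = []     # per fold: |spearman| per pair

    n_folds_used = 0
    for f, Xtr, ytr, Xte, yte in _fold_contexts(c):
        n_folds_used += 1
        # Spearman on the full training partition, once per fold
        if n_pairs:
            R = scipy.stats.rankdata(Xtr, axis=0).astype(np.float32)
            R -= R.mean(axis=0)
            nrm = np.sqrt((R * R).sum(axis=0))
            nrm[nrm == 0] = 1.0
            R /= nrm
            rho = np.empty(n_pairs, dtype=np.float64)
            for s0 in range(0, n_pairs, _BLOCK):
                s1 = min(s0 + _BLOCK, n_pairs)
                rho[s0:s1] = np.abs(
                    (R[:, ii[s0:s1]] * R[:, jj[s0:s1]]).sum(axis=0))
            corr_folds.append(np.clip(rho, 0.0, 1.0))
        for rep in range(n_repeats):
            idx = subsample_indices(seed, f, rep, len(Xtr), subsample)
            ys = ytr[idx]
            if ys.min(initial=1) == ys.max(initial=0):
                logger.info("fold %d repeat %d: single-class subsample, "
                            "skipped", f, rep)
                continue
            Xs = Xtr[idx]
            mu = Xs.mean(axis=0)
            sd = Xs.std(axis=0)
            const = sd == 0
            sd_safe = np.where(const, 1.0, sd)
            Z = (Xs - mu) / sd_safe
            Z[:, const] = 0.0
            Zt = (Xte - mu) / sd_safe
            Zt[:, const] = 0.0
            yc = (ys - ys.mean()).astype(np.float32)
            b = Z.T @ yc / len(ys)
            # single genes: orientation = sign of OLS slope
            sgn = np.sign(b).astype(np.float32)
            single_cells.append(_auc_matrix(Zt * sgn, yte))
            if n_pairs == 0:
                pair_cells.append(np.empty(0))
                continue
            a_pair = np.empty(n_pairs, dtype=np.float64)
            for s0 in range(0, n_pairs, _BLOCK):
                s1 = min(s0 + _BLOCK, n_pairs)
                bi, bj = b[ii[s0:s1]], b[jj[s0:s1]]
                r = (Z[:, ii[s0:s1]] * Z[:, jj[s0:s1]]).mean(axis=0)
                denom = (1 + _RIDGE) ** 2 - r.astype(np.float64) ** 2
                wi = (((1 + _RIDGE) * bi - r * bj) / denom).astype(np.float32)
                wj = (((1 + _RIDGE) * bj - r * bi) / denom).astype(np.float32)
                scores = Zt[:, ii[s0:s1]] * wi + Zt[:, jj[s0:s1]] * wj
                a_pair[s0:s1] = _auc_matrix(scores, yte)
            pair_cells.append(a_pair)
    if not single_cells:
        raise ValueError("no usable folds: every held-out study was "
                         "single-class")

    a_gene = np.median(np.stack(single_cells), axis=0)
    a_i, a_j = a_gene[ii], a_gene[jj]
    a_ij = (np.median(np.stack(pair_cells), axis=0) if n_pairs
            else np.empty(0))
    corr = (np.median(np.stack(corr_folds), axis=0) if n_pairs
            else np.empty(0))
    best = np.maximum(a_i, a_j)
    gene_arr = np.array(genes)
    return pd.DataFrame({
        "gene_i": gene_arr[ii],
        "gene_j": gene_arr[jj],
        "A_i": a_i,
        "A_j": a_j,
        "A_ij": a_ij,
        "S": a_ij / best,
        "M": (a_i + a_j) / 2.0,
        "C": corr,
    })


def pair_auc_cv(c: ExpressionCompendium, i: str, j: str,
                n_repeats: int = DEFAULT_N_REPEATS,
                subsample: float = DEFAULT_SUBSAMPLE,
                seed: int = 0) -> tuple[float, float, float]:
    """Median leave-one-study-out AUCs (A_i, A_j, A_ij) for one pair.

    Uses the identical subsample streams as a full scan, so the returned
    values match the corresponding rows of ``scan_pairs``.
    """
    genes = sorted(c.gene_ids)
    gi, gj = sorted((i, j))
    k = _pair_rank(genes, gi, gj)
    row = scan_pairs(c, chunk=(k, k + 1), seed=seed, n_repeats=n_repeats,
                     subsample=subsample).iloc[0]
    if i <= j:
        return float(row["A_i"]), float(row["A_j"]), float(row["A_ij"])
    return float(row["A_j"]), float(row["A_i"]), float(row["A_ij"])


def _pair_rank(sorted_genes: Sequence[str], gi: str, gj: str) -> int:
    n = len(sorted_genes)
    i = sorted_genes.index(gi)
    j = sorted_genes.index(gj)
    return i * n - i * (i + 1) // 2 + (j - i - 1)
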