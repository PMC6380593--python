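"""Outcome classifiers: Lasso baseline and network-based outcome predictors.

All models are penalized logistic classifiers scored by AUC.  The baseline
Lasso sees every gene as an independent feature.  The network-based
predictors differ in how they aggregate genes into meta-genes first:

* Group Lasso (GL): each network gene seeds a group of itself plus its K
  strongest neighbors; overlapping groups are handled by variable
  duplication (latent group lasso) with penalty lambda * sum_g sqrt(|g|) *
  ||w_g||_2, solved by FISTA with group soft-thresholding.
* Park: average-linkage hierarchical clustering on correlation distance,
  meta-gene = columnwise mean of each cluster, Lasso on meta-genes, cut
  height chosen by inner cross-validation.
* Chuang: greedy subnetwork expansion from each seed gene, adding the
  neighbor that most improves the training AUC of the averaged (z-scored)
  meta-gene, halting when no candidate improves it.
* Taylor: hubs (degree > 5) ranked by dysregulation — the mean absolute
  difference between good- and poor-class Pearson correlation with their
  neighbors; top hubs' subnetworks become averaged meta-genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.linear_model import LogisticRegression

from .data_io import GeneNetwork
from .pairscan import auc

logger = logging.getLogger("synet")

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 0, 12))
DEFAULT_K_GRID = (1, 3, 5, 7, 10)
DEFAULT_TOP_GENES_GRID = (100, 300, 500, 1000)

TAYLOR_HUB_DEGREE = 5         # hubs have degree strictly greater than this
TAYLOR_TOP_HUB_FRACTION = 0.5


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    return Z, mu, sd_safe


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class SparseLinearModel:
    """z-scored linear score w0 + z(X) @ w over named features."""

    features: list[str]
    mu: np.ndarray
    sd: np.ndarray
    weights: np.ndarray
    intercept: float
    config: dict = field(default_factory=dict)

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mu) / self.sd
        return Z

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        return self._transform(X) @ self.weights + self.intercept

    @property
    def signature(self) -> set[str]:
        return {f for f, w in zip(self.features, self.weights) if w != 0}


@dataclass
class MetaGeneModel:
    """Meta-gene aggregation followed by a sparse linear model.

    ``groups`` maps meta-gene name -> member genes; aggregation is either
    the raw columnwise mean (``mean_raw``, Park) or the mean of z-scored
    members (``mean_z``, Chuang/Taylor) with z parameters from training.
    """

    groups: dict[str, list[str]]
    agg: str
    gene_mu: pd.Series
    gene_sd: pd.Series
    inner: SparseLinearModel
    config: dict = field(default_factory=dict)

    def meta_features(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for name, members in self.groups.items():
            sub = X[members].to_numpy(dtype=float)
            if self.agg == "mean_z":
                sub = (sub - self.gene_mu[members].to_numpy()) \
                    / self.gene_sd[members].to_numpy()
            cols[name] = sub.mean(axis=1)
        return pd.DataFrame(cols, index=X.index)

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        return self.inner.predict_score(self.meta_features(X))

    @property
    def signature(self) -> set[str]:
        out: set[str] = set()
        for name in self.inner.signature:
            out |= set(self.groups[name])
        return out


# ---------------------------------------------------------------------------
# Lasso baseline
# ---------------------------------------------------------------------------

def train_lasso(X: pd.DataFrame, y: Sequence[int], lam: float,
                tol: float = 1e-8, max_iter: int = 20_000,
                seed: int = 0) -> SparseLinearModel:
    """L1-penalized logistic regression: (1/n) logloss + lam * ||w||_1.

    Features are z-scored with training statistics; the intercept is
    unpenalized.  Deterministic given inputs.
    """
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    feats = list(X.columns)
    Z, mu, sd = _standardize(X.to_numpy(dtype=float))
    n = len(y)
    C = 1.0 / (n * max(lam, 1e-12))
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="saga", tol=tol,
                             max_iter=max_iter, random_state=seed)
    clf.fit(Z, y)
    coef = clf.coef_.ravel().copy()
    intercept = float(clf.intercept_[0])
    if not coef.any():
        # fully shrunk model: the intercept optimum is analytic
        p = y.mean()
        intercept = float(np.log(p / (1 - p)))
    return SparseLinearModel(feats, mu, sd, coef, intercept,
                             config={"lambda": lam})


# ---------------------------------------------------------------------------
# group structure + overlapping group lasso
# ---------------------------------------------------------------------------

@dataclass
class GroupStructure:
    """Ordered seed-anchored gene groups; overlap allowed."""

    groups: list[tuple[str, list[str]]]   # (seed, members incl. seed)
    K: int

    def __post_init__(self) -> None:
        for seed, members in self.groups:
            if seed not in members:
                raise ValueError(f"group of seed {seed} lacks its seed")
            if len(members) > self.K + 1:
                raise ValueError(f"group of seed {seed} exceeds K+1 genes")

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for _, members in self.groups:
            out |= set(members)
        return sorted(out)


def build_groups(net: GeneNetwork, K: int) -> GroupStructure:
    """One group per network gene: the seed plus its K highest-weight
    neighbors (fewer if its degree is below K).  Ties on weight break by
    neighbor name."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if net.n_edges == 0:
        raise ValueError("cannot build groups from an empty network")
    adj: dict[str, list[tuple[float, str]]] = {}
    for row in net.edges.itertuples(index=False):
        adj.setdefault(row.gene_a, []).append((row.weight, row.gene_b))
        adj.setdefault(row.gene_b, []).append((row.weight, row.gene_a))
    groups = []
    for seed in sorted(adj):
        nbrs = sorted(adj[seed], key=lambda t: (-t[0], t[1]))[:K]
        groups.append((seed, [seed] + [g for _, g in nbrs]))
    return GroupStructure(groups, K)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class GroupLassoModel:
    """Overlapping group lasso via variable duplication.

    ``weights`` holds the per-gene effective weight (sum over duplicated
    copies) in z-space; ``selected_groups`` are the seeds of groups with a
    non-zero coefficient block.
    """

    features: list[str]
    mu: np.ndarray
    sd: np.ndarray
    weights: np.ndarray
    intercept: float
    selected_groups: list[str]
    converged: bool
    n_iter: int
    config: dict = field(default_factory=dict)

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mu) / self.sd
        return Z @ self.weights + self.intercept

    @property
    def signature(self) -> set[str]:
        return {f for f, w in zip(self.features, self.weights) if w != 0}


def train_group_lasso(X: pd.DataFrame, y: Sequence[int],
                      groups: GroupStructure, lam: float,
                      tol: float = 1e-7, max_iter: int = 20_000
                      ) -> GroupLassoModel:
    """FISTA on the duplicated design.

    Objective: (1/n) sum logloss(w0 + Xd w) + lam * sum_g sqrt(|g|) ||w_g||_2
    where Xd stacks a private copy of each group's member columns.
    """
    y = np.asarray(y, dtype=float)
    _check_classes(y.astype(int))
    feats = list(X.columns)
    col_of = {f: k for k, f in enumerate(feats)}
    Z, mu, sd = _standardize(X.to_numpy(dtype=float))

    dup_cols: list[int] = []
    starts: list[int] = []
    sizes: list[int] = []
    for _, members in groups.groups:
        starts.append(len(dup_cols))
        dup_cols.extend(col_of[m] for m in members)
        sizes.append(len(members))
    dup_cols_arr = np.asarray(dup_cols)
    starts_arr = np.asarray(starts)
    sizes_arr = np.asarray(sizes, dtype=float)
    pen = lam * np.sqrt(sizes_arr)
    Xd = Z[:, dup_cols_arr]
    n, p = Xd.shape

    # Lipschitz constant of the logistic gradient: ||Xd||_2^2 / (4n)
    L = (np.linalg.norm(Xd, 2) ** 2) / (4.0 * n) + 1e-12

    w = np.zeros(p)
    b = float(np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12)))
    wv, bv = w.copy(), b     # momentum point
    t_mom = 1.0
    step = 1.0 / L
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_hat = _sigmoid(Xd @ wv + bv)
        resid = (p_hat - y) / n
        grad_w = Xd.T @ resid
        grad_b = resid.sum()
        w_new = wv - step * grad_w
        b_new = bv - step * grad_b
        # group soft-threshold
        norms = np.sqrt(np.maximum(
            np.add.reduceat(w_new ** 2, starts_arr), 0.0))
        scale = np.maximum(0.0, 1.0 - step * pen / np.maximum(norms, 1e-300))
        w_new *= np.repeat(scale, sizes_arr.astype(int))
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        beta = (t_mom - 1.0) / t_new
        wv = w_new + beta * (w_new - w)
        bv = b_new + beta * (b_new - b)
        delta = max(np.abs(w_new - w).max(initial=0.0), abs(b_new - b))
        w, b, t_mom = w_new, b_new, t_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("group lasso did not converge: %d iterations, "
                       "last step %.3e > tol %.1e", it, delta, tol)

    norms = np.sqrt(np.maximum(np.add.reduceat(w ** 2, starts_arr), 0.0))
    selected = [groups.groups[k][0] for k in np.flatnonzero(norms > 0)]
    eff = np.zeros(len(feats))
    np.add.at(eff, dup_cols_arr, w)
    eff[np.abs(eff) < 1e-300] = 0.0
    return GroupLassoModel(feats, mu, sd, eff, b, selected, converged, it,
                           config={"lambda": lam, "K": groups.K})


# ---------------------------------------------------------------------------
# comparison NOPs
# ---------------------------------------------------------------------------

def _oriented_auc(score: np.ndarray, y: np.ndarray) -> float:
    a = auc(score, y)
    return max(a, 1.0 - a)


def park_nop(X: pd.DataFrame, y: Sequence[int],
             cut_heights: Sequence[float] | None = None,
             lam: float = 0.01, inner_folds: int = 3,
             seed: int = 0) -> MetaGeneModel:
    """Hierarchical-clustering meta-genes (Park).

    Average-linkage clustering on correlation distance 1 - |rho|; the cut
    height is chosen by inner cross-validation of a Lasso trained on the
    cluster means (raw columnwise mean per cluster). A zero cut height
    yields singleton clusters, i.e. plain Lasso.
    """
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    genes = list(X.columns)
    V = X.to_numpy(dtype=float)
    sdv = V.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V, rowvar=False)
    corr[~np.isfinite(corr)] = 0.0
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    if cut_heights is None:
        hs = link[:, 2]
        cut_heights = [0.0] + [float(np.quantile(hs, q))
                               for q in (0.25, 0.5, 0.75, 0.9)]

    rng = np.random.default_rng(seed)
    fold_id = _stratified_folds(y, inner_folds, rng)

    def clusters_at(h: float) -> dict[str, list[str]]:
        labels = sch.fcluster(link, t=h, criterion="distance")
        out: dict[str, list[str]] = {}
        for lab in np.unique(labels):
            members = [genes[k] for k in np.flatnonzero(labels == lab)]
            out[f"cluster_{lab}"] = members
        return out

    best: tuple[float, float] | None = None
    for h in cut_heights:
        groups = clusters_at(h)
        meta = _group_means(X, groups)
        scores = []
        for f in range(inner_folds):
            tr, te = fold_id != f, fold_id == f
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            m = train_lasso(meta[tr], y[tr], lam, seed=seed)
            scores.append(auc(m.predict_score(meta[te]), y[te]))
        mean_auc = float(np.mean(scores)) if scores else 0.5
        if best is None or mean_auc > best[1]:
            best = (h, mean_auc)
    h_best = best[0]
    groups = clusters_at(h_best)
    meta = _group_means(X, groups)
    inner = train_lasso(meta, y, lam, seed=seed)
    dummy_mu = pd.Series(0.0, index=genes)
    dummy_sd = pd.Series(1.0, index=genes)
    return MetaGeneModel(groups, "mean_raw", dummy_mu, dummy_sd, inner,
                         config={"cut_height": h_best, "lambda": lam})


def _group_means(X: pd.DataFrame, groups: dict[str, list[str]]
                 ) -> pd.DataFrame:
    return pd.DataFrame(
        {name: X[members].mean(axis=1) for name, members in groups.items()},
        index=X.index)


def _stratified_folds(y: np.ndarray, k: int, rng) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def chuang_nop(X: pd.DataFrame, y: Sequence[int], net: GeneNetwork,
               lam: float = 0.01, max_size: int = 10,
               seed: int = 0) -> MetaGeneModel:
    """Greedy subnetwork meta-genes (Chuang).

    From each seed gene, repeatedly add the neighboring gene of the current
    subnetwork that maximally improves the training AUC of the averaged
    z-scored meta-gene; halt when no candidate improves it.
    """
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    genes = [g for g in net.nodes if g in set(X.columns)]
    if not genes:
        raise ValueError("no network gene present in the expression matrix")
    Z, mu, sd = _standardize(X[list(X.columns)].to_numpy(dtype=float))
    Zdf = pd.DataFrame(Z, index=X.index, columns=X.columns)
    adj: dict[str, set[str]] = {g: set() for g in genes}
    gene_set = set(genes)
    for row in net.edges.itertuples(index=False):
        if row.gene_a in gene_set and row.gene_b in gene_set:
            adj[row.gene_a].add(row.gene_b)
            adj[row.gene_b].add(row.gene_a)

    subnets: dict[frozenset, list[str]] = {}
    expansions: dict[str, list[float]] = {}
    for seed_gene in genes:
        members = [seed_gene]
        current = _oriented_auc(Zdf[members].mean(axis=1).to_numpy(), y)
        trace = [current]
        while len(members) < max_size:
            cands = sorted(
                set().union(*(adj[m] for m in members)) - set(members))
            best_gain, best_gene, best_score = 0.0, None, current
            for cand in cands:
                score = _oriented_auc(
                    Zdf[members + [cand]].mean(axis=1).to_numpy(), y)
                if score - current > best_gain:
                    best_gain, best_gene, best_score = (score - current,
                                                        cand, score)
            if best_gene is None:
                break
            members.append(best_gene)
            current = best_score
            trace.append(current)
        subnets.setdefault(frozenset(members), sorted(members))
        expansions[seed_gene] = trace

    groups = {f"subnet_{k}": members
              for k, members in enumerate(subnets.values())}
    meta = _meta_mean_z(X, groups, pd.Series(mu, index=X.columns),
                        pd.Series(sd, index=X.columns))
    inner = train_lasso(meta, y, lam, seed=seed)
    model = MetaGeneModel(groups, "mean_z", pd.Series(mu, index=X.columns),
                          pd.Series(sd, index=X.columns), inner,
                          config={"lambda": lam, "max_size": max_size})
    model.config["expansion_traces"] = expansions
    return model


def _meta_mean_z(X: pd.DataFrame, groups: dict[str, list[str]],
                 mu: pd.Series, sd: pd.Series) -> pd.DataFrame:
    cols = {}
    for name, members in groups.items():
        sub = (X[members].to_numpy(dtype=float) - mu[members].to_numpy()) \
            / sd[members].to_numpy()
        cols[name] = sub.mean(axis=1)
    return pd.DataFrame(cols, index=X.index)


def taylor_nop(X: pd.DataFrame, y: Sequence[int], net: GeneNetwork,
               lam: float = 0.01, hub_degree: int = TAYLOR_HUB_DEGREE,
               top_fraction: float = TAYLOR_TOP_HUB_FRACTION,
               seed: int = 0) -> MetaGeneModel:
    """Hub-dysregulation meta-genes (Taylor).

    Hubs are genes of degree > ``hub_degree``.  Each hub is scored by the
    mean over its neighbors of |rho_good - rho_poor| (Pearson within each
    outcome class); the top fraction of hubs (with their neighbors) become
    averaged meta-genes for a Lasso.
    """
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need >= 3 samples in each outcome class")
    present = set(X.columns)
    deg = net.degrees()
    adj: dict[str, set[str]] = {}
    for row in net.edges.itertuples(index=False):
        adj.setdefault(row.gene_a, set()).add(row.gene_b)
        adj.setdefault(row.gene_b, set()).add(row.gene_a)
    hubs = [g for g in net.nodes
            if deg[g] > hub_degree and g in present]
    if not hubs:
        raise ValueError(f"no hub (degree > {hub_degree}) present in the "
                         "expression matrix")

    def _cls_corr(mask: np.ndarray, a: str, bs: list[str]) -> np.ndarray:
        va = X[a].to_numpy(dtype=float)[mask]
        vb = X[bs].to_numpy(dtype=float)[mask]
        va = va - va.mean()
        vb = vb - vb.mean(axis=0)
        denom = np.sqrt((va ** 2).sum()) * np.sqrt((vb ** 2).sum(axis=0))
        denom[denom == 0] = np.inf
        return (vb.T @ va) / denom

    good, poor = y == 0, y == 1
    hub_scores: dict[str, float] = {}
    hub_members: dict[str, list[str]] = {}
    for h in hubs:
        nbrs = sorted(g for g in adj[h] if g in present)
        if not nbrs:
            continue
        d_rho = np.abs(_cls_corr(good, h, nbrs) - _cls_corr(poor, h, nbrs))
        hub_scores[h] = float(d_rho.mean())
        hub_members[h] = [h] + nbrs
    ranked = sorted(hub_scores, key=lambda g: (-hub_scores[g], g))
    n_keep = max(1, int(np.ceil(top_fraction * len(ranked))))
    groups = {f"hub_{h}": hub_members[h] for h in ranked[:n_keep]}

    Z, mu, sd = _standardize(X.to_numpy(dtype=float))
    mu_s = pd.Series(mu, index=X.columns)
    sd_s = pd.Series(sd, index=X.columns)
    meta = _meta_mean_z(X, groups, mu_s, sd_s)
    inner = train_lasso(meta, y, lam, seed=seed)
    model = MetaGeneModel(groups, "mean_z", mu_s, sd_s, inner,
                          config={"lambda": lam, "hub_degree": hub_degree,
                                  "top_fraction": top_fraction})
    model.config["hub_scores"] = hub_scores
    return model


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def tune(train_fn: Callable[..., object], grid: Sequence[dict],
         folds: Sequence[tuple[pd.DataFrame, np.ndarray,
                               pd.DataFrame, np.ndarray]],
         X: pd.DataFrame | None = None, y: np.ndarray | None = None):
    """Exhaustive grid search over configs on precomputed inner folds.

    ``train_fn(X_train, y_train, **config)`` must return a model with
    ``predict_score``.  Selects the config maximizing mean inner-fold AUC;
    ties prefer the smaller model: larger ``lambda`` (or ``lam``), then
    smaller ``K``.  Refits on (X, y) when given, else returns the config.
    Returns (best_config, refit_model_or_None, grid_surface DataFrame).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for cfg in grid:
        scores = []
        for X_tr, y_tr, X_te, y_te in folds:
            if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
                continue
            model = train_fn(X_tr, y_tr, **cfg)
            scores.append(auc(model.predict_score(X_te), y_te))
        rows.append({**cfg, "inner_auc":
                     float(np.mean(scores)) if scores else 0.5})
    surface = pd.DataFrame(rows)

    def sort_key(k: int) -> tuple:
        cfg = grid[k]
        lam = cfg.get("lam", cfg.get("lambda", 0.0))
        return (-rows[k]["inner_auc"], -lam, cfg.get("K", 0))

    best_idx = min(range(len(grid)), key=sort_key)
    best_cfg = dict(grid[best_idx])
    model = train_fn(X, y, **best_cfg) if X is not None else None
    return best_cfg, model, surface
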