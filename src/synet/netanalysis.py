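"""Network null models, overlap statistics, topological features and
link prediction.

Null models: node-label shuffling preserves the unlabeled topology exactly
(degree distribution, clustering, components) while destroying which gene
sits where; degree-preserving rewiring (double edge swaps) keeps every
node's degree but randomizes the wiring.

Overlap z-scores standardize the observed gene/link overlap between a
reference network and a thresholded target against a shuffle-based null.

Link prediction asks whether the reference network's links can be
recovered from graph-topological descriptions of gene pairs in other
networks, with a gene-leakage-aware cross-validation (training pairs that
share a gene with any test pair are removed).
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_io import GeneNetwork

logger = logging.getLogger("synet")

DEFAULT_DAMPINGS = (0.1, 0.3, 0.5, 0.85)
DEFAULT_N_NULL = 1000
DEFAULT_LINK_FOLDS = 50


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def shuffle_node_labels(n: GeneNetwork, seed: int = 0) -> GeneNetwork:
    """Permute node identities uniformly at random; the unlabeled topology
    is untouched."""
    nodes = n.nodes
    rng = np.random.default_rng(seed)
    perm = dict(zip(nodes, rng.permutation(nodes)))
    e = n.edges
    return GeneNetwork.from_pairs(
        zip(e["gene_a"].map(perm), e["gene_b"].map(perm)),
        e["weight"].to_numpy())


def rewire_preserving_degree(n: GeneNetwork, n_swaps: int | None = None,
                             seed: int = 0) -> GeneNetwork:
    """Double-edge-swap randomization keeping every node's degree.

    Performs up to ``n_swaps`` successful swaps (default 10 * |E|); no
    self-loops or multi-edges are introduced.  Weights are reassigned to
    the rewired edges in shuffled order.  If the graph is too rigid to
    reach the budget (e.g. a triangle) the achieved count is logged.
    """
    if n.n_edges < 2:
        raise ValueError("rewiring requires >= 2 edges")
    if n_swaps is None:
        n_swaps = 10 * n.n_edges
    rng = np.random.default_rng(seed)
    edges = [tuple(t) for t in
             n.edges[["gene_a", "gene_b"]].itertuples(index=False)]
    edge_set = set(edges)
    m = len(edges)
    done = 0
    attempts = 0
    max_attempts = max(100, 40 * n_swaps)
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, m, size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, c) and (b, d)
        if len({a, b, c, d}) < 4:
            continue
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[k1])
        edge_set.discard(edges[k2])
        edges[k1], edges[k2] = e1, e2
        edge_set.add(e1)
        edge_set.add(e2)
        done += 1
    if done < n_swaps:
        logger.info("rewire: achieved %d of %d swaps (%d attempts)",
                    done, n_swaps, attempts)
    w = n.edges["weight"].to_numpy().copy()
    rng.shuffle(w)
    return GeneNetwork.from_pairs(edges, w)


# ---------------------------------------------------------------------------
# overlap z-scores
# ---------------------------------------------------------------------------

def _overlap(reference: GeneNetwork, target: GeneNetwork, unit: str) -> int:
    if unit == "genes":
        return len(set(reference.nodes) & set(target.nodes))
    if unit == "links":
        return len(reference.edge_set() & target.edge_set())
    raise ValueError(f"unknown overlap unit {unit!r}")


def overlap_zscore(reference: GeneNetwork, target: GeneNetwork,
                   unit: str = "links",
                   fractions: Sequence[float] = (1.0,),
                   n_null: int = DEFAULT_N_NULL, seed: int = 0,
                   null_model: str = "node_shuffle") -> pd.DataFrame:
    """Observed-vs-null overlap between a reference network and the top
    fraction of a target network.

    For each fraction, the target is thresholded to that share of its
    links, the gene or link overlap with the reference is counted, and a
    null distribution is built from ``n_null`` shuffles of the thresholded
    target (node-label shuffling by default, which keeps the degree
    distribution intact; ``null_model="rewire"`` uses degree-preserving
    double edge swaps instead).  Returns one row per fraction with
    observed, null mean/sd and z; z is NaN when the null sd is 0.
    """
    from .data_io import threshold_network

    rows = []
    rng = np.random.default_rng(seed)
    for frac in fractions:
        k = max(1, int(round(frac * target.n_edges)))
        thr = threshold_network(target, "top_links", k)
        obs = _overlap(reference, thr, unit)
        null = np.empty(n_null)
        for t in range(n_null):
            s = int(rng.integers(2**31))
            if null_model == "node_shuffle":
                shuf = shuffle_node_labels(thr, seed=s)
            elif null_model == "rewire":
                shuf = rewire_preserving_degree(thr, seed=s)
            else:
                raise ValueError(f"unknown null model {null_model!r}")
            null[t] = _overlap(reference, shuf, unit)
        sd = null.std(ddof=1)
        if sd == 0:
            logger.warning("overlap null sd = 0 at fraction %s; "
                           "z undefined", frac)
            z = np.nan
        else:
            z = (obs - null.mean()) / sd
        rows.append({"fraction": frac, "observed": obs,
                     "null_mean": null.mean(), "null_sd": sd, "z": z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# topological pair features
# ---------------------------------------------------------------------------

def _node_measures(g: nx.Graph, dampings: Sequence[float]) -> dict:
    out = {"degree": dict(g.degree())}
    for beta in dampings:
        out[f"pagerank{beta}"] = nx.pagerank(g, alpha=beta, tol=1e-12,
                                             max_iter=500)
    out["closeness"] = nx.closeness_centrality(g)
    out["clustering"] = nx.clustering(g)
    try:
        out["eigenvector"] = nx.eigenvector_centrality_numpy(g)
    except Exception:  # empty / degenerate graphs
        out["eigenvector"] = {v: 0.0 for v in g}
    return out


def _finite_diameter(g: nx.Graph) -> int:
    best = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) > 1:
            best = max(best, nx.diameter(sub))
    return best


def topo_features(pairs: Sequence[tuple[str, str]],
                  networks: dict[str, GeneNetwork],
                  dampings: Sequence[float] = DEFAULT_DAMPINGS,
                  null_companion_seed: int | None = None) -> pd.DataFrame:
    """Graph-topological description of gene pairs, per network.

    Node measures (degree, pagerank at each damping, closeness, clustering
    coefficient, eigenvector centrality) are edge-ized as the pair mean and
    absolute difference; pair measures are the direct-link indicator,
    shortest-path length and the neighbor Jaccard index.  A pair
    unreachable (or absent) in a network gets shortest path coded as the
    network's finite diameter + 1 and zeros elsewhere.

    When ``null_companion_seed`` is set, each pair additionally gets the
    same features computed for (gene_i, random gene) — a per-pair expected
    null — under columns suffixed ``__null``.
    """
    pairs = [tuple(sorted(p)) for p in pairs]
    if null_companion_seed is not None:
        rng = np.random.default_rng(null_companion_seed)
        universe = sorted({g for net in networks.values()
                           for g in net.nodes})
        companions = []
        for u, _ in pairs:
            v = u
            while v == u:
                v = universe[int(rng.integers(len(universe)))]
            companions.append(tuple(sorted((u, v))))
        base = topo_features(pairs, networks, dampings)
        null = topo_features(companions, networks, dampings)
        null.columns = [f"{c}__null" for c in null.columns]
        null.index = base.index
        return pd.concat([base, null], axis=1)
    index = pd.MultiIndex.from_tuples(pairs, names=["gene_i", "gene_j"])
    cols = {}
    for net_name, net in networks.items():
        g = net.to_nx()
        nm = _node_measures(g, dampings)
        far = _finite_diameter(g) + 1
        sp_cache: dict[str, dict] = {}

        def sp(u: str, v: str) -> float:
            if u not in g or v not in g:
                return far
            if u not in sp_cache:
                sp_cache[u] = nx.single_source_shortest_path_length(g, u)
            return sp_cache[u].get(v, far)

        feats: dict[str, list] = {}
        for u, v in pairs:
            present_u, present_v = u in g, v in g
            row = {
                "direct_link": float(present_u and present_v
                                     and g.has_edge(u, v)),
                "shortest_path": float(sp(u, v)) if u != v else 0.0,
            }
            if present_u and present_v:
                nu, nv = set(g[u]), set(g[v])
                union = nu | nv
                row["neighbor_jaccard"] = (len(nu & nv) / len(union)
                                           if union else 0.0)
            else:
                row["neighbor_jaccard"] = 0.0
            for meas, values in nm.items():
                a = float(values.get(u, 0.0))
                b = float(values.get(v, 0.0))
                row[f"{meas}_avg"] = (a + b) / 2.0
                row[f"{meas}_diff"] = abs(a - b)
            for key, val in row.items():
                feats.setdefault(key, []).append(val)
        for key, vals in feats.items():
            cols[f"{net_name}|{key}"] = vals
    out = pd.DataFrame(cols, index=index)
    assert np.isfinite(out.to_numpy(dtype=float)).all()
    return out


# ---------------------------------------------------------------------------
# link prediction
# ---------------------------------------------------------------------------

def sample_negative_pairs(reference: GeneNetwork, n: int,
                          seed: int = 0) -> list[tuple[str, str]]:
    """Uniform non-linked pairs over the reference network's genes."""
    nodes = reference.nodes
    linked = reference.edge_set()
    max_pairs = len(nodes) * (len(nodes) - 1) // 2
    if n > max_pairs - len(linked):
        raise ValueError("not enough non-linked pairs to sample")
    rng = np.random.default_rng(seed)
    out: set[tuple[str, str]] = set()
    while len(out) < n:
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        p = (min(nodes[i], nodes[j]), max(nodes[i], nodes[j]))
        if p not in linked:
            out.add(p)
    return sorted(out)


def _leakage_free_folds(pairs: list[tuple[str, str]], labels: np.ndarray,
                        n_folds: int, seed: int
                        ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold assignments where no training pair shares a gene with any test
    pair of its fold."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(pairs), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    folds = []
    for f in range(n_folds):
        test_idx = np.flatnonzero(fold_of == f)
        test_genes = {g for k in test_idx for g in pairs[k]}
        train_idx = np.array([k for k in np.flatnonzero(fold_of != f)
                              if not (pairs[k][0] in test_genes
                                      or pairs[k][1] in test_genes)],
                             dtype=int)
        if len(train_idx) == 0 or len(np.unique(labels[train_idx])) < 2 \
                or len(np.unique(labels[test_idx])) < 2:
            logger.info("link-prediction fold %d emptied by leakage "
                        "removal; skipped", f)
            continue
        folds.append((train_idx, test_idx))
    return folds


def predict_links(features: pd.DataFrame,
                  positives: Sequence[tuple[str, str]],
                  n_folds: int = DEFAULT_LINK_FOLDS, seed: int = 0,
                  lam: float = 0.01) -> dict:
    """Predict reference-network links from topological features.

    ``features`` is a pair-indexed matrix (as from :func:`topo_features`)
    covering both positive pairs (reference links) and sampled negative
    pairs; ``positives`` flags the former.  An L1 logistic classifier is
    trained per fold under the gene-leakage-aware scheme and AUC is
    reported per source network (column prefix before "|") and for all
    networks combined, together with feature selection frequencies.
    """
    from .pairscan import auc as _auc

    pos = {tuple(sorted(p)) for p in positives}
    pairs = list(features.index)
    y = np.array([1 if p in pos else 0 for p in pairs])
    folds = _leakage_free_folds(pairs, y, n_folds, seed)
    if not folds:
        raise ValueError("no usable link-prediction folds")
    net_names = sorted({c.split("|")[0] for c in features.columns})
    col_groups = {name: [c for c in features.columns
                         if c.startswith(name + "|")]
                  for name in net_names}
    col_groups["combined"] = list(features.columns)

    X_all = features.to_numpy(dtype=float)
    col_pos = {c: k for k, c in enumerate(features.columns)}
    aucs: dict[str, list[float]] = {k: [] for k in col_groups}
    sel_counts = pd.Series(0.0, index=features.columns)
    for train_idx, test_idx in folds:
        for name, cols in col_groups.items():
            ck = [col_pos[c] for c in cols]
            Xtr = X_all[np.ix_(train_idx, ck)]
            Xte = X_all[np.ix_(test_idx, ck)]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            clf = LogisticRegression(
                l1_ratio=1.0, solver="saga", tol=1e-6, max_iter=5000,
                C=1.0 / (len(train_idx) * lam), random_state=seed)
            clf.fit((Xtr - mu) / sd, y[train_idx])
            score = (Xte - mu) / sd @ clf.coef_.ravel()
            aucs[name].append(_auc(score, y[test_idx]))
            if name == "combined":
                sel_counts[np.asarray(cols)[clf.coef_.ravel() != 0]] += 1
    return {
        "auc": {k: float(np.mean(v)) for k, v in aucs.items()},
        "auc_per_fold": {k: list(map(float, v)) for k, v in aucs.items()},
        "selection_frequency": (sel_counts / len(folds)).to_dict(),
        "folds": [(train_idx.tolist(), test_idx.tolist())
                  for train_idx, test_idx in folds],
        "pairs": pairs,
        "labels": y.tolist(),
    }
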