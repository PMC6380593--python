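"""Cross-study validation harness.

Evaluation is leave-one-study-out: each study in turn is the untouched
test set while networks are inferred and models trained on the remaining
studies only.  A single immutable :class:`FoldPlan` fixes the study
assignments (outer and inner) and the subsample streams, and is reused
verbatim by every compared method so that performance differences cannot
stem from fold composition.  Per repeat, the model is refit on a fresh
70%-with-replacement draw of the outer training samples.

A leakage guard checks every training call's sample ids against the
held-out study and aborts the run on any intersection.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (ExpressionCompendium, GeneNetwork, OUTCOME_POOR,
                      OUTCOME_GOOD)
from . import nop as _nop
from .netbuild import build_corr_network, infer_synet
from .pairscan import auc

logger = logging.getLogger("synet")

DEFAULT_N_REPEATS = 10
DEFAULT_SUBSAMPLE = 0.7


class LeakageError(RuntimeError):
    """Test-study samples reached a training call."""


def _assert_disjoint(train_ids: Sequence[str], test_ids: Sequence[str],
                     context: str) -> None:
    inter = set(train_ids) & set(test_ids)
    if inter:
        raise LeakageError(
            f"{context}: {len(inter)} sample(s) appear in both training "
            f"and test sets, e.g. {sorted(inter)[:3]}")


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Deterministic study-level train/test assignments.

    ``outer[f]`` = (test_study, train_studies); ``inner[f]`` lists
    (inner_test_study, inner_train_studies) drawn from the outer training
    studies only.
    """

    studies: tuple[str, ...]
    outer: tuple[tuple[str, tuple[str, ...]], ...]
    inner: tuple[tuple[tuple[str, tuple[str, ...]], ...], ...]
    n_repeats: int
    subsample: float
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer)

    def to_json(self) -> str:
        obj = {
            "studies": list(self.studies),
            "outer": [{"test": t, "train": list(tr)} for t, tr in self.outer],
            "inner": [[{"test": t, "train": list(tr)} for t, tr in folds]
                      for folds in self.inner],
            "n_repeats": self.n_repeats,
            "subsample": self.subsample,
            "seed": self.seed,
        }
        return json.dumps(obj, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        obj = json.loads(text)
        return cls(
            studies=tuple(obj["studies"]),
            outer=tuple((f["test"], tuple(f["train"])) for f in obj["outer"]),
            inner=tuple(tuple((f["test"], tuple(f["train"])) for f in folds)
                        for folds in obj["inner"]),
            n_repeats=obj["n_repeats"],
            subsample=obj["subsample"],
            seed=obj["seed"],
        )

    def validate(self) -> None:
        tests = [t for t, _ in self.outer]
        if sorted(tests) != sorted(set(tests)) or set(tests) != set(self.studies):
            raise LeakageError("outer test studies do not partition the "
                               "study set")
        for f, (test, train) in enumerate(self.outer):
            if test in train:
                raise LeakageError(f"outer fold {f}: test study {test!r} "
                                   "also in training studies")
            for it, itr in self.inner[f]:
                if it == test or test in itr:
                    raise LeakageError(
                        f"outer fold {f}: inner fold uses the outer test "
                        f"study {test!r}")
                if not (set(itr) | {it}) <= set(train):
                    raise LeakageError(
                        f"outer fold {f}: inner fold leaves the outer "
                        "training studies")


def make_fold_plan(c: ExpressionCompendium,
                   n_repeats: int = DEFAULT_N_REPEATS,
                   seed: int = 0,
                   subsample: float = DEFAULT_SUBSAMPLE) -> FoldPlan:
    """Leave-one-study-out outer folds; within each, leave-one-study-out
    inner folds over the outer training studies."""
    studies = tuple(c.studies)
    if len(studies) < 3:
        raise ValueError("fold plan requires >= 3 studies")
    outer = []
    inner = []
    for test in studies:
        train = tuple(s for s in studies if s != test)
        outer.append((test, train))
        inner.append(tuple((it, tuple(s for s in train if s != it))
                           for it in train))
    return FoldPlan(studies, tuple(outer), tuple(inner),
                    n_repeats, subsample, seed)


# ---------------------------------------------------------------------------
# evaluation results
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    method: str
    network: str
    aucs: np.ndarray                       # folds x repeats, NaN = skipped
    signatures: dict = field(default_factory=dict)      # (fold, rep) -> set
    configs: dict = field(default_factory=dict)         # (fold, rep) -> dict
    predictions: dict = field(default_factory=dict)     # (fold, rep) -> Series

    def vote_matrix(self) -> pd.DataFrame:
        """Samples x repeats frame of predicted classes, ready for
        :func:`majority_vote_prognosis` (each sample is predicted in the
        repeats where its study was the held-out test study)."""
        by_rep: dict[int, dict] = {}
        for (_, rep), series in self.predictions.items():
            by_rep.setdefault(rep, {}).update(series.to_dict())
        return pd.DataFrame({f"repeat_{r}": pd.Series(v)
                             for r, v in sorted(by_rep.items())})

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for f in range(self.aucs.shape[0]):
            for r in range(self.aucs.shape[1]):
                rows.append({"method": self.method, "network": self.network,
                             "fold": f, "repeat": r,
                             "auc": self.aucs[f, r]})
        return pd.DataFrame(rows)


def stability_metrics(r: EvalResult) -> dict[str, float]:
    """Mean and sample standard deviation of the AUC over fold x repeat
    cells."""
    cells = r.aucs[np.isfinite(r.aucs)]
    if cells.size < 2:
        raise ValueError("need >= 2 fold x repeat cells")
    return {"mean_auc": float(cells.mean()),
            "sd_auc": float(cells.std(ddof=1))}


def signature_jaccard(signatures: Sequence[set]) -> dict[str, float]:
    """Mean and sd of the pairwise Jaccard index over signature sets.

    Two empty sets count as identical (J = 1, logged)."""
    sigs = list(signatures)
    if len(sigs) < 2:
        raise ValueError("need >= 2 signatures")
    vals = []
    for a in range(len(sigs)):
        for b in range(a + 1, len(sigs)):
            A, B = set(sigs[a]), set(sigs[b])
            if not A and not B:
                logger.info("two empty signatures: Jaccard defined as 1")
                vals.append(1.0)
            else:
                vals.append(len(A & B) / len(A | B))
    arr = np.asarray(vals)
    return {"mean_jaccard": float(arr.mean()),
            "sd_jaccard": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}


def majority_vote_prognosis(predictions: pd.DataFrame,
                            seed: int = 0) -> pd.Series:
    """Per-sample good/poor class by majority over repeats.

    ``predictions``: samples x repeats frame of {good, poor} (NaN where a
    sample was not predicted in a repeat).  Exact ties break by a seeded
    coin flip; samples never predicted are excluded (logged).
    """
    rng = np.random.default_rng(seed)
    out = {}
    n_dropped = 0
    for sample, row in predictions.iterrows():
        votes = row.dropna()
        if votes.empty:
            n_dropped += 1
            continue
        n_poor = int((votes == OUTCOME_POOR).sum())
        n_good = int((votes == OUTCOME_GOOD).sum())
        if n_poor > n_good:
            out[sample] = OUTCOME_POOR
        elif n_good > n_poor:
            out[sample] = OUTCOME_GOOD
        else:
            out[sample] = OUTCOME_POOR if rng.random() < 0.5 else OUTCOME_GOOD
    if n_dropped:
        logger.info("majority vote: %d sample(s) never predicted, excluded",
                    n_dropped)
    return pd.Series(out, name="prognosis")


def logrank_pvalue(groups: pd.Series, annot: pd.DataFrame) -> float:
    """Log-rank test between predicted good and poor groups using the
    survival annotation (survival_time, event)."""
    from lifelines.statistics import logrank_test

    a = annot.loc[groups.index]
    poor = groups == OUTCOME_POOR
    res = logrank_test(a.loc[poor, "survival_time"],
                       a.loc[~poor, "survival_time"],
                       event_observed_A=a.loc[poor, "event"],
                       event_observed_B=a.loc[~poor, "event"])
    return float(res.p_value)


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def _restrict_network(net: GeneNetwork, genes: set[str]) -> GeneNetwork:
    keep = net.edges[net.edges["gene_a"].isin(genes)
                     & net.edges["gene_b"].isin(genes)]
    n_drop = net.n_edges - len(keep)
    if n_drop:
        logger.info("dropped %d network edge(s) with genes absent from "
                    "the compendium", n_drop)
    return GeneNetwork(keep)


def _fit_method(method: str, X: pd.DataFrame, y: np.ndarray,
                network: GeneNetwork | None, cfg: dict, seed: int):
    cfg = dict(cfg)
    lam = cfg.pop("lam", 0.01)
    if method == "lasso":
        feats = X.columns
        if network is not None:
            feats = [g for g in X.columns if g in set(network.nodes)]
        return _nop.train_lasso(X[list(feats)], y, lam, seed=seed)
    if method == "gl":
        if network is None:
            raise ValueError("group lasso requires a network")
        groups = _nop.build_groups(network, K=cfg.pop("K", 5))
        return _nop.train_group_lasso(X[groups.genes], y, groups, lam)
    if method == "park":
        return _nop.park_nop(X, y, lam=lam, seed=seed, **cfg)
    if method == "chuang":
        if network is None:
            raise ValueError("chuang requires a network")
        return _nop.chuang_nop(X, y, network, lam=lam, seed=seed, **cfg)
    if method == "taylor":
        if network is None:
            raise ValueError("taylor requires a network")
        return _nop.taylor_nop(X, y, network, lam=lam, seed=seed, **cfg)
    raise ValueError(f"unknown method {method!r}")


def _expand_grid(cfg: dict) -> list[dict]:
    keys = [k for k, v in cfg.items() if isinstance(v, (list, tuple))]
    grid = [dict(cfg)]
    for k in keys:
        grid = [dict(g, **{k: v}) for g in grid for v in cfg[k]]
    return grid


def run_cross_study(c: ExpressionCompendium, plan: FoldPlan,
                    methods: dict[str, dict],
                    networks: dict[str, object] | None = None,
                    synet_links: int = 100,
                    corr_links: int = 100,
                    scan_repeats: int = 2) -> list[EvalResult]:
    """Evaluate every (method, network) combination under one fold plan.

    ``methods`` maps method name (lasso, gl, park, chuang, taylor) to its
    config; list-valued entries define a tuning grid resolved in the inner
    folds.  ``networks`` maps a display name to a fixed
    :class:`GeneNetwork`, the string "synet" or "corr" (inferred per outer
    fold from training data only), or None (no network; full gene set).
    """
    plan.validate()
    if networks is None:
        networks = {"none": None}
    lab = c.labelled()
    results = []
    synet_cache: dict[int, GeneNetwork] = {}
    for method, cfg in methods.items():
        for net_name, net_src in networks.items():
            res = _run_one(lab, plan, method, cfg, net_name, net_src,
                           synet_links, corr_links, scan_repeats,
                           synet_cache)
            results.append(res)
    return results


def _run_one(lab: ExpressionCompendium, plan: FoldPlan, method: str,
             cfg: dict, net_name: str, net_src, synet_links: int,
             corr_links: int, scan_repeats: int,
             synet_cache: dict) -> EvalResult:
    aucs = np.full((plan.n_outer, plan.n_repeats), np.nan)
    res = EvalResult(method, net_name, aucs)
    genes = set(lab.gene_ids)
    for f, (test_study, train_studies) in enumerate(plan.outer):
        train_c = lab.subset_studies(train_studies)
        test_c = lab.subset_studies([test_study])
        _assert_disjoint(train_c.sample_ids, test_c.sample_ids,
                         f"outer fold {f}")
        y_te = test_c.binary_labels().to_numpy()
        if len(np.unique(y_te)) < 2:
            logger.info("fold %d: single-class test study %s skipped",
                        f, test_study)
            continue
        X_te = test_c.values

        # resolve the network from training data only
        if isinstance(net_src, GeneNetwork):
            network = _restrict_network(net_src, genes)
        elif net_src == "synet":
            key = (net_name, f, synet_links, scan_repeats, plan.seed)
            if key not in synet_cache:
                synet_cache[key] = infer_synet(
                    train_c, n_links=synet_links, seed=plan.seed,
                    n_repeats=scan_repeats)
            network = synet_cache[key]
        elif net_src is None:
            network = None
        elif net_src != "corr":
            raise ValueError(f"unknown network source {net_src!r}")

        grid = _expand_grid(cfg)
        inner_folds = None
        fold_best_cfg = None
        if len(grid) > 1:
            inner_folds = []
            for it, itr in plan.inner[f]:
                in_tr = lab.subset_studies(itr)
                in_te = lab.subset_studies([it])
                _assert_disjoint(in_tr.sample_ids, test_c.sample_ids,
                                 f"fold {f} inner train")
                inner_folds.append((in_tr.values,
                                    in_tr.binary_labels().to_numpy(),
                                    in_te.values,
                                    in_te.binary_labels().to_numpy()))
        for rep in range(plan.n_repeats):
            rng = np.random.default_rng([plan.seed, 7919 + f, rep])
            ids = train_c.sample_ids.to_numpy()
            draw = rng.integers(0, len(ids),
                                size=math.ceil(plan.subsample * len(ids)))
            fit_ids = ids[draw]
            _assert_disjoint(fit_ids, test_c.sample_ids,
                             f"fold {f} repeat {rep} refit draw")
            X_fit = train_c.values.loc[fit_ids]
            y_fit = (train_c.outcome.loc[fit_ids] == OUTCOME_POOR
                     ).astype(int).to_numpy()
            if net_src == "corr":
                fit_c = train_c.subset_samples(pd.unique(fit_ids))
                network = build_corr_network(fit_c, n_links=corr_links)

            if len(grid) > 1:
                net_now = network

                def train_fn(Xi, yi, **kw):
                    return _fit_method(method, Xi, yi, net_now, kw,
                                       plan.seed)

                # the grid surface is deterministic given the fold unless
                # the network itself depends on the repeat draw (corr)
                if net_src == "corr" or fold_best_cfg is None:
                    fold_best_cfg, _, _ = _nop.tune(train_fn, grid,
                                                    inner_folds)
                best_cfg = fold_best_cfg
            else:
                best_cfg = grid[0]
            model = _fit_method(method, X_fit, y_fit, network, best_cfg,
                                plan.seed)
            score = model.predict_score(X_te)
            aucs[f, rep] = auc(score, y_te)
            res.signatures[(f, rep)] = set(model.signature)
            res.configs[(f, rep)] = dict(best_cfg)
            res.predictions[(f, rep)] = pd.Series(
                np.where(score > 0, OUTCOME_POOR, OUTCOME_GOOD),
                index=test_c.sample_ids)
    return res
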