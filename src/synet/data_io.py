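"""I/O and preprocessing for multi-study expression compendia and gene networks.

A compendium is a samples x genes expression matrix joined with per-sample
annotation (study of origin, survival time in years, event indicator).
Survival is dichotomized at a configurable horizon (5 years by default) into
good / poor outcome; samples censored before the horizon carry no usable
label and are marked ``excluded``.

Networks are weighted undirected graphs over gene symbols, stored as
3-column edge lists (gene_a, gene_b, weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("synet")

OUTCOME_GOOD = "good"
OUTCOME_POOR = "poor"
OUTCOME_EXCLUDED = "excluded"

#: Survival horizon (years) used to dichotomize outcome.
DEFAULT_HORIZON_YEARS = 5.0


class CompendiumError(ValueError):
    """Malformed expression matrix or sample annotation."""


class NetworkError(ValueError):
    """Malformed network edge list."""


# ---------------------------------------------------------------------------
# outcome labels
# ---------------------------------------------------------------------------

def derive_outcome(time: float, event: int | bool,
                   threshold: float = DEFAULT_HORIZON_YEARS) -> str:
    """Dichotomize a survival record at ``threshold`` years.

    poor  -- the event occurred before the threshold;
    good  -- followed up at least to the threshold (event or not);
    excluded -- censored before the threshold: the class is unknowable.
    """
    if time < 0:
        raise CompendiumError(f"negative survival time: {time}")
    if time >= threshold:
        return OUTCOME_GOOD
    return OUTCOME_POOR if event else OUTCOME_EXCLUDED


@dataclass
class ExpressionCompendium:
    """Samples x genes expression values plus survival annotation.

    ``values`` is indexed by sample id with gene symbols as columns;
    ``annot`` is indexed by sample id with at least columns
    ``study``, ``survival_time``, ``event`` (1 = occurred, 0 = censored)
    and optionally ``rfs_time`` / ``rfs_event`` (recurrence-free survival,
    preferred for labelling when present).
    """

    values: pd.DataFrame
    annot: pd.DataFrame
    horizon: float = DEFAULT_HORIZON_YEARS
    outcome: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self.outcome = self._derive_outcomes()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        v, a = self.values, self.annot
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].tolist()
            raise CompendiumError(f"duplicate sample ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].tolist()
            raise CompendiumError(f"duplicate gene ids: {dup[:5]}")
        missing = v.index.difference(a.index)
        if len(missing):
            raise CompendiumError(
                f"samples missing from annotation: {missing.tolist()[:5]}")
        for col in ("study", "survival_time", "event"):
            if col not in a.columns:
                raise CompendiumError(f"annotation lacks column {col!r}")
        bad = ~np.isfinite(v.to_numpy(dtype=float))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CompendiumError(
                f"non-numeric/missing expression at sample {v.index[r]!r}, "
                f"gene {v.columns[c]!r}")
        if (a.loc[v.index, "survival_time"] < 0).any():
            raise CompendiumError("negative survival time in annotation")
        # align annotation to matrix order; canonical index naming
        self.values.index.name = "sample_id"
        self.annot = a.loc[v.index]
        self.annot.index.name = "sample_id"

    def _derive_outcomes(self) -> pd.Series:
        a = self.annot
        use_rfs = "rfs_time" in a.columns and "rfs_event" in a.columns
        if use_rfs:
            time = a["rfs_time"].where(a["rfs_time"].notna(), a["survival_time"])
            event = a["rfs_event"].where(a["rfs_time"].notna(), a["event"])
        else:
            time, event = a["survival_time"], a["event"]
        out = [derive_outcome(t, e, self.horizon)
               for t, e in zip(time.to_numpy(float), event.to_numpy())]
        return pd.Series(out, index=a.index, name="outcome")

    # -- views -------------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def study_of(self) -> pd.Series:
        return self.annot["study"]

    @property
    def studies(self) -> list[str]:
        return sorted(self.annot["study"].unique())

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionCompendium":
        idx = pd.Index(sample_ids)
        return ExpressionCompendium(self.values.loc[idx], self.annot.loc[idx],
                                    horizon=self.horizon)

    def subset_studies(self, studies: Iterable[str]) -> "ExpressionCompendium":
        keep = self.annot["study"].isin(list(studies))
        return self.subset_samples(self.values.index[keep])

    def labelled(self) -> "ExpressionCompendium":
        """Drop samples whose outcome is excluded (censored before horizon)."""
        keep = self.outcome != OUTCOME_EXCLUDED
        return self.subset_samples(self.values.index[keep])

    def binary_labels(self) -> pd.Series:
        """0/1 labels (poor = 1) over labelled samples only."""
        lab = self.outcome[self.outcome != OUTCOME_EXCLUDED]
        return (lab == OUTCOME_POOR).astype(int)


def read_compendium(expr_path: str | Path, annot_path: str | Path,
                    horizon: float = DEFAULT_HORIZON_YEARS) -> ExpressionCompendium:
    """Read a TSV expression matrix (rows = samples, header = gene symbols,
    first column ``sample_id``) and a TSV annotation table."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.columns = [str(c).upper() for c in expr.columns]
    annot = pd.read_csv(annot_path, sep="\t", index_col=0)
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()].tolist()
        raise CompendiumError(f"duplicate sample ids in annotation: {dup[:5]}")
    try:
        mat = expr.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(expr.columns):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            if coerced.isna().any():
                i = int(np.argmax(coerced.isna().to_numpy()))
                raise CompendiumError(
                    f"non-numeric cell at row {expr.index[i]!r} "
                    f"(line {i + 2}), column {col!r} (column {j + 2})")
        raise
    return ExpressionCompendium(mat, annot, horizon=horizon)


def write_compendium(c: ExpressionCompendium, expr_path: str | Path,
                     annot_path: str | Path) -> None:
    c.values.rename_axis("sample_id").to_csv(expr_path, sep="\t")
    c.annot.rename_axis("sample_id").to_csv(annot_path, sep="\t")


# ---------------------------------------------------------------------------
# per-study quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_per_study(c: ExpressionCompendium) -> ExpressionCompendium:
    """Quantile-normalize expression within each study independently.

    Every sample's sorted value vector is replaced by the mean sorted vector
    of its study, so all samples of a study share one value distribution.
    Studies with a single sample are passed through unchanged (warned).
    """
    out = c.values.astype(float)
    for study in c.studies:
        rows = c.annot.index[c.annot["study"] == study]
        if len(rows) < 2:
            logger.warning("study %s has a single sample; quantile "
                           "normalization skipped", study)
            continue
        block = out.loc[rows].to_numpy(float)
        order = np.argsort(block, axis=1, kind="stable")
        ranks = np.empty_like(order)
        n_g = block.shape[1]
        ranks[np.arange(block.shape[0])[:, None],
              order] = np.arange(n_g)[None, :]
        mean_q = np.sort(block, axis=1).mean(axis=0)
        out.loc[rows] = mean_q[ranks]
    return ExpressionCompendium(out, c.annot, horizon=c.horizon)


# ---------------------------------------------------------------------------
# batch-correction hook
# ---------------------------------------------------------------------------

def batch_correct(c: ExpressionCompendium, corrector=None) -> ExpressionCompendium:
    """Optional pluggable batch-effect correction.

    ``corrector`` is a callable ``(values_df, batch_series) -> values_df``
    (e.g. a Combat implementation). Identity when None.
    """
    if corrector is None:
        return c
    corrected = corrector(c.values, c.annot["study"])
    return ExpressionCompendium(corrected, c.annot, horizon=c.horizon)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Weighted undirected network over gene symbols.

    ``edges`` holds canonical rows (gene_a < gene_b lexicographically),
    one per unordered pair, weight > 0; no self-loops.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, weight

    def __post_init__(self) -> None:
        e = self.edges.reset_index(drop=True).copy()
        if len(e):
            a = e["gene_a"].astype(str).str.upper()
            b = e["gene_b"].astype(str).str.upper()
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            e["gene_a"], e["gene_b"] = lo, hi
            if (a == b).any():
                raise NetworkError("self-loop in edge table")
            if e.duplicated(["gene_a", "gene_b"]).any():
                raise NetworkError("duplicate edge in edge table")
            e = e.sort_values(["gene_a", "gene_b"], kind="stable",
                              ignore_index=True)
        else:
            e = pd.DataFrame(columns=["gene_a", "gene_b", "weight"])
        self.edges = e[["gene_a", "gene_b", "weight"]]

    @property
    def nodes(self) -> list[str]:
        if not len(self.edges):
            return []
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def degrees(self) -> pd.Series:
        d = pd.concat([self.edges["gene_a"], self.edges["gene_b"]])
        return d.value_counts().reindex(self.nodes, fill_value=0).sort_index()

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["gene_a", "gene_b", "weight"]].itertuples(index=False))
        return g

    @classmethod
    def from_nx(cls, g: nx.Graph) -> "GeneNetwork":
        rows = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
        return cls(pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   weights: Iterable[float] | None = None) -> "GeneNetwork":
        pairs = list(pairs)
        w = list(weights) if weights is not None else [1.0] * len(pairs)
        return cls(pd.DataFrame(
            {"gene_a": [p[0] for p in pairs],
             "gene_b": [p[1] for p in pairs], "weight": w}))


def read_network(path: str | Path, weighting: str = "given") -> GeneNetwork:
    """Read a TSV edge list (2 or 3 columns).

    ``weighting="given"`` requires a third weight column;
    ``weighting="degree_average"`` ignores any weights and assigns
    weight(i, j) = (deg(i) + deg(j)) / 2 computed on the unweighted graph
    (the convention for unweighted interactomes such as HumanInt).
    Duplicate edges keep the maximum weight; self-loops are dropped.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                if weighting != "degree_average":
                    raise NetworkError(
                        f"line {ln}: 2-column edge list requires "
                        f"weighting='degree_average'")
                a, b, w = parts[0], parts[1], 1.0
            elif len(parts) == 3:
                a, b = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError:
                    raise NetworkError(f"line {ln}: non-numeric weight "
                                       f"{parts[2]!r}") from None
            else:
                raise NetworkError(f"line {ln}: expected 2 or 3 columns, "
                                   f"got {len(parts)}")
            if not a or not b:
                raise NetworkError(f"line {ln}: empty gene symbol")
            rows.append((a.upper(), b.upper(), w))
    n_loops = sum(1 for a, b, _ in rows if a == b)
    if n_loops:
        logger.info("dropped %d self-loop(s) from %s", n_loops, path)
    rows = [(min(a, b), max(a, b), w) for a, b, w in rows if a != b]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    df = (df.groupby(["gene_a", "gene_b"], as_index=False)["weight"].max())
    if weighting == "degree_average":
        deg = pd.concat([df["gene_a"], df["gene_b"]]).value_counts()
        df["weight"] = (deg[df["gene_a"]].to_numpy()
                        + deg[df["gene_b"]].to_numpy()) / 2.0
    return GeneNetwork(df)


def write_network(n: GeneNetwork, path: str | Path) -> None:
    n.edges.to_csv(path, sep="\t", index=False, header=False)


def threshold_network(n: GeneNetwork, mode: str = "top_links",
                      k: int = 50_000) -> GeneNetwork:
    """Keep the strongest part of a weighted network.

    ``top_links``: the k highest-weight edges (isolated nodes drop out).
    ``top_genes``: add edges in descending weight until k distinct genes
    are touched. Weight ties break lexicographically on (gene_a, gene_b).
    """
    if k < 1:
        raise NetworkError("k must be >= 1")
    e = n.edges.sort_values(["weight", "gene_a", "gene_b"],
                            ascending=[False, True, True], kind="stable",
                            ignore_index=True)
    if mode == "top_links":
        if k >= len(e):
            if k > len(e):
                logger.warning("top_links k=%d exceeds %d edges; "
                               "returning whole network", k, len(e))
            return GeneNetwork(e)
        return GeneNetwork(e.iloc[:k])
    if mode == "top_genes":
        seen: set[str] = set()
        keep = []
        for row in e.itertuples(index=False):
            new = {row.gene_a, row.gene_b} - seen
            if len(seen) + len(new) > k:
                break
            keep.append(row)
            seen |= new
            if len(seen) >= k:
                break
        if len(seen) < k and len(keep) == len(e):
            logger.warning("top_genes k=%d exceeds %d genes; "
                           "returning whole network", k, n.n_nodes)
        return GeneNetwork(pd.DataFrame(keep, columns=e.columns))
    raise NetworkError(f"unknown threshold mode {mode!r}")
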