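"""Synthetic multi-study expression compendia with planted survival signal.

The generator emulates the statistical structure a synergistic-pair scan is
designed to detect: a latent binary outcome per sample, individually
predictive ("marginal") genes carrying an outcome mean-shift, planted
synergistic pairs whose two genes share a dominant common factor while the
outcome signal lives only in their contrast (so each gene alone is barely
predictive but a linear combination of the two is), correlated co-expression
blocks with no outcome signal, per-study additive batch shifts, and censored
survival times whose dichotomization at 5 years recovers the latent outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionCompendium, GeneNetwork

# Construction constants for planted synergy pairs: the shared factor has
# weight SHARED_SCALE and the private noise sd PAIR_NOISE_SD, so at
# effect_size e the per-gene outcome shift is e/2 against a total sd of
# ~sqrt(SHARED_SCALE^2 + PAIR_NOISE_SD^2) (marginal AUC ~ 0.52 at e = 1)
# while the contrast g_i - g_j has shift e against sd ~ sqrt(2)*PAIR_NOISE_SD
# (pair AUC ~ 0.84 at e = 1).
SHARED_SCALE = 6.0
PAIR_NOISE_SD = 0.5
BLOCK_FACTOR_SCALE = 1.0

# Exponential survival scales (years): poor-class mean 1.2 gives
# P(T > 5 | poor) ~ 1.5%, good-class times are offset past the horizon,
# so class <-> 5-year status agrees for >= 95% of uncensored samples.
POOR_MEAN_YEARS = 1.2
GOOD_OFFSET_YEARS = 5.0
GOOD_MEAN_YEARS = 5.0
CENSOR_MAX_YEARS = 10.0


@dataclass
class SynthConfig:
    """Study conditions for one simulated compendium."""

    n_studies: int = 4
    samples_per_study: int = 250
    n_genes: int = 300
    n_marginal: int = 20
    n_synergy_pairs: int = 10
    n_corr_blocks: int = 5
    block_size: int = 10
    effect_size: float = 1.0
    batch_shift_sd: float = 0.3
    censor_rate: float = 0.2
    synergy_mechanism: str = "contrast"  # or "xor"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_studies, self.samples_per_study, self.n_genes,
                  self.n_marginal, self.n_synergy_pairs, self.n_corr_blocks,
                  self.block_size)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        used = (self.n_marginal + 2 * self.n_synergy_pairs
                + self.n_corr_blocks * self.block_size)
        if used > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {used} structured genes "
                f"> n_genes = {self.n_genes}")

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_compendium(cfg: SynthConfig) -> tuple[ExpressionCompendium, dict]:
    """Draw one compendium and return it with its ground truth.

    Truth dict keys: ``marginal`` (gene list), ``synergy_pairs``
    (list of (g_i, g_j) with g_i < g_j), ``corr_blocks`` (list of gene
    lists) and ``latent_outcome`` (0 good / 1 poor per sample id).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_studies * cfg.samples_per_study
    genes = _gene_names(cfg.n_genes)

    # gene role assignment, deterministic layout
    pos = 0
    marginal = genes[pos:pos + cfg.n_marginal]
    pos += cfg.n_marginal
    pairs = []
    for _ in range(cfg.n_synergy_pairs):
        pairs.append((genes[pos], genes[pos + 1]))
        pos += 2
    blocks = []
    for _ in range(cfg.n_corr_blocks):
        blocks.append(genes[pos:pos + cfg.block_size])
        pos += cfg.block_size

    y = rng.integers(0, 2, size=n)          # latent outcome, 1 = poor
    x = rng.normal(size=(n, cfg.n_genes))   # baseline noise
    values = pd.DataFrame(x, columns=genes)
    e = cfg.effect_size

    for g in marginal:
        values[g] += e * y
    for gi, gj in pairs:
        shared = rng.normal(size=n) * SHARED_SCALE
        ei = rng.normal(size=n) * PAIR_NOISE_SD
        ej = rng.normal(size=n) * PAIR_NOISE_SD
        if cfg.synergy_mechanism == "contrast":
            values[gi] = shared + (e / 2.0) * y + ei
            values[gj] = shared - (e / 2.0) * y + ej
        elif cfg.synergy_mechanism == "xor":
            # outcome flips the sign of the shared factor: neither gene nor
            # any linear pair combination is marginally informative, but the
            # product is -- a stress case linear meta-genes cannot capture.
            sgn = np.where(y == 1, -1.0, 1.0)
            values[gi] = shared + ei
            values[gj] = shared * sgn + ej
        else:
            raise ValueError(
                f"unknown synergy mechanism {cfg.synergy_mechanism!r}")
    for block in blocks:
        factor = rng.normal(size=n) * BLOCK_FACTOR_SCALE
        for g in block:
            values[g] += factor

    # per-study per-gene additive batch shift
    study = np.repeat([f"STUDY{s + 1}" for s in range(cfg.n_studies)],
                      cfg.samples_per_study)
    for s in range(cfg.n_studies):
        shift = rng.normal(scale=cfg.batch_shift_sd, size=cfg.n_genes)
        values.iloc[s * cfg.samples_per_study:(s + 1) * cfg.samples_per_study] \
            += shift

    # survival times consistent with the latent class at the 5-year horizon
    t_poor = rng.exponential(POOR_MEAN_YEARS, size=n)
    t_good = GOOD_OFFSET_YEARS + rng.exponential(GOOD_MEAN_YEARS, size=n)
    time = np.where(y == 1, t_poor, t_good)
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < cfg.censor_rate
    c_time = rng.uniform(0.0, CENSOR_MAX_YEARS, size=n)
    cut = censored & (c_time < time)
    time = np.where(cut, c_time, time)
    event = np.where(cut, 0, event)

    sample_ids = [f"{st}_{i:04d}" for i, st in enumerate(study)]
    values.index = pd.Index(sample_ids, name="sample_id")
    annot = pd.DataFrame(
        {"study": study, "survival_time": time, "event": event},
        index=values.index)
    truth = {
        "marginal": marginal,
        "synergy_pairs": pairs,
        "corr_blocks": blocks,
        "latent_outcome": pd.Series(y, index=values.index),
    }
    return ExpressionCompendium(values, annot), truth


def truth_network(truth: dict, all_genes: Sequence[str] | None = None
                  ) -> GeneNetwork:
    """Planted-structure network: one edge per planted synergy pair plus a
    chain over the marginal genes.

    When ``all_genes`` is given, the remaining (noise) genes are linked as
    a perfect matching so the network spans the whole gene universe — the
    appropriate truth-aligned reference when comparing against
    degree-preserving shuffles, which keep the gene set fixed.
    """
    pairs = list(truth["synergy_pairs"])
    marg = list(truth["marginal"])
    pairs += list(zip(marg[:-1], marg[1:]))
    if all_genes is not None:
        used = set(marg) | {g for p in truth["synergy_pairs"] for g in p}
        rest = [g for g in all_genes if g not in used]
        pairs += list(zip(rest[0::2], rest[1::2]))
    return GeneNetwork.from_pairs(pairs)


def simulate_network(n_genes: int, model: str = "erdos_renyi",
                     n_links: int = 100, seed: int = 0) -> GeneNetwork:
    """Random weighted network over the synthetic gene universe.

    ``erdos_renyi`` draws exactly ``n_links`` uniform edges;
    ``scale_free`` grows a preferential-attachment graph and then trims or
    tops up uniformly to exactly ``n_links`` edges. Weights ~ Uniform(0, 1].
    """
    max_links = n_genes * (n_genes - 1) // 2
    if n_links > max_links:
        raise ValueError(f"n_links = {n_links} exceeds C({n_genes}, 2) "
                         f"= {max_links}")
    rng = np.random.default_rng(seed)
    names = _gene_names(n_genes)
    if n_links == 0:
        return GeneNetwork.from_pairs([])
    if model == "erdos_renyi":
        g = nx.gnm_random_graph(n_genes, n_links,
                                seed=int(rng.integers(2**31)))
    elif model == "scale_free":
        m = max(1, round(n_links / max(n_genes, 1)))
        g = nx.barabasi_albert_graph(n_genes, m,
                                     seed=int(rng.integers(2**31)))
        edges = sorted(tuple(sorted(uv)) for uv in g.edges())
        if len(edges) > n_links:
            idx = rng.choice(len(edges), size=n_links, replace=False)
            g = nx.Graph(list(np.array(edges, dtype=object)[np.sort(idx)]))
        while g.number_of_edges() < n_links:
            u, v = rng.integers(0, n_genes, size=2)
            if u != v and not g.has_edge(int(u), int(v)):
                g.add_edge(int(u), int(v))
    else:
        raise ValueError(f"unknown network model {model!r}")
    pairs = sorted((names[min(u, v)], names[max(u, v)]) for u, v in g.edges())
    w = 1.0 - rng.random(len(pairs))  # Uniform(0, 1]
    return GeneNetwork.from_pairs(pairs, w)
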