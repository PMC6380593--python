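import numpy as np
import pandas as pd
import pytest

from synet import (GeneNetwork, GroupStructure, auc, build_groups,
                   chuang_nop, park_nop, simulate_network, taylor_nop,
                   train_group_lasso, train_lasso, tune)
from synet.nop import _sigmoid, _standardize


def _toy_data(n=60, p=8, seed=0, informative=(0, 3)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"G{k}" for k in range(p)])
    logit = sum(X[f"G{k}"] for k in informative)
    y = (rng.random(n) < _sigmoid(2.0 * logit.to_numpy())).astype(int)
    return X, y


def cd_logistic_lasso(Z, y, lam, sweeps=4000):
    """Independent coordinate-descent oracle for L1 logistic regression
    (mean log-loss + lam * ||w||_1, unpenalized intercept)."""
    n, p = Z.shape
    w, b = np.zeros(p), 0.0
    for _ in range(sweeps):
        for j in range(p):
            pr = _sigmoid(Z @ w + b)
            g = Z[:, j] @ (pr - y) / n
            h = (Z[:, j] ** 2 * pr * (1 - pr)).sum() / n + 1e-12
            u = w[j] - g / h
            w[j] = np.sign(u) * max(0.0, abs(u) - lam / h)
        pr = _sigmoid(Z @ w + b)
        b -= (pr - y).mean() / max((pr * (1 - pr)).mean(), 1e-12)
    return w, b


# ---------------------------------------------------------------------------
# Lasso baseline
# ---------------------------------------------------------------------------

def test_huge_penalty_shrinks_everything_to_majority_class():
    X, y = _toy_data(seed=1)
    m = train_lasso(X, y, lam=1e6)
    assert (m.weights == 0).all()
    majority = 1 if y.mean() > 0.5 else 0
    assert (m.intercept > 0) == (majority == 1)
    assert m.signature == set()


def test_tiny_penalty_separable_reaches_training_auc_one():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["GA", "GB"])
    y = (X["GA"] > 0).astype(int).to_numpy()
    m = train_lasso(X, y, lam=1e-6, max_iter=50_000)
    assert auc(m.predict_score(X), y) == 1.0


def test_lasso_matches_coordinate_descent_oracle():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(20, 10)),
                     columns=[f"G{k}" for k in range(10)])
    y = (rng.random(20) < _sigmoid(X.iloc[:, 0].to_numpy()
                                   - X.iloc[:, 3].to_numpy())).astype(int)
    lam = 0.05
    m = train_lasso(X, y, lam, tol=1e-12, max_iter=500_000)
    Z, _, _ = _standardize(X.to_numpy(float))
    w_ref, b_ref = cd_logistic_lasso(Z, y.astype(float), lam)
    assert np.abs(m.weights - w_ref).max() < 1e-6
    assert abs(m.intercept - b_ref) < 1e-6


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------

def test_isolated_edge_groups():
    net = GeneNetwork.from_pairs([("A", "B")])
    gs = build_groups(net, K=3)
    assert gs.groups == [("A", ["A", "B"]), ("B", ["B", "A"])]


def test_star_neighbor_priority_by_weight():
    net = GeneNetwork.from_pairs(
        [("S", "N4"), ("S", "N3"), ("S", "N2"), ("S", "N1")],
        [4.0, 3.0, 2.0, 1.0])
    gs = build_groups(net, K=2)
    group = dict(gs.groups)["S"]
    assert group == ["S", "N4", "N3"]


def test_group_members_are_network_neighbors():
    net = simulate_network(30, "erdos_renyi", 80, seed=6)
    gs = build_groups(net, K=4)
    edges = net.edge_set()
    for seed_gene, members in gs.groups:
        assert members[0] == seed_gene
        assert len(members) <= 5
        for m in members[1:]:
            assert tuple(sorted((seed_gene, m))) in edges


def test_empty_network_rejected():
    with pytest.raises(ValueError):
        build_groups(GeneNetwork.from_pairs([]), K=2)


# ---------------------------------------------------------------------------
# overlapping group lasso
# ---------------------------------------------------------------------------

def test_group_lasso_full_shrinkage():
    X, y = _toy_data(seed=4)
    gs = GroupStructure([(g, [g]) for g in X.columns], K=1)
    m = train_group_lasso(X, y, gs, lam=1e6)
    assert (m.weights == 0).all() and m.selected_groups == []


def test_singleton_groups_reduce_to_lasso():
    X, y = _toy_data(n=40, p=6, seed=5)
    lam = 0.03
    gs = GroupStructure([(g, [g]) for g in X.columns], K=1)
    gl = train_group_lasso(X, y, gs, lam, tol=1e-12, max_iter=500_000)
    lasso = train_lasso(X, y, lam, tol=1e-12, max_iter=500_000)
    assert np.abs(gl.weights - lasso.weights).max() < 1e-6
    assert abs(gl.intercept - lasso.intercept) < 1e-6


def test_signal_group_enters_path_first():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(200, 6)),
                     columns=[f"G{k}" for k in range(6)])
    y = (rng.random(200) < _sigmoid(
        2.0 * (X["G0"] - X["G1"]).to_numpy())).astype(int)
    gs = GroupStructure([("G0", ["G0", "G1"]), ("G2", ["G2", "G3"]),
                         ("G4", ["G4", "G5"])], K=1)
    first = None
    for lam in np.geomspace(0.5, 1e-3, 15):
        m = train_group_lasso(X, y, gs, lam)
        if m.selected_groups:
            first = m.selected_groups
            break
    assert first == ["G0"]


def test_group_lasso_signature_covers_selected_members():
    X, y = _toy_data(seed=7)
    gs = GroupStructure([("G0", ["G0", "G3"]), ("G1", ["G1", "G2"])], K=1)
    m = train_group_lasso(X[["G0", "G1", "G2", "G3"]], y, gs, lam=0.01)
    assert m.signature <= {"G0", "G1", "G2", "G3"}
    assert "G0" in m.selected_groups


# ---------------------------------------------------------------------------
# Park (clustering)
# ---------------------------------------------------------------------------

def test_zero_cut_height_behaves_as_plain_lasso():
    X, y = _toy_data(n=80, seed=8)
    park = park_nop(X, y, cut_heights=[0.0], lam=0.02)
    lasso = train_lasso(X, y, 0.02)
    assert np.allclose(park.predict_score(X), lasso.predict_score(X),
                       atol=1e-8)


def test_duplicated_blocks_recovered_as_clusters():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(60, 2))
    X = pd.DataFrame(
        np.column_stack([base[:, 0]] * 3 + [base[:, 1]] * 3),
        columns=["A1", "A2", "A3", "B1", "B2", "B3"])
    y = (base[:, 0] > 0).astype(int)
    model = park_nop(X, y, cut_heights=[0.5], lam=0.05)
    clusters = {frozenset(m) for m in model.groups.values()}
    assert frozenset(["A1", "A2", "A3"]) in clusters
    assert frozenset(["B1", "B2", "B3"]) in clusters
    # meta-gene is the exact columnwise mean
    meta = model.meta_features(X)
    block = next(name for name, m in model.groups.items()
                 if set(m) == {"A1", "A2", "A3"})
    assert np.allclose(meta[block], X[["A1", "A2", "A3"]].mean(axis=1))


# ---------------------------------------------------------------------------
# Chuang (greedy subnetworks)
# ---------------------------------------------------------------------------

def test_greedy_halts_on_no_improvement_and_traces_increase():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(rng.normal(size=(100, 4)),
                     columns=["S", "N1", "N2", "N3"])
    y = (X["S"] > 0).astype(int).to_numpy()   # only the seed is informative
    net = GeneNetwork.from_pairs([("S", "N1"), ("S", "N2"), ("S", "N3")])
    model = chuang_nop(X, y, net, lam=0.05)
    traces = model.config["expansion_traces"]
    for trace in traces.values():
        assert all(b > a for a, b in zip(trace, trace[1:]))
    assert ["S"] in [sorted(m) for m in model.groups.values()] or \
        any(len(m) == 1 for m in model.groups.values())


def test_greedy_absorbs_jointly_informative_neighbors():
    """Averaging two outcome-shifted genes raises the signal-to-noise of
    the meta-gene, so greedy expansion pulls in informative partners.
    (Contrast-style planted pairs cancel under averaging by construction,
    which is exactly the weakness of averaging-based aggregation.)"""
    from synet import SynthConfig, simulate_compendium, truth_network
    cfg = SynthConfig(n_studies=2, samples_per_study=150, n_genes=24,
                      n_marginal=10, n_synergy_pairs=0, n_corr_blocks=0,
                      seed=12)
    c, truth = simulate_compendium(cfg)
    lab = c.labelled()
    net = truth_network(truth, all_genes=lab.gene_ids)
    model = chuang_nop(lab.values, lab.binary_labels().to_numpy(), net,
                       lam=0.05)
    marginal = set(truth["marginal"])
    multi = [m for m in model.groups.values() if len(m) > 1]
    absorbed = {g for m in multi for g in m if g in marginal}
    assert len(absorbed) >= 8   # >= 8 of 10 informative genes co-grouped


# ---------------------------------------------------------------------------
# Taylor (hub dysregulation)
# ---------------------------------------------------------------------------

def _hub_net(extra=()):
    pairs = [("HUB", f"N{k}") for k in range(6)] + list(extra)
    return GeneNetwork.from_pairs(pairs)


def test_identical_class_structure_gives_zero_dysregulation():
    rng = np.random.default_rng(13)
    half = pd.DataFrame(rng.normal(size=(30, 7)),
                        columns=["HUB"] + [f"N{k}" for k in range(6)])
    X = pd.concat([half, half], ignore_index=True)   # classes share rows
    y = np.array([0] * 30 + [1] * 30)
    model = taylor_nop(X, y, _hub_net(), lam=0.05)
    assert model.config["hub_scores"]["HUB"] == pytest.approx(0.0, abs=1e-12)


def test_sign_flipping_hub_ranks_first():
    rng = np.random.default_rng(14)
    n = 200
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    hub = rng.normal(size=n)
    flip = np.where(y == 0, 1.0, -1.0)
    cols = {"HUB": hub}
    for k in range(6):   # neighbors correlate +0.8 in good, -0.8 in poor
        cols[f"N{k}"] = flip * 0.8 * hub + 0.6 * rng.normal(size=n)
    hub2 = rng.normal(size=n)
    cols["HUB2"] = hub2
    for k in range(6):   # stable hub: same correlation in both classes
        cols[f"M{k}"] = 0.8 * hub2 + 0.6 * rng.normal(size=n)
    X = pd.DataFrame(cols)
    net = GeneNetwork.from_pairs(
        [("HUB", f"N{k}") for k in range(6)]
        + [("HUB2", f"M{k}") for k in range(6)])
    model = taylor_nop(X, y, net, lam=0.05)
    scores = model.config["hub_scores"]
    assert scores["HUB"] > 1.0
    assert scores["HUB"] > scores["HUB2"]


def test_degree_five_gene_is_not_a_hub():
    rng = np.random.default_rng(15)
    X = pd.DataFrame(rng.normal(size=(40, 7)),
                     columns=["H5"] + [f"N{k}" for k in range(6)])
    y = np.array([0, 1] * 20)
    net5 = GeneNetwork.from_pairs([("H5", f"N{k}") for k in range(5)])
    with pytest.raises(ValueError, match="hub"):
        taylor_nop(X, y, net5, lam=0.05)


def test_taylor_needs_three_samples_per_class():
    X = pd.DataFrame(np.random.default_rng(16).normal(size=(8, 7)),
                     columns=["HUB"] + [f"N{k}" for k in range(6)])
    y = np.array([1, 0, 0, 0, 0, 0, 0, 1])
    with pytest.raises(ValueError, match="3 samples"):
        taylor_nop(X, y, _hub_net(), lam=0.05)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def _tune_folds(seed=17):
    X, y = _toy_data(n=120, seed=seed)
    half = 60
    return X, y, [(X[:half], y[:half], X[half:], y[half:])]


def test_single_point_grid_is_passthrough():
    X, y, folds = _tune_folds()
    cfg, model, surface = tune(train_lasso, [{"lam": 0.05}], folds, X, y)
    assert cfg == {"lam": 0.05}
    assert len(surface) == 1 and model is not None


def test_grid_argmax_contract():
    X, y, folds = _tune_folds()
    grid = [{"lam": 1e6}, {"lam": 0.02}]
    cfg, _, surface = tune(train_lasso, grid, folds, X, y)
    assert cfg == {"lam": 0.02}
    assert surface["inner_auc"].max() == \
        surface.loc[surface["lam"] == 0.02, "inner_auc"].iloc[0]


def test_tie_breaks_prefer_larger_lambda():
    X, y, folds = _tune_folds()
    grid = [{"lam": 1e5}, {"lam": 1e6}]   # both fully shrunk -> tied AUC
    cfg, _, _ = tune(train_lasso, grid, folds, X, y)
    assert cfg == {"lam": 1e6}


def test_empty_grid_rejected():
    X, y, folds = _tune_folds()
    with pytest.raises(ValueError):
        tune(train_lasso, [], folds)
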