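import numpy as np
import pandas as pd
import pytest

from synet import (CompendiumError, ExpressionCompendium, GeneNetwork,
                   NetworkError, derive_outcome, quantile_normalize_per_study,
                   read_compendium, read_network, threshold_network,
                   write_compendium, write_network)


# ---------------------------------------------------------------------------
# outcome labels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("time,event,expected", [
    (3.0, 1, "poor"),
    (7.2, 0, "good"),
    (7.2, 1, "good"),
    (2.1, 0, "excluded"),
    (5.0, 0, "good"),       # exactly at the horizon counts as followed up
])
def test_outcome_dichotomization(time, event, expected):
    assert derive_outcome(time, event) == expected


def test_negative_survival_time_rejected():
    with pytest.raises(CompendiumError):
        derive_outcome(-1.0, 1)


def test_rfs_preferred_over_overall_survival():
    """When recurrence-free survival columns are present they drive the
    label; overall survival is the fallback."""
    values = pd.DataFrame({"G1": [0.0, 0.0]}, index=["a", "b"])
    annot = pd.DataFrame({
        "study": ["s", "s"],
        "survival_time": [8.0, 8.0], "event": [0, 0],
        "rfs_time": [2.0, np.nan], "rfs_event": [1, np.nan],
    }, index=["a", "b"])
    c = ExpressionCompendium(values, annot)
    assert c.outcome["a"] == "poor"     # early recurrence
    assert c.outcome["b"] == "good"     # falls back to OS


# ---------------------------------------------------------------------------
# compendium I/O
# ---------------------------------------------------------------------------

def _write_toy(tmp_path, drop_sample=None, bad_cell=False):
    expr = tmp_path / "expr.tsv"
    annot = tmp_path / "annot.tsv"
    rows = [("s1", "1.0", "2.0"), ("s2", "3.0", "4.0"), ("s3", "5.0", "6.0")]
    if bad_cell:
        rows[1] = ("s2", "oops", "4.0")
    expr.write_text("sample_id\tg1\tg2\n"
                    + "\n".join("\t".join(r) for r in rows) + "\n")
    ann = [("s1", "A", "6.0", "1"), ("s2", "A", "2.0", "1"),
           ("s3", "B", "9.0", "0")]
    if drop_sample:
        ann = [a for a in ann if a[0] != drop_sample]
    annot.write_text("sample_id\tstudy\tsurvival_time\tevent\n"
                     + "\n".join("\t".join(a) for a in ann) + "\n")
    return expr, annot


def test_read_toy_compendium(tmp_path):
    c = read_compendium(*_write_toy(tmp_path))
    assert c.n_samples == 3 and c.n_genes == 2
    assert list(c.gene_ids) == ["G1", "G2"]   # symbols uppercased
    assert c.outcome.tolist() == ["good", "poor", "good"]


def test_missing_annotation_names_the_sample(tmp_path):
    with pytest.raises(CompendiumError, match="s2"):
        read_compendium(*_write_toy(tmp_path, drop_sample="s2"))


def test_non_numeric_cell_reports_coordinates(tmp_path):
    with pytest.raises(CompendiumError, match="G1"):
        read_compendium(*_write_toy(tmp_path, bad_cell=True))


def test_compendium_round_trip(tmp_path, tiny_compendium):
    write_compendium(tiny_compendium, tmp_path / "e.tsv", tmp_path / "a.tsv")
    back = read_compendium(tmp_path / "e.tsv", tmp_path / "a.tsv")
    pd.testing.assert_frame_equal(back.values, tiny_compendium.values)
    assert (back.outcome == tiny_compendium.outcome).all()
    assert (back.annot["study"] == tiny_compendium.annot["study"]).all()


def test_duplicate_sample_ids_rejected():
    values = pd.DataFrame(np.zeros((2, 1)), index=["a", "a"], columns=["G"])
    annot = pd.DataFrame({"study": ["s", "s"], "survival_time": [1, 1],
                          "event": [1, 1]}, index=["a", "a"])
    with pytest.raises(CompendiumError, match="duplicate"):
        ExpressionCompendium(values, annot)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _two_sample_study(vals_a, vals_b):
    values = pd.DataFrame([vals_a, vals_b], index=["a", "b"],
                          columns=["G1", "G2", "G3"], dtype=float)
    annot = pd.DataFrame({"study": ["s", "s"], "survival_time": [6, 6],
                          "event": [1, 1]}, index=["a", "b"])
    return ExpressionCompendium(values, annot)


def test_quantile_normalization_hand_computed():
    c = quantile_normalize_per_study(_two_sample_study([1, 2, 3], [4, 5, 6]))
    assert c.values.loc["a"].tolist() == [2.5, 3.5, 4.5]
    assert c.values.loc["b"].tolist() == [2.5, 3.5, 4.5]


def test_quantile_normalization_fixed_point_and_idempotence():
    c0 = _two_sample_study([3, 1, 2], [1, 2, 3])  # same sorted values
    c1 = quantile_normalize_per_study(c0)
    pd.testing.assert_frame_equal(c1.values, c0.values)
    c2 = quantile_normalize_per_study(c1)
    pd.testing.assert_frame_equal(c2.values, c1.values)


def test_quantile_normalization_sample_order_invariant(tiny_compendium):
    ref = quantile_normalize_per_study(tiny_compendium)
    perm = tiny_compendium.sample_ids[::-1]
    shuffled = tiny_compendium.subset_samples(perm)
    out = quantile_normalize_per_study(shuffled)
    pd.testing.assert_frame_equal(out.values.sort_index(),
                                  ref.values.sort_index())


def test_single_sample_study_passes_through():
    values = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["G1", "G2"])
    annot = pd.DataFrame({"study": ["solo"], "survival_time": [6],
                          "event": [1]}, index=["a"])
    c = quantile_normalize_per_study(ExpressionCompendium(values, annot))
    assert c.values.loc["a"].tolist() == [1.0, 2.0]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _write_edges(tmp_path, lines):
    p = tmp_path / "net.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p


def test_degree_average_weighting_triangle(tmp_path):
    p = _write_edges(tmp_path, ["a\tb", "b\tc", "a\tc"])
    net = read_network(p, weighting="degree_average")
    assert net.edges["weight"].tolist() == [2.0, 2.0, 2.0]


def test_degree_average_weighting_path(tmp_path):
    p = _write_edges(tmp_path, ["a\tb", "b\tc"])
    net = read_network(p, weighting="degree_average")
    assert net.edges["weight"].tolist() == [1.5, 1.5]


def test_duplicate_edge_keeps_max_weight(tmp_path):
    p = _write_edges(tmp_path, ["a\tb\t1", "b\ta\t3"])
    net = read_network(p)
    assert net.n_edges == 1
    assert net.edges["weight"].iloc[0] == 3.0


def test_two_column_edge_list_requires_degree_average(tmp_path):
    p = _write_edges(tmp_path, ["a\tb"])
    with pytest.raises(NetworkError):
        read_network(p, weighting="given")


def test_malformed_row_reports_line_number(tmp_path):
    p = _write_edges(tmp_path, ["a\tb\t1", "a\tb\tc\td"])
    with pytest.raises(NetworkError, match="line 2"):
        read_network(p)


def test_network_round_trip(tmp_path):
    net = GeneNetwork.from_pairs([("A", "B"), ("B", "C")], [1.5, 2.5])
    write_network(net, tmp_path / "n.tsv")
    back = read_network(tmp_path / "n.tsv")
    pd.testing.assert_frame_equal(back.edges, net.edges)


def test_self_loops_dropped(tmp_path):
    p = _write_edges(tmp_path, ["a\ta\t2", "a\tb\t1"])
    assert read_network(p).n_edges == 1


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _weighted_net():
    return GeneNetwork.from_pairs([("A", "B"), ("B", "C"), ("C", "D")],
                                  [3.0, 2.0, 1.0])


def test_top_links_keeps_highest_weights():
    out = threshold_network(_weighted_net(), "top_links", 2)
    assert sorted(out.edges["weight"]) == [2.0, 3.0]


def test_top_links_noop_when_k_exceeds_edges():
    net = _weighted_net()
    out = threshold_network(net, "top_links", 10)
    pd.testing.assert_frame_equal(out.edges, net.edges)


def test_top_genes_on_star():
    star = GeneNetwork.from_pairs(
        [("HUB", f"L{k}") for k in range(4)], [4.0, 3.0, 2.0, 1.0])
    out = threshold_network(star, "top_genes", 3)
    assert out.n_edges == 2
    assert sorted(out.edges["weight"]) == [3.0, 4.0]


def test_threshold_is_subgraph_and_monotone():
    net = _weighted_net()
    prev: set = set()
    for k in (1, 2, 3):
        sub = threshold_network(net, "top_links", k)
        edges = sub.edge_set()
        assert edges <= net.edge_set()
        assert prev <= edges            # nested in k
        prev = edges
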