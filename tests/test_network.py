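"""Subgroup networks, PRV properties and the feature-selection chain."""
import numpy as np
import pandas as pd
import pytest

from prognet import network as net
from prognet import synthetic as syn


def _net(anchor, subgroup, nodes, edges):
    return net.InteractionNetwork(anchor, subgroup, frozenset(nodes),
                                  dict(edges))


NODES = ["a", "b", "g", "h"]


def test_prv_toy_value():
    plus = _net("x", "biomarker+", NODES, {("a", "g"): 1.0, ("b", "g"): 0.8})
    minus = _net("x", "biomarker-", NODES, {("a", "g"): 1.0})
    prv = net.compute_prv(plus, minus)
    assert prv.table.loc["g", "prv"] == pytest.approx(0.8)
    assert prv.table.loc["b", "prv"] == pytest.approx(0.8)
    assert prv.table.loc["a", "prv"] == pytest.approx(0.0)


def test_prv_identity_and_symmetry():
    edges = {("a", "g"): 0.9, ("b", "h"): 0.7}
    plus = _net("x", "biomarker+", NODES, edges)
    minus = _net("x", "biomarker-", NODES, edges)
    assert (net.compute_prv(plus, minus).table["prv"] == 0.0).all()
    plus2 = _net("x", "biomarker+", NODES, {("a", "g"): 0.9})
    minus2 = _net("x", "biomarker-", NODES, {("b", "h"): 0.6})
    fwd = net.compute_prv(plus2, minus2).table["prv"]
    rev = net.compute_prv(minus2, plus2).table["prv"]
    assert (fwd == rev).all()
    assert (fwd >= 0).all()
    assert sorted(net.compute_prv(plus2, minus2).table["rank"]) == [1, 2, 3, 4]


def test_prv_node_universe_mismatch_errors():
    plus = _net("x", "biomarker+", ["a", "b"], {})
    minus = _net("x", "biomarker-", ["a", "c"], {})
    with pytest.raises(ValueError):
        net.compute_prv(plus, minus)


def test_build_network_edges_and_interactome_mask(rng):
    n = 30
    x = rng.normal(size=n)
    expr = pd.DataFrame({
        "g1": x, "g2": 2 * x + rng.normal(0, 1e-6, n),
        "g3": rng.normal(size=n), "g4": 2 * x,
    }).T
    expr.columns = [f"s{i}" for i in range(n)]
    inter = net.Interactome.from_pairs([("g1", "g2"), ("g1", "g3")])
    built = net.build_subgroup_network(expr, list(expr.columns), inter, 0.6)
    assert built.edges[("g1", "g2")] == pytest.approx(1.0, abs=1e-6)
    assert ("g1", "g3") not in built.edges  # uncorrelated
    assert ("g1", "g4") not in built.edges  # correlated but masked out
    assert built.nodes == frozenset({"g1", "g2", "g3"})


def test_pearson_hand_example_threshold_behaviour():
    expr = pd.DataFrame([[1, 2, 3], [1, 2, 4]], index=["x", "y"],
                        columns=["s1", "s2", "s3"]).astype(float)
    inter = net.Interactome.from_pairs([("x", "y")])
    r = 3.0 / (np.sqrt(2.0) * np.sqrt(42.0 / 9.0))  # 0.98198
    lo = net.build_subgroup_network(expr, ["s1", "s2", "s3"], inter, 0.6)
    assert lo.edges[("x", "y")] == pytest.approx(r, abs=1e-4)
    hi = net.build_subgroup_network(expr, ["s1", "s2", "s3"], inter, 0.99)
    assert ("x", "y") not in hi.edges


def test_build_network_preconditions(small_bundle, small_interactome):
    with pytest.raises(ValueError):
        net.build_subgroup_network(small_bundle.expression,
                                   small_bundle.sample_ids[:2],
                                   small_interactome, 0.6)
    with pytest.raises(ValueError):
        net.build_subgroup_network(small_bundle.expression,
                                   small_bundle.sample_ids,
                                   small_interactome, 1.5)


def test_zero_variance_gene_contributes_no_edges():
    expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "g"],
                        columns=[f"s{i}" for i in range(5)])
    inter = net.Interactome.from_pairs([("flat", "g")])
    built = net.build_subgroup_network(expr, list(expr.columns), inter, 0.5)
    assert built.edges == {}


def test_interactome_canonicalization():
    inter = net.Interactome.from_pairs([("b", "a"), ("a", "b"), ("c", "a")])
    assert inter.pairs == (("a", "b"), ("a", "c"))
    assert ("b", "a") in inter
    with pytest.raises(ValueError):
        net.Interactome.from_pairs([("a", "a")])
    with pytest.raises(ValueError):
        net.Interactome.from_pairs([("a", "b")], weights=[1.5])


def test_select_candidates_rules():
    tbl = pd.DataFrame({"prv": [3.0, 2.0, 2.0, 0.0, 1.0]},
                       index=pd.Index(["anchor", "b", "a", "z", "c"],
                                      name="gene"))
    order = sorted(tbl.index, key=lambda g: (-tbl.loc[g, "prv"], g))
    tbl.loc[order, "rank"] = np.arange(1, 6)
    prv = net.PRVTable("anchor", tbl)
    # anchor excluded, zero-PRV excluded, tie broken lexicographically
    assert net.select_candidates(prv, k=5) == ["a", "b", "c"]
    assert net.select_candidates(prv, k=2) == ["a", "b"]
    with pytest.raises(ValueError):
        net.select_candidates(prv, k=6)


@pytest.mark.parametrize("lists, expected", [
    ([{"a", "b", "c"}, {"b", "c", "d"}, {"c", "b"}], {"b", "c"}),
    ([{"a"}, set()], set()),
    ([{"a", "b"}] * 7, {"a", "b"}),
])
def test_intersect_lists(lists, expected):
    assert net.intersect_lists(lists) == expected


def test_survival_filter_alpha_one_keeps_all(small_bundle):
    genes = list(small_bundle.truth.planted_prognostic_genes)
    kept, pvals = net.survival_filter(genes, small_bundle.expression,
                                      small_bundle.survival, alpha=1.0)
    assert kept == sorted(genes)
    assert set(pvals) == set(genes)


def test_survival_filter_cox_variant_agrees_on_strong_signal(small_bundle):
    genes = list(small_bundle.truth.planted_prognostic_genes)[:2]
    kept_lr, _ = net.survival_filter(genes, small_bundle.expression,
                                     small_bundle.survival, alpha=0.05)
    kept_cox, _ = net.survival_filter(genes, small_bundle.expression,
                                      small_bundle.survival, alpha=0.05,
                                      test="cox")
    assert kept_lr == kept_cox


def test_run_feature_selection_recovers_planted_module(small_bundle,
                                                       small_interactome):
    sel = net.run_feature_selection(small_bundle, small_interactome,
                                    syn.LITERATURE_BIOMARKERS)
    planted = set(small_bundle.truth.planted_prognostic_genes)
    assert planted <= sel.overlap
    assert len(set(sel.panel.novel_genes) & planted) >= 6
    assert sel.panel.literature_genes == syn.LITERATURE_BIOMARKERS


def test_panel_disjointness_enforced():
    with pytest.raises(ValueError):
        net.BiomarkerPanel(("EPCAM",), ("EPCAM",))
    p = net.BiomarkerPanel(("EPCAM", "PKM"), ("CUL1",))
    assert p.combined == ("EPCAM", "PKM", "CUL1")
    assert len(p) == 3


def test_missing_literature_gene_errors(small_bundle, small_interactome):
    with pytest.raises(KeyError):
        net.run_feature_selection(small_bundle, small_interactome,
                                  ["NOT_PRESENT"])
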