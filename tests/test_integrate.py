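from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from evquant.integrate import (
    MetaboliteNormalizer,
    adjust_p,
    annotate_mz,
    filter_degs,
    intersect_nominate,
    link_lncrnas,
    map_mirnas,
    metabolite_ora,
    norm_metabolites,
    ora,
    top_features,
)

PROTON = 1.00727646688


# ---------------------------------------------------------------------------
# DEG filtering and network construction


def _deg(gene, lfc, p):
    return {"gene_id": gene, "log2fc": lfc, "p_adj": p, "direction": "up" if lfc > 0 else "down"}


def test_filter_degs_strict_cutoffs():
    tab = pd.DataFrame([_deg("a", 1.5, 0.04), _deg("b", 3.0, 0.05), _deg("c", -1.0, 0.01), _deg("d", -2.5, 0.001)])
    up, down = filter_degs(tab)
    assert list(up["gene_id"]) == ["a"]  # 1.5 > log2(2) = 1, p < 0.05
    assert list(down["gene_id"]) == ["d"]  # b fails strict p, c fails strict |fc|
    e_up, e_down = filter_degs(tab.iloc[0:0])
    assert e_up.empty and e_down.empty


def test_map_mirnas_node_and_edge_bookkeeping():
    edges = pd.DataFrame(
        {"gene": ["g1", "g1", "g2", "g9"], "mirna": ["m1", "m2", "m3", "m4"]}
    )
    net = map_mirnas(["g1", "g2"], edges)
    assert net.number_of_nodes() == 5  # 2 genes + 3 miRNAs; m4 excluded
    assert net.number_of_edges() == 3
    empty = map_mirnas(["gX"], edges)
    assert empty.number_of_nodes() == 0


def test_link_lncrnas_attachment_rules():
    net = map_mirnas(["g1"], pd.DataFrame({"gene": ["g1"], "mirna": ["m1"]}))
    lnc = pd.DataFrame(
        {
            "lncrna": ["L1", "L2"],
            "target": ["g1", "g7"],
            "mechanism": ["regulates", "binds"],
            "direction": ["up", "down"],
        }
    )
    out = link_lncrnas(net, lnc)
    assert "L1" in out and out.nodes["L1"]["kind"] == "lncrna"
    assert "L2" not in out  # unreachable target
    bad = lnc.assign(mechanism=["sponges", "binds"])
    with pytest.raises(ValueError, match="sponges"):
        link_lncrnas(net, bad)


# ---------------------------------------------------------------------------
# enrichment


def _brute_force_tail(n_univ, pathway, selected, universe):
    """P(X >= k) by enumerating all subsets of the universe of |selected|."""
    k_obs = len(pathway & selected)
    hits = total = 0
    for sub in combinations(sorted(universe), len(selected)):
        total += 1
        hits += len(pathway & set(sub)) >= k_obs
    return hits / total


def test_ora_worked_examples():
    universe = set(range(10))
    pathway = {0, 1, 2, 3, 4}
    res = ora({0, 1, 2, 3}, {"pw": pathway}, universe)
    assert res.loc[0, "p_raw"] == pytest.approx(5 / 210)
    res0 = ora({5, 6, 7, 8}, {"pw": {0}}, universe)
    assert res0.loc[0, "p_raw"] == 1.0  # k = 0
    sat = ora(universe, {"pw": pathway}, universe)
    assert sat.loc[0, "p_raw"] == 1.0  # saturation: k = K with certainty


def test_ora_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = int(rng.integers(5, 13))
        universe = set(range(n))
        pathway = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False).tolist())
        selected = set(rng.choice(n, size=int(rng.integers(1, n // 2 + 1)), replace=False).tolist())
        res = ora(selected, {"pw": pathway}, universe)
        ref = _brute_force_tail(n, pathway, selected, universe)
        assert res.loc[0, "p_raw"] == pytest.approx(ref, abs=1e-12)


def test_ora_requires_selected_subset_of_universe():
    with pytest.raises(ValueError):
        ora({"x"}, {"pw": {"a"}}, {"a", "b"})


def test_adjust_p_examples_and_monotonicity():
    assert np.allclose(adjust_p([0.01, 0.02, 0.03, 0.04], "bh"), 0.04)
    assert np.allclose(adjust_p([0.02], "bonferroni"), [0.02])
    assert np.allclose(adjust_p([0.03, 0.6], "bonferroni"), [0.06, 1.0])
    rng = np.random.default_rng(0)
    p = rng.random(20)
    adj = adjust_p(p, "bh")
    assert (adj >= p - 1e-15).all()
    with pytest.raises(ValueError):
        adjust_p([1.2])


# ---------------------------------------------------------------------------
# metabolomics steps


def test_norm_median_step():
    m = pd.DataFrame({"s1": [2.0, 4.0, 8.0]}, index=["f1", "f2", "f3"])
    out = norm_metabolites(m, log=False, pareto=False)
    assert np.allclose(out["s1"], [0.5, 1.0, 2.0])


def test_norm_pareto_step():
    m = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["s1", "s2", "s3"], index=["f"])
    out = norm_metabolites(m, median_norm=False, log=False)
    assert np.allclose(out.loc["f"], [-1.0, 0.0, 1.0])  # sample SD is 1


def test_norm_constant_feature_flagged():
    m = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]], columns=list("abc"), index=["f1", "f2"])
    with pytest.warns(UserWarning, match="constant"):
        out = norm_metabolites(m, median_norm=False, log=False)
    assert np.allclose(out.loc["f1"], 0.0)


def test_norm_zero_imputation():
    m = pd.DataFrame([[0.0, 4.0], [2.0, 8.0]], columns=["a", "b"], index=["f1", "f2"])
    with pytest.warns(UserWarning, match="imputed"):
        out = norm_metabolites(m, median_norm=False, log=False, pareto=False)
    assert out.loc["f1", "a"] == 1.0  # half of the minimum positive value (2)


def test_normalizer_transformer_matches_function():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.uniform(1, 100, size=(6, 4)))
    via_fn = norm_metabolites(m.T).T
    via_tf = MetaboliteNormalizer().fit_transform(m)
    assert np.allclose(via_fn.to_numpy(), via_tf.to_numpy())


def test_annotate_mz_tolerance_and_ambiguity():
    lib = pd.DataFrame(
        {
            "metabolite_id": ["glc", "twin_a", "twin_b"],
            "monoisotopic_mass": [180.0634, 300.0000, 300.0004],
            "level": ["1", "1", "2a"],
        }
    )
    feats = pd.DataFrame(
        {
            "feature_id": ["f1", "f2", "f3"],
            "mz": [180.0634 + PROTON, (180.0634 + PROTON) * (1 + 10e-6), 300.0002 + PROTON],
        }
    )
    ann = annotate_mz(feats, lib, ppm=3.0)
    assert set(ann.loc[ann["feature_id"] == "f1", "metabolite_id"]) == {"glc"}
    assert "f2" not in set(ann["feature_id"])  # 10 ppm off
    twins = ann.loc[ann["feature_id"] == "f3"]
    assert set(twins["metabolite_id"]) == {"twin_a", "twin_b"}
    assert twins["ambiguous"].all()
    with pytest.raises(ValueError):
        annotate_mz(feats, lib.iloc[0:0])


def test_metabolite_ora_filters():
    lib_levels = {"m%d" % i: ("1" if i < 20 else "2b") for i in range(24)}
    annotated = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(24)],
            "metabolite_id": list(lib_levels),
            "level": list(lib_levels.values()),
        }
    )
    db = {
        "enriched": {f"m{i}" for i in range(10)},  # 8 of 10 significant
        "too_few": {"m10", "m11"},  # only 2 significant members
        "low_conf": {"m20", "m21", "m22", "m23"},  # level-2b members only
    }
    sig = {f"m{i}" for i in range(8)} | {"m10", "m11", "m20", "m21", "m22"}
    res = metabolite_ora(annotated, sig, db, min_sig=3)
    assert list(res["pathway_id"]) == ["enriched"]
    assert res.loc[0, "significant"]
    assert res.loc[0, "p_adj"] < 0.05


def test_top_features_ranking_rules():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "feature_id": [f"f{i:02d}" for i in range(15)],
            "p": [0.01] * 3 + [0.5] * 12,
            "effect": list(rng.normal(size=15)),
        }
    )
    top = top_features(df, k=10)
    assert len(top) == 10
    assert set(top["feature_id"][:3]) == {"f00", "f01", "f02"}
    # ties on p broken by |effect| descending
    tied = df[df["p"] == 0.5].reindex(top.index[3:]).copy()
    effects = top["effect"][3:].abs().to_numpy()
    assert (np.diff(effects) <= 1e-12).all()
    with pytest.warns(UserWarning):
        assert len(top_features(df, k=99)) == 15
    with pytest.raises(ValueError):
        top_features(df, k=0)


# ---------------------------------------------------------------------------
# nomination


def test_intersect_nominate_set_logic():
    mirna = pd.DataFrame(
        {"pathway_id": ["A", "B"], "significant": [True, True], "overlap_k": 1, "set_size": 1,
         "p_raw": 0.01, "p_adj": 0.01}
    )
    metab = pd.DataFrame(
        {"pathway_id": ["B", "C"], "significant": [True, True], "overlap_k": 3, "set_size": 5,
         "p_raw": 0.01, "p_adj": 0.01}
    )
    net = nx.DiGraph()
    net.add_node("m1", kind="mirna")
    net.add_node("g1", kind="gene")
    net.add_node("L1", kind="lncrna")
    net.add_edge("m1", "g1")
    net.add_edge("L1", "g1")
    db = {
        "A": {"genes": {"gX"}, "mirnas": {"mX"}},
        "B": {"genes": {"g1"}, "mirnas": {"m1"}},
        "C": {"genes": set(), "mirnas": set()},
    }
    cands = intersect_nominate(mirna, metab, net, db)
    ids = sorted((c.candidate_id, c.kind, c.pathway_id) for c in cands)
    assert ids == [("L1", "lncrna", "B"), ("m1", "mirna", "B")]
    none = intersect_nominate(mirna.assign(significant=False), metab, net, db)
    assert none == []
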