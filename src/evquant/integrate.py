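"""Cross-omics pathway integration and biomarker nomination.

The procedure mirrors a pathway-centric multi-omics workflow for NSCLC:

1. filter a differential-expression table (adjusted p < 0.05, |FC| > 2);
2. build a gene--miRNA--lncRNA regulatory network from validated edge lists;
3. test the network miRNAs for pathway over-representation (one-sided
   hypergeometric, BH adjustment);
4. normalise an untargeted metabolomics intensity matrix (sample-median
   division, log10, Pareto scaling), test features between groups, annotate
   m/z features against a mass library at 3 ppm, and run metabolite
   pathway over-representation (level-1/2a metabolites only, pathways with
   at least 3 significant members);
5. intersect the significant pathways of both arms and nominate the
   miRNAs over-represented in them plus any lncRNA connected to one of
   their genes.

The metabolite arm is a declared simplification of the mummichog idea:
top-ranked features -> ppm annotation -> hypergeometric pathway test,
without the permutation null of the full algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .metrics import rank_sum_test

__all__ = [
    "filter_degs",
    "map_mirnas",
    "link_lncrnas",
    "ora",
    "adjust_p",
    "norm_metabolites",
    "MetaboliteNormalizer",
    "annotate_mz",
    "metabolite_ora",
    "top_features",
    "intersect_nominate",
    "run_integration",
]

PROTON_MASS = 1.00727646688  # Da

#: default adducts: (name, m/z offset from the neutral monoisotopic mass)
DEFAULT_ADDUCTS = (("[M+H]+", PROTON_MASS), ("[M-H]-", -PROTON_MASS))

EDGE_MECHANISMS = {"regulates", "binds", "associates"}


# ---------------------------------------------------------------------------
# transcriptomics arm


def filter_degs(table: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 2.0):
    """Split a DEG table into (up, down) using strict cut-offs.

    Keeps rows with ``p_adj < p_cut`` and ``|log2fc| > log2(fc_cut)``,
    partitioned by the sign of log2fc.
    """
    if table.empty:
        return table.copy(), table.copy()
    keep = (table["p_adj"] < p_cut) & (table["log2fc"].abs() > np.log2(fc_cut))
    kept = table.loc[keep]
    return kept.loc[kept["log2fc"] > 0].copy(), kept.loc[kept["log2fc"] < 0].copy()


def map_mirnas(degs, edges: pd.DataFrame) -> nx.DiGraph:
    """Directed miRNA -> gene network restricted to the filtered DEGs.

    ``degs`` is an iterable of gene ids (or a DataFrame with a ``gene_id``
    column).  miRNAs without an edge to any DEG are excluded.
    """
    if isinstance(degs, pd.DataFrame):
        genes = set(degs["gene_id"])
    else:
        genes = set(degs)
    net = nx.DiGraph()
    hits = edges.loc[edges["gene"].isin(genes)]
    for gene, mirna in zip(hits["gene"], hits["mirna"]):
        net.add_node(mirna, kind="mirna")
        net.add_node(gene, kind="gene")
        net.add_edge(mirna, gene, mechanism="regulates", direction="down")
    return net


def link_lncrnas(network: nx.DiGraph, lnc_edges: pd.DataFrame) -> nx.DiGraph:
    """Extend the network with lncRNA (and TF) nodes and typed edges.

    ``lnc_edges`` columns: lncrna, target, mechanism, direction.  Edges are
    only added when the target is already in the network, so unreachable
    lncRNAs stay excluded.  Unknown mechanisms raise an error.
    """
    net = network.copy()
    bad = set(lnc_edges["mechanism"]) - EDGE_MECHANISMS
    if bad:
        raise ValueError(f"unknown edge mechanism(s): {sorted(bad)}")
    for row in lnc_edges.itertuples(index=False):
        if row.target in net:
            net.add_node(row.lncrna, kind=getattr(row, "kind", "lncrna"))
            net.add_edge(row.lncrna, row.target, mechanism=row.mechanism, direction=row.direction)
    return net


# ---------------------------------------------------------------------------
# enrichment statistics


def ora(
    selected,
    pathway_db: dict,
    universe,
    method: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    For each pathway set K (intersected with the universe of size N), given
    n selected ids of which k fall in the pathway, the p-value is
    ``P(X >= k)`` for X hypergeometric(N, K, n).  Returns a DataFrame with
    raw and adjusted p-values and a significance flag at ``alpha``.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected ids must be a subset of the universe")
    n_univ = len(universe)
    rows = []
    for pw, members in pathway_db.items():
        members = set(members) & universe
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), len(selected))) if members else 1.0
        rows.append((pw, k, len(members), min(p, 1.0)))
    res = pd.DataFrame(rows, columns=["pathway_id", "overlap_k", "set_size", "p_raw"])
    res["p_adj"] = adjust_p(res["p_raw"].to_numpy(), method=method) if len(res) else []
    res["significant"] = res["p_adj"] < alpha
    return res


def adjust_p(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# metabolomics arm


def norm_metabolites(
    matrix: pd.DataFrame,
    median_norm: bool = True,
    log: bool = True,
    pareto: bool = True,
) -> pd.DataFrame:
    """Normalise a feature x sample intensity matrix.

    Steps (individually switchable): impute zeros to half the smallest
    positive intensity, divide each sample (column) by its median,
    log10-transform, then Pareto-scale each feature (row): centre and
    divide by the square root of the sample standard deviation.
    Zero-variance features are centred but left unscaled, with a warning.
    """
    m = matrix.astype(float).copy()
    if (m < 0).any().any():
        raise ValueError("intensities must be >= 0")
    if (m == 0).any().any():
        half_min = m[m > 0].min().min() / 2.0
        warnings.warn("zero intensities imputed to half the minimum positive value")
        m = m.mask(m == 0, half_min)
    if median_norm:
        m = m / m.median(axis=0)
    if log:
        m = np.log10(m)
    if not pareto:
        return m
    centered = m.sub(m.mean(axis=1), axis=0)
    sd = m.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} constant feature(s) left unscaled")
    scale = np.sqrt(sd.where(~zero_var, 1.0))
    return centered.div(scale, axis=0)


class MetaboliteNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the metabolomics normalisation.

    Expects X with samples as rows and features as columns (sklearn
    orientation); wraps :func:`norm_metabolites`, which uses the
    metabolomics convention of features as rows.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return norm_metabolites(X.T).T

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X).transform(X)


def annotate_mz(
    features: pd.DataFrame,
    library: pd.DataFrame,
    ppm: float = 3.0,
    adducts=DEFAULT_ADDUCTS,
) -> pd.DataFrame:
    """Match m/z features to library metabolites within a ppm tolerance.

    ``features`` needs columns (feature_id, mz); ``library`` needs
    (metabolite_id, monoisotopic_mass, level).  A feature matching several
    library entries keeps all matches, flagged ambiguous.
    """
    if library.empty:
        raise ValueError("empty annotation library")
    rows = []
    for f in features.itertuples(index=False):
        matches = []
        for met in library.itertuples(index=False):
            for name, delta in adducts:
                expected = met.monoisotopic_mass + delta
                if expected <= 0:
                    continue
                if abs(f.mz - expected) / expected <= ppm * 1e-6:
                    matches.append((name, met, f.mz - expected))
        for name, met, err in matches:
            rows.append((f.feature_id, met.metabolite_id, name, met.level, err, len(matches) > 1))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "metabolite_id", "adduct", "level", "mz_error", "ambiguous"],
    )


def metabolite_ora(
    annotated: pd.DataFrame,
    significant_metabolites,
    pathway_db: dict,
    min_sig: int = 3,
    level_filter=("1", "2a"),
    method: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway over-representation for annotated metabolites.

    Only metabolites at the configured annotation levels enter the
    universe; pathways with fewer than ``min_sig`` significant members are
    removed before multiple-testing adjustment.
    """
    lv = annotated.loc[annotated["level"].astype(str).isin([str(l) for l in level_filter])]
    universe = set(lv["metabolite_id"])
    selected = set(significant_metabolites) & universe
    metab_db = {pw: set(members) & universe for pw, members in pathway_db.items()}
    res = ora(selected, metab_db, universe, method="bh", alpha=alpha)
    # recompute adjustment after the >= min_sig filter
    res = res.loc[res["overlap_k"] >= min_sig].reset_index(drop=True)
    if len(res):
        res["p_adj"] = adjust_p(res["p_raw"].to_numpy(), method=method)
        res["significant"] = res["p_adj"] < alpha
    return res


def top_features(feature_stats: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k most significant features, ranked by raw p, then |effect|,
    then feature id (documented tie-break)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = feature_stats.copy()
    if k > len(df):
        warnings.warn(f"requested top {k} but only {len(df)} features available")
        k = len(df)
    df["_abs_effect"] = -df["effect"].abs()
    df = df.sort_values(["p", "_abs_effect", "feature_id"], kind="mergesort")
    return df.drop(columns="_abs_effect").head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# nomination


@dataclass
class Candidate:
    """A nominated biomarker with its evidence chain."""

    candidate_id: str
    kind: str  # mirna | lncrna
    pathway_id: str
    evidence: tuple = field(default_factory=tuple)


def intersect_nominate(
    mirna_enrich: pd.DataFrame,
    metab_enrich: pd.DataFrame,
    network: nx.DiGraph,
    pathway_db: dict,
) -> list[Candidate]:
    """Nominate biomarkers from pathways significant in both arms.

    For each pathway significant in both the miRNA and the metabolite
    enrichment, emit (a) the network miRNAs that belong to the pathway's
    miRNA set and (b) any network lncRNA connected to a gene in the
    pathway's gene set, each with its evidence chain.
    """
    sig_mirna = set(mirna_enrich.loc[mirna_enrich["significant"], "pathway_id"])
    sig_metab = set(metab_enrich.loc[metab_enrich["significant"], "pathway_id"])
    shared = sorted(sig_mirna & sig_metab)
    candidates: list[Candidate] = []
    mirna_nodes = {n for n, d in network.nodes(data=True) if d.get("kind") == "mirna"}
    lnc_nodes = {n for n, d in network.nodes(data=True) if d.get("kind") == "lncrna"}
    for pw in shared:
        sets = pathway_db[pw]
        pw_mirnas = set(sets.get("mirnas", ()))
        pw_genes = set(sets.get("genes", ()))
        for m in sorted(pw_mirnas & mirna_nodes):
            targets = tuple(sorted(set(network.successors(m)) & pw_genes))
            candidates.append(
                Candidate(m, "mirna", pw, evidence=("pathway-overrepresented", pw, "targets") + targets)
            )
        for l in sorted(lnc_nodes):
            linked = sorted(set(network.successors(l)) & pw_genes)
            if linked:
                candidates.append(
                    Candidate(l, "lncrna", pw, evidence=("linked-gene",) + tuple(linked) + ("pathway", pw))
                )
    return candidates


def run_integration(fixture, alpha: float = 0.05, ppm: float = 3.0, min_sig: int = 3) -> dict:
    """End-to-end integration on an omics fixture.

    Returns a dict with the filtered DEGs, the regulatory network, both
    enrichment tables and the nominated candidates.
    """
    up, down = filter_degs(fixture.deg_table)
    degs = pd.concat([up, down])
    net = map_mirnas(degs, fixture.mirna_edges)
    net = link_lncrnas(net, fixture.lnc_edges)

    selected_mirnas = {n for n, d in net.nodes(data=True) if d.get("kind") == "mirna"}
    universe_mirnas = set(fixture.mirna_edges["mirna"])
    mirna_db = {pw: sets.get("mirnas", set()) for pw, sets in fixture.pathway_db.items()}
    mirna_enrich = ora(selected_mirnas, mirna_db, universe_mirnas, alpha=alpha)

    norm = norm_metabolites(fixture.intensities)
    groups = fixture.sample_groups
    cases = groups.index[groups == "case"]
    ctrls = groups.index[groups == "control"]
    pvals, effects = [], []
    for fid in norm.index:
        u, p = rank_sum_test(norm.loc[fid, cases], norm.loc[fid, ctrls])
        pvals.append(p)
        effects.append(float(norm.loc[fid, cases].mean() - norm.loc[fid, ctrls].mean()))
    feat_stats = pd.DataFrame(
        {"feature_id": norm.index, "p": pvals, "effect": effects}
    ).reset_index(drop=True)
    feat_stats["p_adj"] = adjust_p(feat_stats["p"].to_numpy(), method="bh")

    annotated = annotate_mz(fixture.features, fixture.annotation_library, ppm=ppm)
    sig_features = set(feat_stats.loc[feat_stats["p_adj"] < alpha, "feature_id"])
    sig_metabolites = set(annotated.loc[annotated["feature_id"].isin(sig_features), "metabolite_id"])
    metab_db = {pw: sets.get("metabolites", set()) for pw, sets in fixture.pathway_db.items()}
    metab_enrich = metabolite_ora(annotated, sig_metabolites, metab_db, min_sig=min_sig, alpha=alpha)

    candidates = intersect_nominate(mirna_enrich, metab_enrich, net, fixture.pathway_db)
    return {
        "degs": degs,
        "network": net,
        "mirna_enrichment": mirna_enrich,
        "feature_stats": feat_stats,
        "annotated": annotated,
        "metabolite_enrichment": metab_enrich,
        "candidates": candidates,
    }
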