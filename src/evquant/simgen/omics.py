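"""Synthetic cross-omics fixture with one planted signal chain.

The fixture emulates the inputs of the pathway-integration procedure: a
differential-expression table (Geo2R-style output on an external NSCLC
cohort), validated gene--miRNA and lncRNA--target edge lists, a pathway
database with gene/miRNA/metabolite member sets, and an untargeted
metabolomics feature matrix with a mass-annotation library.

One pathway is planted so that it passes both enrichment arms: its miRNA
member is the only miRNA targeting any filtered DEG (so the miRNA-side
hypergeometric test is significant by construction), and most of its
metabolite members carry a strong case-vs-control intensity shift.  A
planted lncRNA regulates one of the pathway's DEGs, completing the
nomination chain.  Decoy pathways, miRNAs, lncRNAs and metabolites carry
no signal and should never be nominated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._errors import ConfigError

__all__ = ["OmicsSimConfig", "OmicsFixture", "simulate_omics_fixture"]

_PROTON = 1.00727646688


@dataclass(frozen=True)
class OmicsSimConfig:
    """Study conditions for the omics fixture.

    ``plant_signal=False`` produces a decoy-only fixture (no miRNA targets
    a DEG, no metabolite shift) for negative controls.
    """

    n_genes: int = 60
    n_degs: int = 10
    n_mirnas: int = 150
    n_lncrnas: int = 6
    n_decoy_pathways: int = 4
    planted_pathway: str = "pathway_planted"
    planted_mirna: str = "miR-P1"
    planted_lncrna: str = "LNC-P1"
    n_metabolites: int = 40  # level-1/2a annotated universe
    n_low_confidence: int = 4  # level 2b/3 metabolites, excluded by the level filter
    n_unannotated_features: int = 5
    pathway_metabolites: int = 10
    n_diff_metabolites: int = 8
    metab_log2fc: float = 2.0
    metab_log10_sd: float = 0.15
    n_cases: int = 10
    n_controls: int = 10
    plant_signal: bool = True
    pathway_db: dict | None = None  # optional externally supplied pathway names

    def __post_init__(self):
        if self.n_degs < 5 or self.n_degs > self.n_genes // 2:
            raise ConfigError("n_degs: need 5 <= n_degs <= n_genes / 2")
        if self.n_mirnas < 10:
            raise ConfigError("n_mirnas: must be >= 10")
        if self.n_diff_metabolites > self.pathway_metabolites:
            raise ConfigError("n_diff_metabolites: cannot exceed pathway_metabolites")
        if self.pathway_metabolites > self.n_metabolites // 2:
            raise ConfigError("pathway_metabolites: too large for the metabolite universe")
        if self.n_cases < 3 or self.n_controls < 3:
            raise ConfigError("n_cases/n_controls: need at least 3 per group")
        if self.pathway_db is not None and self.planted_pathway not in self.pathway_db:
            raise ConfigError("planted_pathway: absent from the supplied pathway_db")


@dataclass
class OmicsFixture:
    """All inputs for :func:`evquant.integrate.run_integration`, plus truth."""

    deg_table: pd.DataFrame
    mirna_edges: pd.DataFrame
    lnc_edges: pd.DataFrame
    pathway_db: dict
    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_groups: pd.Series
    annotation_library: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _distinct_masses(rng: np.random.Generator, n: int) -> np.ndarray:
    """Monoisotopic masses in 100-800 Da, pairwise separated by > 20 ppm."""
    masses: list[float] = []
    while len(masses) < n:
        m = rng.uniform(100.0, 800.0)
        if all(abs(m - x) / x > 20e-6 for x in masses):
            masses.append(m)
    return np.asarray(masses)


def simulate_omics_fixture(cfg: OmicsSimConfig, seed: int) -> OmicsFixture:
    """Build the fixture; identical (cfg, seed) give identical output."""
    rng = np.random.default_rng(seed)

    # --- DEG table -------------------------------------------------------
    genes = [f"g{i + 1:03d}" for i in range(cfg.n_genes)]
    deg_idx = rng.choice(cfg.n_genes, size=cfg.n_degs, replace=False)
    deg_genes = [genes[i] for i in sorted(deg_idx)]
    null_genes = [g for g in genes if g not in set(deg_genes)]
    rows = []
    for g in genes:
        if g in set(deg_genes):
            mag = rng.uniform(1.5, 4.0)
            sign = rng.choice([-1.0, 1.0])
            lfc = sign * mag
            p = rng.uniform(1e-6, 0.01)
        else:
            lfc = rng.uniform(-0.9, 0.9)
            p = rng.uniform(0.1, 1.0)
        rows.append((g, lfc, p, "up" if lfc > 0 else "down"))
    deg_table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_adj", "direction"])

    # --- miRNA edges -----------------------------------------------------
    planted_targets = [deg_genes[i] for i in rng.choice(cfg.n_degs, size=3, replace=False)]
    mirnas = [cfg.planted_mirna] + [f"miR-d{i + 1:03d}" for i in range(cfg.n_mirnas - 1)]
    edges = []
    if cfg.plant_signal:
        for g in planted_targets:
            edges.append((g, cfg.planted_mirna))
    else:
        for g in rng.choice(null_genes, size=3, replace=False):
            edges.append((g, cfg.planted_mirna))
    for m in mirnas[1:]:
        for g in rng.choice(null_genes, size=2, replace=False):
            edges.append((g, m))
    mirna_edges = pd.DataFrame(edges, columns=["gene", "mirna"])

    # --- lncRNA edges ----------------------------------------------------
    lnc_rows = []
    planted_lnc_target = planted_targets[0] if cfg.plant_signal else null_genes[0]
    lnc_rows.append((cfg.planted_lncrna, planted_lnc_target, "regulates", "up"))
    for i in range(cfg.n_lncrnas - 1):
        g = null_genes[int(rng.integers(0, len(null_genes)))]
        mech = ["regulates", "binds", "associates"][int(rng.integers(0, 3))]
        lnc_rows.append((f"LNC-d{i + 1:02d}", g, mech, "down"))
    lnc_edges = pd.DataFrame(lnc_rows, columns=["lncrna", "target", "mechanism", "direction"])

    # --- metabolites and features ---------------------------------------
    n_lib = cfg.n_metabolites + cfg.n_low_confidence
    met_ids = [f"MET{i + 1:03d}" for i in range(n_lib)]
    masses = _distinct_masses(rng, n_lib)
    levels = ["1" if i % 2 == 0 else "2a" for i in range(cfg.n_metabolites)]
    levels += ["2b" if i % 2 == 0 else "3" for i in range(cfg.n_low_confidence)]
    library = pd.DataFrame(
        {"metabolite_id": met_ids, "monoisotopic_mass": masses, "level": levels}
    )

    feat_rows = []
    for i, (mid, mass) in enumerate(zip(met_ids, masses)):
        feat_rows.append((f"F{i + 1:03d}", mass + _PROTON, rng.uniform(30.0, 600.0), mid))
    for j in range(cfg.n_unannotated_features):
        base = rng.uniform(100.0, 800.0)
        feat_rows.append((f"FX{j + 1:02d}", base * (1 + 50e-6), rng.uniform(30.0, 600.0), None))
    features = pd.DataFrame(feat_rows, columns=["feature_id", "mz", "rt", "_true_metabolite"])

    # pathway membership: planted metabolites come from the level-1/2a pool
    hi_conf = met_ids[: cfg.n_metabolites]
    planted_mets = [hi_conf[i] for i in rng.choice(cfg.n_metabolites, size=cfg.pathway_metabolites, replace=False)]
    diff_mets = planted_mets[: cfg.n_diff_metabolites] if cfg.plant_signal else []
    null_mets = [m for m in hi_conf if m not in set(planted_mets)]

    # --- pathway database ------------------------------------------------
    pathway_db: dict = {}
    extra_genes = [null_genes[int(i)] for i in rng.choice(len(null_genes), size=2, replace=False)]
    pathway_db[cfg.planted_pathway] = {
        "genes": set(planted_targets) | set(extra_genes) if cfg.plant_signal else set(extra_genes),
        "mirnas": {cfg.planted_mirna},
        "metabolites": set(planted_mets),
    }
    decoy_names = (
        [p for p in cfg.pathway_db if p != cfg.planted_pathway]
        if cfg.pathway_db is not None
        else [f"pathway_decoy_{i + 1}" for i in range(cfg.n_decoy_pathways)]
    )
    for name in decoy_names:
        pathway_db[name] = {
            "genes": set(rng.choice(null_genes, size=3, replace=False)),
            "mirnas": set(rng.choice(mirnas[1:], size=3, replace=False)),
            "metabolites": set(rng.choice(null_mets, size=min(8, len(null_mets)), replace=False)),
        }

    # --- intensity matrix ------------------------------------------------
    samples = [f"case{i + 1:02d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1:02d}" for i in range(cfg.n_controls)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_cases + ["control"] * cfg.n_controls, index=samples, name="group"
    )
    base = rng.uniform(4.0, 6.0, size=len(features))
    log10 = base[:, None] + rng.normal(0.0, cfg.metab_log10_sd, size=(len(features), len(samples)))
    # alternate the direction of the planted shifts so the per-sample median
    # (the normalisation denominator) is not dragged by the signal
    shift = cfg.metab_log2fc * np.log10(2.0)
    diff_feature_rows = features.index[features["_true_metabolite"].isin(diff_mets)]
    case_cols = np.arange(cfg.n_cases)
    for i, r in enumerate(diff_feature_rows):
        log10[r, case_cols] += shift if i % 2 == 0 else -shift
    intensities = pd.DataFrame(10.0**log10, index=features["feature_id"], columns=samples)

    truth = {
        "pathway": cfg.planted_pathway if cfg.plant_signal else None,
        "mirna": cfg.planted_mirna if cfg.plant_signal else None,
        "lncrna": cfg.planted_lncrna if cfg.plant_signal else None,
        "deg_genes": deg_genes,
        "mirna_targets": planted_targets if cfg.plant_signal else [],
        "diff_metabolites": diff_mets,
    }
    return OmicsFixture(
        deg_table=deg_table,
        mirna_edges=mirna_edges,
        lnc_edges=lnc_edges,
        pathway_db=pathway_db,
        features=features.drop(columns="_true_metabolite"),
        intensities=intensities,
        sample_groups=groups,
        annotation_library=library,
        truth=truth,
    )
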