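"""Synthetic qPCR and survival cohorts with planted effects.

The qPCR generator emits a long-format Cq table (target, reference and
spike-in assays with technical replicates) in which a chosen fold change is
planted as a ``-log2(FC)`` shift of the case target Cq relative to controls,
so downstream 2^-ddCt quantification should recover the planted value.

The survival generator draws exponential event times with a planted hazard
ratio between expression groups and independent exponential censoring
calibrated to the requested censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._errors import ConfigError

__all__ = ["CohortSimConfig", "simulate_cq_table", "simulate_survival_table", "MAX_CYCLES"]

MAX_CYCLES = 45  # qPCR run length; Cq at this sentinel means "not detected"


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror an early-stage NSCLC cohort of 32 patients against 10
    healthy-donor controls with a down-regulated target miRNA
    (``planted_fold_change`` < 1 means lower expression in cases).
    ``hazard_ratio_low_vs_high`` is the event hazard of the low-expression
    group relative to the high-expression group.
    """

    n_patients: int = 32
    n_controls: int = 10
    planted_fold_change: float = 0.25
    target_cq_mean: float = 25.0
    reference_cq_mean: float = 20.0
    reference_cq_sd: float = 0.2
    spikein_cq_mean: float = 22.0
    n_replicates: int = 2
    hazard_ratio_low_vs_high: float = 4.0
    median_survival_high_months: float = 40.0
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("n_patients: must be >= 2")
        if self.n_controls < 1:
            raise ConfigError("n_controls: must be >= 1")
        if self.planted_fold_change <= 0:
            raise ConfigError("planted_fold_change: must be positive")
        if self.reference_cq_sd < 0:
            raise ConfigError("reference_cq_sd: must be >= 0")
        if self.hazard_ratio_low_vs_high <= 0:
            raise ConfigError("hazard_ratio_low_vs_high: must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate: must be in [0, 1)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates: must be >= 1")


def simulate_cq_table(cfg: CohortSimConfig) -> pd.DataFrame:
    """Long-format Cq table: (sample_id, group, assay, replicate, cq).

    Case samples carry a ``-log2(planted_fold_change)`` shift on the target
    assay; draws at or beyond the run length are emitted at the
    ``MAX_CYCLES`` sentinel (undetected).
    """
    rng = np.random.default_rng(cfg.seed)
    shift = -np.log2(cfg.planted_fold_change)
    sd = cfg.reference_cq_sd
    rows = []
    samples = [(f"HD{i + 1:03d}", "control") for i in range(cfg.n_controls)]
    samples += [(f"P{i + 1:03d}", "case") for i in range(cfg.n_patients)]
    for sample_id, group in samples:
        target_mean = cfg.target_cq_mean + (shift if group == "case" else 0.0)
        for assay, mean in (
            ("target", target_mean),
            ("reference", cfg.reference_cq_mean),
            ("spikein", cfg.spikein_cq_mean),
        ):
            for rep in range(1, cfg.n_replicates + 1):
                cq = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                cq = min(cq, MAX_CYCLES)
                rows.append((sample_id, group, assay, rep, cq))
    return pd.DataFrame(rows, columns=["sample_id", "group", "assay", "replicate", "cq"])


def simulate_survival_table(cfg: CohortSimConfig) -> pd.DataFrame:
    """Per-patient survival records: (patient_id, time_months, event,
    endpoint, expression_group).

    Event times are exponential with rate ``lambda_high`` (from the high
    group's median survival) or ``lambda_high * HR`` for the low group.
    Censoring times are independent exponentials with rate
    ``lambda_g * c / (1 - c)``, which makes the marginal probability of
    censoring exactly ``c`` in each group.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    lam_high = np.log(2.0) / cfg.median_survival_high_months
    groups = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
    rng.shuffle(groups)
    lam = np.where(groups == "low", lam_high * cfg.hazard_ratio_low_vs_high, lam_high)
    t_event = rng.exponential(1.0 / lam)
    c = cfg.censoring_rate
    if c > 0:
        lam_cens = lam * c / (1.0 - c)
        t_cens = rng.exponential(1.0 / lam_cens)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive follow-up
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "endpoint": "OS",
            "expression_group": groups,
        }
    )
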