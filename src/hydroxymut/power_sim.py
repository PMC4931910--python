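"""Generative simulation of attainable D² versus window and cohort size.

Large windows explain more deviance than small ones even for a perfect
predictor, simply because small windows carry few mutations.  This module
quantifies that: a synthetic genome is tiled into windows with known CpG
counts, each window receives a Beta(3,4) "ideal" predictor of its
mutation rate, the rate is scaled so a patient carries 174 expected
mutations in total (the observed average CpG>T burden per whole genome),
per-patient counts are drawn binomially, and a Poisson GLM of the
patient-summed counts on the predictor records the attainable D².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import fit_poisson_glm

DEFAULT_WINDOW_SIZES = (3_000, 10_000, 100_000, 1_000_000, 3_000_000)
DEFAULT_N_PATIENTS = (10, 50, 174, 500)


@dataclass
class PowerSimConfig:
    window_sizes: tuple = DEFAULT_WINDOW_SIZES
    n_patients: tuple = DEFAULT_N_PATIENTS
    n_replicates: int = 10
    target_mutations_per_patient: float = 174.0
    beta_a: float = 3.0
    beta_b: float = 4.0
    seed: int = 17082

    def __post_init__(self):
        if self.target_mutations_per_patient <= 0:
            raise ValueError("target mutations per patient must be positive")
        if any(w < 1000 for w in self.window_sizes):
            raise ValueError("window sizes below 1 kb are not supported")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class PowerSimResult:
    runs: pd.DataFrame        # window_size, n_patients, replicate, d2, mean_mutations_per_patient
    config: PowerSimConfig = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Mean and sd of D² per (window size, cohort size) cell."""
        g = self.runs.groupby(["window_size", "n_patients"])["d2"]
        out = g.agg(["mean", "std"]).reset_index()
        return out.rename(columns={"mean": "d2_mean", "std": "d2_sd"})


def simulate_patient_counts(cpg_counts, n_patients: int, cfg: PowerSimConfig, rng):
    """One replicate: per-window summed counts plus per-patient totals.

    predictor_i ~ Beta(a, b); the coefficient is set to
    target / Σ n_i predictor_i so the binomial expectation of a patient's
    total equals the target burden; per patient, counts_i ~
    Binomial(n_i, predictor_i x coefficient).
    """
    n = np.asarray(cpg_counts, int)
    predictor = rng.beta(cfg.beta_a, cfg.beta_b, size=len(n))
    denom = float(np.sum(n * predictor))
    if denom <= 0:
        raise ValueError("no CpG sites in any window")
    coefficient = cfg.target_mutations_per_patient / denom
    prob = predictor * coefficient
    if (prob > 1).any():
        warnings.warn("predictor x coefficient exceeded 1 in some windows; clipped")
        prob = np.minimum(prob, 1.0)
    draws = rng.binomial(n[None, :], prob[None, :], size=(n_patients, len(n)))
    return predictor, draws.sum(axis=0), draws.sum(axis=1)


def run_power_sim(cpg_counts_by_window_size: dict, cfg: PowerSimConfig | None = None
                  ) -> PowerSimResult:
    """Grid of D² over (window size, cohort size), ``n_replicates`` each.

    ``cpg_counts_by_window_size`` maps each window size in
    ``cfg.window_sizes`` to the per-window CpG counts of the genome tiled
    at that size (from a real genome or
    :func:`synthetic_data.simulate_window_cpg_counts`).
    """
    cfg = cfg or PowerSimConfig()
    missing = [w for w in cfg.window_sizes if w not in cpg_counts_by_window_size]
    if missing:
        raise ValueError(f"no CpG counts supplied for window sizes {missing}")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for ws in cfg.window_sizes:
        n = np.asarray(cpg_counts_by_window_size[ws], int)
        keep = n > 0
        for n_pat in cfg.n_patients:
            for rep in range(cfg.n_replicates):
                predictor, y, totals = simulate_patient_counts(n[keep], n_pat, cfg, rng)
                if len(y) == 1:
                    # single window: the predictor is the rate, D² saturates
                    d2 = 1.0
                else:
                    res = fit_poisson_glm(y.astype(float), predictor,
                                          (n[keep] * n_pat).astype(float),
                                          predictor_names=["predictor"])
                    d2 = res.d2
                rows.append((ws, n_pat, rep, d2, float(totals.mean())))
    runs = pd.DataFrame(rows, columns=["window_size", "n_patients", "replicate",
                                       "d2", "mean_mutations_per_patient"])
    return PowerSimResult(runs=runs, config=cfg)


def compare_to_real(result: PowerSimResult, observed_d2: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side table of simulated mean D² and an observed D² curve.

    ``observed_d2`` needs columns window_size and d2 on exactly the
    simulated window-size axis; no statistic is computed, the table is for
    plotting.
    """
    sim = result.summary().groupby("window_size")["d2_mean"].mean().reset_index()
    obs = observed_d2[["window_size", "d2"]].rename(columns={"d2": "d2_observed"})
    if sorted(obs["window_size"]) != sorted(sim["window_size"]):
        raise ValueError("observed curve is on a different window-size axis")
    return sim.merge(obs, on="window_size").rename(columns={"d2_mean": "d2_simulated"})
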