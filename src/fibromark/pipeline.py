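"""End-to-end driver: simulate -> preprocess -> DMP -> network -> synergy.

A single YAML-style mapping configures every stage; unknown keys and
out-of-range values are collected into one violation list. The driver
writes all stage outputs plus a machine-readable ``report.json`` and is
bit-reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .diffmeth import dmp_scan, select_candidates, write_candidates_bed
from .ggmnet import ggm_network
from .preprocess import PreprocessParams, run_preprocess, write_cohort
from .simdata import (
    MethCohortConfig,
    dmr_study_config,
    paired_precision_matrix,
    simulate_dose_grid,
    simulate_methylation_cohort,
    simulate_protein_panel,
)
from .synergy import flag_synergy, synergy_map

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(self.violations))


@dataclass
class DMPParams:
    alpha: float = 0.05
    delta_min: float = 0.10
    min_cpgs_per_locus: int = 2


@dataclass
class NetworkParams:
    n_proteins: int = 22
    n_samples: int = 7
    min_posterior: float = 0.6
    planted_edges: int = 5
    planted_pcor: float = 0.5


@dataclass
class SynergyParams:
    alpha: float = 0.05
    n_doses_a: int = 5
    n_doses_b: int = 4
    n_replicates: int = 4
    noise_sd: float = 0.02
    planted_interaction: float = 0.15


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fibromark_run"
    n_planted_loci: int = 10
    cohort: MethCohortConfig = None  # filled in validate_config / __post_init__
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    dmp: DMPParams = field(default_factory=DMPParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    synergy: SynergyParams = field(default_factory=SynergyParams)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.cohort is None:
            self.cohort = dmr_study_config(self.seed, n_planted_loci=self.n_planted_loci)


_RANGES = {
    ("dmp", "alpha"): (0.0, 1.0),
    ("dmp", "delta_min"): (0.0, 1.0),
    ("network", "min_posterior"): (0.0, 1.0),
    ("network", "planted_pcor"): (-1.0, 1.0),
    ("synergy", "alpha"): (0.0, 1.0),
    ("synergy", "noise_sd"): (0.0, float("inf")),
}


def validate_config(raw: dict) -> RunConfig:
    """Build a typed RunConfig from a raw mapping, reporting all violations.

    Unknown keys (top-level or per-stage) and out-of-range values are
    collected and raised together as a :class:`ConfigError`.
    """
    raw = dict(raw or {})
    violations = []
    sections = {
        "cohort": MethCohortConfig,
        "preprocess": PreprocessParams,
        "dmp": DMPParams,
        "network": NetworkParams,
        "synergy": SynergyParams,
    }
    top_fields = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in top_fields:
            violations.append(f"unknown key: {key!r}")
            continue
        if key in sections:
            cls = sections[key]
            allowed = {f.name for f in fields(cls)}
            sub = dict(value or {})
            for k in list(sub):
                if k not in allowed:
                    violations.append(f"unknown key: {key}.{k!r}")
                    sub.pop(k)
            for (sec, name), (lo, hi) in _RANGES.items():
                if sec == key and name in sub and not lo <= float(sub[name]) <= hi:
                    violations.append(
                        f"{key}.{name} = {sub[name]} outside [{lo}, {hi}]"
                    )
                    sub.pop(name)
            if key == "cohort":
                sub.setdefault("seed", raw.get("seed", 0))
            try:
                kwargs[key] = cls(**sub)
            except (TypeError, ValueError) as err:
                violations.append(f"{key}: {err}")
        else:
            kwargs[key] = value
    if violations:
        raise ConfigError(violations)
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a simulated study and write outputs + report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed, "stages": {}}
    t_all = time.perf_counter()

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    cohort, truth = simulate_methylation_cohort(config.cohort)
    write_cohort(cohort, out / "raw")
    (out / "ground_truth.json").write_text(json.dumps(truth.to_jsonable(), indent=1))
    report["stages"]["simulate"] = {
        "n_probes": cohort.n_probes,
        "n_samples": cohort.n_samples,
        "n_true_dmps": len(truth.true_dmp_ids),
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    clean, qc = run_preprocess(cohort, config.preprocess)
    clean.beta.to_csv(out / "beta_clean.tsv", sep="\t", index_label="probe_id")
    (out / "qc_report.json").write_text(json.dumps(qc, indent=1))
    qc["seconds"] = round(time.perf_counter() - t0, 2)
    report["stages"]["preprocess"] = qc

    # --- differential methylation ----------------------------------------
    t0 = time.perf_counter()
    dmp = dmp_scan(clean, alpha=config.dmp.alpha)
    dmp.to_csv(out / "dmp_results.tsv", sep="\t", index_label="probe_id")
    candidates = select_candidates(
        dmp,
        alpha=config.dmp.alpha,
        delta_min=config.dmp.delta_min,
        min_cpgs_per_locus=config.dmp.min_cpgs_per_locus,
    )
    write_candidates_bed(candidates, dmp, clean.annotation, out / "candidates.bed")
    n_sig = int((dmp["p_adjusted"] < config.dmp.alpha).sum())
    report["stages"]["dmp"] = {
        "probes_tested": int(dmp["converged"].sum()),
        "significant": n_sig,
        "candidates": len(candidates),
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # --- protein network --------------------------------------------------
    t0 = time.perf_counter()
    net_cfg = config.network
    rng = np.random.default_rng([3, config.seed])
    nodes = rng.permutation(net_cfg.n_proteins)
    edges = [
        (int(nodes[2 * i]), int(nodes[2 * i + 1])) for i in range(net_cfg.planted_edges)
    ]
    omega = paired_precision_matrix(net_cfg.n_proteins, edges, net_cfg.planted_pcor)
    panel, net_truth = simulate_protein_panel(
        omega, net_cfg.n_samples, seed=int(rng.integers(2**31))
    )
    panel.to_csv(out / "protein_panel.tsv", sep="\t")
    result = ggm_network(panel, min_posterior=net_cfg.min_posterior)
    result.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    report["stages"]["network"] = {
        "n_proteins": net_cfg.n_proteins,
        "n_samples": net_cfg.n_samples,
        "shrinkage_lambda": round(result.shrinkage_lambda, 4),
        "eta0": round(result.eta0, 4),
        "edges_selected": int(len(result.edges)),
        "true_edges": len(net_truth.true_edge_support),
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # --- synergy ----------------------------------------------------------
    t0 = time.perf_counter()
    syn = config.synergy
    rng2 = np.random.default_rng([4, config.seed])
    fa = np.concatenate([[0.0], np.linspace(0.1, 0.5, syn.n_doses_a - 1)])
    fb = np.concatenate([[0.0], np.linspace(0.1, 0.4, syn.n_doses_b - 1)])
    interaction = np.zeros((syn.n_doses_a, syn.n_doses_b))
    interaction[syn.n_doses_a // 2, syn.n_doses_b // 2] = syn.planted_interaction
    grid, syn_truth = simulate_dose_grid(
        fa, fb, interaction, syn.noise_sd, syn.n_replicates,
        seed=int(rng2.integers(2**31)),
    )
    smap = flag_synergy(synergy_map(grid), alpha=syn.alpha)
    smap.to_frame().to_csv(out / "synergy_map.tsv", sep="\t", index=False)
    n_flagged = int((smap.flags == "synergistic").sum())
    report["stages"]["synergy"] = {
        "grid": [syn.n_doses_a, syn.n_doses_b],
        "flagged_synergistic": n_flagged,
        "planted_interaction": syn.planted_interaction,
        "seconds": round(time.perf_counter() - t0, 2),
    }

    report["seconds_total"] = round(time.perf_counter() - t_all, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
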