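"""Seeded generators for every input the pipeline consumes.

The methylation generator emulates an Illumina 450K-style case/control
cohort: per-probe beta-distributed methylation with a logit-linear mean
model (group, age, smoking, chemotherapy effects), Infinium type I/II
design with type II dynamic-range compression, dye-channel bias on raw
intensities, detection failures and low-bead artifacts. The protein
generator draws multivariate-normal panels from a specified precision
matrix; the dose-grid generator produces replicated viability surfaces
under Bliss independence with an optional planted interaction; the qPCR
generator produces ct tables whose noiseless delta-delta-ct recovers a
configured fold change.

Every generator is a pure function of its configuration and seed and
emits a :class:`GroundTruth` from which the planted signal can be
re-derived exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import BETA_OFFSET, MethylationCohort

__all__ = [
    "MethCohortConfig",
    "GroundTruth",
    "simulate_methylation_cohort",
    "simulate_protein_panel",
    "simulate_dose_grid",
    "simulate_qpcr_table",
    "paired_precision_matrix",
    "planted_effect_to_logit",
    "dmr_study_config",
]

HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "HPRT1")


@dataclass(frozen=True)
class MethCohortConfig:
    """Configuration of the synthetic methylation cohort.

    The defaults describe the study design the pipeline targets: 12 fibrosis
    cases vs 12 fibrosis-free controls on a 450K-style array, with realistic
    artifact rates (rare detection failures and low-bead wells, moderate
    red-channel gain, ~70% type II probes with compressed dynamic range).

    ``planted_loci`` is a list of ``(locus_id, effect, n_affected_cpgs)``
    tuples with the case-vs-control effect on the logit-mean scale;
    ``planted_baselines`` optionally pins the baseline methylation mean of a
    planted locus so the implied beta-scale difference is controlled.
    """

    n_cases: int = 12
    n_controls: int = 12
    n_probes: int = 20000
    n_loci: int = 4000
    probes_per_locus: tuple[int, int] = (1, 4)
    planted_loci: tuple = ()
    planted_baselines: dict = field(default_factory=dict)
    # mixture of two beta distributions for per-probe baseline means
    baseline_mean_distribution: tuple = (0.5, 1.5, 6.0, 6.0, 1.5)
    precision: float = 50.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.004, "smoker_ever": 0.05, "chemotherapy": 0.05}
    )
    age_range: tuple[float, float] = (40.0, 70.0)
    smoker_prob: float = 0.4
    chemo_prob: float = 0.5
    type2_fraction: float = 0.7
    type2_compression: float = 0.85
    dye_bias: float = 0.15
    detection_fail_rate: float = 0.002
    low_bead_rate: float = 0.005
    snp_probe_fraction: float = 0.01
    emit_intensities: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_probes", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cases + self.n_controls < 4:
            raise ValueError(
                "fewer than 4 samples makes the downstream regression unidentifiable"
            )
        for name in (
            "detection_fail_rate",
            "low_bead_rate",
            "type2_fraction",
            "smoker_prob",
            "chemo_prob",
            "snp_probe_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.type2_compression <= 1.0:
            raise ValueError("type2_compression must lie in (0, 1]")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class GroundTruth:
    """Planted parameters emitted alongside every simulation."""

    true_dmp_ids: set = field(default_factory=set)
    true_effect_betas: dict = field(default_factory=dict)
    true_effect_logits: dict = field(default_factory=dict)
    true_partial_correlations: np.ndarray | None = None
    true_edge_support: set = field(default_factory=set)
    true_interaction: np.ndarray | None = None
    true_fold_changes: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out = {
            "true_dmp_ids": sorted(self.true_dmp_ids),
            "true_effect_betas": self.true_effect_betas,
            "true_effect_logits": self.true_effect_logits,
            "true_edge_support": sorted(map(list, self.true_edge_support)),
            "true_fold_changes": self.true_fold_changes,
        }
        if self.true_partial_correlations is not None:
            out["true_partial_correlations"] = self.true_partial_correlations.tolist()
        if self.true_interaction is not None:
            out["true_interaction"] = self.true_interaction.tolist()
        return out


def planted_effect_to_logit(baseline: float, beta_difference: float) -> float:
    """Logit-scale effect that moves a baseline mean by ``beta_difference``."""
    target = baseline + beta_difference
    if not 0.0 < target < 1.0:
        raise ValueError("baseline + difference must stay inside (0, 1)")
    return float(logit(target) - logit(baseline))


# ---------------------------------------------------------------------------
# Methylation cohort
# ---------------------------------------------------------------------------


def _locus_sizes(config: MethCohortConfig) -> np.ndarray:
    """Locus sizes come from a dedicated stream so that helper code can
    reproduce the gene/locus layout without replaying the whole generator."""
    rng = np.random.default_rng([1, config.seed])
    return rng.integers(
        config.probes_per_locus[0], config.probes_per_locus[1] + 1, size=config.n_loci
    )


def _draw_baseline_means(rng: np.random.Generator, n: int, params: tuple) -> np.ndarray:
    w, a1, b1, a2, b2 = params
    lo = rng.random(n) < w
    means = np.where(lo, rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n))
    return np.clip(means, 1e-3, 1 - 1e-3)


def simulate_methylation_cohort(
    config: MethCohortConfig,
) -> tuple[MethylationCohort, GroundTruth]:
    """Generate a case/control 450K-style cohort plus its ground truth.

    Per probe j and sample i the beta value is drawn from a beta
    distribution with precision phi and mean
    ``expit(logit(m_j) + effect_j * case_i + covariate terms)``; type II
    probe values are then compressed toward 0.5, converted to channel
    intensities, distorted by the dye bias and re-assembled as
    ``M / (M + U + 100)``. Detection-p and bead-count layers carry the
    configured artifact rates.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_cases + config.n_controls
    n_probes = config.n_probes

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    # sample sheet: cases first, covariates independent of group
    fibrosis = np.array([1] * config.n_cases + [0] * config.n_controls)
    age = rng.uniform(*config.age_range, size=n_samples)
    smoker = (rng.random(n_samples) < config.smoker_prob).astype(int)
    chemo = (rng.random(n_samples) < config.chemo_prob).astype(int)
    samples = pd.DataFrame(
        {
            "fibrosis": fibrosis,
            "age": np.round(age, 1),
            "smoker_ever": smoker,
            "chemotherapy": chemo,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # gene loci: the first `n_loci` blocks of probes form gene loci, the rest
    # are intergenic
    locus_sizes = _locus_sizes(config)
    gene_of_probe = np.full(n_probes, "", dtype=object)
    region = np.full(n_probes, "intergenic", dtype=object)
    locus_members: dict[str, np.ndarray] = {}
    pos = 0
    region_choices = np.array(["TSS200", "TSS1500", "body", "UTR", "1st exon"])
    for g in range(config.n_loci):
        size = int(locus_sizes[g])
        if pos + size > n_probes:
            break
        name = f"GENE{g:05d}"
        idx = np.arange(pos, pos + size)
        gene_of_probe[idx] = name
        region[idx] = rng.choice(region_choices, size=size)
        locus_members[name] = idx
        pos += size

    baseline = _draw_baseline_means(rng, n_probes, config.baseline_mean_distribution)

    # plant group effects
    effect = np.zeros(n_probes)
    truth = GroundTruth()
    for locus_id, eff, n_aff in config.planted_loci:
        if locus_id not in locus_members:
            raise ValueError(f"planted locus {locus_id!r} does not exist")
        members = locus_members[locus_id]
        if n_aff > members.size:
            raise ValueError(f"locus {locus_id!r} has only {members.size} CpGs")
        affected = members[:n_aff]
        if locus_id in config.planted_baselines:
            baseline[affected] = config.planted_baselines[locus_id]
        effect[affected] = eff

    design_type = np.where(rng.random(n_probes) < config.type2_fraction, "II", "I")
    snp_flag = rng.random(n_probes) < config.snp_probe_fraction
    # type I probes measure both signals in a single colour channel
    channel = np.where(
        design_type == "II", "both", np.where(rng.random(n_probes) < 0.5, "red", "green")
    )

    annotation = pd.DataFrame(
        {
            "chromosome": rng.choice([f"chr{c}" for c in range(1, 23)], size=n_probes),
            "position": rng.integers(1, 2_000_000, size=n_probes),
            "strand": rng.choice(["+", "-"], size=n_probes),
            "design_type": design_type,
            "gene_symbols": gene_of_probe,
            "region_relation": region,
            "cgi_relation": rng.choice(["island", "shore", "open_sea"], size=n_probes),
            "snp_associated": snp_flag,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # logit-linear mean model
    age_c = age - np.mean(config.age_range)
    eta = logit(baseline)[:, None] + effect[:, None] * fibrosis[None, :]
    ce = config.covariate_effects
    eta = eta + (
        ce.get("age", 0.0) * age_c[None, :]
        + ce.get("smoker_ever", 0.0) * smoker[None, :]
        + ce.get("chemotherapy", 0.0) * chemo[None, :]
    )
    mu = np.clip(expit(eta), 1e-4, 1 - 1e-4)
    phi = config.precision
    y = rng.beta(mu * phi, (1 - mu) * phi)
    y = np.clip(y, 1e-6, 1 - 1e-6)

    # type II dynamic-range compression toward 0.5
    if config.type2_compression < 1.0:
        sel = design_type == "II"
        y[sel] = 0.5 + config.type2_compression * (y[sel] - 0.5)

    # truth on the beta scale at reference covariates (cohort covariate means)
    ref = (
        ce.get("age", 0.0) * np.mean(age_c)
        + ce.get("smoker_ever", 0.0) * np.mean(smoker)
        + ce.get("chemotherapy", 0.0) * np.mean(chemo)
    )
    planted = np.flatnonzero(effect != 0.0)
    for j in planted:
        pid = probe_ids[j]
        lb = logit(baseline[j]) + ref
        truth.true_dmp_ids.add(pid)
        truth.true_effect_logits[pid] = float(effect[j])
        truth.true_effect_betas[pid] = float(expit(lb + effect[j]) - expit(lb))

    if config.emit_intensities:
        total = np.exp(rng.normal(np.log(5000.0), 0.25, size=y.shape))
        M = y * total
        U = (1 - y) * total
        if config.dye_bias != 0.0:
            gain = 1.0 + config.dye_bias
            red_i = channel == "red"
            both_i = channel == "both"
            M[red_i] *= gain
            U[red_i] *= gain
            U[both_i] *= gain  # type II unmethylated signal is read in red
        beta_obs = M / (M + U + BETA_OFFSET)
        signal_meth = pd.DataFrame(M, index=annotation.index, columns=samples.index)
        signal_unmeth = pd.DataFrame(U, index=annotation.index, columns=samples.index)
    else:
        beta_obs = y
        signal_meth = signal_unmeth = None

    # detection p-values: mostly tiny, occasional failures with garbage betas
    detection_p = rng.uniform(0.0, 0.005, size=y.shape)
    fails = rng.random(y.shape) < config.detection_fail_rate
    detection_p[fails] = rng.uniform(0.011, 0.8, size=int(fails.sum()))
    beta_obs = np.where(fails, rng.uniform(0, 1, size=y.shape), beta_obs)

    bead_count = rng.poisson(13.0, size=y.shape) + 1
    low = rng.random(y.shape) < config.low_bead_rate
    bead_count[low] = rng.integers(0, 3, size=int(low.sum()))

    cohort = MethylationCohort(
        beta=pd.DataFrame(beta_obs, index=annotation.index, columns=samples.index),
        detection_p=pd.DataFrame(detection_p, index=annotation.index, columns=samples.index),
        bead_count=pd.DataFrame(bead_count, index=annotation.index, columns=samples.index),
        signal_meth=signal_meth,
        signal_unmeth=signal_unmeth,
        channel=pd.Series(channel, index=annotation.index, name="channel"),
        annotation=annotation,
        samples=samples,
    )
    return cohort, truth


def dmr_study_config(
    seed: int,
    n_planted_loci: int = 10,
    beta_diff_range: tuple[float, float] = (0.12, 0.20),
    cpgs_per_dmr: tuple[int, int] = (2, 4),
    **overrides,
) -> MethCohortConfig:
    """Study-design configuration with planted differentially methylated loci.

    Draws, per planted locus, a baseline methylation level in the mid-range,
    a beta-scale case-vs-control difference inside ``beta_diff_range``
    (hypomethylation, the direction the fibrosis screen predominantly found)
    and 2-4 affected CpGs, then converts the difference to the logit-scale
    effect the generator plants.
    """
    rng = np.random.default_rng([2, seed])
    base = MethCohortConfig(seed=seed, **overrides)
    # choose loci large enough to host the requested number of CpGs
    locus_sizes = _locus_sizes(base)
    eligible = np.flatnonzero(locus_sizes >= cpgs_per_dmr[1])
    chosen = rng.choice(eligible, size=n_planted_loci, replace=False)
    planted, baselines = [], {}
    for g in chosen:
        locus = f"GENE{g:05d}"
        m = float(rng.uniform(0.45, 0.65))
        diff = -float(rng.uniform(*beta_diff_range))
        n_aff = int(rng.integers(cpgs_per_dmr[0], cpgs_per_dmr[1] + 1))
        planted.append((locus, planted_effect_to_logit(m, diff), n_aff))
        baselines[locus] = m
    return MethCohortConfig(
        seed=seed,
        planted_loci=tuple(planted),
        planted_baselines=baselines,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Protein panel
# ---------------------------------------------------------------------------


def precision_to_partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix: -w_ij/sqrt(w_ii w_jj)."""
    omega = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def paired_precision_matrix(
    n_proteins: int, edges: list[tuple[int, int]], partial_correlation: float = 0.5
) -> np.ndarray:
    """Precision matrix with unit diagonal and the given edges.

    Each listed (i, j) pair receives off-diagonal entry
    ``-partial_correlation``; with disjoint pairs the implied partial
    correlation at each edge is exactly ``partial_correlation``.
    """
    omega = np.eye(n_proteins)
    for i, j in edges:
        omega[i, j] = omega[j, i] = -partial_correlation
    return omega


def simulate_protein_panel(
    precision: np.ndarray,
    n_samples: int,
    seed: int,
    protein_names: list[str] | None = None,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a proteins x samples panel from N(0, precision^-1).

    The panel emulates log relative protein signals (irradiated vs
    unirradiated) per sample. ``noise_sd`` adds optional independent
    log-scale measurement noise on top of the structured signal.
    """
    omega = np.asarray(precision, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("precision must be a square matrix")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError("precision must be symmetric")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as err:
        eigmin = float(np.linalg.eigvalsh(omega).min())
        raise ValueError(
            f"precision is not positive definite (smallest eigenvalue {eigmin:.3g})"
        ) from err
    p = omega.shape[0]
    if protein_names is None:
        protein_names = [f"P{i:02d}" for i in range(p)]
    rng = np.random.default_rng(seed)
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    x = chol @ rng.standard_normal((p, n_samples))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    panel = pd.DataFrame(
        x,
        index=pd.Index(protein_names, name="protein"),
        columns=[f"F{i:02d}" for i in range(n_samples)],
    )
    pcor = precision_to_partial_correlations(omega)
    support = {
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(pcor[i, j]) > 1e-12
    }
    truth = GroundTruth(true_partial_correlations=pcor, true_edge_support=support)
    return panel, truth


# ---------------------------------------------------------------------------
# Dose grids
# ---------------------------------------------------------------------------


def simulate_dose_grid(
    effect_a: np.ndarray,
    effect_b: np.ndarray,
    interaction: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    doses_a: np.ndarray | None = None,
    doses_b: np.ndarray | None = None,
):
    """Generate a replicated viability grid under Bliss independence.

    ``effect_a`` / ``effect_b`` are the per-dose single-agent fractions
    affected (the first entry must be 0, the untreated level). Expected
    viability per well is ``(1 - fa)(1 - fb) - interaction`` plus Gaussian
    noise, clamped to [0, 1]. Returns a :class:`~fibromark.synergy.DoseGrid`
    and the ground truth holding the planted interaction grid.
    """
    from .synergy import DoseGrid

    fa = np.asarray(effect_a, dtype=float)
    fb = np.asarray(effect_b, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("fractions affected must lie in [0, 1]")
    if fa[0] != 0.0 or fb[0] != 0.0:
        raise ValueError("the first dose level of each agent must be the untreated 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if interaction is None:
        interaction = np.zeros((fa.size, fb.size))
    interaction = np.asarray(interaction, dtype=float)
    if interaction.shape != (fa.size, fb.size):
        raise ValueError("interaction grid is not conformable with the dose axes")
    rng = np.random.default_rng(seed)
    expected = (1 - fa)[:, None] * (1 - fb)[None, :] - interaction
    wells = expected[:, :, None] + rng.normal(
        0.0, noise_sd, size=(fa.size, fb.size, n_replicates)
    )
    wells = np.clip(wells, 0.0, 1.0)
    grid = DoseGrid(
        doses_a=np.arange(fa.size, dtype=float) if doses_a is None else np.asarray(doses_a),
        doses_b=np.arange(fb.size, dtype=float) if doses_b is None else np.asarray(doses_b),
        signal=wells,
    )
    truth = GroundTruth(true_interaction=interaction)
    return grid, truth


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_qpcr_table(
    true_fold_changes: dict,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 1,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format ct table whose noiseless delta-delta-ct
    analysis recovers the configured treatment/control fold changes.

    Targets with fold change f have their treatment ct lowered by log2(f)
    relative to control; the three housekeeping genes are condition-stable.
    """
    for gene, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        sample = f"S{s:02d}"
        hk_base = {g: rng.uniform(18.0, 22.0) for g in HOUSEKEEPING_GENES}
        for gene, f in true_fold_changes.items():
            base = rng.uniform(24.0, 28.0)
            for condition, ct in (("control", base), ("treatment", base - np.log2(f))):
                rows.append((sample, gene, condition, ct + rng.normal(0, ct_noise_sd)))
        for g, base in hk_base.items():
            for condition in ("control", "treatment"):
                rows.append((sample, g, condition, base + rng.normal(0, ct_noise_sd)))
    table = pd.DataFrame(rows, columns=["sample", "gene", "condition", "ct"])
    return table, GroundTruth(true_fold_changes=dict(true_fold_changes))
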