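"""Methylation-array cohort container and preprocessing.

Implements the QC and normalization chain used for Illumina 450K-style
beta-value matrices in a case/control EWAS of radiation-induced fibrosis:

1. bead filter        — detection p set to 1 where bead count < 3
2. detection mask     — beta set to missing where detection p > 0.01
3. missingness filter — probes with > 30% missing dropped
4. SNP filter         — SNP-associated probes dropped
5. kNN imputation     — k = 10, probes as items, distance-weighted
6. colour correction  — smooth quantile normalization between channels
7. BMIQ               — beta-mixture quantile normalization of type II probes
8. variance filter    — probes with across-sample s.d. < 5% dropped

All stages operate on (and return) :class:`MethylationCohort` copies; the
orchestrator :func:`run_preprocess` runs them in the order above and emits a
QC report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MethylationCohort",
    "PreprocessParams",
    "apply_bead_filter",
    "mask_by_detection",
    "drop_high_missing_probes",
    "drop_snp_probes",
    "impute_knn",
    "correct_color_bias",
    "bmiq_normalize",
    "fit_beta_mixture",
    "filter_low_variance",
    "run_preprocess",
    "read_cohort",
    "write_cohort",
]

# Probe annotation columns expected throughout the pipeline.
ANNOTATION_COLUMNS = (
    "chromosome",
    "position",
    "strand",
    "design_type",
    "gene_symbols",
    "region_relation",
    "cgi_relation",
    "snp_associated",
)

REGION_CATEGORIES = ("TSS200", "TSS1500", "body", "UTR", "1st exon", "intergenic")

#: Conventional stabilizing offset for beta = M / (M + U + offset).
BETA_OFFSET = 100.0


@dataclass
class MethylationCohort:
    """Probes x samples methylation matrices with QC layers and metadata.

    Attributes
    ----------
    beta : DataFrame
        Methylation fractions in [0, 1]; NaN marks masked values.
    detection_p : DataFrame or None
        Per-value detection p-values in [0, 1].
    bead_count : DataFrame or None
        Per-value bead counts (non-negative integers).
    signal_meth, signal_unmeth : DataFrame or None
        Optional raw channel intensities (methylated / unmethylated).
    channel : Series or None
        Per-probe channel assignment: ``red`` / ``green`` for Infinium I
        (both signals in one channel), ``both`` for Infinium II
        (methylated in green, unmethylated in red).
    annotation : DataFrame
        Probe annotation (design type, gene, region relation, SNP flag, ...).
    samples : DataFrame
        Sample sheet with covariates ``fibrosis``, ``age``, ``smoker_ever``,
        ``chemotherapy``.
    normalized_stages : set
        Names of normalization stages already applied (``color``, ``bmiq``);
        re-running the pipeline skips them, making preprocessing idempotent.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    signal_meth: pd.DataFrame | None = None
    signal_unmeth: pd.DataFrame | None = None
    channel: pd.Series | None = None
    normalized_stages: set = field(default_factory=set)

    def __post_init__(self) -> None:
        probes = self.beta.index
        samples = self.beta.columns
        for name in ("detection_p", "bead_count", "signal_meth", "signal_unmeth"):
            layer = getattr(self, name)
            if layer is not None and (
                not layer.index.equals(probes) or not layer.columns.equals(samples)
            ):
                raise ValueError(f"layer {name!r} is not aligned with the beta matrix")
        if not self.annotation.index.equals(probes):
            raise ValueError("annotation index does not match the beta matrix rows")
        if not self.samples.index.equals(samples):
            raise ValueError("sample sheet index does not match the beta matrix columns")
        if self.channel is not None and not self.channel.index.equals(probes):
            raise ValueError("channel assignment does not match the beta matrix rows")

    # -- basic interrogation -------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def copy(self) -> "MethylationCohort":
        layers = {
            name: (getattr(self, name).copy() if getattr(self, name) is not None else None)
            for name in ("detection_p", "bead_count", "signal_meth", "signal_unmeth", "channel")
        }
        return MethylationCohort(
            beta=self.beta.copy(),
            annotation=self.annotation.copy(),
            samples=self.samples.copy(),
            normalized_stages=set(self.normalized_stages),
            **layers,
        )

    def subset_probes(self, probe_ids) -> "MethylationCohort":
        """Return a cohort restricted (in order) to ``probe_ids``."""
        layers = {}
        for name in ("detection_p", "bead_count", "signal_meth", "signal_unmeth", "channel"):
            layer = getattr(self, name)
            layers[name] = layer.loc[probe_ids] if layer is not None else None
        return MethylationCohort(
            beta=self.beta.loc[probe_ids],
            annotation=self.annotation.loc[probe_ids],
            samples=self.samples,
            normalized_stages=set(self.normalized_stages),
            **layers,
        )


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing thresholds; the defaults are the study settings."""

    min_beads: int = 3
    detection_p_max: float = 0.01
    max_missing_fraction: float = 0.3
    knn_k: int = 10
    sd_min: float = 0.05
    color_correction: bool = True
    bmiq: bool = True
    beta_offset: float = BETA_OFFSET

    def __post_init__(self) -> None:
        if self.min_beads < 0:
            raise ValueError("min_beads must be non-negative")
        for name in ("detection_p_max", "max_missing_fraction", "sd_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


# ---------------------------------------------------------------------------
# Stage 1-4: raw-data filtering
# ---------------------------------------------------------------------------


def apply_bead_filter(cohort: MethylationCohort, min_beads: int = 3) -> MethylationCohort:
    """Set detection p to 1 wherever the bead count falls below ``min_beads``.

    Beta values are untouched at this stage; the subsequent detection mask
    removes the affected values.
    """
    if cohort.bead_count is None:
        raise ValueError("bead filter requires a bead-count layer")
    if cohort.detection_p is None:
        raise ValueError("bead filter requires a detection-p layer")
    out = cohort.copy()
    low = out.bead_count.to_numpy() < min_beads
    dp = out.detection_p.to_numpy(copy=True)
    dp[low] = 1.0
    out.detection_p = pd.DataFrame(dp, index=out.beta.index, columns=out.beta.columns)
    return out


def mask_by_detection(
    cohort: MethylationCohort, detection_p_max: float = 0.01
) -> tuple[MethylationCohort, int]:
    """Mask beta values whose detection p exceeds the threshold (strictly).

    Returns the modified cohort and the number of newly missing cells.
    """
    if cohort.detection_p is None:
        raise ValueError("detection masking requires a detection-p layer")
    out = cohort.copy()
    beta = out.beta.to_numpy(copy=True)
    fail = (out.detection_p.to_numpy() > detection_p_max) & ~np.isnan(beta)
    beta[fail] = np.nan
    out.beta = pd.DataFrame(beta, index=out.beta.index, columns=out.beta.columns)
    return out, int(fail.sum())


def drop_high_missing_probes(
    cohort: MethylationCohort, max_missing_fraction: float = 0.3
) -> tuple[MethylationCohort, list]:
    """Drop probes whose missing fraction exceeds the threshold (strictly)."""
    frac = cohort.beta.isna().mean(axis=1)
    dropped = cohort.beta.index[frac > max_missing_fraction]
    keep = cohort.beta.index.difference(dropped, sort=False)
    return cohort.subset_probes(keep), list(dropped)


def drop_snp_probes(cohort: MethylationCohort) -> tuple[MethylationCohort, list]:
    """Drop probes flagged as SNP-associated in the annotation."""
    if "snp_associated" not in cohort.annotation.columns:
        raise ValueError("annotation lacks the snp_associated flag")
    flagged = cohort.annotation.index[cohort.annotation["snp_associated"].astype(bool)]
    keep = cohort.beta.index.difference(flagged, sort=False)
    if len(keep) == 0:
        warnings.warn("all probes are SNP-associated; cohort is empty", stacklevel=2)
    return cohort.subset_probes(keep), list(flagged)


# ---------------------------------------------------------------------------
# Stage 5: kNN imputation
# ---------------------------------------------------------------------------


def _nan_euclidean_sq(receivers: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Squared NaN-aware Euclidean distances, scaled by n_features/co-observed.

    Matrix-product formulation of the masked distance so the whole receiver
    block is handled by BLAS: with zero-filled values A, B and observation
    masks Ma, Mb,  sum_co (a-b)^2 = (A^2)Mb' + Ma(B^2)' - 2AB'.
    """
    n_feat = receivers.shape[1]
    Ma = (~np.isnan(receivers)).astype(float)
    Mb = (~np.isnan(donors)).astype(float)
    A = np.where(np.isnan(receivers), 0.0, receivers)
    B = np.where(np.isnan(donors), 0.0, donors)
    co = Ma @ Mb.T
    sq = (A**2) @ Mb.T + Ma @ (B**2).T - 2.0 * (A @ B.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(co > 0, n_feat * sq / co, np.inf)
    return np.maximum(d2, 0.0)


def impute_knn(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing beta values by k-nearest-neighbour probes.

    Probes are the items and samples the feature axis; the distance is the
    (NaN-aware) Euclidean distance over co-observed samples and neighbour
    contributions are weighted by inverse distance (ties at zero distance
    average the zero-distance neighbours). Only donors observed at the
    target sample count toward a cell's k neighbours; a probe with no
    reachable donor falls back to its own mean. Observed entries are
    returned unchanged and the output is clipped to [0, 1].
    """
    values = beta.to_numpy(dtype=float)
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return beta.copy()
    n_probes, n_samples = values.shape
    if n_probes <= k:
        warnings.warn(
            f"matrix has only {n_probes} probes; using all available neighbours",
            stacklevel=2,
        )
        k = max(n_probes - 1, 1)

    filled = values.copy()
    receivers = np.flatnonzero(nan_mask.any(axis=1))
    donor_ok = ~nan_mask  # per (donor, sample) availability
    for start in range(0, receivers.size, 512):
        rows = receivers[start : start + 512]
        d2 = _nan_euclidean_sq(values[rows], values)
        d2[np.arange(rows.size), rows] = np.inf  # never self-impute
        for ri, row in enumerate(rows):
            for col in np.flatnonzero(nan_mask[row]):
                dist = np.where(donor_ok[:, col], d2[ri], np.inf)
                finite = np.isfinite(dist)
                n_avail = int(finite.sum())
                if n_avail == 0:
                    continue  # probe-mean fallback below
                kk = min(k, n_avail)
                nn = np.argpartition(dist, kk - 1)[:kk]
                d = np.sqrt(dist[nn])
                if np.any(d < 1e-12):
                    sel = d < 1e-12
                    filled[row, col] = values[nn[sel], col].mean()
                else:
                    w = 1.0 / d
                    filled[row, col] = np.sum(w * values[nn, col]) / w.sum()

    still = np.isnan(filled)
    if still.any():
        row_mean = np.nanmean(np.where(still, np.nan, filled), axis=1)
        filled[still] = np.broadcast_to(row_mean[:, None], filled.shape)[still]
    out = np.clip(filled, 0.0, 1.0)
    out[~nan_mask] = values[~nan_mask]
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# Stage 6: colour-bias correction (smooth quantile normalization)
# ---------------------------------------------------------------------------


def _quantile_map_to_average(values_by_channel: dict) -> dict:
    """Map both channels onto their pooled average quantile function.

    Each value v with empirical cdf position p in its own channel maps to
    the mean of v and the other channel's quantile at p. The map is
    monotone within each channel, and a channel pair with identical value
    distributions is a fixed point.
    """
    channels = [ch for ch, v in values_by_channel.items() if v.size]
    if len(channels) != 2:
        return {ch: v for ch, v in values_by_channel.items()}
    a, b = channels
    sorted_vals = {ch: np.sort(values_by_channel[ch]) for ch in channels}
    positions = {
        ch: (np.arange(sorted_vals[ch].size) + 0.5) / sorted_vals[ch].size
        for ch in channels
    }
    out = {}
    for ch, other in ((a, b), (b, a)):
        v = values_by_channel[ch]
        # tie-averaged ranks keep equal inputs equal
        p = (pd.Series(v).rank(method="average").to_numpy() - 0.5) / v.size
        other_q = np.interp(p, positions[other], sorted_vals[other])
        out[ch] = 0.5 * (v + other_q)
    return out


def correct_color_bias(
    cohort: MethylationCohort,
    offset: float = BETA_OFFSET,
    observed_mask: np.ndarray | None = None,
) -> MethylationCohort:
    """Equalize the red/green intensity distributions per sample.

    Smooth quantile normalization: within each sample, both channels are
    mapped onto their pooled average quantile function (a monotone map), and
    betas are recomputed as M / (M + U + offset) from the corrected
    intensities.

    Parameters
    ----------
    observed_mask : bool array (probes x samples), optional
        Where False, the existing beta value (e.g. an imputed one) is kept
        instead of being recomputed from intensities.
    """
    if cohort.signal_meth is None or cohort.signal_unmeth is None or cohort.channel is None:
        warnings.warn(
            "no channel intensities available; colour correction skipped", stacklevel=2
        )
        return cohort.copy()
    out = cohort.copy()
    M = out.signal_meth.to_numpy(dtype=float, copy=True)
    U = out.signal_unmeth.to_numpy(dtype=float, copy=True)
    ch = out.channel.to_numpy()
    is_red = ch == "red"
    is_green = ch == "green"
    is_both = ch == "both"
    for j in range(M.shape[1]):
        # channel pools: type I contributes both signals to its channel,
        # type II splits M->green, U->red
        red_vals = np.concatenate([M[is_red, j], U[is_red, j], U[is_both, j]])
        green_vals = np.concatenate([M[is_green, j], U[is_green, j], M[is_both, j]])
        mapped = _quantile_map_to_average({"red": red_vals, "green": green_vals})
        r, g = mapped["red"], mapped["green"]
        n1 = is_red.sum()
        M[is_red, j] = r[:n1]
        U[is_red, j] = r[n1 : 2 * n1]
        U[is_both, j] = r[2 * n1 :]
        n2 = is_green.sum()
        M[is_green, j] = g[:n2]
        U[is_green, j] = g[n2 : 2 * n2]
        M[is_both, j] = g[2 * n2 :]
    out.signal_meth = pd.DataFrame(M, index=out.beta.index, columns=out.beta.columns)
    out.signal_unmeth = pd.DataFrame(U, index=out.beta.index, columns=out.beta.columns)
    beta_new = M / (M + U + offset)
    beta_old = out.beta.to_numpy(copy=True)
    if observed_mask is None:
        observed_mask = ~np.isnan(beta_old)
    beta_old[observed_mask] = beta_new[observed_mask]
    out.beta = pd.DataFrame(
        np.clip(beta_old, 0.0, 1.0), index=out.beta.index, columns=out.beta.columns
    )
    out.normalized_stages.add("color")
    return out


# ---------------------------------------------------------------------------
# Stage 7: BMIQ (beta-mixture quantile normalization)
# ---------------------------------------------------------------------------


def fit_beta_mixture(
    x: np.ndarray,
    n_components: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> dict:
    """Fit a 3-state beta mixture (unmethylated / hemimethylated / methylated).

    EM with class initialization by fixed thresholds (<= 0.25 unmethylated,
    >= 0.75 methylated) and a weighted method-of-moments M-step. Returns
    component shape parameters ``a``, ``b``, weights ``w``, the final
    log-likelihood and a convergence flag.
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-6, 1.0 - 1e-6)
    n = x.size
    logx = np.log(x)[:, None]
    log1mx = np.log1p(-x)[:, None]
    resp = np.zeros((n, n_components))
    resp[x <= 0.25, 0] = 1.0
    resp[(x > 0.25) & (x < 0.75), 1] = 1.0
    resp[x >= 0.75, 2] = 1.0
    # guard against empty classes on degenerate inputs
    resp += 1e-3
    resp /= resp.sum(axis=1, keepdims=True)
    a = np.full(n_components, 2.0)
    b = np.full(n_components, 2.0)
    w = resp.mean(axis=0)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # M-step: weighted method of moments per component
        wsum = resp.sum(axis=0)
        m = (resp * x[:, None]).sum(axis=0) / wsum
        v = (resp * (x[:, None] - m) ** 2).sum(axis=0) / wsum
        v = np.maximum(v, 1e-8)
        common = np.maximum(m * (1 - m) / v - 1.0, 1e-2)
        a = np.maximum(m * common, 1e-2)
        b = np.maximum((1 - m) * common, 1e-2)
        w = wsum / n
        # E-step (beta log-pdf written out: scipy dispatch is too slow here)
        logpdf = (
            (a - 1.0)[None, :] * logx
            + (b - 1.0)[None, :] * log1mx
            - special.betaln(a, b)[None, :]
        )
        logw = np.log(np.maximum(w, 1e-12))
        joint = logpdf + logw[None, :]
        mx = joint.max(axis=1, keepdims=True)
        resp = np.exp(joint - mx)
        norm = resp.sum(axis=1, keepdims=True)
        resp /= norm
        total = float((mx[:, 0] + np.log(norm[:, 0])).sum())
        if abs(total - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            prev_ll = total
            break
        prev_ll = total
    if not converged:
        warnings.warn("beta-mixture EM did not converge; using best iterate", stacklevel=2)
    return {"a": a, "b": b, "w": w, "loglik": float(prev_ll), "converged": converged}


def _fit_subsample(x: np.ndarray, cap: int = 4000) -> np.ndarray:
    """Deterministic quantile-stratified subsample for mixture fitting."""
    if x.size <= cap:
        return x
    xs = np.sort(x)
    return xs[np.linspace(0, x.size - 1, cap).astype(int)]


def _mixture_cdf(x: np.ndarray, fit: dict) -> np.ndarray:
    cdf = np.zeros_like(x, dtype=float)
    for ak, bk, wk in zip(fit["a"], fit["b"], fit["w"]):
        cdf += wk * stats.beta.cdf(x, ak, bk)
    return cdf


def bmiq_normalize(
    beta: pd.DataFrame,
    design_type: pd.Series,
    min_probes: int = 50,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Map type II probe betas onto the type I distribution, per sample.

    For each sample a 3-state beta mixture is fitted to the type I and to the
    type II values; type II values are then transformed by the monotone
    probability-integral map ``F_I^{-1}(F_II(x))`` built from the two fitted
    mixture CDFs, so the type II distribution matches the type I reference.
    Type I values are returned bit-identical.
    """
    design = design_type.loc[beta.index].astype(str).to_numpy()
    is2 = design == "II"
    is1 = design == "I"
    out = beta.to_numpy(dtype=float, copy=True)
    grid = np.linspace(0.0, 1.0, 2001)
    for j, sample in enumerate(beta.columns):
        x1 = out[is1, j]
        x2 = out[is2, j]
        ok1, ok2 = ~np.isnan(x1), ~np.isnan(x2)
        if ok1.sum() < min_probes or ok2.sum() < min_probes:
            warnings.warn(
                f"sample {sample!r} has fewer than {min_probes} probes of one "
                "design type; BMIQ skipped for it",
                stacklevel=2,
            )
            continue
        if np.nanstd(x2[ok2]) < 1e-12:
            # degenerate: all type II values equal; map through type I median
            fit1 = fit_beta_mixture(_fit_subsample(x1[ok1]), tol=tol, max_iter=max_iter)
            cdf1 = np.maximum.accumulate(_mixture_cdf(grid, fit1))
            x2new = np.interp(0.5, cdf1, grid)
            vals = x2.copy()
            vals[ok2] = x2new
            out[is2, j] = vals
            continue
        fit1 = fit_beta_mixture(_fit_subsample(x1[ok1]), tol=tol, max_iter=max_iter)
        fit2 = fit_beta_mixture(_fit_subsample(x2[ok2]), tol=tol, max_iter=max_iter)
        u = _mixture_cdf(np.clip(x2[ok2], 1e-6, 1 - 1e-6), fit2)
        cdf1 = np.maximum.accumulate(_mixture_cdf(grid, fit1))
        # strictly increasing grid for inversion
        cdf1 = cdf1 + np.arange(grid.size) * 1e-12
        mapped = np.interp(u * (1 + 2e-9), cdf1 / cdf1[-1], grid)
        vals = x2.copy()
        vals[ok2] = np.clip(mapped, 0.0, 1.0)
        out[is2, j] = vals
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# Stage 8: variance filter
# ---------------------------------------------------------------------------


def filter_low_variance(beta: pd.DataFrame, sd_min: float = 0.05) -> tuple[pd.DataFrame, list]:
    """Drop probes whose across-sample s.d. is below ``sd_min`` (strictly)."""
    sd = beta.std(axis=1, ddof=1)
    dropped = beta.index[sd < sd_min]
    return beta.drop(index=dropped), list(dropped)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_preprocess(
    cohort: MethylationCohort, params: PreprocessParams | None = None
) -> tuple[MethylationCohort, dict]:
    """Run the full filtering + preprocessing chain and emit a QC report.

    Stage order: bead filter, detection mask, missingness drop, SNP drop,
    kNN imputation, colour correction, BMIQ, variance filter. Stages recorded
    in ``cohort.normalized_stages`` are skipped, so the pipeline is a fixed
    point on its own output.
    """
    params = params or PreprocessParams()
    report: dict = {"probes_in": cohort.n_probes, "n_samples": cohort.n_samples}

    work = cohort
    if work.bead_count is not None and work.detection_p is not None:
        n_low = int((work.bead_count.to_numpy() < params.min_beads).sum())
        work = apply_bead_filter(work, params.min_beads)
        report["cells_low_bead"] = n_low
    else:
        report["cells_low_bead"] = 0

    if work.detection_p is not None:
        work, n_masked = mask_by_detection(work, params.detection_p_max)
        report["cells_masked"] = n_masked
    else:
        report["cells_masked"] = 0

    work, dropped_missing = drop_high_missing_probes(work, params.max_missing_fraction)
    report["probes_dropped_missing"] = len(dropped_missing)

    work, dropped_snp = drop_snp_probes(work)
    report["probes_dropped_snp"] = len(dropped_snp)

    missing_mask = work.beta.isna().to_numpy()
    report["cells_imputed"] = int(missing_mask.sum())
    if missing_mask.any():
        work = work.copy()
        work.beta = impute_knn(work.beta, params.knn_k)
        # stamp imputed cells as resolved so the QC layers describe the
        # cleaned matrix (and a second pass is a no-op)
        if work.detection_p is not None:
            dp = work.detection_p.to_numpy(copy=True)
            dp[missing_mask] = 0.0
            work.detection_p = pd.DataFrame(
                dp, index=work.beta.index, columns=work.beta.columns
            )
        if work.bead_count is not None:
            bc = work.bead_count.to_numpy(copy=True)
            bc[missing_mask & (bc < params.min_beads)] = params.min_beads
            work.bead_count = pd.DataFrame(
                bc, index=work.beta.index, columns=work.beta.columns
            )

    if params.color_correction and "color" not in work.normalized_stages:
        work = correct_color_bias(
            work, offset=params.beta_offset, observed_mask=~missing_mask
        )
        report["color_corrected"] = "color" in work.normalized_stages
    else:
        report["color_corrected"] = "color" in work.normalized_stages

    if params.bmiq and "bmiq" not in work.normalized_stages:
        work = work.copy()
        work.beta = bmiq_normalize(work.beta, work.annotation["design_type"])
        work.normalized_stages.add("bmiq")
        report["bmiq_applied"] = True
    else:
        report["bmiq_applied"] = "bmiq" in work.normalized_stages

    beta_kept, dropped_sd = filter_low_variance(work.beta, params.sd_min)
    report["probes_dropped_low_variance"] = len(dropped_sd)
    work = work.subset_probes(beta_kept.index)
    work.beta = beta_kept

    report["probes_out"] = work.n_probes
    report["probes_removed_total"] = report["probes_in"] - report["probes_out"]
    return work, report


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: MethylationCohort, directory) -> None:
    """Write the cohort as TSV/CSV tables (probe_id first column)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.beta.to_csv(directory / "beta.tsv", sep="\t", index_label="probe_id")
    if cohort.detection_p is not None:
        cohort.detection_p.to_csv(
            directory / "detection_p.tsv", sep="\t", index_label="probe_id"
        )
    if cohort.bead_count is not None:
        cohort.bead_count.to_csv(directory / "beads.tsv", sep="\t", index_label="probe_id")
    if cohort.signal_meth is not None:
        cohort.signal_meth.to_csv(
            directory / "signal_meth.tsv", sep="\t", index_label="probe_id"
        )
    if cohort.signal_unmeth is not None:
        cohort.signal_unmeth.to_csv(
            directory / "signal_unmeth.tsv", sep="\t", index_label="probe_id"
        )
    annot = cohort.annotation.copy()
    if cohort.channel is not None:
        annot["channel"] = cohort.channel
    annot.to_csv(directory / "annotation.csv", index_label="probe_id")
    cohort.samples.to_csv(directory / "samples.csv", index_label="sample_id")


def read_cohort(directory) -> MethylationCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    from pathlib import Path

    directory = Path(directory)

    def _opt(name, **kw):
        path = directory / name
        return pd.read_csv(path, index_col="probe_id", **kw) if path.exists() else None

    beta = pd.read_csv(directory / "beta.tsv", sep="\t", index_col="probe_id")
    annotation = pd.read_csv(directory / "annotation.csv", index_col="probe_id")
    channel = None
    if "channel" in annotation.columns:
        channel = annotation.pop("channel")
    samples = pd.read_csv(directory / "samples.csv", index_col="sample_id")
    layers = {
        "detection_p": _opt("detection_p.tsv", sep="\t"),
        "bead_count": _opt("beads.tsv", sep="\t"),
        "signal_meth": _opt("signal_meth.tsv", sep="\t"),
        "signal_unmeth": _opt("signal_unmeth.tsv", sep="\t"),
    }
    for df in (beta, *filter(lambda x: x is not None, layers.values())):
        df.columns.name = "sample_id"
    return MethylationCohort(
        beta=beta, channel=channel, annotation=annotation, samples=samples, **layers
    )
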