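"""Bliss-independence synergy analysis of drug x radiation dose grids.

Viability signals on a replicated dose-combination grid (e.g. a DGKA
inhibitor crossed with ionizing-radiation doses, quadruplicate wells) are
converted to fractions affected relative to the untreated control; the
Bliss expectation fa + fb - fa*fb built from the single-agent marginals is
compared with the observed combination effect. Positive delta
(observed - expected) means stronger growth suppression than independence
predicts, i.e. synergy; the map is also exposed on the viability scale
(-delta) matching how combination screens are usually displayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .auxquant import holm_sidak

__all__ = [
    "DoseGrid",
    "SynergyMap",
    "fraction_affected",
    "bliss_expected",
    "synergy_map",
    "flag_synergy",
    "read_well_table",
]


@dataclass
class DoseGrid:
    """Replicated viability signals over a dose-combination grid.

    ``signal`` has shape (len(doses_a), len(doses_b), n_replicates); the
    (0, 0) cell holds the untreated control wells.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 3 or self.signal.shape[:2] != (
            self.doses_a.size,
            self.doses_b.size,
        ):
            raise ValueError("signal must have shape (n_doses_a, n_doses_b, n_reps)")
        if self.doses_a[0] != 0.0 or self.doses_b[0] != 0.0:
            raise ValueError("the (0, 0) untreated combination must be present")
        if np.any(self.signal < 0):
            raise ValueError("viability signals must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[2]


@dataclass
class SynergyMap:
    """Per-combination observed/expected fractions affected and deltas."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    fa_observed: np.ndarray
    fa_expected: np.ndarray
    delta: np.ndarray  # observed - expected; > 0 = synergistic suppression
    se: np.ndarray
    n_replicates: int
    flags: np.ndarray | None = None  # "synergistic" / "additive" / "antagonistic"
    p_adjusted: np.ndarray | None = None

    @property
    def viability_delta(self) -> np.ndarray:
        """Delta on the viability scale (negative where growth is
        suppressed more than expected)."""
        return -self.delta

    def to_frame(self) -> pd.DataFrame:
        ia, ib = np.meshgrid(
            np.arange(self.doses_a.size), np.arange(self.doses_b.size), indexing="ij"
        )
        out = pd.DataFrame(
            {
                "dose_a": self.doses_a[ia.ravel()],
                "dose_b": self.doses_b[ib.ravel()],
                "fa_observed": self.fa_observed.ravel(),
                "fa_expected": self.fa_expected.ravel(),
                "delta": self.delta.ravel(),
                "se": self.se.ravel(),
            }
        )
        if self.flags is not None:
            out["flag"] = self.flags.ravel()
            out["p_adjusted"] = self.p_adjusted.ravel()
        return out


def fraction_affected(signal_treated, signal_control) -> np.ndarray:
    """Fraction affected 1 - treated/control, clamped to [0, 1].

    Values above the control (growth stimulation) clamp to 0; a warning is
    emitted since the clamp hides the stimulation.
    """
    control = np.asarray(signal_control, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control signal must be positive")
    fa = 1.0 - np.asarray(signal_treated, dtype=float) / control
    if np.any(fa < 0):
        warnings.warn("treated signal above control; fraction affected clamped to 0",
                      stacklevel=2)
    return np.clip(fa, 0.0, 1.0)


def bliss_expected(fa, fb):
    """Bliss independence expectation fa + fb - fa*fb."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("fractions affected must lie in [0, 1]")
    out = fa + fb - fa * fb
    return float(out) if out.ndim == 0 else out


def synergy_map(grid: DoseGrid) -> SynergyMap:
    """Observed-minus-expected Bliss surface with propagated replicate s.e.

    Fractions affected are averaged over replicates first; the expectation
    at (a, b) uses the observed single-agent marginals at (a, 0) and (0, b).
    The standard error of delta propagates the replicate s.e. of the
    combination and of both marginals.
    """
    na, nb, nrep = grid.signal.shape
    control = grid.signal[0, 0, :].mean()
    if control <= 0:
        raise ValueError("control wells have non-positive mean signal")
    fa_wells = np.clip(1.0 - grid.signal / control, 0.0, 1.0)
    fa_obs = fa_wells.mean(axis=2)
    # the untreated combination defines the reference: its own fraction
    # affected is 0 by definition (clipped well noise would otherwise bias it)
    fa_obs[0, 0] = 0.0
    se = fa_wells.std(axis=2, ddof=1) / np.sqrt(nrep) if nrep > 1 else np.zeros((na, nb))

    fa_a = fa_obs[:, 0]  # agent A alone
    fa_b = fa_obs[0, :]  # agent B alone
    expected = bliss_expected(fa_a[:, None], fa_b[None, :])
    delta = fa_obs - expected

    # se(delta)^2 = se_comb^2 + ((1-fb) se_a)^2 + ((1-fa) se_b)^2
    se_a, se_b = se[:, 0], se[0, :]
    se_delta = np.sqrt(
        se**2
        + ((1 - fa_b)[None, :] * se_a[:, None]) ** 2
        + ((1 - fa_a)[:, None] * se_b[None, :]) ** 2
    )
    # margins and the untreated cell match their own expectation by construction
    se_delta[:, 0] = 0.0
    se_delta[0, :] = 0.0
    return SynergyMap(
        doses_a=grid.doses_a,
        doses_b=grid.doses_b,
        fa_observed=fa_obs,
        fa_expected=expected,
        delta=delta,
        se=se_delta,
        n_replicates=nrep,
    )


def flag_synergy(smap: SynergyMap, alpha: float = 0.05) -> SynergyMap:
    """Per-combination t-test of delta against 0 with Holm-Sidak correction.

    Only true combinations (both doses > 0) are tested; flags are
    ``synergistic`` (delta > 0, adjusted p < alpha), ``antagonistic``
    (delta < 0, adjusted p < alpha) or ``additive``.
    """
    if smap.n_replicates < 2:
        warnings.warn("single replicate: significance flags withheld", stacklevel=2)
        smap.flags = None
        return smap
    na, nb = smap.delta.shape
    test = np.zeros((na, nb), dtype=bool)
    test[1:, 1:] = True
    t = np.zeros((na, nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t[test] = smap.delta[test] / smap.se[test]
    df = smap.n_replicates - 1
    p = 2.0 * stats.t.sf(np.abs(t[test]), df=df)
    p[~np.isfinite(t[test])] = 1.0
    # zero replicate variance: only a delta beyond float round-off counts
    zero_se = smap.se[test] == 0
    p[zero_se] = np.where(np.abs(smap.delta[test][zero_se]) < 1e-10, 1.0, 0.0)
    padj = holm_sidak(p)
    flags = np.full((na, nb), "additive", dtype=object)
    sig = padj < alpha
    dsub = smap.delta[test]
    flat = np.full(dsub.shape, "additive", dtype=object)
    flat[sig & (dsub > 0)] = "synergistic"
    flat[sig & (dsub < 0)] = "antagonistic"
    flags[test] = flat
    pmat = np.ones((na, nb))
    pmat[test] = padj
    smap.flags = flags
    smap.p_adjusted = pmat
    return smap


def read_well_table(path) -> DoseGrid:
    """Read a long-format plate table (dose_a, dose_b, replicate, signal)."""
    df = pd.read_csv(path)
    da = np.sort(df["dose_a"].unique())
    db = np.sort(df["dose_b"].unique())
    nrep = int(df.groupby(["dose_a", "dose_b"]).size().max())
    signal = np.full((da.size, db.size, nrep), np.nan)
    for (a, b), sub in df.groupby(["dose_a", "dose_b"]):
        i = np.searchsorted(da, a)
        j = np.searchsorted(db, b)
        vals = sub["signal"].to_numpy()
        signal[i, j, : vals.size] = vals
    if np.isnan(signal).any():
        raise ValueError("well table is not a complete replicated grid")
    return DoseGrid(doses_a=da, doses_b=db, signal=signal)
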