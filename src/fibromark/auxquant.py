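"""Small quantification formulas used around the main analyses.

Delta-delta-ct relative expression with triple housekeeping normalization,
ChIP percent-input normalization, SRM (selected reaction monitoring)
light/heavy peptide ratios, and the Holm-Sidak step-down multiple-testing
correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HOUSEKEEPING",
    "ddct_expression",
    "chip_relative_signal",
    "srm_ratio",
    "holm_sidak",
]

HOUSEKEEPING = ("ACTB", "GAPDH", "HPRT1")


def ddct_expression(
    table: pd.DataFrame,
    housekeeping: tuple = HOUSEKEEPING,
    mode: str = "arithmetic",
) -> pd.DataFrame:
    """Relative expression 2^-ddct per target gene and sample.

    For each housekeeping gene h:
    ddct = (ct_target - ct_h)_treatment - (ct_target - ct_h)_control and the
    per-housekeeper relative expressions 2^-ddct are averaged (arithmetic
    mean by default, ``mode='geometric'`` optional). Missing housekeeper
    measurements are skipped with a warning; a target with no usable
    housekeeper is an error.

    ``table`` is long-format with columns sample, gene, condition
    (treatment/control), ct.
    """
    required = {"sample", "gene", "condition", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    ct = table.set_index(["sample", "gene", "condition"])["ct"]
    targets = [g for g in table["gene"].unique() if g not in housekeeping]
    rows = []
    for sample in table["sample"].unique():
        for gene in targets:
            values = []
            for hk in housekeeping:
                try:
                    ddct = (
                        ct.loc[(sample, gene, "treatment")]
                        - ct.loc[(sample, hk, "treatment")]
                    ) - (
                        ct.loc[(sample, gene, "control")] - ct.loc[(sample, hk, "control")]
                    )
                except KeyError:
                    warnings.warn(
                        f"missing ct for housekeeper {hk!r} in sample {sample!r}; skipped",
                        stacklevel=2,
                    )
                    continue
                values.append(2.0 ** (-ddct))
            if not values:
                raise ValueError(
                    f"no housekeeping measurements available for {gene!r}/{sample!r}"
                )
            if mode == "arithmetic":
                expr = float(np.mean(values))
            elif mode == "geometric":
                expr = float(np.exp(np.mean(np.log(values))))
            else:
                raise ValueError("mode must be 'arithmetic' or 'geometric'")
            rows.append({"sample": sample, "gene": gene, "relative_expression": expr})
    return pd.DataFrame(rows)


def chip_relative_signal(
    ip_quantity: float, input_quantity: float, dilution_factor: float = 1.0
) -> float:
    """ChIP signal normalized to the non-immunoprecipitated input control.

    With ``dilution_factor`` set to the input dilution (e.g. 100 for a 1%
    input), the result is percent input.
    """
    if input_quantity <= 0:
        raise ValueError("input quantity must be positive")
    return float(ip_quantity / input_quantity * dilution_factor)


def srm_ratio(
    light_areas,
    heavy_areas,
    light_background=0.0,
    heavy_background=0.0,
) -> float:
    """Light/heavy transition ratio with per-transition background reduction.

    Background-reduced areas are floored at zero, summed over transitions,
    and the ratio of the light to the heavy sum is returned. A zero heavy
    sum yields NaN with a warning.
    """
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    if light.size != heavy.size:
        raise ValueError("light and heavy transition counts must match")
    if np.any(light < 0) or np.any(heavy < 0):
        raise ValueError("peak areas must be non-negative")
    lb = np.broadcast_to(np.asarray(light_background, dtype=float), light.shape)
    hb = np.broadcast_to(np.asarray(heavy_background, dtype=float), heavy.shape)
    num = np.maximum(light - lb, 0.0).sum()
    den = np.maximum(heavy - hb, 0.0).sum()
    if den <= 0:
        warnings.warn("background-reduced heavy signal is zero; ratio undefined",
                      stacklevel=2)
        return float("nan")
    return float(num / den)


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]
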