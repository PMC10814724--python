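"""Derived echo quantities: body-surface area, weight-adjusted diameters
and the two wall-thickness definitions.

BSA uses Meeh's allometric formula BSA = k * W^(2/3) with the rodent
constant k = 9.8 cm^2 g^(-2/3) by default; its square root (cm) is the
body-size regressor of the normative model.  Weight adjustment is
(diameter / body weight) * 100, carrying pseudo-units mm g^-1 * 100 so
adjusted values are never mixed with raw mm.  Wall thickness exists in two
distinct named forms — the caliper difference (outer - inner) and the mean
of the upper and lower wall — and the two are never substituted for one
another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LENGTH_MEASUREMENTS, VESSEL_PAIRS

#: Default Meeh constant for mice, cm^2 per g^(2/3).
MEEH_K: float = 9.8

#: Derived columns appended by :func:`derive_table`, in order.
DERIVED_COLUMNS: tuple[str, ...] = (
    "bsa_cm2",
    "sqrt_bsa_cm",
    *[f"{m}_wadj" for m in LENGTH_MEASUREMENTS],
    "carotid_wall_mean_mm",
    "carotid_wall_mean_wadj",
    "carotid_wall_diff_mm",
    "aorta_wall_mean_mm",
    "aorta_wall_mean_wadj",
)


def bsa_from_weight(body_weight_g, meeh_k: float = MEEH_K):
    """Body-surface area (cm^2) from body weight (g), Meeh's formula.

    BSA = k * W^(2/3); monotone increasing in W, and doubling the weight
    multiplies BSA by exactly 2^(2/3).
    """
    w = np.asarray(body_weight_g, dtype=float)
    if np.any(w[~np.isnan(w)] < 0):
        raise ValueError("body_weight_g must be >= 0")
    out = meeh_k * np.power(w, 2.0 / 3.0)
    return float(out) if np.isscalar(body_weight_g) else out


def weight_adjust(diameter_mm, body_weight_g):
    """Weight-adjusted diameter: (diameter / weight) * 100.

    Pseudo-units mm g^-1 * 100; linear in the diameter and inversely
    proportional to the weight.
    """
    w = np.asarray(body_weight_g, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0):
        raise ValueError("body_weight_g must be > 0")
    out = np.asarray(diameter_mm, dtype=float) / w * 100.0
    scalar = np.isscalar(diameter_mm) and np.isscalar(body_weight_g)
    return float(out) if scalar else out


def wall_mean(upper_mm, lower_mm):
    """Mean wall thickness (upper + lower) / 2, mm; symmetric in arguments."""
    u = np.asarray(upper_mm, dtype=float)
    l = np.asarray(lower_mm, dtype=float)
    if np.any(u[~np.isnan(u)] < 0) or np.any(l[~np.isnan(l)] < 0):
        raise ValueError("wall thicknesses must be >= 0")
    out = (u + l) / 2.0
    scalar = np.isscalar(upper_mm) and np.isscalar(lower_mm)
    return float(out) if scalar else out


def wall_diff(outer_mm, inner_mm):
    """Caliper wall thickness: outer diameter minus inner diameter, mm."""
    o = np.asarray(outer_mm, dtype=float)
    i = np.asarray(inner_mm, dtype=float)
    both = ~(np.isnan(o) | np.isnan(i))
    if np.any(o[both] < i[both] - 1e-9):
        raise ValueError(
            "outer diameter smaller than inner diameter: inconsistent calipers"
        )
    out = o - i
    scalar = np.isscalar(outer_mm) and np.isscalar(inner_mm)
    return float(out) if scalar else out


def derive_table(df: pd.DataFrame, meeh_k: float = MEEH_K) -> pd.DataFrame:
    """Append all derived columns to a cohort table.

    Adds ``bsa_cm2``, ``sqrt_bsa_cm``, one ``<measurement>_wadj`` column
    per length measurement, and the carotid/aortic wall summaries.
    """
    out = df.copy()
    out["bsa_cm2"] = bsa_from_weight(out["body_weight_g"].to_numpy(), meeh_k)
    out["sqrt_bsa_cm"] = np.sqrt(out["bsa_cm2"].to_numpy())
    weights = out["body_weight_g"].to_numpy()
    for m in LENGTH_MEASUREMENTS:
        out[f"{m}_wadj"] = weight_adjust(out[m].to_numpy(), weights)
    out["carotid_wall_mean_mm"] = wall_mean(
        out["carotid_upper_wall_mm"].to_numpy(),
        out["carotid_lower_wall_mm"].to_numpy(),
    )
    out["carotid_wall_mean_wadj"] = weight_adjust(
        out["carotid_wall_mean_mm"].to_numpy(), weights
    )
    inner, outer = VESSEL_PAIRS["carotid"]
    out["carotid_wall_diff_mm"] = wall_diff(
        out[outer].to_numpy(), out[inner].to_numpy()
    )
    out["aorta_wall_mean_mm"] = wall_mean(
        out["aorta_upper_wall_mm"].to_numpy(),
        out["aorta_lower_wall_mm"].to_numpy(),
    )
    out["aorta_wall_mean_wadj"] = weight_adjust(
        out["aorta_wall_mean_mm"].to_numpy(), weights
    )
    return out
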