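"""Seeded synthetic longitudinal echo cohorts.

The generator emulates the study design the analysis assumes: dose groups
followed over fixed days, a day-0 normative baseline, dose- and
time-dependent coronary dilation and wall thickening expressed in
normative-SD units, Gaussian measurement noise, and a latent per-animal
severity factor that couples the carotid vessel to the coronary inner
diameter in treated animals.

Construction guarantees the structural record invariants: outer diameters
are built as inner + a non-negative annulus gap whose mean and SD are
derived from the configured norms, so at day 0 (and in controls) both the
inner and outer marginals match the configured normative mean/SD while
outer >= inner always holds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    COUPLED_PRIMITIVES,
    GeneratorConfig,
    MEASUREMENTS,
    VESSEL_PAIRS,
)
from .records import COHORT_COLUMNS, validate_cohort

# Fixed draw order of the random primitives; part of the determinism
# contract (same config + seed => byte-identical cohort).
_SCALAR_PRIMITIVES: tuple[str, ...] = (
    "ejection_fraction_pct",
    "carotid_upper_wall_mm",
    "carotid_lower_wall_mm",
    "aorta_upper_wall_mm",
    "aorta_lower_wall_mm",
    "coronary_inner_d_mm",
    "carotid_inner_d_mm",
    "aorta_inner_d_mm",
)
_GAP_ORDER: tuple[str, ...] = ("coronary", "carotid", "aorta")

_MIN_LENGTH = 1e-6  # mm; guards the >0 invariant in degenerate tails


def _sqrt_bsa(weight_g: np.ndarray, meeh_k: float) -> np.ndarray:
    return np.sqrt(meeh_k * np.power(weight_g, 2.0 / 3.0))


def _cells(groups: np.ndarray, days: np.ndarray) -> dict[tuple[str, int], np.ndarray]:
    """Record indices per (group, day) cell."""
    out: dict[tuple[str, int], np.ndarray] = {}
    frame = pd.DataFrame({"g": groups, "d": days})
    for (g, d), sub in frame.groupby(["g", "d"], sort=False):
        out[(str(g), int(d))] = sub.index.to_numpy()
    return out


def _per_record(cfg: GeneratorConfig, cells, n: int, measurement: str):
    """Per-record effect shift (native units) and noise SD for one measurement."""
    norm = cfg.norms[measurement]
    shift = np.zeros(n)
    noise = np.empty(n)
    for (g, d), idx in cells.items():
        shift[idx] = cfg.effect(g, d, measurement) * norm.sd
        noise[idx] = cfg.noise_sd(g, d, measurement)
    return shift, noise


def _mix(rng, rho: float, severity: np.ndarray, affected: np.ndarray) -> np.ndarray:
    """Unit-variance noise, severity-loaded on affected records."""
    eps = rng.standard_normal(severity.shape[0])
    if rho == 0.0 or not affected.any():
        return eps
    out = eps.copy()
    out[affected] = rho * severity[affected] + np.sqrt(1.0 - rho**2) * eps[affected]
    return out


def _draw_measurements(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    groups: np.ndarray,
    days: np.ndarray,
    sqrt_bsa_c: np.ndarray,
    severity: np.ndarray,
) -> dict[str, np.ndarray]:
    """Draw all raw measurements for a prepared record table.

    ``sqrt_bsa_c`` is sqrt(BSA) centred at the reference weight, so a zero
    slope leaves the configured normative mean untouched.
    """
    n = len(groups)
    cells = _cells(groups, days)
    affected = (groups != cfg.control_group) & (days > 0)
    rho = cfg.severity_rho
    values: dict[str, np.ndarray] = {}

    for m in _SCALAR_PRIMITIVES:
        norm = cfg.norms[m]
        shift, noise = _per_record(cfg, cells, n, m)
        slope = cfg.slope_per_sqrt_bsa.get(m, 0.0)
        mu = norm.mean + slope * sqrt_bsa_c + shift
        z = _mix(rng, rho if m in COUPLED_PRIMITIVES else 0.0, severity, affected)
        values[m] = mu + noise * z

    for vessel in _GAP_ORDER:
        inner, outer = VESSEL_PAIRS[vessel]
        shift_i, noise_i = _per_record(cfg, cells, n, inner)
        shift_o, noise_o = _per_record(cfg, cells, n, outer)
        slope_i = cfg.slope_per_sqrt_bsa.get(inner, 0.0)
        slope_o = cfg.slope_per_sqrt_bsa.get(outer, 0.0)
        mu_gap = (
            (cfg.norms[outer].mean - cfg.norms[inner].mean)
            + (slope_o - slope_i) * sqrt_bsa_c
            + shift_o
            - shift_i
        )
        sd_gap = np.sqrt(np.maximum(noise_o**2 - noise_i**2, 0.0))
        coupled = f"{vessel}_gap" in COUPLED_PRIMITIVES
        z = _mix(rng, rho if coupled else 0.0, severity, affected)
        gap = np.maximum(mu_gap + sd_gap * z, 0.0)
        values[outer] = values[inner] + gap

    for m in MEASUREMENTS[:-1]:
        values[m] = np.maximum(values[m], _MIN_LENGTH)
    values["ejection_fraction_pct"] = np.clip(
        values["ejection_fraction_pct"], 0.5, 100.0
    )
    return values


def _assemble(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    animal_ids: list[str],
    animal_groups: list[str],
    days: tuple[int, ...],
) -> pd.DataFrame:
    n_animals = len(animal_ids)
    n_days = len(days)
    w = cfg.weight
    w0 = w.baseline_mean_g + w.baseline_sd_g * rng.standard_normal(n_animals)
    severity_a = rng.standard_normal(n_animals)

    rec_animal = np.repeat(np.arange(n_animals), n_days)
    rec_day = np.tile(np.asarray(days, dtype=np.int64), n_animals)
    rec_group = np.asarray(animal_groups, dtype=object)[rec_animal]
    n = n_animals * n_days

    weight = (
        w0[rec_animal]
        + w.growth_g_per_day * rec_day
        + w.day_noise_sd_g * rng.standard_normal(n)
    )
    weight = np.maximum(weight, 1.0)
    sqrt_bsa_ref = float(_sqrt_bsa(np.asarray(w.baseline_mean_g), cfg.meeh_k))
    sqrt_bsa_c = _sqrt_bsa(weight, cfg.meeh_k) - sqrt_bsa_ref

    values = _draw_measurements(
        cfg, rng, rec_group, rec_day, sqrt_bsa_c, severity_a[rec_animal]
    )

    for m in MEASUREMENTS:
        p = cfg.missingness.get(m, 0.0)
        if p > 0.0:
            mask = rng.random(n) < p
            values[m] = np.where(mask, np.nan, values[m])

    df = pd.DataFrame(
        {
            "animal_id": np.asarray(animal_ids, dtype=object)[rec_animal],
            "group": rec_group,
            "day": rec_day,
            "body_weight_g": weight,
            **{m: values[m] for m in MEASUREMENTS},
        },
        columns=list(COHORT_COLUMNS),
    )
    validate_cohort(df)
    return df


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the full longitudinal cohort: one row per animal x day.

    Animals are followed across all configured days; the control group at
    every day, and every group at day 0, are draws from the pure normative
    distribution.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(cfg.n_per_group_per_day)))
    animal_ids: list[str] = []
    animal_groups: list[str] = []
    for g in cfg.groups:
        for i in range(cfg.n_per_group_per_day):
            animal_ids.append(f"{g}_{i + 1:0{width}d}")
            animal_groups.append(g)
    return _assemble(cfg, rng, animal_ids, animal_groups, tuple(cfg.days))


def generate_baseline(
    cfg: GeneratorConfig, n: int | None = None, group_label: str = "baseline"
) -> pd.DataFrame:
    """Generate a stand-alone day-0 normative cohort of ``n`` animals.

    All animals are untreated, so every measurement is a pure normative
    draw.  If ``cfg.baseline_ns`` caps a measurement at ``n_m < n``, only
    the first ``n_m`` animals carry that measurement (the rest are
    missing), emulating a baseline in which not every vessel was
    measurable on every animal.
    """
    cfg.validate()
    n = cfg.n_baseline if n is None else int(n)
    if n < 2:
        raise ValueError("baseline size must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(n)))
    ids = [f"{group_label}_{i + 1:0{width}d}" for i in range(n)]
    df = _assemble(cfg, rng, ids, [group_label] * n, (0,))
    if cfg.baseline_ns:
        for m, n_m in cfg.baseline_ns.items():
            df.loc[n_m:, m] = np.nan
    return df
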