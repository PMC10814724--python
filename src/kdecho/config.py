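"""Configuration of the synthetic echo cohort generator.

The generator emulates a longitudinal echocardiography study in a mouse
model of Kawasaki disease: dose groups (control / low / medium / high)
followed at fixed study days, with a day-0 normative cohort whose coronary
measurements match the published reference ranges.  All distributional
knobs — norms, effect sizes, noise, growth, the latent-severity coupling —
live here so that every downstream stage can be tested against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a generator configuration violates an invariant.

    The message always names the offending field.
    """


#: Canonical measurement column names, in CSV column order.
MEASUREMENTS: tuple[str, ...] = (
    "coronary_inner_d_mm",
    "coronary_outer_d_mm",
    "carotid_inner_d_mm",
    "carotid_outer_d_mm",
    "carotid_upper_wall_mm",
    "carotid_lower_wall_mm",
    "aorta_inner_d_mm",
    "aorta_outer_d_mm",
    "aorta_upper_wall_mm",
    "aorta_lower_wall_mm",
    "ejection_fraction_pct",
)

#: Length-valued measurements (everything except ejection fraction).
LENGTH_MEASUREMENTS: tuple[str, ...] = MEASUREMENTS[:-1]

#: Inner/outer diameter pairs; the generator draws the inner diameter and a
#: non-negative annulus gap, then sets outer = inner + gap, so the
#: outer >= inner record invariant holds by construction.
VESSEL_PAIRS: dict[str, tuple[str, str]] = {
    "coronary": ("coronary_inner_d_mm", "coronary_outer_d_mm"),
    "carotid": ("carotid_inner_d_mm", "carotid_outer_d_mm"),
    "aorta": ("aorta_inner_d_mm", "aorta_outer_d_mm"),
}

#: Measurement components sharing the latent per-animal severity factor in
#: treated groups after day 0.  Loading the whole carotid vessel (inner and
#: annulus) keeps the carotid-outer <-> coronary-inner association strong
#: while preserving outer >= inner.
COUPLED_PRIMITIVES: frozenset[str] = frozenset(
    {
        "coronary_inner_d_mm",
        "carotid_upper_wall_mm",
        "carotid_lower_wall_mm",
        "carotid_inner_d_mm",
        "carotid_gap",
    }
)


@dataclass(frozen=True)
class Norm:
    """Day-0 normative mean and SD of one measurement, in native units."""

    mean: float
    sd: float


# Coronary norms are the published day-0 reference ranges of the mouse
# model; the remaining vessels and ejection fraction are plausible defaults
# for ~20 g C57BL/6 mice (these are free parameters of the simulation).
DEFAULT_NORMS: dict[str, Norm] = {
    "coronary_inner_d_mm": Norm(0.217, 0.028),
    "coronary_outer_d_mm": Norm(0.472, 0.056),
    "carotid_inner_d_mm": Norm(0.45, 0.04),
    "carotid_outer_d_mm": Norm(0.60, 0.05),
    "carotid_upper_wall_mm": Norm(0.075, 0.010),
    "carotid_lower_wall_mm": Norm(0.075, 0.010),
    "aorta_inner_d_mm": Norm(1.05, 0.09),
    "aorta_outer_d_mm": Norm(1.20, 0.10),
    "aorta_upper_wall_mm": Norm(0.075, 0.010),
    "aorta_lower_wall_mm": Norm(0.075, 0.010),
    "ejection_fraction_pct": Norm(65.0, 5.0),
}

#: Nominal dose (mg/kg) per group.  Labels only: group effects are set
#: explicitly below, never computed from the dose value.
DEFAULT_GROUPS: dict[str, float] = {
    "control": 0.0,
    "low": 1.0,
    "medium": 2.0,
    "high": 4.0,
}

# Additive mean shifts in units of each measurement's normative SD, per
# (group, day, measurement).  Coronary dilation rises with dose and time
# (high reaches +5 SD by day 21, medium +3 SD, low +1.5 SD); carotid and
# aortic walls thicken early; ejection fraction dips in the high-dose group
# at day 21.  Control is identically zero, and anything not listed is zero.
DEFAULT_EFFECTS: dict[str, dict[int, dict[str, float]]] = {
    "control": {},
    "low": {
        7: {
            "coronary_inner_d_mm": 0.5,
            "carotid_upper_wall_mm": 0.5,
            "carotid_lower_wall_mm": 0.5,
            "carotid_outer_d_mm": 0.25,
            "aorta_upper_wall_mm": 0.4,
            "aorta_lower_wall_mm": 0.4,
        },
        14: {
            "coronary_inner_d_mm": 1.0,
            "carotid_upper_wall_mm": 0.75,
            "carotid_lower_wall_mm": 0.75,
            "carotid_outer_d_mm": 0.5,
            "aorta_upper_wall_mm": 0.4,
            "aorta_lower_wall_mm": 0.4,
        },
        21: {
            "coronary_inner_d_mm": 1.5,
            "carotid_upper_wall_mm": 1.0,
            "carotid_lower_wall_mm": 1.0,
            "carotid_outer_d_mm": 0.75,
            "aorta_upper_wall_mm": 0.4,
            "aorta_lower_wall_mm": 0.4,
        },
        28: {
            "coronary_inner_d_mm": 1.5,
            "carotid_upper_wall_mm": 1.0,
            "carotid_lower_wall_mm": 1.0,
            "carotid_outer_d_mm": 0.75,
            "aorta_upper_wall_mm": 0.5,
            "aorta_lower_wall_mm": 0.5,
            "aorta_outer_d_mm": 0.4,
        },
    },
    "medium": {
        7: {
            "coronary_inner_d_mm": 1.0,
            "carotid_upper_wall_mm": 1.0,
            "carotid_lower_wall_mm": 1.0,
            "carotid_outer_d_mm": 0.5,
            "aorta_upper_wall_mm": 0.75,
            "aorta_lower_wall_mm": 0.75,
        },
        14: {
            "coronary_inner_d_mm": 2.0,
            "carotid_upper_wall_mm": 1.25,
            "carotid_lower_wall_mm": 1.25,
            "carotid_outer_d_mm": 1.0,
            "aorta_upper_wall_mm": 0.75,
            "aorta_lower_wall_mm": 0.75,
        },
        21: {
            "coronary_inner_d_mm": 3.0,
            "carotid_upper_wall_mm": 1.5,
            "carotid_lower_wall_mm": 1.5,
            "carotid_outer_d_mm": 1.25,
            "aorta_upper_wall_mm": 0.75,
            "aorta_lower_wall_mm": 0.75,
        },
        28: {
            "coronary_inner_d_mm": 3.0,
            "carotid_upper_wall_mm": 1.5,
            "carotid_lower_wall_mm": 1.5,
            "carotid_outer_d_mm": 1.5,
            "aorta_upper_wall_mm": 1.0,
            "aorta_lower_wall_mm": 1.0,
            "aorta_outer_d_mm": 0.75,
        },
    },
    "high": {
        7: {
            "coronary_inner_d_mm": 2.0,
            "carotid_upper_wall_mm": 2.0,
            "carotid_lower_wall_mm": 2.0,
            "carotid_outer_d_mm": 1.0,
            "aorta_upper_wall_mm": 1.5,
            "aorta_lower_wall_mm": 1.5,
        },
        14: {
            "coronary_inner_d_mm": 3.5,
            "carotid_upper_wall_mm": 2.5,
            "carotid_lower_wall_mm": 2.5,
            "carotid_outer_d_mm": 2.0,
            "aorta_upper_wall_mm": 1.5,
            "aorta_lower_wall_mm": 1.5,
        },
        21: {
            "coronary_inner_d_mm": 5.0,
            "carotid_upper_wall_mm": 3.0,
            "carotid_lower_wall_mm": 3.0,
            "carotid_outer_d_mm": 2.5,
            "aorta_upper_wall_mm": 1.5,
            "aorta_lower_wall_mm": 1.5,
            "ejection_fraction_pct": -1.5,
        },
        28: {
            "coronary_inner_d_mm": 5.0,
            "carotid_upper_wall_mm": 3.0,
            "carotid_lower_wall_mm": 3.0,
            "carotid_outer_d_mm": 3.0,
            "aorta_upper_wall_mm": 2.0,
            "aorta_lower_wall_mm": 2.0,
            "aorta_outer_d_mm": 1.5,
        },
    },
}

#: Absolute post-baseline measurement noise SD (mm) overriding the
#: normative-SD scaling, per group and measurement.  The dilated coronary
#: in the medium/high groups is measured with SD 0.04 mm.
DEFAULT_NOISE_ABS_SD: dict[str, dict[str, float]] = {
    "high": {"coronary_inner_d_mm": 0.04},
    "medium": {"coronary_inner_d_mm": 0.04},
}

#: Per-measurement day-0 sample sizes emulating a baseline cohort in which
#: not every vessel was measurable on every animal (18 of 38 contribute the
#: coronary inner diameter, 37 the outer).
STUDY_BASELINE_NS: dict[str, int] = {
    "coronary_inner_d_mm": 18,
    "coronary_outer_d_mm": 37,
}


@dataclass(frozen=True)
class WeightModel:
    """Body-weight model: Normal baseline plus linear growth with noise."""

    baseline_mean_g: float = 20.0
    baseline_sd_g: float = 1.5
    growth_g_per_day: float = 0.15
    day_noise_sd_g: float = 0.2


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic longitudinal echo cohort.

    Parameters
    ----------
    seed
        Seed of the single pseudo-random stream; identical configs with
        identical seeds regenerate byte-identical cohorts.
    n_per_group_per_day
        Animals followed per dose group (each is measured at every day).
    n_baseline
        Size of the stand-alone day-0 normative cohort.
    days
        Study days, strictly increasing, day 0 = pre-treatment baseline.
    groups
        Ordered mapping of group label to nominal dose in mg/kg.
    effects
        ``{group: {day: {measurement: shift}}}`` additive mean shifts in
        units of the measurement's normative SD.  Missing entries are 0;
        the control group must be identically 0.
    slope_per_sqrt_bsa
        Optional per-measurement slope of the normative mean on
        sqrt(BSA) (native units per cm), centred at the reference weight.
        Zero (the default) yields the degenerate mean/SD model.
    noise_sd_scale
        Multiplier on the normative SD for post-baseline noise.
    noise_abs_sd
        ``{group: {measurement: sd}}`` absolute noise SD overrides applied
        after day 0.
    severity_rho
        Loading of the latent per-animal severity factor shared by the
        coronary inner diameter and the carotid vessel in treated groups
        after day 0.
    missingness
        ``{measurement: probability}`` of a value being missing.
    baseline_ns
        Optional ``{measurement: n}`` day-0 sample-size caps for the
        baseline cohort (remaining animals get a missing value).
    meeh_k
        Meeh constant of the allometric BSA formula, cm^2 per g^(2/3).
    """

    seed: int = 0
    n_per_group_per_day: int = 9
    n_baseline: int = 38
    days: tuple[int, ...] = (0, 7, 14, 21, 28)
    groups: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    control_group: str = "control"
    weight: WeightModel = field(default_factory=WeightModel)
    norms: dict[str, Norm] = field(default_factory=lambda: dict(DEFAULT_NORMS))
    slope_per_sqrt_bsa: dict[str, float] = field(default_factory=dict)
    effects: dict[str, dict[int, dict[str, float]]] = field(
        default_factory=lambda: {
            g: {int(d): dict(m) for d, m in days.items()}
            for g, days in DEFAULT_EFFECTS.items()
        }
    )
    noise_sd_scale: float = 1.0
    noise_abs_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_NOISE_ABS_SD.items()}
    )
    severity_rho: float = 0.6
    missingness: dict[str, float] = field(default_factory=dict)
    baseline_ns: dict[str, int] | None = None
    meeh_k: float = 9.8

    # -- accessors -------------------------------------------------------

    def effect(self, group: str, day: int, measurement: str) -> float:
        """Mean shift (normative-SD units) for a (group, day, measurement)."""
        return float(self.effects.get(group, {}).get(day, {}).get(measurement, 0.0))

    def noise_sd(self, group: str, day: int, measurement: str) -> float:
        """Measurement noise SD in native units for one cohort cell."""
        if day > 0:
            override = self.noise_abs_sd.get(group, {}).get(measurement)
            if override is not None:
                return float(override)
            return self.noise_sd_scale * self.norms[measurement].sd
        return self.norms[measurement].sd

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first invalid field."""
        if not isinstance(self.seed, int):
            raise ConfigError("seed: must be an integer")
        if self.n_per_group_per_day < 1:
            raise ConfigError("n_per_group_per_day: must be >= 1")
        if self.n_baseline < 2:
            raise ConfigError("n_baseline: must be >= 2")
        days = tuple(self.days)
        if not days:
            raise ConfigError("days: must be non-empty")
        if any(int(d) != d or d < 0 for d in days):
            raise ConfigError("days: must be non-negative integers")
        if list(days) != sorted(set(days)):
            raise ConfigError("days: must be strictly ascending and unique")
        if not self.groups:
            raise ConfigError("groups: must be non-empty")
        for m in MEASUREMENTS:
            if m not in self.norms:
                raise ConfigError(f"norms.{m}: missing")
            norm = self.norms[m]
            # sd == 0 is the degenerate zero-noise limit; model fitting
            # still requires positive spread.
            if not norm.sd >= 0:
                raise ConfigError(f"norms.{m}.sd: must be >= 0")
            if not norm.mean > 0:
                raise ConfigError(f"norms.{m}.mean: must be > 0")
        for extra in set(self.norms) - set(MEASUREMENTS):
            raise ConfigError(f"norms.{extra}: unknown measurement")
        for vessel, (inner, outer) in VESSEL_PAIRS.items():
            if not self.norms[outer].mean > self.norms[inner].mean:
                raise ConfigError(
                    f"norms.{outer}.mean: must exceed norms.{inner}.mean"
                )
            if not self.norms[outer].sd >= self.norms[inner].sd:
                raise ConfigError(
                    f"norms.{outer}.sd: must be >= norms.{inner}.sd "
                    f"(the {vessel} annulus gap needs non-negative variance)"
                )
        for m, s in self.slope_per_sqrt_bsa.items():
            if m not in MEASUREMENTS:
                raise ConfigError(f"slope_per_sqrt_bsa.{m}: unknown measurement")
        if not self.noise_sd_scale >= 0:
            raise ConfigError("noise_sd_scale: must be >= 0")
        for g, table in self.noise_abs_sd.items():
            for m, sd in table.items():
                if m not in MEASUREMENTS:
                    raise ConfigError(f"noise_abs_sd.{g}.{m}: unknown measurement")
                if not sd > 0:
                    raise ConfigError(f"noise_abs_sd.{g}.{m}: must be > 0")
        if not 0.0 <= self.severity_rho < 1.0:
            raise ConfigError("severity_rho: must be in [0, 1)")
        for g, by_day in self.effects.items():
            for d, table in by_day.items():
                for m, shift in table.items():
                    if m not in MEASUREMENTS:
                        raise ConfigError(f"effects.{g}.{d}.{m}: unknown measurement")
                    if g == self.control_group and shift != 0.0:
                        raise ConfigError(
                            f"effects.{self.control_group}.{d}.{m}: control effects "
                            "must be identically 0"
                        )
        for m, p in self.missingness.items():
            if m not in MEASUREMENTS:
                raise ConfigError(f"missingness.{m}: unknown measurement")
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"missingness.{m}: must be in [0, 1)")
        if self.baseline_ns is not None:
            for m, n in self.baseline_ns.items():
                if m not in MEASUREMENTS:
                    raise ConfigError(f"baseline_ns.{m}: unknown measurement")
                if not 2 <= n <= self.n_baseline:
                    raise ConfigError(
                        f"baseline_ns.{m}: must be between 2 and n_baseline"
                    )
        w = self.weight
        if not w.baseline_mean_g > 0:
            raise ConfigError("weight.baseline_mean_g: must be > 0")
        if not w.baseline_sd_g >= 0:
            raise ConfigError("weight.baseline_sd_g: must be >= 0")
        if not w.growth_g_per_day >= 0:
            raise ConfigError("weight.growth_g_per_day: must be >= 0")
        if not w.day_noise_sd_g >= 0:
            raise ConfigError("weight.day_noise_sd_g: must be >= 0")
        if not self.meeh_k > 0:
            raise ConfigError("meeh_k: must be > 0")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n_per_group_per_day": self.n_per_group_per_day,
            "n_baseline": self.n_baseline,
            "days": list(self.days),
            "groups": dict(self.groups),
            "control_group": self.control_group,
            "weight": {
                "baseline_mean_g": self.weight.baseline_mean_g,
                "baseline_sd_g": self.weight.baseline_sd_g,
                "growth_g_per_day": self.weight.growth_g_per_day,
                "day_noise_sd_g": self.weight.day_noise_sd_g,
            },
            "norms": {m: {"mean": n.mean, "sd": n.sd} for m, n in self.norms.items()},
            "slope_per_sqrt_bsa": dict(self.slope_per_sqrt_bsa),
            "effects": {
                g: {int(d): dict(t) for d, t in by_day.items()}
                for g, by_day in self.effects.items()
            },
            "noise_sd_scale": self.noise_sd_scale,
            "noise_abs_sd": {g: dict(t) for g, t in self.noise_abs_sd.items()},
            "severity_rho": self.severity_rho,
            "missingness": dict(self.missingness),
            "baseline_ns": dict(self.baseline_ns) if self.baseline_ns else None,
            "meeh_k": self.meeh_k,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        known = {
            "seed", "n_per_group_per_day", "n_baseline", "days", "groups",
            "control_group", "weight", "norms", "slope_per_sqrt_bsa", "effects",
            "noise_sd_scale", "noise_abs_sd", "severity_rho", "missingness",
            "baseline_ns", "meeh_k",
        }
        for key in data:
            if key not in known:
                raise ConfigError(f"{key}: unknown configuration field")
        kwargs: dict[str, Any] = {}
        for key in known & set(data):
            kwargs[key] = data[key]
        if "days" in kwargs:
            kwargs["days"] = tuple(int(d) for d in kwargs["days"])
        if "weight" in kwargs and isinstance(kwargs["weight"], Mapping):
            kwargs["weight"] = WeightModel(**dict(kwargs["weight"]))
        if "norms" in kwargs:
            norms = dict(DEFAULT_NORMS)
            for m, entry in dict(kwargs["norms"]).items():
                if isinstance(entry, Norm):
                    norms[m] = entry
                else:
                    try:
                        norms[m] = Norm(float(entry["mean"]), float(entry["sd"]))
                    except (KeyError, TypeError) as exc:
                        raise ConfigError(
                            f"norms.{m}: expected mapping with mean and sd"
                        ) from exc
            kwargs["norms"] = norms
        if "effects" in kwargs:
            kwargs["effects"] = {
                g: {int(d): {m: float(v) for m, v in t.items()}
                    for d, t in by_day.items()}
                for g, by_day in dict(kwargs["effects"]).items()
            }
        if kwargs.get("baseline_ns") is not None:
            kwargs["baseline_ns"] = {
                m: int(n) for m, n in dict(kwargs["baseline_ns"]).items()
            }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file: top level must be a mapping")
        # allow a pipeline-style file with a `generator:` block
        if "generator" in data and isinstance(data["generator"], Mapping):
            data = data["generator"]
        return cls.from_dict(data)


def default_config(seed: int = 0, **overrides: Any) -> GeneratorConfig:
    """The study-design default configuration with a given seed."""
    cfg = replace(GeneratorConfig(seed=int(seed)), **overrides)
    cfg.validate()
    return cfg
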