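"""Day-0 normative model, Z-scores and coronary-artery-lesion classification.

The reference model predicts a vessel measurement from the square root of
body-surface area using ordinary least squares on the day-0 (pre-treatment)
cohort; the Z-score of a later observation is its residual from that
prediction in units of the residual SD, and a lesion (CAL) is flagged when
Z strictly exceeds the cutoff (3.0 by default).  A degenerate ``mean_sd``
mode — sample mean and SD without the body-size term — is provided for
designs where the baseline carries no usable size spread.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_CUTOFF = 3.0


class FitError(ValueError):
    """Raised when a normative model cannot be fitted from the baseline."""


@dataclass(frozen=True)
class NormativeModel:
    """Fitted day-0 reference model for one measurement.

    ``predicted = intercept + slope * sqrt_bsa`` (slope is 0 in ``mean_sd``
    mode, where the intercept is the sample mean), and ``residual_sd`` is
    the scale of the Z-score: sqrt(SSE/(n-2)) in regression mode, the
    (n-1)-denominator sample SD in ``mean_sd`` mode.
    """

    measurement: str
    intercept: float
    slope: float
    residual_sd: float
    n: int
    dof: int
    mode: str  # "regression" | "mean_sd"

    def predict(self, sqrt_bsa) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(sqrt_bsa, dtype=float)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class ZScoreResult:
    """Z-score of one observation against a normative model.

    ``z = (observed - predicted) / residual_sd``; ``cal_flag`` is a strict
    ``z > cutoff`` comparison and is None when the observation is missing.
    """

    animal_id: Optional[str]
    day: Optional[int]
    measurement: str
    observed: Optional[float]
    predicted: Optional[float]
    z: Optional[float]
    cal_flag: Optional[bool]


def fit_normative(
    baseline: pd.DataFrame, measurement: str, mode: str = "regression"
) -> NormativeModel:
    """Fit the day-0 reference model for one measurement.

    ``baseline`` must contain only day-0 rows (a ``day`` column, if
    present, is checked) with the raw measurement and, in regression mode,
    the ``sqrt_bsa_cm`` column from :func:`kdecho.derive.derive_table`.
    """
    if mode not in ("regression", "mean_sd"):
        raise FitError(f"unknown mode {mode!r}")
    if "day" in baseline.columns and (baseline["day"] != 0).any():
        raise FitError("baseline must contain day-0 records only")
    if measurement not in baseline.columns:
        raise FitError(f"measurement {measurement!r} not in baseline table")

    sub = baseline.loc[baseline[measurement].notna()]
    y = sub[measurement].to_numpy(dtype=float)
    n = y.size

    if mode == "mean_sd":
        if n < 2:
            raise FitError("mean_sd mode needs >= 2 baseline values")
        sd = float(np.std(y, ddof=1))
        if sd == 0.0:
            raise FitError("zero baseline SD: cannot standardize")
        return NormativeModel(
            measurement=measurement,
            intercept=float(np.mean(y)),
            slope=0.0,
            residual_sd=sd,
            n=n,
            dof=n - 1,
            mode="mean_sd",
        )

    if n < 3:
        raise FitError("regression mode needs >= 3 baseline values")
    if "sqrt_bsa_cm" not in sub.columns:
        raise FitError("regression mode needs the sqrt_bsa_cm column "
                       "(run derive_table first)")
    x = sub["sqrt_bsa_cm"].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12 or np.std(x) == 0.0:
        raise FitError(
            "zero variance in sqrt(BSA): fall back to mode='mean_sd'"
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    residual_sd = float(np.sqrt(res.ssr / (n - 2)))
    if residual_sd == 0.0:
        raise FitError("zero residual SD: cannot standardize")
    return NormativeModel(
        measurement=measurement,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=residual_sd,
        n=n,
        dof=n - 2,
        mode="regression",
    )


def classify_cal(z: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Lesion flag: strictly ``z > cutoff`` (z == cutoff is normal)."""
    if z is None or (isinstance(z, float) and math.isnan(z)):
        raise ValueError("z must be finite")
    return bool(z > cutoff)


def z_score(
    model: NormativeModel,
    observed: Optional[float],
    sqrt_bsa: Optional[float] = None,
    cutoff: float = DEFAULT_CUTOFF,
    animal_id: Optional[str] = None,
    day: Optional[int] = None,
) -> ZScoreResult:
    """Z-score one observation; missing input yields a missing result."""
    if observed is None or (isinstance(observed, float) and math.isnan(observed)):
        return ZScoreResult(animal_id, day, model.measurement,
                            None, None, None, None)
    if model.mode == "regression" and sqrt_bsa is None:
        raise ValueError("sqrt_bsa required for a regression-mode model")
    predicted = float(model.predict(0.0 if sqrt_bsa is None else sqrt_bsa))
    z = (float(observed) - predicted) / model.residual_sd
    return ZScoreResult(
        animal_id, day, model.measurement, float(observed), predicted,
        z, classify_cal(z, cutoff),
    )


def z_values(
    model: NormativeModel, observed: np.ndarray, sqrt_bsa: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized Z-scores (NaN observations stay NaN)."""
    obs = np.asarray(observed, dtype=float)
    if model.slope != 0.0 and sqrt_bsa is None:
        raise ValueError("sqrt_bsa required for a model with nonzero slope")
    if sqrt_bsa is None:
        predicted = model.intercept
    else:
        predicted = model.predict(np.asarray(sqrt_bsa, dtype=float))
    return (obs - predicted) / model.residual_sd


def percent_above(z: Iterable[float], cutoff: float = DEFAULT_CUTOFF) -> float:
    """Percent of non-missing Z-scores strictly above the cutoff, in [0, 100]."""
    arr = np.asarray(list(z) if not isinstance(z, np.ndarray) else z, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("percent_above needs at least one non-missing z")
    return float(100.0 * np.count_nonzero(valid > cutoff) / valid.size)


def score_table(
    df: pd.DataFrame,
    models: Mapping[str, NormativeModel] | NormativeModel,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Append ``z_<measurement>`` and ``cal_<measurement>`` columns.

    ``models`` is a single model or a mapping keyed by measurement name.
    The ``cal_`` columns are nullable booleans (missing where z is missing).
    """
    if isinstance(models, NormativeModel):
        models = {models.measurement: models}
    out = df.copy()
    for measurement, model in models.items():
        sqrt_bsa = None
        if model.mode == "regression" or model.slope != 0.0:
            if "sqrt_bsa_cm" not in out.columns:
                raise ValueError("score_table needs sqrt_bsa_cm for "
                                 "regression-mode models (run derive_table)")
            sqrt_bsa = out["sqrt_bsa_cm"].to_numpy(dtype=float)
        z = z_values(model, out[measurement].to_numpy(dtype=float), sqrt_bsa)
        out[f"z_{measurement}"] = z
        cal = pd.array(z > cutoff, dtype="boolean")
        cal[np.isnan(z)] = pd.NA
        out[f"cal_{measurement}"] = cal
    return out
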