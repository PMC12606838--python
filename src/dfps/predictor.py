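"""Published fractional-polynomial predictors for demand for family planning satisfied.

Demand for family planning satisfied (DFPS) is the proportion of partnered
women 15-49 in need of contraception who use a contraceptive method -- any
method (DFPSany) or a modern method (DFPSm).  When the survey questions needed
to identify women "in need" are unavailable, DFPS can be predicted from
contraceptive prevalence (CPR) alone through a logit-scale fractional
polynomial regression:

    logit(DFPS) = b0 + b_log * ln(CPR) + b_sq * CPR**2 + b_cpdiff * cpdiff

where ``cpdiff = CPRany - CPRm`` proxies reliance on traditional methods.  All
quantities, including cpdiff, enter on the proportion (0-1) scale; the
back-transform guarantees predictions inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorCoefficients",
    "PredictionInput",
    "DFPS_ANY_COEFFS",
    "DFPS_M_COEFFS",
    "default_coefficients",
    "logit",
    "inv_logit",
    "predict_dfps",
    "predict_batch",
    "prediction_surface",
    "MIN_CPR",
    "MAX_CPR",
]

#: Prevalences below this proportion are excluded rather than extrapolated.
MIN_CPR = 0.01
#: Upper guard keeping the logit finite; larger inputs are clamped with a flag.
MAX_CPR = 0.99

_OUTCOMES = ("DFPSany", "DFPSm")


@dataclass(frozen=True)
class PredictorCoefficients:
    """Coefficients of one published DFPS predictor (logit scale).

    ``beta_log`` multiplies the natural log of the relevant CPR (CPRany for
    DFPSany, CPRm for DFPSm), ``beta_sq`` multiplies CPR squared and
    ``beta_cpdiff`` multiplies ``CPRany - CPRm`` on the proportion scale.
    """

    intercept: float
    beta_log: float
    beta_sq: float
    beta_cpdiff: float
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"outcome must be one of {_OUTCOMES}, got {self.outcome!r}")

    def linear_predictor(self, cpr: np.ndarray, cpdiff: np.ndarray) -> np.ndarray:
        cpr = np.asarray(cpr, dtype=float)
        cpdiff = np.asarray(cpdiff, dtype=float)
        return (
            self.intercept
            + self.beta_log * np.log(cpr)
            + self.beta_sq * cpr**2
            + self.beta_cpdiff * cpdiff
        )


#: Published DFPSany predictor (intercept, ln CPRany, CPRany^2, cpdiff).
DFPS_ANY_COEFFS = PredictorCoefficients(1.05, 0.93, 2.49, 0.70, "DFPSany")
#: Published DFPSm predictor (intercept, ln CPRm, CPRm^2, cpdiff).
DFPS_M_COEFFS = PredictorCoefficients(1.12, 0.97, 2.13, -1.43, "DFPSm")


def default_coefficients(outcome: str) -> PredictorCoefficients:
    """Return the published coefficient set for ``outcome`` ("DFPSany"/"DFPSm")."""
    if outcome == "DFPSany":
        return DFPS_ANY_COEFFS
    if outcome == "DFPSm":
        return DFPS_M_COEFFS
    raise ValueError(f"outcome must be one of {_OUTCOMES}, got {outcome!r}")


@dataclass(frozen=True)
class PredictionInput:
    """A pair of contraceptive prevalences for one analysis unit (proportions)."""

    cpr_any: float
    cpr_m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cpr_m <= 1.0 and 0.0 <= self.cpr_any <= 1.0):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.cpr_m > self.cpr_any + 1e-12:
            raise ValueError(
                f"cpr_m ({self.cpr_m}) cannot exceed cpr_any ({self.cpr_any})"
            )

    @property
    def cpdiff(self) -> float:
        return max(self.cpr_any - self.cpr_m, 0.0)


def logit(p):
    """ln(p / (1 - p)). Raises for p outside the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit requires p strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return out.item() if out.ndim == 0 else out


def inv_logit(x):
    """Inverse logit 1 / (1 + exp(-x)); output always in (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.item() if out.ndim == 0 else out


def predict_dfps(
    inp: PredictionInput, coeffs: PredictorCoefficients | None = None, outcome: str | None = None
) -> float:
    """Predicted DFPS (proportion scale) for one unit.

    The primary CPR is CPRany for DFPSany and CPRm for DFPSm.  A primary CPR
    below :data:`MIN_CPR` is outside the model's support and raises; use
    :func:`predict_batch` to flag such rows instead.
    """
    if coeffs is None:
        coeffs = default_coefficients(outcome or "DFPSany")
    cpr = inp.cpr_any if coeffs.outcome == "DFPSany" else inp.cpr_m
    if cpr < MIN_CPR:
        raise ValueError(
            f"primary CPR {cpr:.4f} below the {MIN_CPR:.0%} support bound for "
            f"{coeffs.outcome}; excluded rather than extrapolated"
        )
    cpr = min(cpr, MAX_CPR)
    return float(inv_logit(coeffs.linear_predictor(cpr, inp.cpdiff)))


def predict_batch(
    rows: pd.DataFrame,
    outcome: str = "DFPSany",
    coeffs: PredictorCoefficients | None = None,
) -> pd.DataFrame:
    """Vectorised prediction over a table with ``cpr_any`` / ``cpr_m`` columns.

    Returns a copy of ``rows`` with ``predicted``, ``excluded`` and ``note``
    columns; row order is preserved and malformed rows are flagged, never
    dropped.  For DFPSm with missing ``cpr_any``, cpdiff falls back to 0 with
    an explicit note (an approximation, not silent).
    """
    if coeffs is None:
        coeffs = default_coefficients(outcome)
    out = rows.copy()
    n = len(out)
    predicted = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    notes = np.full(n, "", dtype=object)
    if n == 0:
        out["predicted"], out["excluded"], out["note"] = predicted, excluded, notes
        return out

    cpr_any = pd.to_numeric(out.get("cpr_any"), errors="coerce").to_numpy(dtype=float)
    cpr_m = pd.to_numeric(out.get("cpr_m"), errors="coerce").to_numpy(dtype=float)
    primary = cpr_any if coeffs.outcome == "DFPSany" else cpr_m
    cpdiff = cpr_any - cpr_m

    bad_primary = ~np.isfinite(primary)
    _flag(excluded, notes, bad_primary, "primary CPR missing or non-numeric")
    inverted = np.isfinite(cpdiff) & (cpdiff < -1e-12)
    _flag(excluded, notes, inverted, "cpr_m exceeds cpr_any")
    out_of_range = (
        ~bad_primary & ~inverted & ((primary < 0) | (primary > 1))
    )
    _flag(excluded, notes, out_of_range, "CPR outside [0, 1]")
    below = ~excluded & (primary < MIN_CPR)
    _flag(excluded, notes, below, f"primary CPR below {MIN_CPR:.0%} support bound")

    missing_cpdiff = ~excluded & ~np.isfinite(cpdiff)
    cpdiff = np.where(missing_cpdiff, 0.0, cpdiff)
    notes[missing_cpdiff] = "cpdiff unavailable; assumed 0 (approximation)"

    ok = ~excluded
    clamped = ok & (primary > MAX_CPR)
    notes[clamped] = np.where(
        notes[clamped] == "", f"CPR clamped to {MAX_CPR}", notes[clamped]
    )
    use = np.where(ok, np.clip(primary, MIN_CPR, MAX_CPR), MIN_CPR)
    predicted[ok] = inv_logit(coeffs.linear_predictor(use, np.clip(cpdiff, 0.0, 1.0)))[ok]

    out["predicted"], out["excluded"], out["note"] = predicted, excluded, notes
    return out


def _flag(excluded: np.ndarray, notes: np.ndarray, mask: np.ndarray, note: str) -> None:
    fresh = mask & ~excluded
    excluded[fresh] = True
    notes[fresh] = note


def prediction_surface(
    outcome: str,
    cpdiff_levels: Sequence[float],
    cpr_grid: Sequence[float] | None = None,
    coeffs: PredictorCoefficients | None = None,
) -> pd.DataFrame:
    """Long-format table of predicted DFPS over a CPR grid at fixed cpdiff levels.

    One row per (cpr, cpdiff_level) pair, ordered by level then CPR -- the data
    behind the figure-style curves showing how the prediction shifts with the
    traditional-method gap.
    """
    if coeffs is None:
        coeffs = default_coefficients(outcome)
    if cpr_grid is None:
        cpr_grid = np.linspace(MIN_CPR, MAX_CPR, 99)
    cpr_grid = np.asarray(cpr_grid, dtype=float)
    if np.any((cpr_grid < MIN_CPR) | (cpr_grid > MAX_CPR)):
        raise ValueError(f"cpr_grid must lie within [{MIN_CPR}, {MAX_CPR}]")
    frames = []
    for level in cpdiff_levels:
        pred = inv_logit(coeffs.linear_predictor(cpr_grid, float(level)))
        frames.append(
            pd.DataFrame(
                {"cpr": cpr_grid, "cpdiff_level": float(level), "predicted": pred}
            )
        )
    return pd.concat(frames, ignore_index=True)
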