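"""Charge-based intracellular solubility prediction.

The predictor is a fixed linear map from counting net charge to percent
solubility (percent = -4.6237 x charge + 8.2469), clamped to [0, 100].
A design is called highly soluble when its predicted percent is strictly
above 70. ``fit_linear`` recovers the coefficients from paired
(charge, solubility) data by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import numbering, physchem
from .errors import DegenerateFitError

#: Coefficients of the published charge-to-solubility line.
DEFAULT_SLOPE = -4.6237
DEFAULT_INTERCEPT = 8.2469

#: Strict lower bound (exclusive) for the high-solubility class.
HIGH_SOLUBILITY_THRESHOLD = 70.0


@dataclass(frozen=True)
class SolubilityModel:
    slope: float = DEFAULT_SLOPE  # % per charge unit
    intercept: float = DEFAULT_INTERCEPT  # %
    clamp: bool = True


DEFAULT_MODEL = SolubilityModel()


@dataclass(frozen=True)
class SolubilityPrediction:
    net_charge: int
    percent: float
    high_solubility: bool


@dataclass(frozen=True)
class LinearModelFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: tuple[float, ...] = field(repr=False, default=())


def predict_percent(charge: float, model: SolubilityModel = DEFAULT_MODEL) -> float:
    """slope x charge + intercept, clamped to [0, 100] when enabled."""
    value = model.slope * charge + model.intercept
    if model.clamp:
        value = min(100.0, max(0.0, value))
    return value


def classify(percent: float) -> bool:
    """True iff percent is strictly above the 70% threshold."""
    return percent > HIGH_SOLUBILITY_THRESHOLD


def predict_for_charge(
    charge: int, model: SolubilityModel = DEFAULT_MODEL
) -> SolubilityPrediction:
    percent = predict_percent(charge, model)
    return SolubilityPrediction(charge, percent, classify(percent))


def predict_for_sequence(
    seq, mode: str = "as-is", model: SolubilityModel = DEFAULT_MODEL
) -> SolubilityPrediction:
    """Predict solubility for a sequence or SeqRecord.

    ``mode="as-is"`` scores the entire input (tags and linkers included);
    ``mode="fv-extract"`` first isolates the variable domains and scores
    only their concatenation. Fv extraction failures propagate as
    :class:`~scforge.errors.NotAnAntibodyError`.
    """
    residues = getattr(seq, "residues", seq)
    if mode in ("fv", "fv-extract"):
        domains = numbering.extract_fv(residues)
        residues = "".join(d.sequence for d in domains)
    elif mode not in ("as-is", "asis"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    return predict_for_charge(physchem.net_charge(residues), model)


def fit_linear(pairs: Sequence[tuple[float, float]]) -> LinearModelFit:
    """Ordinary least squares of percent solubility on net charge.

    Requires n >= 3 and non-constant x; otherwise raises
    :class:`DegenerateFitError`.
    """
    if len(pairs) < 3:
        raise DegenerateFitError(f"need at least 3 points, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("net charge is constant across the dataset")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return LinearModelFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r_squared, 0.0), 1.0)),
        n=len(pairs),
        residuals=tuple(float(r) for r in residuals),
    )
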