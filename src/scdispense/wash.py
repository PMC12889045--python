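"""Cartridge-wash carryover kinetics.

After dispensing, the cartridge is flushed with PBS; the contamination rate
of a wash is the ratio of the leftover cell-detection rate (cells/min) to the
original cell density of the sample (cells/min). Carryover decays roughly
geometrically with wash number, so a straight-line fit of log(leftover rate)
on wash index yields a per-wash retention factor, from which the number of
washes needed to reach a target contamination rate follows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import WashSeries


def contamination_rate(leftover: float, original: float) -> float:
    """Leftover detection rate divided by the original cell density.

    Both arguments are in cells/min; the result is a dimensionless fraction.
    """
    if original <= 0:
        raise ValueError(f"original rate must be > 0, got {original}")
    if leftover < 0:
        raise ValueError(f"leftover rate must be >= 0, got {leftover}")
    return leftover / original


@dataclass(frozen=True)
class WashDecayResults:
    """Fitted geometric decay of wash carryover.

    ``retention`` is the fitted per-wash retention factor (exp of the slope
    of log-rate on wash index); ``non_decaying`` flags retention >= 1.
    """

    series: WashSeries
    log_intercept: float
    retention: float
    r_squared: float
    n_points: int
    n_excluded_zeros: int

    @property
    def non_decaying(self) -> bool:
        return self.retention >= 1.0

    def predicted_rate(self, wash_index: int) -> float:
        """Predicted leftover rate (cells/min) after a given 1-based wash."""
        return math.exp(self.log_intercept + wash_index * math.log(self.retention))

    def washes_to_target(self, current_rate: float, target: float) -> int:
        """Smallest integer n with ``current_rate * retention**n <= target``.

        Rates here are contamination *fractions* (leftover/original).
        """
        return washes_to_target(self, current_rate, target)

    def summary(self) -> str:
        lines = [
            "Wash carryover decay fit (log-linear OLS)",
            "=" * 41,
            f"sample:            {self.series.sample_id}",
            f"original rate:     {self.series.original_rate:g} cells/min",
            f"washes fitted:     {self.n_points}"
            + (f" ({self.n_excluded_zeros} zero rates excluded)" if self.n_excluded_zeros else ""),
            f"retention/wash:    {self.retention:.4g}",
            f"r-squared:         {self.r_squared:.4f}",
        ]
        if self.non_decaying:
            lines.append("WARNING: retention >= 1 — series is not decaying")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.series.sample_id,
            "original_rate": self.series.original_rate,
            "log_intercept": self.log_intercept,
            "retention": self.retention,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "n_excluded_zeros": self.n_excluded_zeros,
            "non_decaying": self.non_decaying,
        }


class WashDecayModel:
    """Geometric decay model for a wash series.

    ``fit()`` runs ordinary least squares of log(leftover rate) on the
    1-based wash index; zero rates (washes where no cell was detected) are
    excluded from the log fit with a warning rather than imputed.
    """

    def __init__(self, series: WashSeries):
        self.series = series

    def fit(self) -> WashDecayResults:
        rates = np.asarray(self.series.leftover_rates, dtype=float)
        idx = np.arange(1, len(rates) + 1, dtype=float)
        keep = rates > 0
        n_zero = int((~keep).sum())
        if n_zero:
            warnings.warn(
                f"{n_zero} zero leftover rates excluded from the log-decay fit",
                stacklevel=2,
            )
        if keep.sum() < 2:
            raise ValueError("need >= 2 strictly positive leftover rates to fit")
        x, y = idx[keep], np.log(rates[keep])
        res = stats.linregress(x, y)
        retention = float(np.exp(res.slope))
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        fit = WashDecayResults(
            series=self.series,
            log_intercept=float(res.intercept),
            retention=retention,
            r_squared=r2,
            n_points=int(keep.sum()),
            n_excluded_zeros=n_zero,
        )
        if fit.non_decaying:
            warnings.warn("fitted retention >= 1: series is not decaying", stacklevel=2)
        return fit


def fit_decay(series: WashSeries) -> WashDecayResults:
    """Fit the geometric wash-decay model (functional shorthand)."""
    return WashDecayModel(series).fit()


def washes_to_target(fit: WashDecayResults, current_rate: float, target: float) -> int:
    """Washes needed for the contamination rate to reach ``target``.

    Smallest integer ``n >= 0`` with ``current_rate * retention**n <= target``.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    if current_rate <= target:
        return 0
    if fit.retention >= 1.0:
        raise ValueError("retention >= 1: target contamination rate is unreachable")
    n = math.log(target / current_rate) / math.log(fit.retention)
    n_int = math.ceil(n - 1e-12)
    # guard against float edge at the boundary
    while current_rate * fit.retention**n_int > target:
        n_int += 1
    return int(n_int)
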