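"""Multi-cell (doublet) fraction estimation from two-color well tallies.

A two-fluorophore dispensing assay only *sees* a multi-cell well when the
cells carry different fluorophores: same-color multi-cell wells present as a
single signal. The estimators here invert that color-collision thinning.

Pairwise (exactly-two) model
    A multi-cell well holds exactly two cells, each independently green with
    probability ``p``. The chance the pair is two-colored is ``2 p (1-p)``,
    so the multi-cell fraction among non-empty wells is
    ``m_hat = d_hat / (2 p_hat (1 - p_hat))`` where ``d_hat`` is the observed
    dual-signal fraction. The single-cell dispensing frequency is
    ``100 (1 - m_hat)`` percent.

Truncated-Poisson model
    Cells per non-empty well follow a zero-truncated Poisson(lambda). The
    dual-signal probability is ``1 - A(p) - A(1-p)`` with
    ``A(x) = (exp(lambda (x-1)) - exp(-lambda)) / (1 - exp(-lambda))``;
    lambda is solved by bisection and ``m_hat = P(k >= 2 | k >= 1)``.

Usage follows the Model/Results convention::

    model = DoubletModel(counts)                  # counts: SignalCounts
    res = model.fit(bootstrap=1000, seed=1)       # -> DoubletResults
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .fluor import SignalCounts

_BISECT_LO = 1e-8
_BISECT_HI = 10.0
_BISECT_TOL = 1e-10


def estimate_color_proportion(counts: SignalCounts) -> float:
    """Green-cell proportion from single-signal wells.

    ``p_hat = n_green_only / (n_green_only + n_red_only)``. Same-color
    doublets inflate both single-signal counts slightly; that small bias is
    ignored here.
    """
    denom = counts.n_green_only + counts.n_red_only
    if denom == 0:
        raise ValueError("no single-signal wells; color proportion undefined")
    return counts.n_green_only / denom


def _dual_prob_truncated_poisson(lam: float, p: float) -> float:
    """P(well shows both colors | >=1 cell) under zero-truncated Poisson."""
    denom = -np.expm1(-lam)  # 1 - exp(-lam)

    def a(x: float) -> float:
        return (np.exp(lam * (x - 1.0)) - np.exp(-lam)) / denom

    return 1.0 - a(p) - a(1.0 - p)


@dataclass(frozen=True)
class DoubletResults:
    """Estimates of the multi-cell well fraction and single-cell frequency.

    All fractions are relative to the chosen denominator (non-empty wells by
    default). ``single_cell_freq`` and the CI bounds are percentages.
    """

    counts: SignalCounts
    model: str
    d_hat: float
    p_hat: float
    m_hat: float
    denominator: str = "nonempty"
    ci_low: float | None = None
    ci_high: float | None = None
    lambda_hat: float | None = None
    n_bootstrap: int | None = None

    @property
    def single_cell_freq(self) -> float:
        """Estimated percent of non-empty wells holding exactly one cell."""
        return 100.0 * (1.0 - self.m_hat)

    @property
    def multi_cell_pct(self) -> float:
        return 100.0 * self.m_hat

    @property
    def dual_signal_pct(self) -> float:
        return 100.0 * self.d_hat

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Doublet estimation (two-color collision model)",
            "=" * 47,
            f"model:                  {self.model}",
            f"wells (non-empty):      {c.n_nonempty}"
            f"  [green {c.n_green_only} / red {c.n_red_only} / dual {c.n_dual}"
            f" / empty {c.n_empty}]",
            f"dual-signal fraction:   {self.dual_signal_pct:.2f}%",
            f"green-cell proportion:  {self.p_hat:.3f}",
            f"multi-cell (>=2) wells: {self.multi_cell_pct:.1f}%"
            f" of {self.denominator} wells",
            f"single-cell frequency:  {self.single_cell_freq:.1f}%",
        ]
        if self.lambda_hat is not None:
            lines.append(f"lambda (trunc. Poisson): {self.lambda_hat:.4f}")
        if self.ci_low is not None:
            lines.append(
                f"bootstrap {self.n_bootstrap} reps, 95% CI on single-cell"
                f" frequency: [{self.ci_low:.1f}%, {self.ci_high:.1f}%]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "counts": self.counts.to_dict(),
            "d_hat": self.d_hat,
            "p_hat": self.p_hat,
            "m_hat": self.m_hat,
            "denominator": self.denominator,
            "single_cell_freq_pct": self.single_cell_freq,
            "multi_cell_pct": self.multi_cell_pct,
            "dual_signal_pct": self.dual_signal_pct,
            "lambda_hat": self.lambda_hat,
            "ci_low_pct": self.ci_low,
            "ci_high_pct": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
        }


class DoubletModel:
    """Collision model for the multi-cell well fraction.

    Parameters
    ----------
    counts
        Class tallies from the well classifier.
    model
        ``"pairwise"`` (exactly two cells per multi-cell well, the default)
        or ``"truncated_poisson"``.
    denominator
        ``"nonempty"`` reports ``m_hat`` relative to non-empty wells (the
        convention of the dual-fluorophore assay write-up); ``"dispensed"``
        rescales to all dispensed wells.
    """

    def __init__(
        self,
        counts: SignalCounts,
        model: str = "pairwise",
        denominator: str = "nonempty",
    ):
        if model not in ("pairwise", "truncated_poisson"):
            raise ValueError(f"unknown model {model!r}")
        if denominator not in ("nonempty", "dispensed"):
            raise ValueError(f"unknown denominator {denominator!r}")
        if counts.n_nonempty == 0:
            raise ValueError("no non-empty wells; nothing to estimate")
        self.counts = counts
        self.model = model
        self.denominator = denominator

    def _point_estimate(self, counts: SignalCounts) -> tuple[float, float, float, float | None]:
        """Returns (d_hat, p_hat, m_hat on the nonempty scale, lambda_hat)."""
        d_hat = counts.n_dual / counts.n_nonempty
        p_hat = estimate_color_proportion(counts)
        lambda_hat = None
        if self.model == "pairwise":
            collision = 2.0 * p_hat * (1.0 - p_hat)
            if d_hat == 0.0:
                return d_hat, p_hat, 0.0, lambda_hat
            if collision == 0.0:
                raise ValueError(
                    "color proportion is 0 or 1; the two-color collision "
                    "probability vanishes and the estimator is undefined"
                )
            m_hat = min(d_hat / collision, 1.0)
        else:
            if d_hat == 0.0:
                m_hat = 0.0
                lambda_hat = 0.0
            else:
                sup = _dual_prob_truncated_poisson(_BISECT_HI, p_hat)
                if d_hat >= sup:
                    raise ValueError(
                        f"dual fraction {d_hat:.4f} exceeds the truncated-"
                        f"Poisson model's reachable dual probability {sup:.4f}"
                    )
                lambda_hat = float(
                    brentq(
                        lambda lam: _dual_prob_truncated_poisson(lam, p_hat) - d_hat,
                        _BISECT_LO,
                        _BISECT_HI,
                        xtol=_BISECT_TOL,
                    )
                )
                # P(k >= 2 | k >= 1) = 1 - lam e^-lam / (1 - e^-lam)
                lam = lambda_hat
                m_hat = 1.0 - lam * np.exp(-lam) / -np.expm1(-lam)
        return d_hat, p_hat, m_hat, lambda_hat

    def fit(
        self,
        bootstrap: int = 0,
        level: float = 0.95,
        seed: int | None = None,
    ) -> DoubletResults:
        """Estimate the multi-cell fraction; optionally bootstrap a CI.

        ``bootstrap`` > 0 resamples wells (multinomial over the four classes)
        that many times and attaches a percentile interval on the single-cell
        frequency. Deterministic for a fixed ``seed``.
        """
        d_hat, p_hat, m_scaled, lambda_hat = self._point_estimate(self.counts)
        m_hat = self._rescale(m_scaled, self.counts)
        ci_low = ci_high = None
        if bootstrap > 0:
            ci_low, ci_high = self._bootstrap_ci(bootstrap, level, seed)
        return DoubletResults(
            counts=self.counts,
            model=self.model,
            d_hat=d_hat,
            p_hat=p_hat,
            m_hat=m_hat,
            denominator=self.denominator,
            ci_low=ci_low,
            ci_high=ci_high,
            lambda_hat=lambda_hat,
            n_bootstrap=bootstrap if bootstrap > 0 else None,
        )

    def _rescale(self, m_nonempty: float, counts: SignalCounts) -> float:
        if self.denominator == "nonempty" or counts.n_total == 0:
            return m_nonempty
        return m_nonempty * counts.n_nonempty / counts.n_total

    def _bootstrap_ci(
        self, n_boot: int, level: float, seed: int | None
    ) -> tuple[float, float]:
        rng = np.random.default_rng(seed)
        c = self.counts
        probs = np.array(
            [c.n_green_only, c.n_red_only, c.n_dual, c.n_empty], dtype=float
        )
        probs /= probs.sum()
        draws = rng.multinomial(c.n_total, probs, size=n_boot)
        if self.model == "pairwise":
            return self._pairwise_ci_vectorized(draws, level, n_boot)
        freqs = []
        failures = 0
        for g, r, d, e in draws:
            rep = SignalCounts(int(g), int(r), int(d), int(e))
            if rep.n_nonempty == 0:
                failures += 1
                continue
            try:
                _, _, m, _ = self._point_estimate(rep)
            except ValueError:
                failures += 1
                continue
            freqs.append(100.0 * (1.0 - self._rescale(m, rep)))
        if failures > n_boot / 2:
            raise RuntimeError(
                f"bootstrap failed: estimator undefined in {failures}/{n_boot} replicates"
            )
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(freqs, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def _pairwise_ci_vectorized(
        self, draws: np.ndarray, level: float, n_boot: int
    ) -> tuple[float, float]:
        """Same resampling as the generic path, in closed form per replicate."""
        g, r, d, _ = draws.T.astype(float)
        total = draws.sum(axis=1).astype(float)
        nonempty = g + r + d
        single = g + r
        with np.errstate(divide="ignore", invalid="ignore"):
            d_hat = d / nonempty
            p = g / single
            collision = 2.0 * p * (1.0 - p)
            m = np.minimum(d_hat / collision, 1.0)
        m = np.where(d_hat == 0.0, 0.0, m)
        valid = (nonempty > 0) & ((d_hat == 0.0) | ((single > 0) & (collision > 0)))
        failures = int((~valid).sum())
        if failures > n_boot / 2:
            raise RuntimeError(
                f"bootstrap failed: estimator undefined in {failures}/{n_boot} replicates"
            )
        m = m[valid]
        if self.denominator == "dispensed":
            m = m * nonempty[valid] / total[valid]
        freqs = 100.0 * (1.0 - m)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(freqs, [alpha, 1.0 - alpha])
        return float(lo), float(hi)


def estimate_multi_fraction_pairwise(
    counts: SignalCounts, denominator: str = "nonempty"
) -> DoubletResults:
    """Exactly-two-cell collision estimate (functional shorthand)."""
    return DoubletModel(counts, model="pairwise", denominator=denominator).fit()


def estimate_multi_fraction_poisson(
    counts: SignalCounts, denominator: str = "nonempty"
) -> DoubletResults:
    """Zero-truncated-Poisson collision estimate (functional shorthand)."""
    return DoubletModel(counts, model="truncated_poisson", denominator=denominator).fit()


def bootstrap_ci(
    counts: SignalCounts,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    model: str = "pairwise",
) -> tuple[float, float]:
    """Percentile bootstrap CI on the single-cell frequency (percent)."""
    return DoubletModel(counts, model=model)._bootstrap_ci(n_boot, level, seed)
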