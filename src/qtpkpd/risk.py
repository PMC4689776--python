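"""Probability of QT prolongation, Cp50 and safety margins.

The pro-arrhythmic risk summary is the posterior probability that the drug
effect at concentration ``C`` reaches a threshold (default 10 ms)::

    P(C) = P( slope * C >= threshold )

evaluated as the fraction of posterior slope draws exceeding ``threshold/C``.
Cp50 is the concentration at which this probability crosses 0.5, and the
safety margin is ``Cp50 / Cmax_ref`` for a caller-supplied reference peak
concentration (conventionally the human Cmax for every species, so the
margins are expressed against clinically attained exposure).

``normal_approx_draws`` lets the risk layer run directly from published
median / 95%-interval summaries without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RiskCurve",
    "SafetyMargin",
    "prob_exceed",
    "risk_curve",
    "safety_margin",
    "normal_approx_draws",
    "default_conc_grid",
]


@dataclass
class RiskCurve:
    """Probability of >= ``threshold_ms`` prolongation along a concentration grid."""

    conc_grid_nM: np.ndarray
    prob: np.ndarray
    threshold_ms: float = 10.0
    cp50_nM: Optional[float] = None
    source: str = "posterior draws"

    def __post_init__(self) -> None:
        self.conc_grid_nM = np.asarray(self.conc_grid_nM, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SafetyMargin:
    cp50_nM: float
    cmax_ref_nM: float
    margin: float
    cmax_species: str = "human"


def prob_exceed(slope_draws, conc_nM: float, threshold_ms: float = 10.0) -> float:
    """Posterior probability that the drug effect at ``conc_nM`` is >= threshold.

    Fraction of draws with ``slope * conc >= threshold`` (boundary inclusive).
    At zero concentration the probability is 0 (a positive threshold is
    unattainable).
    """
    if threshold_ms <= 0:
        raise ValueError("threshold_ms must be positive")
    if conc_nM < 0:
        raise ValueError("conc_nM must be >= 0")
    draws = np.asarray(slope_draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need >= 100 slope draws")
    if conc_nM == 0:
        return 0.0
    return float(np.mean(draws * conc_nM >= threshold_ms))


def default_conc_grid(slope_draws, threshold_ms: float = 10.0, n: int = 200) -> np.ndarray:
    """Log-spaced grid spanning the crossing region implied by the draws:
    from ``threshold / q99.9(slope)`` to ``threshold / q0.1(slope)`` (positive
    quantiles only)."""
    draws = np.asarray(slope_draws, dtype=float)
    pos = draws[draws > 0]
    if pos.size == 0:
        return np.logspace(0, 6, n)
    hi_s = np.quantile(pos, 0.999)
    lo_s = np.quantile(pos, 0.001)
    lo_c = threshold_ms / hi_s
    hi_c = threshold_ms / max(lo_s, 1e-12)
    return np.logspace(np.log10(lo_c), np.log10(hi_c), n)


def risk_curve(slope_draws, conc_grid=None, threshold_ms: float = 10.0) -> RiskCurve:
    """Evaluate the exceedance probability along a concentration grid and
    locate Cp50 by monotone piecewise-linear interpolation of the 0.5 crossing.

    ``cp50_nM`` is ``None`` when the curve never reaches 0.5 (e.g. more than
    half the posterior mass at non-positive slopes).
    """
    draws = np.asarray(slope_draws, dtype=float)
    if conc_grid is None:
        conc_grid = default_conc_grid(draws, threshold_ms)
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    prob = np.array([prob_exceed(draws, c, threshold_ms) for c in grid])
    cp50 = None
    if prob.max() >= 0.5:
        if prob[0] >= 0.5:
            cp50 = float(grid[0])
        else:
            k = int(np.argmax(prob >= 0.5))
            # bisection refinement of the bracketed 0.5 crossing, so Cp50 is
            # exact for step curves (point-mass posteriors) as well
            c0, c1 = float(grid[k - 1]), float(grid[k])
            for _ in range(60):
                mid = 0.5 * (c0 + c1)
                if prob_exceed(draws, mid, threshold_ms) >= 0.5:
                    c1 = mid
                else:
                    c0 = mid
            cp50 = c1
    return RiskCurve(grid, prob, threshold_ms, cp50)


def safety_margin(cp50_nM: float, cmax_ref_nM: float,
                  cmax_species: str = "human") -> SafetyMargin:
    """Safety margin Cp50 / Cmax_ref (reference peak concentration supplied
    by the caller; conventionally the human Cmax for every species)."""
    if cp50_nM is None or cp50_nM <= 0 or cmax_ref_nM <= 0:
        raise ValueError("cp50 and cmax_ref must be positive")
    return SafetyMargin(cp50_nM, cmax_ref_nM, cp50_nM / cmax_ref_nM, cmax_species)


def normal_approx_draws(median: float, ci_low: float, ci_high: float,
                        n: int, seed) -> np.ndarray:
    """Normal draws matched to a published median and central 95% interval:
    ``Normal(median, (ci_high - ci_low) / 3.92)``."""
    if not ci_low < median < ci_high:
        raise ValueError("require ci_low < median < ci_high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(median, (ci_high - ci_low) / 3.92, int(n))
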