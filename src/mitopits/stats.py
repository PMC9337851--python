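"""Location-preference inference for puncta on an organelle network.

Given counts of spots at endpoints vs edges, the raw endpoint proportion
``p`` gives uncorrected odds ``p/(1-p)`` against a 50/50 null.  Because a
tubular network's surface is dominated by edges, the honest null is
area-weighted: the corrected odds ratio divides the observed odds by the
odds expected under uniform-per-area placement,

    OR_corr = [p/(1-p)] * [a_edge/a_end],

and the corrected preference is ``100*OR/(1+OR)`` percent.  Goodness of
fit uses the chi-square statistic with the upper tail from the
regularized incomplete gamma function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaincc

__all__ = [
    "LocationCounts",
    "PreferenceResult",
    "endpoint_proportion",
    "odds",
    "uncorrected_preference",
    "corrected_preference",
    "chisq_gof",
    "chi2_pvalue",
    "preference_analysis",
    "format_p",
]


@dataclass
class LocationCounts:
    """Spot counts per location class."""

    n_endpoint: int = 0
    n_branchpoint: int = 0
    n_edge: int = 0
    n_free: int = 0

    def __post_init__(self) -> None:
        for f in ("n_endpoint", "n_branchpoint", "n_edge", "n_free"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_endpoint + self.n_branchpoint + self.n_edge + self.n_free

    def __add__(self, other: "LocationCounts") -> "LocationCounts":
        return LocationCounts(
            n_endpoint=self.n_endpoint + other.n_endpoint,
            n_branchpoint=self.n_branchpoint + other.n_branchpoint,
            n_edge=self.n_edge + other.n_edge,
            n_free=self.n_free + other.n_free,
        )


@dataclass
class PreferenceResult:
    p_hat: float
    odds: float
    odds_ratio_corrected: Optional[float]
    preference_corrected_pct: Optional[float]
    chi2: float
    df: int
    p_value: float
    chi2_corrected: Optional[float] = None
    p_value_corrected: Optional[float] = None


def endpoint_proportion(counts: LocationCounts) -> float:
    """Endpoint share among endpoint + edge spots (others ignored)."""
    denom = counts.n_endpoint + counts.n_edge
    if denom == 0:
        raise ValueError("no endpoint or edge spots")
    return counts.n_endpoint / denom


def odds(p_hat: float) -> float:
    """p/(1-p); +inf when p == 1."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if p_hat == 1.0:
        return math.inf
    return p_hat / (1.0 - p_hat)


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper tail of the chi-square distribution, Q(df/2, chi2/2)."""
    if chi2 < 0 or df < 1:
        raise ValueError("need chi2 >= 0 and df >= 1")
    return float(gammaincc(df / 2.0, chi2 / 2.0))


def chisq_gof(observed: Sequence[float], expected_probs: Sequence[float],
              continuity: bool = False):
    """Chi-square goodness of fit of counts against class probabilities.

    Returns ``(chi2, df, p_value)`` with ``df = k - 1``.  The optional
    Yates continuity correction subtracts 0.5 from each |O - E|.
    """
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected_probs must match in length")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected_probs must sum to 1")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed total must be positive")
    exp = n * probs
    if np.any(exp <= 0):
        raise ValueError("every expected count must be positive")
    dev = np.abs(obs - exp)
    if continuity:
        dev = np.clip(dev - 0.5, 0.0, None)
    chi2 = float(np.sum(dev**2 / exp))
    df = len(obs) - 1
    return chi2, df, chi2_pvalue(chi2, df)


def uncorrected_preference(counts: LocationCounts, continuity: bool = False):
    """Odds and chi-square of endpoint/edge counts against a 50/50 null.

    Returns ``(odds, chi2, p_value)``; odds is +inf when all spots are at
    endpoints (chi2 stays finite).
    """
    p_hat = endpoint_proportion(counts)
    chi2, _df, p = chisq_gof([counts.n_endpoint, counts.n_edge], [0.5, 0.5],
                             continuity=continuity)
    return odds(p_hat), chi2, p


def corrected_preference(p_hat: float, a_end: float, a_edge: float,
                         counts: Optional[LocationCounts] = None,
                         continuity: bool = False):
    """Surface-area-corrected endpoint preference.

    ``OR_corr = [p/(1-p)] * [a_edge/a_end]``; the preference percentage is
    ``100*OR/(1+OR)``.  ``a_end``/``a_edge`` may be the raw area fractions
    as printed (only their ratio enters the odds ratio).  When counts are
    supplied, a chi-square against the area-weighted null (normalized
    ``a_end``, ``a_edge``) is included.

    Returns ``(OR_corr, preference_pct, chi2_corr, p_value_corr)``; the
    last two are None without counts.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError("p_hat must lie strictly in (0, 1)")
    if a_end <= 0 or a_edge <= 0:
        raise ValueError("area fractions must be positive (degenerate null)")
    or_corr = odds(p_hat) * (a_edge / a_end)
    preference_pct = 100.0 * or_corr / (1.0 + or_corr)
    chi2_corr = p_corr = None
    if counts is not None:
        total_a = a_end + a_edge
        chi2_corr, _df, p_corr = chisq_gof(
            [counts.n_endpoint, counts.n_edge],
            [a_end / total_a, a_edge / total_a],
            continuity=continuity,
        )
    return or_corr, preference_pct, chi2_corr, p_corr


def preference_analysis(counts: LocationCounts, a_end: float, a_edge: float,
                        continuity: bool = False) -> PreferenceResult:
    """Full preference analysis bundle from counts and area fractions."""
    p_hat = endpoint_proportion(counts)
    odds_val, chi2, p = uncorrected_preference(counts, continuity=continuity)
    if 0.0 < p_hat < 1.0:
        or_corr, pref, chi2_c, p_c = corrected_preference(
            p_hat, a_end, a_edge, counts=counts, continuity=continuity)
    else:
        or_corr = pref = chi2_c = p_c = None
    return PreferenceResult(
        p_hat=p_hat, odds=odds_val,
        odds_ratio_corrected=or_corr, preference_corrected_pct=pref,
        chi2=chi2, df=1, p_value=p,
        chi2_corrected=chi2_c, p_value_corrected=p_c,
    )


def format_p(p: float) -> str:
    """Display convention: 2 significant figures, floored at < 2.2e-16."""
    if p < 2.2e-16:
        return "< 2.2e-16"
    return f"{p:.1e}"
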