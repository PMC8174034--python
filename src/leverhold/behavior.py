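"""Behavioral summaries: acquisition metrics, devaluation normalization,
prefeeding exclusions, and proportion comparisons.

Outcome devaluation (sensory-specific satiation) probes whether lever
pressing is goal-directed: each mouse's non-reinforced test-day response
rate is normalized to the mean response rate of its last two
criterion-training sessions; a selective drop on the devalued day marks
goal-directed control, insensitivity marks habitual control. Mice that did
not consume enough of the prefed outcome (< 0.1 g pellets on the devalued
day, < 0.1 ml sucrose on the valued day) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import MS_PER_MIN, BehavioralSession, success_mask

PREFEED_MIN_PELLETS_G = 0.1
PREFEED_MIN_SUCROSE_ML = 0.1


@dataclass(frozen=True)
class SessionMetrics:
    session_id: str
    total_presses: int
    percent_rewarded: float
    response_rate_per_min: float
    duration_bin_edges_ms: Optional[np.ndarray] = None
    duration_histogram: Optional[np.ndarray] = None  # proportions, sums to 1


def default_duration_bins(criterion_ms: int) -> np.ndarray:
    """Ten equal bins from 0 to twice the criterion, plus an overflow bin."""
    return np.append(np.linspace(0.0, 2.0 * criterion_ms, 11), np.inf)


def session_metrics(
    session: BehavioralSession,
    duration_bin_edges_ms: Optional[np.ndarray] = None,
) -> SessionMetrics:
    """Total presses, percent rewarded, response rate, duration histogram."""
    n = session.n_presses
    minutes = session.session_end_ms / MS_PER_MIN
    if n == 0:
        return SessionMetrics(session.session_id, 0, 0.0, 0.0, None, None)
    pct = 100.0 * float(success_mask(session).sum()) / n
    rate = n / minutes if minutes > 0 else 0.0
    edges = (
        duration_bin_edges_ms
        if duration_bin_edges_ms is not None
        else default_duration_bins(session.criterion_ms)
    )
    hist, _ = np.histogram(session.durations_ms, bins=edges)
    return SessionMetrics(
        session_id=session.session_id,
        total_presses=n,
        percent_rewarded=pct,
        response_rate_per_min=rate,
        duration_bin_edges_ms=np.asarray(edges, dtype=float),
        duration_histogram=hist / n,
    )


def devaluation_normalize(
    rr_test: float, rr_last1: float, rr_last2: float
) -> float:
    """Test-day response rate over the mean of the last two training sessions."""
    baseline = (rr_last1 + rr_last2) / 2.0
    if baseline <= 0:
        raise ValueError("undefined normalization: zero baseline response rate")
    return rr_test / baseline


@dataclass(frozen=True)
class ExclusionFlag:
    excluded: bool
    reason: str = ""


def prefeed_exclusion(pellets_g: float, sucrose_ml: float) -> ExclusionFlag:
    """Exclude mice that under-consumed during prefeeding (strict thresholds)."""
    if pellets_g < 0 or sucrose_ml < 0:
        raise ValueError("consumption cannot be negative")
    reasons = []
    if pellets_g < PREFEED_MIN_PELLETS_G:
        reasons.append(f"pellets {pellets_g:g} g < {PREFEED_MIN_PELLETS_G} g")
    if sucrose_ml < PREFEED_MIN_SUCROSE_ML:
        reasons.append(f"sucrose {sucrose_ml:g} ml < {PREFEED_MIN_SUCROSE_ML} ml")
    return ExclusionFlag(excluded=bool(reasons), reason="; ".join(reasons))


@dataclass(frozen=True)
class DevaluationResult:
    mouse_id: str
    normalized_rr_valued: float
    normalized_rr_devalued: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class ProportionTest:
    counts: np.ndarray  # 2x2 contingency table
    statistic: float
    df: int
    p_value: float


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> ProportionTest:
    """Pearson chi-square comparison of two proportions (df = 1).

    Continuity correction is off by default. Raises on any zero margin
    (the statistic is undefined there).
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    return ProportionTest(counts=table, statistic=float(chi2), df=int(df), p_value=float(p))
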