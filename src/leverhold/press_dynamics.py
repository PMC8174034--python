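"""Within-press firing dynamics.

Presses are grouped into within-session duration quartiles (rank-based,
balanced counts) and each press is divided into four equal-duration
segments (0-25%, ..., 75-100% of the hold). Two complementary summaries:

* **segment spike proportions** — how the spikes emitted during a press
  distribute over its four quarters, per press and averaged per unit;
* **quartile segment profiles** — segment firing rates z-scored against a
  pre-onset baseline whose length is proportionate to the quartile's mean
  press duration, averaged within quartile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BehavioralSession, UnitRecording

logger = logging.getLogger(__name__)

N_SEGMENTS = 4
BASELINE_BIN_MS = 20.0


@dataclass(frozen=True)
class QuartileAssignment:
    """Rank-based duration-quartile labels for one session's presses."""

    session_id: str
    labels: np.ndarray  # per press, 1..4
    boundaries_ms: tuple[float, float, float]  # max duration in Q1..Q3
    mean_duration_ms: tuple[float, float, float, float]

    def presses_in(self, quartile: int) -> np.ndarray:
        return np.flatnonzero(self.labels == quartile)


@dataclass(frozen=True)
class SegmentProfile:
    unit_id: str
    quartile: int
    mean_z: tuple[float, float, float, float]
    n_presses: int
    degenerate_baseline: bool = False


def assign_quartiles(session: BehavioralSession) -> QuartileAssignment:
    """Split presses into four duration quartiles by rank.

    Presses are sorted by duration (ties broken by press order) and cut
    into four contiguous rank blocks as equal as possible, the remainder
    going to the earliest quartiles; counts therefore differ by at most
    one. Boundaries are the maximum duration within Q1-Q3.
    """
    n = session.n_presses
    if n < 4:
        raise ValueError(f"{session.session_id}: insufficient presses ({n} < 4)")
    durations = session.durations_ms
    order = np.lexsort((np.arange(n), durations))  # stable by press order
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    boundaries = tuple(float(durations[labels == q].max()) for q in (1, 2, 3))
    means = tuple(float(durations[labels == q].mean()) for q in (1, 2, 3, 4))
    return QuartileAssignment(
        session_id=session.session_id,
        labels=labels,
        boundaries_ms=boundaries,
        mean_duration_ms=means,
    )


def spike_presence_fraction(
    unit: UnitRecording, session: BehavioralSession
) -> float:
    """Fraction of presses containing at least one spike in [onset, offset)."""
    if session.n_presses == 0:
        raise ValueError(f"{session.session_id}: no presses")
    st = unit.spike_times
    counts = np.searchsorted(st, session.press_offsets, side="left") - np.searchsorted(
        st, session.press_onsets, side="left"
    )
    return float(np.mean(counts > 0))


def _segment_counts(
    spikes: np.ndarray, onset: float, offset: float
) -> np.ndarray:
    """Spike counts in the four equal quarters of [onset, offset)."""
    edges = onset + (offset - onset) * np.arange(N_SEGMENTS + 1) / N_SEGMENTS
    pos = np.searchsorted(spikes, edges, side="left")
    return np.diff(pos).astype(float)


def segment_spike_proportions(
    unit: UnitRecording, session: BehavioralSession
) -> tuple[np.ndarray, np.ndarray]:
    """Per-press spike proportions over the four duration segments.

    Returns ``(per_press, unit_mean)`` where ``per_press`` is an
    (n_presses, 4) array of segment counts divided by the press's total
    in-press count (rows of presses without spikes are NaN and excluded
    from the unweighted per-unit mean, which is NaN if no press had a
    spike).
    """
    st = unit.spike_times
    per_press = np.full((session.n_presses, N_SEGMENTS), np.nan)
    for i, (on, off) in enumerate(
        zip(session.press_onsets, session.press_offsets)
    ):
        counts = _segment_counts(st, on, off)
        total = counts.sum()
        if total > 0:
            per_press[i] = counts / total
    included = ~np.isnan(per_press[:, 0])
    unit_mean = (
        per_press[included].mean(axis=0)
        if included.any()
        else np.full(N_SEGMENTS, np.nan)
    )
    return per_press, unit_mean


def quartile_segment_profiles(
    unit: UnitRecording,
    session: BehavioralSession,
    qa: QuartileAssignment | None = None,
) -> list[SegmentProfile]:
    """Duration-quartile segment profiles, z-scored against scaled baselines.

    For quartile q with mean press duration ``d_q``: each member press's
    segment rates (Hz; count / quarter length) are z-scored against the
    mean and SD of ~20-ms-binned rates pooled over the ``[-d_q, 0)``
    pre-onset baselines of all presses in that quartile, then averaged
    across member presses. A quartile whose pooled baseline SD is zero is
    flagged degenerate (NaN profile) so group means can exclude it.
    """
    if qa is None:
        qa = assign_quartiles(session)
    st = unit.spike_times
    on, off = session.press_onsets, session.press_offsets
    profiles = []
    for q in (1, 2, 3, 4):
        idx = qa.presses_in(q)
        d_q = qa.mean_duration_ms[q - 1]
        # baseline bins ~20 ms, equal-width, covering exactly [-d_q, 0)
        n_bins = max(1, int(round(d_q / BASELINE_BIN_MS)))
        bw = d_q / n_bins
        pooled = []
        for i in idx:
            edges = on[i] - d_q + bw * np.arange(n_bins + 1)
            counts = np.diff(np.searchsorted(st, edges, side="left"))
            pooled.append(counts / (bw / 1000.0))
        pooled = np.concatenate(pooled)
        b_mean = float(pooled.mean())
        b_sd = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
        if b_sd == 0.0:
            logger.warning(
                "unit %s quartile %d: zero baseline SD; profile flagged",
                unit.unit_id,
                q,
            )
            profiles.append(
                SegmentProfile(
                    unit_id=unit.unit_id,
                    quartile=q,
                    mean_z=(np.nan,) * 4,
                    n_presses=len(idx),
                    degenerate_baseline=True,
                )
            )
            continue
        zs = np.empty((len(idx), N_SEGMENTS))
        for row, i in enumerate(idx):
            seg_len_s = (off[i] - on[i]) / N_SEGMENTS / 1000.0
            rates = _segment_counts(st, on[i], off[i]) / seg_len_s
            zs[row] = (rates - b_mean) / b_sd
        profiles.append(
            SegmentProfile(
                unit_id=unit.unit_id,
                quartile=q,
                mean_z=tuple(float(v) for v in zs.mean(axis=0)),
                n_presses=len(idx),
            )
        )
    return profiles
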