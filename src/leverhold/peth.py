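"""Peri-event time histograms, modulation detection, and z-scored summaries.

The analysis pipeline per unit and task event (press onset, press offset,
reward delivery) is:

1. bin spikes in 20-ms bins over a +/-10-s window around each event and
   average across events (Hz);
2. smooth with a 3-tap Gaussian-weighted moving average;
3. take baseline statistics from the -10 s to -2 s window before press
   onset (mean, SD, and an empirical 95% interval of the 400 baseline
   bins);
4. flag the unit up-modulated (down-modulated) if at least four
   consecutive bins within -2 s to +3 s of the event exceed (fall below)
   the baseline 95% interval; modulation onset is the left edge of the
   first bin of the first qualifying run;
5. z-score the PETH against the baseline mean/SD for population averages
   and 250-ms epoch summaries.

Because the task is self-paced, event windows may overlap and a spike may
legitimately count toward more than one event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import BehavioralSession, Outcome, UnitRecording, success_mask

logger = logging.getLogger(__name__)

EventType = Literal["press_onset", "press_offset", "reward"]
Direction = Literal["up", "down", "none"]

BIN_WIDTH_MS = 20.0
PETH_WINDOW_MS = (-10_000.0, 10_000.0)
BASELINE_WINDOW_MS = (-10_000.0, -2_000.0)
DETECTION_WINDOW_MS = (-2_000.0, 3_000.0)
MIN_CONSECUTIVE_BINS = 4
SMOOTH_SIGMA_BINS = 0.4
EPOCH_BIN_MS = 250.0

#: the three named 1-s epochs summarized in four 250-ms bins
EPOCHS: dict[str, tuple[float, float]] = {
    "pre_onset": (-1000.0, 0.0),
    "post_offset": (0.0, 1000.0),
    "post_reward": (0.0, 1000.0),
}


@dataclass(frozen=True)
class Peth:
    """Trial-averaged event-aligned firing rate in fixed-width bins."""

    unit_id: str
    event_type: EventType
    window_ms: tuple[float, float] = PETH_WINDOW_MS
    bin_width_ms: float = BIN_WIDTH_MS
    rate_per_bin: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_events: int = 0
    smoothed: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "rate_per_bin", np.asarray(self.rate_per_bin, dtype=float)
        )

    @property
    def n_bins(self) -> int:
        return len(self.rate_per_bin)

    @property
    def bin_left_edges_ms(self) -> np.ndarray:
        return self.window_ms[0] + self.bin_width_ms * np.arange(self.n_bins)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_left_edges_ms + self.bin_width_ms / 2.0

    def slice_bins(self, t_start: float, t_stop: float) -> np.ndarray:
        """Indices of bins whose left edge lies in [t_start, t_stop)."""
        edges = self.bin_left_edges_ms
        return np.flatnonzero((edges >= t_start) & (edges < t_stop))


@dataclass(frozen=True)
class BaselineStats:
    """Reference statistics from the pre-press baseline window."""

    mean_hz: float
    sd_hz: float
    lower95_hz: float
    upper95_hz: float
    window_ms: tuple[float, float] = BASELINE_WINDOW_MS
    n_bins: int = 0


@dataclass(frozen=True)
class ModulationResult:
    unit_id: str
    event_type: EventType
    direction: Direction
    onset_latency_ms: Optional[float] = None
    has_up_run: bool = False
    has_down_run: bool = False
    window_ms: tuple[float, float] = DETECTION_WINDOW_MS

    @property
    def modulated(self) -> bool:
        return self.direction != "none"


@dataclass(frozen=True)
class ZScoredPeth:
    unit_id: str
    event_type: EventType
    z_per_bin: np.ndarray
    baseline: BaselineStats
    window_ms: tuple[float, float] = PETH_WINDOW_MS
    bin_width_ms: float = BIN_WIDTH_MS
    undefined: bool = False  # degenerate baseline (sd = 0) with off-mean bins

    def __post_init__(self):
        object.__setattr__(self, "z_per_bin", np.asarray(self.z_per_bin, dtype=float))

    @property
    def bin_left_edges_ms(self) -> np.ndarray:
        return self.window_ms[0] + self.bin_width_ms * np.arange(len(self.z_per_bin))

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_left_edges_ms + self.bin_width_ms / 2.0


@dataclass(frozen=True)
class EpochSummary:
    """Mean z in four consecutive 250-ms bins of a named epoch."""

    unit_id: str
    epoch: str
    bin_means: tuple[float, float, float, float]


# ---------------------------------------------------------------------------


def bin_spikes(
    unit: UnitRecording,
    event_times: Sequence[float] | np.ndarray,
    window_ms: tuple[float, float] = PETH_WINDOW_MS,
    bin_width_ms: float = BIN_WIDTH_MS,
    event_type: EventType = "press_onset",
) -> Peth:
    """Average event-aligned spike counts into a rate PETH (Hz).

    Bins are half-open ``[left, right)`` relative to each event. Windows of
    nearby events may overlap; a spike then counts toward each event.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events")
    start, stop = window_ms
    n_bins = (stop - start) / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the window length")
    n_bins = int(round(n_bins))
    edges = start + bin_width_ms * np.arange(n_bins + 1)
    spikes = np.asarray(unit.spike_times, dtype=float)
    counts = np.zeros(n_bins)
    for e in event_times:
        pos = np.searchsorted(spikes, e + edges, side="left")
        counts += np.diff(pos)
    rate = counts / (len(event_times) * bin_width_ms / 1000.0)
    return Peth(
        unit_id=unit.unit_id,
        event_type=event_type,
        window_ms=window_ms,
        bin_width_ms=bin_width_ms,
        rate_per_bin=rate,
        n_events=len(event_times),
        smoothed=False,
    )


def smooth_peth(peth: Peth, sigma_bins: float = SMOOTH_SIGMA_BINS) -> Peth:
    """Gaussian-weighted moving average over three bins.

    The 3-tap kernel is ``exp(-k^2 / (2 sigma^2))`` for k in {-1, 0, 1},
    normalized to sum to one; at the edges the kernel is truncated and
    renormalized so a constant signal stays constant.
    """
    if peth.smoothed:
        raise ValueError("PETH already smoothed")
    w = np.exp(-1.0 / (2.0 * sigma_bins**2))
    kernel = np.array([w, 1.0, w])
    num = np.convolve(peth.rate_per_bin, kernel, mode="same")
    den = np.convolve(np.ones(peth.n_bins), kernel, mode="same")
    return Peth(
        unit_id=peth.unit_id,
        event_type=peth.event_type,
        window_ms=peth.window_ms,
        bin_width_ms=peth.bin_width_ms,
        rate_per_bin=num / den,
        n_events=peth.n_events,
        smoothed=True,
    )


def baseline_stats(
    peth: Peth, window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> BaselineStats:
    """Mean, sample SD, and empirical 95% interval of the baseline bins.

    The interval is the 2.5th/97.5th percentile of the trial-averaged
    baseline bin values (the distribution of the PETH over the baseline
    window), computed from the press-onset-aligned smoothed PETH.
    """
    idx = peth.slice_bins(*window_ms)
    if idx.size == 0:
        raise ValueError("baseline window outside PETH window")
    vals = peth.rate_per_bin[idx]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BaselineStats(
        mean_hz=float(np.mean(vals)),
        sd_hz=sd,
        lower95_hz=float(lo),
        upper95_hz=float(hi),
        window_ms=window_ms,
        n_bins=len(vals),
    )


def _runs_of_true(mask: np.ndarray, min_len: int) -> list[int]:
    """Start indices of maximal True runs with length >= min_len."""
    starts = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                starts.append(i)
            i = j
        else:
            i += 1
    return starts


def detect_modulation(
    peth: Peth,
    baseline: BaselineStats,
    window_ms: tuple[float, float] = DETECTION_WINDOW_MS,
    min_bins: int = MIN_CONSECUTIVE_BINS,
) -> ModulationResult:
    """Classify a unit's event-aligned response against its baseline interval.

    Up-modulated: >= ``min_bins`` consecutive bins above the baseline upper
    95% bound within the detection window; down-modulated symmetrically
    below the lower bound. If both occur, the direction of the earlier
    qualifying run wins (tie: up); both flags are retained. Onset latency
    is the left edge of the first bin of the first qualifying run.
    """
    idx = peth.slice_bins(*window_ms)
    if idx.size == 0:
        raise ValueError("detection window outside PETH window")
    rates = peth.rate_per_bin[idx]
    edges = peth.bin_left_edges_ms[idx]
    up_starts = _runs_of_true(rates > baseline.upper95_hz, min_bins)
    down_starts = _runs_of_true(rates < baseline.lower95_hz, min_bins)
    has_up, has_down = bool(up_starts), bool(down_starts)
    direction: Direction = "none"
    onset = None
    if has_up or has_down:
        first_up = up_starts[0] if has_up else np.inf
        first_down = down_starts[0] if has_down else np.inf
        direction = "up" if first_up <= first_down else "down"
        onset = float(edges[int(min(first_up, first_down))])
    return ModulationResult(
        unit_id=peth.unit_id,
        event_type=peth.event_type,
        direction=direction,
        onset_latency_ms=onset,
        has_up_run=has_up,
        has_down_run=has_down,
        window_ms=window_ms,
    )


def zscore_peth(peth: Peth, baseline: BaselineStats) -> ZScoredPeth:
    """z-score each bin against the baseline mean and SD.

    With a degenerate baseline (SD = 0), bins equal to the mean get z = 0
    and any other bin makes the trace undefined; undefined traces are
    flagged so population averaging can exclude them with a logged
    warning.
    """
    rates = peth.rate_per_bin
    if baseline.sd_hz > 0:
        z = (rates - baseline.mean_hz) / baseline.sd_hz
        undefined = False
    else:
        off_mean = rates != baseline.mean_hz
        z = np.where(off_mean, np.nan, 0.0)
        undefined = bool(off_mean.any())
        if undefined:
            logger.warning(
                "unit %s (%s): zero baseline SD with non-baseline rates; "
                "z-trace flagged undefined",
                peth.unit_id,
                peth.event_type,
            )
    return ZScoredPeth(
        unit_id=peth.unit_id,
        event_type=peth.event_type,
        z_per_bin=z,
        baseline=baseline,
        window_ms=peth.window_ms,
        bin_width_ms=peth.bin_width_ms,
        undefined=undefined,
    )


def unit_baseline(
    unit: UnitRecording,
    session: BehavioralSession,
    sigma_bins: float = SMOOTH_SIGMA_BINS,
) -> BaselineStats:
    """The unit's single baseline: press-onset-aligned over all presses.

    One baseline period serves every alignment (onset, offset, reward) of
    the same unit.
    """
    peth = smooth_peth(
        bin_spikes(unit, session.press_onsets, event_type="press_onset"),
        sigma_bins=sigma_bins,
    )
    return baseline_stats(peth)


def event_times_for(session: BehavioralSession, event_type: EventType) -> np.ndarray:
    if event_type == "press_onset":
        return session.press_onsets
    if event_type == "press_offset":
        return session.press_offsets
    if event_type == "reward":
        return session.reward_times
    raise ValueError(f"unknown event type {event_type!r}")


def split_by_outcome(
    unit: UnitRecording,
    session: BehavioralSession,
    event_type: EventType = "press_offset",
    baseline: BaselineStats | None = None,
    sigma_bins: float = SMOOTH_SIGMA_BINS,
) -> tuple[Optional[ZScoredPeth], Optional[ZScoredPeth]]:
    """Success and failure PETHs, each z-scored against the all-press baseline.

    A class with zero events yields ``None`` for that PETH (logged).
    """
    mask = success_mask(session)
    if event_type == "reward":
        raise ValueError("reward alignment has no failure events to split")
    events = event_times_for(session, event_type)
    if baseline is None:
        baseline = unit_baseline(unit, session, sigma_bins=sigma_bins)
    out: list[Optional[ZScoredPeth]] = []
    for label, sel in (("success", mask), ("failure", ~mask)):
        sub = events[sel]
        if sub.size == 0:
            logger.info(
                "unit %s: no %s presses; %s PETH absent", unit.unit_id, label, label
            )
            out.append(None)
            continue
        peth = smooth_peth(
            bin_spikes(unit, sub, event_type=event_type), sigma_bins=sigma_bins
        )
        out.append(zscore_peth(peth, baseline))
    return out[0], out[1]


def classify_unit_events(
    results: Iterable[ModulationResult],
) -> frozenset[str]:
    """Membership category: the set of events at which the unit modulates.

    Direction-agnostic; one of the eight subsets of
    {press_onset, press_offset, reward}.
    """
    return frozenset(r.event_type for r in results if r.modulated)


def epoch_summary(z: ZScoredPeth, epoch: str) -> EpochSummary:
    """Mean z in the four consecutive 250-ms bins of a named epoch.

    Each 20-ms bin is assigned to the 250-ms bin containing its left edge,
    so bins hold 12 or 13 constituent values (250 / 20 = 12.5).
    """
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {sorted(EPOCHS)}")
    start, stop = EPOCHS[epoch]
    if start < z.window_ms[0] or stop > z.window_ms[1]:
        raise ValueError("epoch outside PETH window")
    edges = z.bin_left_edges_ms
    means = []
    for k in range(4):
        lo = start + k * EPOCH_BIN_MS
        hi = start + (k + 1) * EPOCH_BIN_MS
        sel = (edges >= lo) & (edges < hi)
        means.append(float(np.mean(z.z_per_bin[sel])))
    return EpochSummary(unit_id=z.unit_id, epoch=epoch, bin_means=tuple(means))


@dataclass(frozen=True)
class GroupTrace:
    group: str
    mean: np.ndarray
    sem: np.ndarray
    n_units: int
    bin_centers_ms: np.ndarray


def group_average(
    zs: Sequence[ZScoredPeth], groups: Sequence[str]
) -> dict[str, GroupTrace]:
    """Unweighted per-bin mean +/- SEM across units within each group.

    Up- and down-modulated units are combined in a single population
    trace. Traces flagged undefined are excluded with a warning.
    """
    if len(zs) != len(groups):
        raise ValueError("zs and groups must have equal length")
    by_group: dict[str, list[ZScoredPeth]] = {}
    for z, g in zip(zs, groups):
        if z.undefined:
            logger.warning("unit %s excluded from group average (undefined z)", z.unit_id)
            continue
        by_group.setdefault(g, []).append(z)
    if not by_group:
        raise ValueError("no units to average")
    out = {}
    for g, members in by_group.items():
        mat = np.vstack([z.z_per_bin for z in members])
        mean = mat.mean(axis=0)
        sem = (
            mat.std(axis=0, ddof=1) / np.sqrt(len(members))
            if len(members) > 1
            else np.zeros(mat.shape[1])
        )
        out[g] = GroupTrace(
            group=g,
            mean=mean,
            sem=sem,
            n_units=len(members),
            bin_centers_ms=members[0].bin_centers_ms,
        )
    return out
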