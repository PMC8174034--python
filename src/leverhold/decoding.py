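"""Pseudo-population decoding of press success from event-aligned spiking.

Units recorded in different sessions are pooled into a pseudo-population:
for each resampling run, every unit independently contributes the 1-ms
raster of randomly drawn success and failure events, and the k-th drawn
event of each unit is stitched into pseudo-trial k. A linear
maximum-margin classifier (SVM) is trained and tested on sliding-window
firing-rate features (200-ms bins stepped every 100 ms) with 10-fold
cross-validation, and the run-averaged accuracy is compared against
shuffled-label null distributions (5 nulls x 500 runs by default) with an
empirical one-sided p-value and Benjamini-Hochberg correction over time
points.

Only sessions with at least 10 successful presses enter the analysis.
Because units come from different sessions, within-session noise
correlations are not preserved — an inherent limit of pseudo-population
decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core import BehavioralSession, Dataset, UnitRecording, success_mask
from .peth import event_times_for

logger = logging.getLogger(__name__)

Alignment = Literal["press_onset", "press_offset"]

RASTER_WINDOW_MS = (-2000.0, 10_000.0)
RASTER_BIN_MS = 1.0
SLIDE_STEP_MS = 100.0
SLIDE_WIDTH_MS = 200.0
N_SPLITS = 10
N_RUNS = 500
N_NULLS = 5
MIN_SUCCESSES = 10
SVM_C = 1.0


def session_inclusion(
    session: BehavioralSession, min_successes: int = MIN_SUCCESSES
) -> bool:
    """True iff the session has at least ``min_successes`` successful presses."""
    if session.n_presses == 0:
        return False
    return int(success_mask(session).sum()) >= min_successes


@dataclass(frozen=True)
class PseudoTrialSet:
    """One draw of balanced pseudo-trials: unit x trial x 1-ms-bin counts."""

    unit_ids: tuple[str, ...]
    n_per_class: int
    labels: np.ndarray  # (2 * n_per_class,) of {1: success, 0: failure}
    counts: np.ndarray  # (n_units, 2 * n_per_class, n_bins) int16
    alignment: Alignment
    window_ms: tuple[float, float] = RASTER_WINDOW_MS

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def _eligible_units(
    dataset: Dataset, n_per_class: Optional[int], min_successes: int
) -> tuple[list[tuple[UnitRecording, np.ndarray, np.ndarray]], int]:
    """Units from included sessions with their per-class event times."""
    per_unit = []
    for u in dataset.units:
        s = dataset.session(u.session_id)
        if not session_inclusion(s, min_successes):
            logger.info(
                "unit %s excluded: session %s below %d successes",
                u.unit_id, s.session_id, min_successes,
            )
            continue
        per_unit.append((u, success_mask(s)))
    if not per_unit:
        raise ValueError("no units from included sessions")
    min_count = min(min(int(m.sum()), int((~m).sum())) for _, m in per_unit)
    if n_per_class is None:
        n_per_class = min_count
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1 (some unit has an empty class)")
    return per_unit, n_per_class


def build_pseudopopulation(
    dataset: Dataset,
    alignment: Alignment = "press_offset",
    n_per_class: Optional[int] = None,
    seed: int | np.random.Generator = 0,
    min_successes: int = MIN_SUCCESSES,
) -> PseudoTrialSet:
    """Draw one balanced pseudo-trial set from the eligible units.

    Each unit independently draws ``n_per_class`` success and failure
    events without replacement; the k-th drawn event of every unit forms
    pseudo-trial k. Units with fewer than ``n_per_class`` events in either
    class are dropped with a warning. ``n_per_class`` defaults to the
    minimum per-class count over eligible units. Deterministic for a
    fixed seed.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    eligible, n_per_class = _eligible_units(dataset, n_per_class, min_successes)
    start, stop = RASTER_WINDOW_MS
    n_bins = int(round((stop - start) / RASTER_BIN_MS))
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    for u, mask in eligible:
        session = dataset.session(u.session_id)
        events = event_times_for(session, alignment)
        succ, fail = events[mask], events[~mask]
        if len(succ) < n_per_class or len(fail) < n_per_class:
            logger.warning(
                "unit %s dropped: fewer than %d events in a class",
                u.unit_id, n_per_class,
            )
            continue
        drawn = np.concatenate(
            [
                rng.choice(succ, size=n_per_class, replace=False),
                rng.choice(fail, size=n_per_class, replace=False),
            ]
        )
        unit_counts = np.zeros((2 * n_per_class, n_bins), dtype=np.int16)
        st = u.spike_times
        for k, e in enumerate(drawn):
            a = np.searchsorted(st, e + start, side="left")
            b = np.searchsorted(st, e + start + n_bins * RASTER_BIN_MS, side="left")
            idx = ((st[a:b] - (e + start)) // RASTER_BIN_MS).astype(np.intp)
            idx = idx[idx < n_bins]  # float-edge guard
            np.add.at(unit_counts[k], idx, 1)
        rows.append(unit_counts)
        kept_ids.append(u.unit_id)
    if not rows:
        raise ValueError("no units remain after the per-class count filter")
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)]
    )
    return PseudoTrialSet(
        unit_ids=tuple(kept_ids),
        n_per_class=n_per_class,
        labels=labels,
        counts=np.stack(rows),
        alignment=alignment,
    )


def sliding_features(
    pts: PseudoTrialSet,
    step_ms: float = SLIDE_STEP_MS,
    width_ms: float = SLIDE_WIDTH_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window firing-rate features from the 1-ms rasters.

    Returns ``(time_centers_ms, features)`` with features shaped
    (n_times, n_trials, n_units) in Hz; the feature at center t is the
    spike count in ``[t - width/2, t + width/2)`` scaled to a rate. Time
    centers span the raster window wherever the full width fits.
    """
    start, stop = pts.window_ms
    half = width_ms / 2.0
    centers = np.arange(start + half, stop - half + 1e-9, step_ms)
    n_bins = pts.counts.shape[2]
    lo = np.round((centers - half - start) / RASTER_BIN_MS).astype(int)
    hi = np.round((centers + half - start) / RASTER_BIN_MS).astype(int)
    # segment sums between consecutive needed cut points avoid a full
    # cumulative sum over the 1-ms rasters
    cuts = np.unique(np.concatenate(([0], lo, hi, [n_bins])))
    inner = cuts[:-1]
    # per-unit cast keeps the transient int64 copy small
    seg = np.stack(
        [
            np.add.reduceat(pts.counts[i].astype(np.int64), inner, axis=1)
            for i in range(pts.counts.shape[0])
        ]
    )
    cum = np.zeros(pts.counts.shape[:2] + (len(cuts),), dtype=np.int64)
    np.cumsum(seg, axis=2, out=cum[:, :, 1:])
    pos_lo = np.searchsorted(cuts, lo)
    pos_hi = np.searchsorted(cuts, hi)
    window_counts = cum[:, :, pos_hi] - cum[:, :, pos_lo]  # (units, trials, times)
    feats = window_counts.astype(float) * (1000.0 / width_ms)
    return centers, np.transpose(feats, (2, 1, 0))


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int,
    rng: np.random.Generator,
    C: float = SVM_C,
) -> float:
    """Mean test accuracy of a linear SVM over stratified CV folds.

    Features are z-scored per unit by training-fold statistics to avoid
    test-set leakage; folds degenerate to a single class are skipped.
    """
    skf = StratifiedKFold(
        n_splits=n_splits,
        shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    accs = []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            logger.info("degenerate CV fold skipped")
            continue
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train] - mu) / sd, y[train])
        accs.append(clf.score((X[test] - mu) / sd, y[test]))
    return float(np.mean(accs))


@dataclass(frozen=True)
class DecodingResult:
    time_centers_ms: np.ndarray
    accuracy: np.ndarray  # run-averaged, per time point
    run_accuracies: np.ndarray  # (n_runs, n_times)
    null_accuracies: Optional[np.ndarray] = None  # (n_nulls, n_runs, n_times)
    p_raw: Optional[np.ndarray] = None
    significant_raw: Optional[np.ndarray] = None
    significant_bh: Optional[np.ndarray] = None
    alignment: Alignment = "press_offset"
    n_units: int = 0
    n_per_class: int = 0


def decode_timecourse(
    pts_builder: Callable[[np.random.Generator], PseudoTrialSet],
    n_runs: int = N_RUNS,
    n_splits: int = N_SPLITS,
    seed: int = 0,
    step_ms: float = SLIDE_STEP_MS,
    width_ms: float = SLIDE_WIDTH_MS,
    C: float = SVM_C,
    shuffle_labels: bool = False,
    t_range: Optional[tuple[float, float]] = None,
) -> DecodingResult:
    """Run-averaged sliding-window decoding accuracy.

    Each run rebuilds the pseudo-trials with fresh event draws, computes
    sliding features, and scores a linear SVM with stratified
    cross-validation at every time point (restricted to ``t_range`` when
    given). With ``shuffle_labels`` the class labels are permuted once
    per run (the null procedure). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    run_accs = None
    centers = None
    meta = {}
    for r in range(n_runs):
        pts = pts_builder(rng)
        centers, feats = sliding_features(pts, step_ms=step_ms, width_ms=width_ms)
        if t_range is not None:
            keep = (centers >= t_range[0]) & (centers <= t_range[1])
            centers, feats = centers[keep], feats[keep]
        y = pts.labels
        if shuffle_labels:
            y = rng.permutation(y)
        if run_accs is None:
            run_accs = np.empty((n_runs, len(centers)))
            meta = dict(n_units=pts.n_units, n_per_class=pts.n_per_class,
                        alignment=pts.alignment)
        for ti in range(len(centers)):
            run_accs[r, ti] = _cv_accuracy(feats[ti], y, n_splits, rng, C=C)
    return DecodingResult(
        time_centers_ms=centers,
        accuracy=run_accs.mean(axis=0),
        run_accuracies=run_accs,
        **meta,
    )


def null_distributions(
    pts_builder: Callable[[np.random.Generator], PseudoTrialSet],
    n_nulls: int = N_NULLS,
    n_runs: int = N_RUNS,
    n_splits: int = N_SPLITS,
    seed: int = 0,
    step_ms: float = SLIDE_STEP_MS,
    width_ms: float = SLIDE_WIDTH_MS,
    C: float = SVM_C,
    t_range: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Shuffled-label null accuracies, shaped (n_nulls, n_runs, n_times)."""
    nulls = []
    for k in range(n_nulls):
        res = decode_timecourse(
            pts_builder,
            n_runs=n_runs,
            n_splits=n_splits,
            seed=seed + 10_000 * (k + 1),
            step_ms=step_ms,
            width_ms=width_ms,
            C=C,
            shuffle_labels=True,
            t_range=t_range,
        )
        nulls.append(res.run_accuracies)
    return np.stack(nulls)


def significance_mask(
    result: DecodingResult,
    null_accuracies: np.ndarray,
    alpha: float = 0.05,
) -> DecodingResult:
    """Empirical one-sided p-values against the pooled nulls, with BH.

    p(t) = (1 + #{pooled null accuracies at t >= observed}) / (1 + N_null);
    ``significant_raw`` marks p <= alpha, ``significant_bh`` applies
    Benjamini-Hochberg over all time points at the same alpha.
    """
    pooled = null_accuracies.reshape(-1, null_accuracies.shape[-1])
    n_null = pooled.shape[0]
    exceed = (pooled >= result.accuracy[None, :]).sum(axis=0)
    p_raw = (1.0 + exceed) / (1.0 + n_null)
    sig_raw = p_raw <= alpha
    sig_bh = multipletests(p_raw, alpha=alpha, method="fdr_bh")[0]
    return DecodingResult(
        time_centers_ms=result.time_centers_ms,
        accuracy=result.accuracy,
        run_accuracies=result.run_accuracies,
        null_accuracies=null_accuracies,
        p_raw=p_raw,
        significant_raw=sig_raw,
        significant_bh=sig_bh,
        alignment=result.alignment,
        n_units=result.n_units,
        n_per_class=result.n_per_class,
    )
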