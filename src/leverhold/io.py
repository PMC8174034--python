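"""Reading and writing the delimited-text table dialects.

Two tables describe a dataset:

* **session table** — one row per press, columns ``session_id, mouse_id,
  group, criterion_ms, press_index, onset_ms, offset_ms, rewarded,
  session_end_ms``;
* **spike table** — one row per spike, columns ``unit_id, session_id,
  spike_time_ms``.

Both are comma-separated UTF-8 with a header row. Row order is irrelevant
to the loaded result; writers emit the same dialects with floating times at
millisecond precision (>= 3 decimals).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BehavioralSession,
    Dataset,
    FormatError,
    Group,
    UnitRecording,
)

SESSION_COLUMNS = [
    "session_id",
    "mouse_id",
    "group",
    "criterion_ms",
    "press_index",
    "onset_ms",
    "offset_ms",
    "rewarded",
    "session_end_ms",
]
SPIKE_COLUMNS = ["unit_id", "session_id", "spike_time_ms"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def load_dataset(
    session_table_path: os.PathLike | str,
    spike_table_path: os.PathLike | str,
    validate: bool = True,
    enforce_task_limits: bool = True,
) -> Dataset:
    """Load and validate a dataset from the two-table dialect."""
    sess_df = pd.read_csv(session_table_path, float_precision="round_trip")
    spike_df = pd.read_csv(spike_table_path, float_precision="round_trip")
    _require_columns(sess_df, SESSION_COLUMNS, session_table_path)
    _require_columns(spike_df, SPIKE_COLUMNS, spike_table_path)

    sessions = []
    for sid, g in sess_df.groupby("session_id", sort=True):
        g = g.sort_values("press_index")
        meta = g.iloc[0]
        rewarded = g["rewarded"].astype(int).to_numpy()
        offsets = g["offset_ms"].to_numpy(dtype=float)
        sessions.append(
            BehavioralSession(
                session_id=str(sid),
                mouse_id=str(meta["mouse_id"]),
                group=Group(str(meta["group"])),
                criterion_ms=int(meta["criterion_ms"]),
                press_onsets=g["onset_ms"].to_numpy(dtype=float),
                press_offsets=offsets,
                reward_times=offsets[rewarded == 1],
                session_end_ms=float(meta["session_end_ms"]),
            )
        )

    units = []
    for (uid, sid), g in spike_df.groupby(["unit_id", "session_id"], sort=True):
        units.append(
            UnitRecording(
                unit_id=str(uid),
                session_id=str(sid),
                spike_times=np.sort(g["spike_time_ms"].to_numpy(dtype=float)),
            )
        )

    ds = Dataset(
        sessions=tuple(sessions),
        units=tuple(units),
        provenance=f"loaded from {session_table_path} + {spike_table_path}",
    )
    if validate:
        ds.validate(enforce_task_limits=enforce_task_limits)
    return ds


def session_table(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for s in dataset.sessions:
        rewarded_offsets = set(s.reward_times.tolist())
        for i, (on, off) in enumerate(zip(s.press_onsets, s.press_offsets)):
            rows.append(
                dict(
                    session_id=s.session_id,
                    mouse_id=s.mouse_id,
                    group=s.group.value,
                    criterion_ms=s.criterion_ms,
                    press_index=i,
                    onset_ms=on,
                    offset_ms=off,
                    rewarded=int(off in rewarded_offsets),
                    session_end_ms=s.session_end_ms,
                )
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def spike_table(dataset: Dataset) -> pd.DataFrame:
    rows = [
        dict(unit_id=u.unit_id, session_id=u.session_id, spike_time_ms=t)
        for u in dataset.units
        for t in u.spike_times
    ]
    return pd.DataFrame(rows, columns=SPIKE_COLUMNS)


def write_dataset(
    dataset: Dataset,
    session_table_path: os.PathLike | str,
    spike_table_path: os.PathLike | str,
) -> None:
    """Write a dataset in the same dialects ``load_dataset`` reads.

    Timestamps are written with enough precision to round-trip exactly
    (behavioral times are 10-ms-grid integers; spike times are printed via
    repr so ``write . load`` is the identity on valid inputs).
    """
    Path(session_table_path).parent.mkdir(parents=True, exist_ok=True)
    Path(spike_table_path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g prints enough digits to round-trip any double bit-exactly
    session_table(dataset).to_csv(
        session_table_path, index=False, float_format="%.17g"
    )
    spike_table(dataset).to_csv(spike_table_path, index=False, float_format="%.17g")
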