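"""Oddball reaction times and session metadata validation.

The oddball task presents a stream of standard (80 %) and deviant (20 %)
stimuli; the participant presses a button on deviants.  Reaction time is
the latency from deviant onset to the first button press falling inside
a valid-response window — by default 0.1–1.0 s, where the lower bound
excludes anticipations and the upper bound equals the inter-stimulus
interval so a press can never be re-assigned across stimuli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

EVENT_KINDS = ("standard", "deviant", "press")

DEFAULT_VALID_WINDOW_S: tuple[float, float] = (0.1, 1.0)

#: Required columns of the per-session metadata table.
SESSION_TABLE_COLUMNS = ("subject", "session", "sss", "sleep_min")


@dataclass
class OddballLog:
    """Ordered event log of one oddball run.

    ``events`` is a DataFrame with columns ``time_s`` (float, non-decreasing),
    ``kind`` (standard / deviant / press) and ``modality`` (audio / visual,
    constant within one log).
    """

    events: pd.DataFrame
    subject: int | str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        required = {"time_s", "kind", "modality"}
        missing = required - set(self.events.columns)
        if missing:
            raise SchemaError(f"oddball log missing columns: {sorted(missing)}")
        times = self.events["time_s"].to_numpy(dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be non-decreasing")
        bad = set(self.events["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        modalities = set(self.events["modality"].unique())
        if len(modalities) > 1:
            raise ValueError(f"mixed modalities in one log: {sorted(modalities)}")

    @property
    def modality(self) -> str | None:
        if len(self.events):
            return str(self.events["modality"].iloc[0])
        return None

    def times_of(self, kind: str) -> np.ndarray:
        return self.events.loc[self.events["kind"] == kind, "time_s"].to_numpy(
            dtype=float
        )


@dataclass
class RTResult:
    """Reaction-time bookkeeping for one log.

    ``hits + misses`` always equals the number of deviants; each press is
    assigned to at most one deviant, and presses matching no deviant are
    false alarms.  ``mean_rt_s`` is NaN when there are no hits.
    """

    mean_rt_s: float
    n_hits: int
    n_misses: int
    n_false_alarms: int
    rts_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def extract_reaction_times(
    log: OddballLog,
    valid_window_s: tuple[float, float] = DEFAULT_VALID_WINDOW_S,
) -> RTResult:
    """Assign presses to deviants and summarize reaction times.

    For each deviant (in time order) the first unassigned press with
    latency in ``[lo, hi]`` is its response; deviants without one are
    misses.  A log without deviants yields the defined empty result.
    """
    lo, hi = valid_window_s
    if not (0.0 <= lo < hi):
        raise ValueError(f"invalid response window {valid_window_s}")
    deviants = log.times_of("deviant")
    presses = log.times_of("press")
    used = np.zeros(presses.size, dtype=bool)
    rts = []
    n_miss = 0
    start = 0
    for onset in deviants:
        hit_idx = -1
        for j in range(start, presses.size):
            if used[j]:
                continue
            lat = presses[j] - onset
            if lat < lo:
                continue
            if lat > hi:
                break
            hit_idx = j
            break
        if hit_idx >= 0:
            used[hit_idx] = True
            rts.append(presses[hit_idx] - onset)
            # presses are sorted and latencies only shrink for later deviants,
            # so skipped earlier presses can never become hits
            start = hit_idx
        else:
            n_miss += 1
    rts = np.asarray(rts, dtype=float)
    n_false = int((~used).sum())
    mean_rt = float(rts.mean()) if rts.size else math.nan
    return RTResult(
        mean_rt_s=mean_rt,
        n_hits=int(rts.size),
        n_misses=n_miss,
        n_false_alarms=n_false,
        rts_s=rts,
    )


@dataclass
class TableIssue:
    """A single validation finding with the offending row index."""

    row: int
    column: str
    message: str


def validate_session_table(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[TableIssue]]:
    """Check the per-session metadata table and drop invalid rows.

    Flags SSS scores outside {1..7} (or non-integer), negative sleep
    durations, and duplicated (subject, session) pairs; every violation is
    reported with its row index.  Missing required columns raise
    :class:`SchemaError`.
    """
    missing = [c for c in SESSION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"session table missing columns: {missing}")
    issues: list[TableIssue] = []
    bad_rows: set[int] = set()

    for idx, row in table.iterrows():
        sss = row["sss"]
        if not (float(sss).is_integer() and 1 <= int(sss) <= 7):
            issues.append(TableIssue(idx, "sss", f"SSS {sss!r} outside 1..7"))
            bad_rows.add(idx)
        if row["sleep_min"] < 0:
            issues.append(
                TableIssue(idx, "sleep_min", f"negative sleep {row['sleep_min']!r}")
            )
            bad_rows.add(idx)

    dup_mask = table.duplicated(subset=["subject", "session"], keep=False)
    for key, grp in table[dup_mask].groupby(["subject", "session"]):
        rows = list(grp.index)
        for idx in rows:
            issues.append(
                TableIssue(
                    idx,
                    "subject/session",
                    f"duplicate (subject {key[0]}, {key[1]}) at rows {rows}",
                )
            )
            bad_rows.add(idx)

    clean = table.drop(index=sorted(bad_rows))
    return clean, issues
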