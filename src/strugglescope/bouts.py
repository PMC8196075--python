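"""Struggle-bout segmentation, typing, and per-session summaries.

A bout opens at any frame where some tracked point transitions from
immobile to mobile while no bout is open (that frame is time 0.0 of the
bout), and it closes once every tracked point has been immobile for
strictly more than the gap parameter (0.7 s by default; at 10 fps that is a
run of at least 8 all-immobile frames). Mobile episodes separated by
all-immobile runs of at most the gap are merged into a single bout. A
bout's offset is its last frame with any point mobile; duration includes
the onset frame (``duration = offset - onset + 1/fps``).

Bouts are typed by which points moved within them: ``head_only``,
``tail_only``, or ``full_body`` (both the head fiber and the tail tip have
at least one mobile frame anywhere inside the bout — the movements need not
share a frame).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, StruggleScopeError
from .kinematics import HEAD_POINT, TAIL_POINT, MobilitySeries

BOUT_TYPES = ("head_only", "tail_only", "full_body")

__all__ = [
    "BOUT_TYPES",
    "Bout",
    "BoutTable",
    "BoutSummary",
    "segment_bouts",
    "classify_bout_type",
    "summarize_bouts",
    "count_bouts_by_day",
]


@dataclass
class Bout:
    """One typed struggle bout, in seconds and in frames."""

    onset_s: float
    offset_s: float
    duration_s: float
    bout_type: str
    onset_frame: int
    offset_frame: int
    mobile_frames: dict[str, int]
    truncated: bool = False


@dataclass
class BoutTable:
    """Ordered, non-overlapping bouts for one session."""

    bouts: list[Bout]
    session_s: float
    gap_s: float
    fps: float
    session_id: str = "session"

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def of_type(self, bout_type: str) -> list[Bout]:
        return [b for b in self.bouts if b.bout_type == bout_type]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": self.session_id,
                "onset_s": [b.onset_s for b in self.bouts],
                "offset_s": [b.offset_s for b in self.bouts],
                "duration_s": [b.duration_s for b in self.bouts],
                "type": [b.bout_type for b in self.bouts],
                "truncated": [b.truncated for b in self.bouts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_bed(self, path) -> None:
        """Write bouts as 0-based half-open frame intervals (BED-like)."""
        df = pd.DataFrame(
            {
                "chrom": self.session_id,
                "start": [b.onset_frame for b in self.bouts],
                "end": [b.offset_frame + 1 for b in self.bouts],
                "name": [b.bout_type for b in self.bouts],
            }
        )
        df.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class BoutSummary:
    """Per-type counts/durations and percent-of-session breakdown."""

    counts: dict[str, int]
    total_s: dict[str, float]
    mean_s: dict[str, float]
    percent_of_session: dict[str, float]
    percent_immobile: float
    session_s: float


def classify_bout_type(
    bout_mobility: np.ndarray,
    point_names: list[str],
    head: str = HEAD_POINT,
    tail: str = TAIL_POINT,
) -> str:
    """Type a bout from the per-point mobility inside [onset, offset].

    ``full_body`` requires at least one mobile frame for both the head and
    the tail anywhere within the bout; otherwise the bout is ``head_only``
    or ``tail_only``.
    """
    bout_mobility = np.asarray(bout_mobility, dtype=bool)
    if not bout_mobility.any():
        raise StruggleScopeError("bout contains no mobile frames")
    counts = bout_mobility.sum(axis=0)
    head_moved = head in point_names and counts[point_names.index(head)] > 0
    tail_moved = tail in point_names and counts[point_names.index(tail)] > 0
    if head_moved and tail_moved:
        return "full_body"
    if tail_moved:
        return "tail_only"
    return "head_only"


def _mobile_runs(any_mobile: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, stop) frame pairs."""
    idx = np.flatnonzero(any_mobile)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def segment_bouts(
    mob: MobilitySeries, gap_s: float = 0.7, session_id: str = "session"
) -> BoutTable:
    """Segment a mobility series into bouts using the gap-merge rule.

    A bout terminates only after strictly more than ``gap_s`` of
    consecutive all-immobile frames; shorter immobile runs are absorbed
    into the bout. Bouts cut off by the end of the session (no full
    closing run observed) are kept and flagged ``truncated``.
    """
    if gap_s <= 0:
        raise ConfigError("gap_s must be positive")
    fps = mob.fps
    if gap_s < 1.0 / fps:
        raise ConfigError(
            f"gap_s={gap_s} is finer than one frame at fps={fps}"
        )
    # Largest all-immobile run (in frames) that does NOT terminate a bout.
    max_merge_frames = int(np.floor(gap_s * fps + 1e-9))

    runs = _mobile_runs(mob.mobile.any(axis=1))
    n_frames = mob.n_frames
    bouts: list[Bout] = []
    group: list[tuple[int, int]] = []

    def _close(group: list[tuple[int, int]]) -> None:
        onset_f, offset_f = group[0][0], group[-1][1]
        window = mob.mobile[onset_f : offset_f + 1]
        btype = classify_bout_type(window, mob.point_names)
        counts = {
            name: int(window[:, j].sum()) for j, name in enumerate(mob.point_names)
        }
        truncated = (n_frames - 1 - offset_f) <= max_merge_frames
        onset_s = onset_f / fps
        offset_s = offset_f / fps
        bouts.append(
            Bout(
                onset_s=onset_s,
                offset_s=offset_s,
                duration_s=offset_s - onset_s + 1.0 / fps,
                bout_type=btype,
                onset_frame=onset_f,
                offset_frame=offset_f,
                mobile_frames=counts,
                truncated=truncated,
            )
        )

    for run in runs:
        if group and (run[0] - group[-1][1] - 1) > max_merge_frames:
            _close(group)
            group = []
        group.append(run)
    if group:
        _close(group)

    return BoutTable(
        bouts=bouts,
        session_s=n_frames / fps,
        gap_s=gap_s,
        fps=fps,
        session_id=session_id,
    )


def summarize_bouts(table: BoutTable) -> BoutSummary:
    """Counts, total time, mean duration and percent-of-session per type."""
    counts: dict[str, int] = {}
    total: dict[str, float] = {}
    mean: dict[str, float] = {}
    pct: dict[str, float] = {}
    for t in BOUT_TYPES:
        sel = table.of_type(t)
        counts[t] = len(sel)
        total[t] = float(sum(b.duration_s for b in sel))
        mean[t] = float(total[t] / len(sel)) if sel else 0.0
        pct[t] = 100.0 * total[t] / table.session_s
    return BoutSummary(
        counts=counts,
        total_s=total,
        mean_s=mean,
        percent_of_session=pct,
        percent_immobile=100.0 - sum(pct.values()),
        session_s=table.session_s,
    )


def count_bouts_by_day(
    tables: dict[tuple[str, int], BoutTable], bout_type: str = "full_body"
) -> pd.DataFrame:
    """Long-format (subject, day, count) table of per-session bout counts.

    ``tables`` maps ``(subject, day)`` to that session's :class:`BoutTable`.
    The output is ready for paired/repeated-measures statistics.
    """
    rows = [
        {"subject": subj, "day": day, "count": len(tab.of_type(bout_type))}
        for (subj, day), tab in sorted(tables.items())
    ]
    return pd.DataFrame(rows, columns=["subject", "day", "count"])
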