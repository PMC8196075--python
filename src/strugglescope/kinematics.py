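"""Body-point kinematics: pose-table ingestion, frame speeds, mobility.

A restraint session is filmed at a fixed frame rate (10 fps by default) and
a markerless tracker reports per-frame x/y positions for named body points —
at minimum the fiberoptic cable on the head (``head_fiber``) and the tip of
the tail (``tail_tip``). This module converts those trajectories into
per-frame speeds (pixels/frame) and a per-point mobile/immobile state using
adaptive thresholds: a point is mobile in a frame when its speed strictly
exceeds ``mean(S) + k * sd(S)``, where ``S`` is the subset of that point's
session speeds at or below the ``q``-quantile. Defaults: head ``q=0.95,
k=1`` and tail ``q=0.99, k=3``. Because the threshold is derived from each
session's own speed distribution it is scale-equivariant: rescaling the
camera (multiplying all coordinates by ``c > 0``) leaves the mobility
classification unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    InsufficientDataError,
    MissingPointError,
)

HEAD_POINT = "head_fiber"
TAIL_POINT = "tail_tip"

__all__ = [
    "PoseTrack",
    "SpeedSeries",
    "PointThreshold",
    "MobilityThresholdConfig",
    "MobilitySeries",
    "read_pose_table",
    "compute_speeds",
    "compute_mobility_threshold",
    "classify_mobility",
]


@dataclass
class PoseTrack:
    """Per-frame 2-D coordinates (and optional confidence) for named points.

    Attributes
    ----------
    point_names : list of str
        Labels for the tracked points.
    positions : ndarray, shape (n_frames, n_points, 2)
        Pixel coordinates.
    fps : float
        Frame rate, frames/second.
    confidence : ndarray, shape (n_frames, n_points), optional
        Tracker likelihood in [0, 1].
    """

    point_names: list[str]
    positions: np.ndarray
    fps: float = 10.0
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise FormatError(
                f"positions must have shape (n_frames, n_points, 2), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.point_names):
            raise FormatError("positions second axis must match point_names")
        if not self.fps > 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.positions.shape[:2]:
                raise FormatError("confidence shape must be (n_frames, n_points)")
        if not np.isfinite(self.positions).all():
            raise FormatError("positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def point_index(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise MissingPointError(
                f"point {name!r} not in track (has {self.point_names})"
            ) from None


@dataclass
class SpeedSeries:
    """Per-frame, per-point speed in pixels/frame. Frame 0 speed is 0."""

    point_names: list[str]
    speeds: np.ndarray  # (n_frames, n_points)
    fps: float

    @property
    def n_frames(self) -> int:
        return self.speeds.shape[0]

    def point_index(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise MissingPointError(
                f"point {name!r} not in series (has {self.point_names})"
            ) from None


@dataclass(frozen=True)
class PointThreshold:
    """Quantile/SD-multiplier pair defining one point's mobility threshold."""

    quantile: float
    sd_multiplier: float

    def __post_init__(self) -> None:
        if not 0 < self.quantile <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {self.quantile}")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


@dataclass
class MobilityThresholdConfig:
    """Per-point mobility threshold settings.

    Defaults follow the head/tail convention: the head fiber uses one
    standard deviation above the bottom 95% of frame speeds, the tail tip
    three standard deviations above the bottom 99%. Points without an entry
    fall back to ``default``.
    """

    per_point: dict[str, PointThreshold] = field(
        default_factory=lambda: {
            HEAD_POINT: PointThreshold(0.95, 1.0),
            TAIL_POINT: PointThreshold(0.99, 3.0),
        }
    )
    default: PointThreshold = field(default_factory=lambda: PointThreshold(0.95, 1.0))

    def for_point(self, name: str) -> PointThreshold:
        return self.per_point.get(name, self.default)


@dataclass
class MobilitySeries:
    """Boolean mobile flag per frame per point, plus thresholds used."""

    point_names: list[str]
    mobile: np.ndarray  # (n_frames, n_points), bool
    thresholds: dict[str, float]
    fps: float

    @property
    def n_frames(self) -> int:
        return self.mobile.shape[0]

    def point_index(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise MissingPointError(
                f"point {name!r} not in series (has {self.point_names})"
            ) from None


def _read_three_row_header(path) -> pd.DataFrame:
    # DeepLabCut-style CSV: rows scorer / bodyparts / coords, first column is
    # the frame index.
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    return df


def _is_three_row_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.split(",")[0].strip().lower() == "scorer"


def read_pose_table(
    path,
    point_map: dict[str, str] | None = None,
    fps: float = 10.0,
    confidence_threshold: float | None = None,
) -> PoseTrack:
    """Read a tracked-pose table into a :class:`PoseTrack`.

    Two dialects are supported and auto-detected:

    * the three-row-header CSV emitted by DeepLabCut-style trackers
      (``scorer`` / ``bodyparts`` / ``coords`` header rows with ``x``, ``y``
      and optionally ``likelihood`` columns per body part);
    * a flat table with columns ``frame, point, x, y[, confidence]``.

    Parameters
    ----------
    point_map : dict, optional
        Maps canonical point names (keys) to the labels used in the file
        (values). ``None`` keeps every body part in the file under its own
        label. Missing requested labels raise :class:`MissingPointError`.
    confidence_threshold : float, optional
        If given and the file carries a likelihood/confidence column,
        coordinates below the threshold are replaced by linear
        interpolation from neighbouring frames. Disabled by default.
    """
    if _is_three_row_header(path):
        df = _read_three_row_header(path)
        bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
        frame_index = df.index.to_numpy()
        per_label: dict[str, pd.DataFrame] = {}
        for bp in bodyparts:
            sub = df.xs(bp, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            per_label[bp] = sub
    else:
        flat = pd.read_csv(path)
        required = {"frame", "point", "x", "y"}
        if not required.issubset(flat.columns):
            raise FormatError(
                f"flat pose table must have columns {sorted(required)}, "
                f"got {list(flat.columns)}"
            )
        per_label = {}
        frame_index = None
        for label, grp in flat.groupby("point", sort=False):
            grp = grp.set_index("frame")
            if frame_index is None:
                frame_index = grp.index.to_numpy()
            elif len(grp) != len(frame_index):
                raise FormatError("all points must have identical frame count")
            cols = ["x", "y"] + (["confidence"] if "confidence" in grp else [])
            per_label[str(label)] = grp[cols].rename(
                columns={"confidence": "likelihood"}
            )

    frame_index = np.asarray(frame_index)
    if len(frame_index) == 0:
        raise FormatError("pose table is empty")
    if np.any(np.diff(frame_index.astype(float)) <= 0):
        raise FormatError("frame index must be strictly increasing")

    if point_map is None:
        point_map = {label: label for label in per_label}
    missing = [lab for lab in point_map.values() if lab not in per_label]
    if missing:
        raise MissingPointError(
            f"points {missing} not found in table (has {sorted(per_label)})"
        )

    names = list(point_map)
    n_frames = len(frame_index)
    positions = np.empty((n_frames, len(names), 2), dtype=float)
    confidence = None
    for j, (canonical, label) in enumerate(point_map.items()):
        sub = per_label[label]
        xy = sub[["x", "y"]].astype(float)
        if "likelihood" in sub.columns:
            lik = sub["likelihood"].astype(float).to_numpy()
            if confidence is None:
                confidence = np.ones((n_frames, len(names)))
            confidence[:, j] = lik
            if confidence_threshold is not None:
                bad = lik < confidence_threshold
                xy = xy.mask(bad[:, None] * np.ones((1, 2), dtype=bool))
                xy = xy.interpolate(method="linear", limit_direction="both")
        arr = xy.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError(
                f"point {canonical!r} has non-finite coordinates after "
                "gap interpolation"
            )
        positions[:, j, :] = arr

    return PoseTrack(
        point_names=names, positions=positions, fps=fps, confidence=confidence
    )


def compute_speeds(track: PoseTrack) -> SpeedSeries:
    """Per-frame Euclidean displacement of every point, pixels/frame.

    ``speed[t]`` is the distance between positions at frames ``t-1`` and
    ``t``; ``speed[0]`` is defined as 0.
    """
    if track.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames to compute speeds")
    d = np.diff(track.positions, axis=0)
    sp = np.hypot(d[..., 0], d[..., 1])
    speeds = np.vstack([np.zeros((1, sp.shape[1])), sp])
    return SpeedSeries(point_names=list(track.point_names), speeds=speeds, fps=track.fps)


def compute_mobility_threshold(
    speeds: np.ndarray, quantile: float, sd_multiplier: float
) -> float:
    """Adaptive mobility threshold for one point's session speeds.

    Let ``S`` be the speeds at or below the session's ``quantile``-quantile
    (linear-interpolation quantile). The threshold is
    ``mean(S) + sd_multiplier * sd(S)`` with the n-1 sd denominator. A
    zero-variance subset returns its common value, so that no frame is
    strictly above threshold.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.ndim != 1:
        raise ValueError("speeds must be 1-D (one point)")
    if speeds.size < 10:
        raise InsufficientDataError(
            f"need >= 10 frames of speeds, got {speeds.size}"
        )
    qv = np.quantile(speeds, quantile)
    subset = speeds[speeds <= qv]
    if subset.size == 0:
        raise DegenerateInputError("quantile subset is empty")
    sd = subset.std(ddof=1) if subset.size > 1 else 0.0
    return float(subset.mean() + sd_multiplier * sd)


def classify_mobility(
    speeds: SpeedSeries, cfg: MobilityThresholdConfig | None = None
) -> MobilitySeries:
    """Flag each frame of each point as mobile (speed strictly > threshold)."""
    if cfg is None:
        cfg = MobilityThresholdConfig()
    mobile = np.zeros_like(speeds.speeds, dtype=bool)
    thresholds: dict[str, float] = {}
    for j, name in enumerate(speeds.point_names):
        pt = cfg.for_point(name)
        thr = compute_mobility_threshold(
            speeds.speeds[:, j], pt.quantile, pt.sd_multiplier
        )
        thresholds[name] = thr
        mobile[:, j] = speeds.speeds[:, j] > thr
    return MobilitySeries(
        point_names=list(speeds.point_names),
        mobile=mobile,
        thresholds=thresholds,
        fps=speeds.fps,
    )
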