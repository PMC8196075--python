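"""Peri-event alignment of photometry to bout onsets.

For each bout the trace is extracted over a window relative to onset
(default −5…+10 s) on the recording's own sample grid (nearest-sample
mapping, no interpolation) and standardized against its own pre-onset
baseline window (−5…−3 s):

    Z(t) = (x(t) - mean(baseline)) / sd(baseline)

so that, by construction, every retained row has baseline mean 0 and sd 1.
Named analysis windows (default ``post`` = 0–5 s after onset, independent
of bout length, and ``pre`` = −3–0 s) yield per-bout signed trapezoidal
AUC (Z·s) and max peak (Z, signed). Bouts whose window leaves the
recording, or whose baseline has zero variance, are flagged and excluded —
never dropped silently. An artificial lock shift (``offset_s``, +10 s for
the uncorrelated-activity control) can be applied to every onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bouts import BoutTable
from .errors import ConfigError

__all__ = [
    "PeriEventConfig",
    "EventAlignedMatrix",
    "align_to_events",
    "zscore_peri_event",
    "compute_auc",
    "compute_max_peak",
    "bout_metrics",
    "build_heatmap",
]


@dataclass
class PeriEventConfig:
    """Peri-event window layout and artificial lock offset."""

    window: tuple[float, float] = (-5.0, 10.0)
    baseline: tuple[float, float] = (-5.0, -3.0)
    analysis_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"post": (0.0, 5.0), "pre": (-3.0, 0.0)}
    )
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        w0, w1 = self.window
        if w0 >= w1:
            raise ConfigError("window start must precede window end")
        b0, b1 = self.baseline
        if not (w0 <= b0 < b1 <= 0):
            raise ConfigError("baseline window must precede onset, inside window")
        for name, (a0, a1) in self.analysis_windows.items():
            if not (w0 <= a0 < a1 <= w1):
                raise ConfigError(
                    f"analysis window {name!r} must lie inside the peri-event window"
                )


@dataclass
class EventAlignedMatrix:
    """Events × relative-time grid of peri-event Z, with exclusion flags.

    ``z`` holds NaN rows for excluded events; ``events`` records onset,
    duration, type, and the exclusion reason per row.
    """

    rel_time: np.ndarray
    z: np.ndarray  # (n_events, n_t); NaN rows for excluded events
    raw: np.ndarray
    events: pd.DataFrame
    cfg: PeriEventConfig

    @property
    def retained(self) -> np.ndarray:
        return ~self.events["excluded"].to_numpy()

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def zscore_peri_event(
    row: np.ndarray, rel_time: np.ndarray, baseline: tuple[float, float]
) -> np.ndarray:
    """Standardize one aligned row against its baseline-window samples.

    Raises ``ValueError`` on degenerate baselines (fewer than 2 samples or
    zero sd); callers flag the row instead of propagating.
    """
    mask = (rel_time >= baseline[0] - 1e-9) & (rel_time <= baseline[1] + 1e-9)
    base = row[mask]
    if base.size < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    sd = base.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate_baseline")
    return (row - base.mean()) / sd


def align_to_events(
    time: np.ndarray,
    values: np.ndarray,
    bouts: BoutTable | np.ndarray,
    cfg: PeriEventConfig | None = None,
    durations: np.ndarray | None = None,
) -> EventAlignedMatrix:
    """Time-lock a session trace to bout onsets.

    ``bouts`` may be a :class:`BoutTable` or a plain array of onset times
    (seconds, same time base as ``time``; then ``durations`` may supply
    bout lengths for downstream metrics).
    """
    if cfg is None:
        cfg = PeriEventConfig()
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = float(np.median(np.diff(time)))
    i0_grid = int(np.ceil(cfg.window[0] / dt - 1e-9))
    i1_grid = int(np.floor(cfg.window[1] / dt + 1e-9))
    rel_idx = np.arange(i0_grid, i1_grid + 1)
    rel_time = rel_idx * dt

    if isinstance(bouts, BoutTable):
        onsets = np.array([b.onset_s for b in bouts])
        durs = np.array([b.duration_s for b in bouts])
        types = [b.bout_type for b in bouts]
    else:
        onsets = np.asarray(bouts, dtype=float)
        durs = (
            np.asarray(durations, dtype=float)
            if durations is not None
            else np.full(onsets.shape, np.nan)
        )
        types = [""] * onsets.size

    n_ev, n_t = onsets.size, rel_time.size
    raw = np.full((n_ev, n_t), np.nan)
    z = np.full((n_ev, n_t), np.nan)
    excluded = np.zeros(n_ev, dtype=bool)
    reasons = [""] * n_ev

    t0 = time[0]
    for i, onset in enumerate(onsets):
        center = int(round((onset + cfg.offset_s - t0) / dt))
        idx = center + rel_idx
        if idx[0] < 0 or idx[-1] >= time.size:
            excluded[i] = True
            reasons[i] = "window_out_of_range"
            continue
        row = values[idx]
        raw[i] = row
        try:
            z[i] = zscore_peri_event(row, rel_time, cfg.baseline)
        except ValueError:
            excluded[i] = True
            reasons[i] = "degenerate_baseline"
            raw[i] = row

    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": durs,
            "bout_type": types,
            "excluded": excluded,
            "reason": reasons,
        }
    )
    return EventAlignedMatrix(rel_time=rel_time, z=z, raw=raw, events=events, cfg=cfg)


def _window_mask(rel_time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (rel_time >= window[0] - 1e-9) & (rel_time <= window[1] + 1e-9)


def compute_auc(
    zrow: np.ndarray, rel_time: np.ndarray, window: tuple[float, float]
) -> float:
    """Signed trapezoidal integral of Z over a window (Z·s)."""
    m = _window_mask(rel_time, window)
    return float(np.trapezoid(zrow[m], rel_time[m]))


def compute_max_peak(
    zrow: np.ndarray, rel_time: np.ndarray, window: tuple[float, float]
) -> float:
    """Maximum (signed) Z within a window."""
    m = _window_mask(rel_time, window)
    return float(np.max(zrow[m]))


def bout_metrics(mat: EventAlignedMatrix) -> pd.DataFrame:
    """Per-bout AUC and max peak for each named analysis window.

    Excluded rows carry NaN metrics. ``auc_positive``/``peak_positive``
    flag strictly positive post-window values (used to split bouts into
    with/without an associated transient).
    """
    df = mat.events[["onset_s", "duration_s", "bout_type", "excluded", "reason"]].copy()
    for name, window in mat.cfg.analysis_windows.items():
        aucs = np.full(len(df), np.nan)
        peaks = np.full(len(df), np.nan)
        for i in range(len(df)):
            if mat.events["excluded"].iat[i]:
                continue
            aucs[i] = compute_auc(mat.z[i], mat.rel_time, window)
            peaks[i] = compute_max_peak(mat.z[i], mat.rel_time, window)
        df[f"auc_{name}"] = aucs
        df[f"peak_{name}"] = peaks
    if "auc_post" in df:
        df["auc_positive"] = df["auc_post"] > 0
        df["peak_positive"] = df["peak_post"] > 0
    return df


def build_heatmap(
    mat: EventAlignedMatrix,
    groups: np.ndarray | None = None,
    clip: tuple[float, float] = (-5.0, 5.0),
    ax=None,
):
    """Event heatmap plus mean ± s.e.m. trace across retained bouts.

    Values are clipped to ``clip`` for display only — metrics elsewhere use
    the unclipped matrix. Rows can be grouped (e.g. by subject) via
    ``groups``, which reorders rows into contiguous blocks.

    Returns ``(fig, mean, sem)``; ``fig`` is None when ``ax`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    keep = mat.retained
    z = mat.z[keep]
    if z.shape[0] == 0:
        raise ValueError("no retained rows to plot")
    if groups is not None:
        order = np.argsort(np.asarray(groups)[keep], kind="stable")
        z = z[order]
    mean = z.mean(axis=0)
    sem = (
        z.std(axis=0, ddof=1) / np.sqrt(z.shape[0])
        if z.shape[0] > 1
        else np.zeros_like(mean)
    )

    fig = None
    if ax is None:
        fig, axes = plt.subplots(
            2, 1, figsize=(6, 6), sharex=True, height_ratios=[2, 1]
        )
        ax_hm, ax_tr = axes
    else:
        ax_hm, ax_tr = ax, None
    extent = [mat.rel_time[0], mat.rel_time[-1], z.shape[0], 0]
    ax_hm.imshow(
        np.clip(z, clip[0], clip[1]),
        aspect="auto",
        extent=extent,
        cmap="coolwarm",
        vmin=clip[0],
        vmax=clip[1],
    )
    ax_hm.axvline(0.0, color="k", lw=0.5)
    ax_hm.set_ylabel("bout")
    if ax_tr is not None:
        ax_tr.plot(mat.rel_time, mean, color="C0")
        ax_tr.fill_between(
            mat.rel_time, mean - sem, mean + sem, alpha=0.3, color="C0"
        )
        ax_tr.axvline(0.0, color="k", lw=0.5)
        ax_tr.set_xlabel("time from bout onset (s)")
        ax_tr.set_ylabel("Z")
    return fig, mean, sem
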