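"""Two-channel photometry processing: ΔF/F, airPLS baseline, transients.

The 470 nm channel carries the activity-dependent sensor fluorescence; the
405 nm channel excites the indicator at its isosbestic point and reports
only motion and bleaching artifacts. The reference is fit to the signal by
ordinary least squares over the whole session, and

    ΔF/F(t) = (F470(t) - fitted405(t)) / fitted405(t).

Slow residual drift is then estimated by airPLS (adaptive iteratively
reweighted penalized least squares) and subtracted, the corrected trace is
standardized to a session-level Z score, and transients are maximal runs of
samples with Z at or above a threshold (2.91 by default, an outlier
criterion). Each transient reports its maximum Z (max peak) and trapezoidal
area; transient frequency is the count divided by the session duration.

Sensors recorded without a reference channel (e.g. glutamate/GABA
indicators acquired single-channel) use the airPLS baseline of the raw
signal itself as F0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded

from .errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    InsufficientDataError,
)

__all__ = [
    "PhotometryRecording",
    "IsosbesticFit",
    "DffTrace",
    "BaselineConfig",
    "Transient",
    "TransientConfig",
    "PhotometryResult",
    "read_photometry_table",
    "fit_isosbestic",
    "compute_dff",
    "airpls_baseline",
    "whittaker_smooth",
    "standardize_trace",
    "detect_transients",
    "transient_frequency",
    "process_recording",
    "transients_to_dataframe",
]


@dataclass
class PhotometryRecording:
    """Uniformly sampled signal channel with optional isosbestic reference."""

    time: np.ndarray
    signal: np.ndarray
    reference: np.ndarray | None = None
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise FormatError("time and signal must have equal length")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.signal.shape:
                raise FormatError("reference and signal must have equal length")
        dt = np.diff(self.time)
        if self.time.size >= 2:
            if np.any(dt <= 0):
                raise FormatError("time must be strictly increasing")
            step = np.median(dt)
            if np.any(np.abs(dt - step) > 0.01 * step):
                raise FormatError("sampling is non-uniform beyond 1% tolerance")
            inferred = 1.0 / step
            if self.sample_rate is None:
                self.sample_rate = float(inferred)
            elif abs(self.sample_rate - inferred) > 0.01 * inferred:
                raise FormatError(
                    f"sample_rate={self.sample_rate} inconsistent with time "
                    f"step (inferred {inferred:.6g} Hz)"
                )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return float(self.n_samples / self.sample_rate)


@dataclass
class IsosbesticFit:
    """OLS fit of the signal channel on the reference channel."""

    slope: float
    intercept: float
    fitted_reference: np.ndarray


@dataclass
class DffTrace:
    """Fractional fluorescence change over time."""

    time: np.ndarray
    dff: np.ndarray


@dataclass
class BaselineConfig:
    """airPLS settings: smoothness penalty and iteration control."""

    lambda_: float = 5e4
    diff_order: int = 1
    max_iter: int = 50
    convergence: float = 0.001

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.diff_order not in (1, 2):
            raise ValueError("diff_order must be 1 or 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Transient:
    """One supra-threshold run: timing, max peak (Z) and area (Z*s)."""

    start_s: float
    end_s: float
    max_peak: float
    area: float
    n_samples: int


@dataclass
class TransientConfig:
    z_threshold: float = 2.91
    min_samples: int = 1

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def read_photometry_table(path, decimate_to: float | None = None) -> PhotometryRecording:
    """Read a delimited-text recording (time_s, signal[, reference]).

    ``decimate_to`` block-averages the channels down to (approximately) the
    requested rate; averaging doubles as anti-alias smoothing.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.shape[1] > 3:
        raise FormatError(
            f"expected 2 or 3 columns (time, signal[, reference]), "
            f"got {df.shape[1]}"
        )
    time = df.iloc[:, 0].to_numpy(dtype=float)
    signal = df.iloc[:, 1].to_numpy(dtype=float)
    reference = df.iloc[:, 2].to_numpy(dtype=float) if df.shape[1] == 3 else None
    rec = PhotometryRecording(time=time, signal=signal, reference=reference)
    if decimate_to is not None:
        rec = _decimate(rec, decimate_to)
    return rec


def _decimate(rec: PhotometryRecording, target_rate: float) -> PhotometryRecording:
    factor = int(round(rec.sample_rate / target_rate))
    if factor < 1:
        raise FormatError("target rate exceeds the recording's sample rate")
    if factor == 1:
        return rec
    n = (rec.n_samples // factor) * factor

    def block(x: np.ndarray) -> np.ndarray:
        return x[:n].reshape(-1, factor).mean(axis=1)

    return PhotometryRecording(
        time=block(rec.time),
        signal=block(rec.signal),
        reference=None if rec.reference is None else block(rec.reference),
    )


def fit_isosbestic(rec: PhotometryRecording) -> IsosbesticFit:
    """OLS of the 470 nm signal on the 405 nm reference, whole session."""
    if rec.reference is None:
        raise DegenerateInputError("recording has no reference channel")
    ref = rec.reference
    if np.ptp(ref) == 0 or ref.std() == 0:
        raise DegenerateInputError("reference channel is constant")
    slope, intercept = np.polyfit(ref, rec.signal, 1)
    return IsosbesticFit(
        slope=float(slope),
        intercept=float(intercept),
        fitted_reference=slope * ref + intercept,
    )


def compute_dff(rec: PhotometryRecording, fit: IsosbesticFit) -> DffTrace:
    """ΔF/F = (signal - fitted reference) / fitted reference."""
    f0 = fit.fitted_reference
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise DomainError(
            f"fitted reference is non-positive at sample {bad[0]} "
            f"(t={rec.time[bad[0]]:.3f} s)"
        )
    return DffTrace(time=rec.time, dff=(rec.signal - f0) / f0)


def _dtd_diagonals(n: int, order: int) -> np.ndarray:
    """Upper-banded diagonals of D'D for the d-th order difference matrix."""
    coeffs = np.array(
        [(-1) ** k * math.comb(order, k) for k in range(order + 1)], dtype=float
    )
    D = sparse.diags(
        [np.full(n - order, c) for c in coeffs],
        offsets=list(range(order + 1)),
        shape=(n - order, n),
        format="csr",
    )
    dtd = (D.T @ D).todia()
    ab = np.zeros((order + 1, n))
    for off, row in zip(dtd.offsets, dtd.data):
        if off >= 0:
            ab[order - off, :] = row
    return ab


def whittaker_smooth(
    y: np.ndarray, w: np.ndarray, lambda_: float, diff_order: int = 1
) -> np.ndarray:
    """Solve (W + λ·D'D) z = W y — the weighted Whittaker smoother."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ab = lambda_ * _dtd_diagonals(n, diff_order)
    ab[-1, :] += w
    return solveh_banded(ab, w * y, lower=False)


def airpls_baseline(y: np.ndarray, cfg: BaselineConfig | None = None) -> np.ndarray:
    """Adaptive iteratively reweighted penalized-least-squares baseline.

    Iterates a weighted Whittaker smoother: points above the current
    baseline (candidate peaks) get weight 0, points below get weight
    ``exp(i·|r_i|/s)`` where ``s`` is the summed magnitude of negative
    residuals, and the two endpoints are anchored with the largest such
    weight. Iteration stops when ``s`` falls below ``convergence * Σ|y|``
    or ``max_iter`` is reached. The returned baseline hugs slow drift while
    riding under positive transients.
    """
    if cfg is None:
        cfg = BaselineConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise InsufficientDataError(f"need >= 10 samples, got {n}")
    abs_sum = np.abs(y).sum()
    if abs_sum == 0:
        return np.zeros(n)
    w = np.ones(n)
    z = y.copy()
    for it in range(1, cfg.max_iter + 1):
        z = whittaker_smooth(y, w, cfg.lambda_, cfg.diff_order)
        r = y - z
        neg = r < 0
        s = float(np.abs(r[neg]).sum())
        if s < cfg.convergence * abs_sum or it == cfg.max_iter:
            break
        w[~neg] = 0.0
        # clip the exponent: as s -> 0 the reweighting factor overflows
        expo = np.clip(it * np.abs(r[neg]) / s, None, 50.0)
        w[neg] = np.exp(expo)
        edge = np.exp(np.clip(it * np.abs(r[neg]).max() / s, None, 50.0))
        w[0] = edge
        w[-1] = edge
    return z


def standardize_trace(y: np.ndarray) -> np.ndarray:
    """Session-level Z score: (y - mean) / sd, n-1 denominator."""
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("trace has zero variance")
    return (y - y.mean()) / sd


def detect_transients(
    z: np.ndarray,
    sample_rate: float | None = None,
    cfg: TransientConfig | None = None,
    time: np.ndarray | None = None,
) -> list[Transient]:
    """Maximal runs of consecutive samples with Z >= threshold.

    A transient starts at the first sample at or above the threshold and
    ends at the last sample before Z drops below it. Runs shorter than
    ``min_samples`` are discarded. ``area`` is the trapezoidal integral of
    Z over the run (0 for single-sample runs).
    """
    if cfg is None:
        cfg = TransientConfig()
    z = np.asarray(z, dtype=float)
    if time is None:
        if sample_rate is None:
            raise ValueError("provide sample_rate or time")
        time = np.arange(z.size) / sample_rate
    above = z >= cfg.z_threshold
    idx = np.flatnonzero(above)
    out: list[Transient] = []
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    for a, b in zip(starts, stops):
        if b - a + 1 < cfg.min_samples:
            continue
        seg = z[a : b + 1]
        area = float(np.trapezoid(seg, time[a : b + 1])) if b > a else 0.0
        out.append(
            Transient(
                start_s=float(time[a]),
                end_s=float(time[b]),
                max_peak=float(seg.max()),
                area=area,
                n_samples=int(b - a + 1),
            )
        )
    return out


def transient_frequency(transients: list[Transient], duration_s: float) -> float:
    """Transients per second (Hz)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return len(transients) / duration_s


def transients_to_dataframe(transients: list[Transient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [t.start_s for t in transients],
            "end_s": [t.end_s for t in transients],
            "max_peak_z": [t.max_peak for t in transients],
            "area": [t.area for t in transients],
            "n_samples": [t.n_samples for t in transients],
        }
    )


@dataclass
class PhotometryResult:
    """End-to-end photometry processing output for one session."""

    dff: DffTrace
    corrected: np.ndarray
    z: np.ndarray
    transients: list[Transient]
    frequency_hz: float
    fit: IsosbesticFit | None = None


def process_recording(
    rec: PhotometryRecording,
    sensor_mode: str = "dual",
    baseline_cfg: BaselineConfig | None = None,
    transient_cfg: TransientConfig | None = None,
) -> PhotometryResult:
    """Run the full trace pipeline: ΔF/F → airPLS → session Z → transients.

    ``sensor_mode='dual'`` applies the isosbestic regression (calcium
    indicators with a 405 nm reference); ``'single'`` divides by the airPLS
    baseline of the raw signal instead (single-channel sensors).
    """
    if baseline_cfg is None:
        baseline_cfg = BaselineConfig()
    if transient_cfg is None:
        transient_cfg = TransientConfig()
    fit = None
    if sensor_mode == "dual":
        fit = fit_isosbestic(rec)
        dff = compute_dff(rec, fit)
    elif sensor_mode == "single":
        base = airpls_baseline(rec.signal, baseline_cfg)
        bad = np.flatnonzero(base <= 0)
        if bad.size:
            raise DomainError(
                f"airPLS baseline non-positive at sample {bad[0]}"
            )
        dff = DffTrace(time=rec.time, dff=(rec.signal - base) / base)
    else:
        raise ValueError("sensor_mode must be 'dual' or 'single'")
    corrected = dff.dff - airpls_baseline(dff.dff, baseline_cfg)
    z = standardize_trace(corrected)
    transients = detect_transients(z, time=rec.time, cfg=transient_cfg)
    return PhotometryResult(
        dff=dff,
        corrected=corrected,
        z=z,
        transients=transients,
        frequency_hz=transient_frequency(transients, rec.duration_s),
        fit=fit,
    )
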