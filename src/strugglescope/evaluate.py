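"""Recovery metrics against synthetic ground truth.

Matches detected bouts/transients to the generator's true events and
reports recall, false-discovery proportion, onset accuracy, and the
bout-type confusion matrix. Matching is one-to-one and greedy: detected
bouts pair with the true bout they overlap most (a detected bout touching
no true bout is a false discovery); a true bout counts as recovered at a
given onset tolerance when its paired detection's onset lies within it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import BOUT_TYPES, BoutTable
from .photometry import Transient

__all__ = ["BoutMatchResult", "match_bouts", "match_transients", "mobility_agreement"]


@dataclass
class BoutMatchResult:
    recall: float  # true bouts recovered within onset tolerance
    fdp: float  # detected bouts overlapping no true bout
    onset_errors: np.ndarray  # per matched pair, seconds
    confusion: pd.DataFrame  # true type x detected type, matched pairs
    n_true: int
    n_detected: int

    @property
    def type_accuracy(self) -> float:
        total = self.confusion.to_numpy().sum()
        return float(np.trace(self.confusion.to_numpy()) / total) if total else np.nan


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def match_bouts(
    true_bouts: pd.DataFrame, detected: BoutTable, onset_tol_s: float = 0.2
) -> BoutMatchResult:
    """Match detected bouts to ground-truth intervals.

    ``true_bouts`` needs columns ``onset_s, offset_s, bout_type``. Interval
    overlap uses closed intervals padded by half a frame on each side, so
    single-frame events can still overlap.
    """
    fps = detected.fps
    pad = 0.5 / fps
    t_on = true_bouts["onset_s"].to_numpy(dtype=float)
    t_off = true_bouts["offset_s"].to_numpy(dtype=float)
    d_on = np.array([b.onset_s for b in detected])
    d_off = np.array([b.offset_s for b in detected])

    n_true, n_det = t_on.size, d_on.size
    # candidate pairs sorted by decreasing overlap; greedy one-to-one
    pairs = []
    for i in range(n_true):
        for j in range(n_det):
            ov = _overlap(
                t_on[i] - pad, t_off[i] + pad, d_on[j] - pad, d_off[j] + pad
            )
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda p: -p[0])
    true_match = np.full(n_true, -1)
    det_match = np.full(n_det, -1)
    for _, i, j in pairs:
        if true_match[i] == -1 and det_match[j] == -1:
            true_match[i] = j
            det_match[j] = i

    matched = np.flatnonzero(true_match >= 0)
    onset_err = np.array(
        [d_on[true_match[i]] - t_on[i] for i in matched], dtype=float
    )
    recall = (
        float(np.mean(np.abs(onset_err) <= onset_tol_s) * matched.size / n_true)
        if n_true
        else np.nan
    )
    fdp = float(np.mean(det_match < 0)) if n_det else 0.0

    confusion = pd.DataFrame(
        0, index=list(BOUT_TYPES), columns=list(BOUT_TYPES), dtype=int
    )
    for i in matched:
        tt = true_bouts["bout_type"].iat[i]
        dt = detected.bouts[true_match[i]].bout_type
        confusion.loc[tt, dt] += 1

    return BoutMatchResult(
        recall=recall,
        fdp=fdp,
        onset_errors=onset_err,
        confusion=confusion,
        n_true=n_true,
        n_detected=n_det,
    )


def match_transients(
    true_times: np.ndarray,
    detected: list[Transient],
    footprint_s: float = 4.5,
    tol_s: float = 0.25,
) -> dict:
    """Compare detected supra-threshold runs to injected transient onsets.

    Each injected transient occupies a footprint ``[t - tol_s, t +
    footprint_s]`` (the default covers three decay constants of the
    standard kernel). A transient is detected when at least one run
    overlaps its footprint; a run is spurious when it overlaps no
    footprint. The mapping is deliberately not one-to-one: a single
    transient whose decay dips through the threshold fragments into
    several runs, and those fragments are not false calls.
    """
    true_times = np.asarray(true_times, dtype=float)
    n_true = true_times.size
    n_det = len(detected)
    hit = np.zeros(n_true, dtype=bool)
    spurious = np.ones(n_det, dtype=bool)
    for j, tr in enumerate(detected):
        for i, tt in enumerate(true_times):
            if tr.start_s <= tt + footprint_s and tr.end_s >= tt - tol_s:
                hit[i] = True
                spurious[j] = False
    return {
        "detection_rate": float(hit.mean()) if n_true else np.nan,
        "spurious_rate": float(spurious.mean()) if n_det else 0.0,
        "n_true": n_true,
        "n_detected": n_det,
        "n_spurious": int(spurious.sum()),
    }


def mobility_agreement(true_mobility: np.ndarray, detected_mobility: np.ndarray) -> float:
    """Frame-level agreement between true and detected mobility flags."""
    t = np.asarray(true_mobility, dtype=bool)
    d = np.asarray(detected_mobility, dtype=bool)
    if t.shape != d.shape:
        raise ValueError("mobility arrays must have the same shape")
    return float((t == d).mean())
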