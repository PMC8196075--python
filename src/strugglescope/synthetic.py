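"""Synthetic restraint-stress sessions with ground truth.

Generates the two data streams the pipeline consumes — tracked-pose
sessions and two-channel photometry — from a known generative model, so
that every stage (mobility thresholds, bout segmentation, ΔF/F, transient
detection, peri-event coupling, multi-day statistics) can be validated
against ground truth without any recorded data.

Behavior model
--------------
Struggle-bout onsets follow a homogeneous Poisson process (default 1 bout
per minute over a 30-minute session); durations are gamma distributed
(default shape 4, scale 0.5 s → mean 2 s); each bout is typed head-only /
tail-only / full-body by a categorical draw. Within a bout the involved
points take isotropic Gaussian steps (default sd 5 px/frame). Immobile
tracking noise is modeled as quantized hold-plus-sway: each frame a point
either holds its reported position exactly (tracker quantization,
probability 0.3) or sways one near-constant-length step (1 px, CV 4%) in a
random direction — a regular, respiration-like micromotion. This matters:
the adaptive threshold (mean + k·sd of the bottom-quantile speeds) sits at
roughly the 84th percentile of any single-scale symmetric jitter
distribution, so idle noise must be either quantized-still or
metronome-regular for a percentile+SD rule to separate idle from struggle,
which is exactly the regime the rule presumes on real recordings.

Photometry model
----------------
The 470 nm channel is ``bleach470(t)·(1 + C(t)) + g·artifact(t) + noise``
and the 405 nm reference is ``bleach405(t) + g·artifact(t) + noise``, with
independent single-exponential bleaching per channel (so the isosbestic
regression has real work to do) and a shared motion artifact modeled as a smoothed-Gaussian fractional
light loss multiplying both channels (shared *fractional* light loss is
the regime in which a single regression slope can cancel the artifact). The indicator trace ``C(t)`` is a sum of double-exponential
kernels ``k(t) = (exp(-t/τ_d) - exp(-t/τ_r))`` normalized to unit peak
(rise 0.1 s, decay 1.5 s). Each bout triggers a transient with probability
``p_trig`` whose amplitude is ``β·duration + noise`` in Z-units (β is the
behavior–signal coupling, default 2.5 Z per second of bout); spontaneous
transients occur at a Poisson rate. Amplitudes in Z-units are converted to
ΔF/F through a fixed factor matched to the nominal ΔF/F noise floor
(0.005), so "amplitude 5 Z" means five noise floors.

Multi-day designs scale the coupling per day (habituation,
``β_day = β·δ^(day-1)``), optionally boost bout and spontaneous-transient
rates on a drug day, and can flip the transient sign to emulate sensors
whose bout-locked response deflects negative (GABA sensors).

All outputs are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .kinematics import HEAD_POINT, TAIL_POINT, PoseTrack
from .photometry import PhotometryRecording

__all__ = [
    "BehaviorSimParams",
    "PhotometrySimParams",
    "StudyDesign",
    "SyntheticGroundTruth",
    "SimulatedSession",
    "simulate_pose_session",
    "simulate_photometry_session",
    "simulate_session",
    "simulate_study",
]


@dataclass
class BehaviorSimParams:
    """Behavioral generative parameters (defaults: 30-min session, 10 fps)."""

    session_s: float = 1800.0
    fps: float = 10.0
    bout_rate_per_min: float = 1.0
    duration_shape: float = 4.0
    duration_scale: float = 0.5  # seconds; mean duration = shape*scale = 2 s
    type_probs: tuple[float, float, float] = (0.5, 0.2, 0.3)  # head/tail/full
    hold_prob: float = 0.3
    idle_speed_px: float = 1.0
    idle_speed_cv: float = 0.04
    move_step_px: float = 5.0
    merge_gap_s: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ConfigError("type_probs must sum to 1")
        if self.bout_rate_per_min < 0:
            raise ConfigError("bout rate must be >= 0")


@dataclass
class PhotometrySimParams:
    """Photometry generative parameters.

    Transient amplitudes are expressed in Z-units (multiples of the nominal
    ΔF/F noise floor ``dff_per_z``).
    """

    sample_rate: float = 20.0
    session_s: float = 1800.0
    # bleaching: F(t) = f0 * (plateau + (1 - plateau) * exp(-t/tau))
    f0_470: float = 100.0
    plateau_470: float = 0.7
    tau_470: float = 600.0
    f0_405: float = 80.0
    plateau_405: float = 0.7
    tau_405: float = 800.0
    artifact_frac_sd: float = 0.01  # fractional light loss, shared
    artifact_tau_s: float = 0.25
    noise_sd_470: float = 0.4  # a.u.; ≈ dff_per_z * mean F470
    noise_sd_405: float = 0.04
    dff_per_z: float = 0.005
    tau_rise: float = 0.1
    tau_decay: float = 1.5
    coupling_z_per_s: float = 2.5  # transient amplitude per second of bout
    amp_noise_z: float = 0.5
    p_trig: float = 0.95
    spont_rate_hz: float = 0.01
    spont_amp_z: float = 4.0
    spont_min_sep_s: float = 0.0
    sign: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigError("need tau_decay > tau_rise > 0")
        if not 0 <= self.p_trig <= 1:
            raise ConfigError("p_trig must be in [0, 1]")
        if self.sign not in (-1, 1):
            raise ConfigError("sign must be +1 or -1")


@dataclass
class StudyDesign:
    """Multi-day, multi-subject design with habituation and a drug day."""

    n_subjects: int = 8
    days: int = 6
    behavior: BehaviorSimParams = field(default_factory=BehaviorSimParams)
    photometry: PhotometrySimParams = field(default_factory=PhotometrySimParams)
    habituation_delta: float = 1.0  # per-day coupling multiplier decay
    drug_day: int | None = 5
    drug_bout_rate_mult: float = 1.5
    drug_transient_rate_mult: float = 1.5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.habituation_delta < 0:
            raise ConfigError("habituation_delta must be >= 0")

    def coupling_multiplier(self, day: int) -> float:
        return self.habituation_delta ** (day - 1)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows: true bouts, transients, components."""

    bouts: pd.DataFrame  # onset_s, offset_s, duration_s, bout_type
    mobility: np.ndarray | None = None  # (n_frames, n_points) bool
    point_names: list[str] | None = None
    fps: float | None = None
    transients: pd.DataFrame | None = None  # time_s, amp_z, source
    components: dict[str, np.ndarray] = field(default_factory=dict)
    n_merged_bouts: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class SimulatedSession:
    pose: PoseTrack
    recording: PhotometryRecording
    truth: SyntheticGroundTruth


def _draw_bouts(params: BehaviorSimParams, rng: np.random.Generator):
    """Poisson onsets + gamma durations, merged where they (nearly) collide."""
    rate_s = params.bout_rate_per_min / 60.0
    onsets = []
    t = 0.0
    while rate_s > 0:
        t += rng.exponential(1.0 / rate_s)
        if t >= params.session_s:
            break
        onsets.append(t)
    durations = rng.gamma(params.duration_shape, params.duration_scale, len(onsets))
    types = rng.choice(3, size=len(onsets), p=list(params.type_probs))

    fps = params.fps
    n_frames = int(round(params.session_s * fps))
    intervals = []
    for onset, dur, tcode in zip(onsets, durations, types):
        f0 = int(round(onset * fps))
        nf = max(2, int(round(dur * fps)))
        f1 = min(f0 + nf - 1, n_frames - 1)
        if f1 <= f0:
            continue
        head = tcode in (0, 2)
        tail = tcode in (1, 2)
        intervals.append([f0, f1, head, tail])

    # merge bouts whose separation could not be resolved by the gap rule
    merge_frames = int(round(params.merge_gap_s * fps))
    merged: list[list] = []
    n_merged = 0
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= merge_frames:
            prev = merged[-1]
            prev[1] = max(prev[1], iv[1])
            prev[2] = prev[2] or iv[2]
            prev[3] = prev[3] or iv[3]
            n_merged += 1
        else:
            merged.append(list(iv))
    return merged, n_merged, n_frames


def _bout_type(head: bool, tail: bool) -> str:
    if head and tail:
        return "full_body"
    return "tail_only" if tail else "head_only"


def simulate_pose_session(
    params: BehaviorSimParams, rng: np.random.Generator | None = None
) -> tuple[PoseTrack, SyntheticGroundTruth]:
    """Simulate one tracked-pose session; returns the track + ground truth."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    intervals, n_merged, n_frames = _draw_bouts(params, rng)

    point_names = [HEAD_POINT, TAIL_POINT]
    anchors = np.array([[100.0, 100.0], [220.0, 160.0]])
    n_pts = len(point_names)

    moving = np.zeros((n_frames, n_pts), dtype=bool)
    for f0, f1, head, tail in intervals:
        if head:
            moving[f0 : f1 + 1, 0] = True
        if tail:
            moving[f0 : f1 + 1, 1] = True

    # idle hold-plus-sway steps
    hold = rng.random((n_frames, n_pts)) < params.hold_prob
    angle = rng.uniform(0, 2 * np.pi, (n_frames, n_pts))
    length = params.idle_speed_px * (
        1.0 + params.idle_speed_cv * rng.standard_normal((n_frames, n_pts))
    )
    length = np.clip(length, 0.0, None)
    steps = np.where(
        hold[..., None], 0.0, length[..., None] * np.stack(
            [np.cos(angle), np.sin(angle)], axis=-1
        )
    )
    # struggle steps on top, for the involved points
    move = params.move_step_px * rng.standard_normal((n_frames, n_pts, 2))
    steps = steps + np.where(moving[..., None], move, 0.0)
    steps[0] = 0.0
    positions = anchors[None, :, :] + np.cumsum(steps, axis=0)

    bouts = pd.DataFrame(
        {
            "onset_s": [f0 / params.fps for f0, *_ in intervals],
            "offset_s": [f1 / params.fps for _, f1, *_ in intervals],
            "duration_s": [
                (f1 - f0 + 1) / params.fps for f0, f1, *_ in intervals
            ],
            "bout_type": [_bout_type(h, t) for *_, h, t in intervals],
        }
    )
    truth = SyntheticGroundTruth(
        bouts=bouts,
        mobility=moving,
        point_names=point_names,
        fps=params.fps,
        n_merged_bouts=n_merged,
        params={"behavior": params},
    )
    track = PoseTrack(point_names=point_names, positions=positions, fps=params.fps)
    return track, truth


def _kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential transient kernel, normalized to unit peak."""
    t_peak = (
        np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    )
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k[t < 0] = 0.0
    return k / peak


def simulate_photometry_session(
    params: PhotometrySimParams,
    truth: SyntheticGroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhotometryRecording, SyntheticGroundTruth]:
    """Simulate a two-channel recording, optionally locked to bout truth.

    When ``truth`` (from :func:`simulate_pose_session`) is given, bouts
    trigger transients with probability ``p_trig`` and amplitude
    ``coupling_z_per_s * duration + N(0, amp_noise_z)``; spontaneous
    transients are added at ``spont_rate_hz`` either way. The returned
    ground truth records transient times/amplitudes and the clean signal
    components (bleach curves, artifact, indicator).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.session_s * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    events: list[tuple[float, float, str]] = []  # (time, amp_z, source)
    if truth is not None and len(truth.bouts):
        for _, row in truth.bouts.iterrows():
            if rng.random() < params.p_trig:
                amp = (
                    params.coupling_z_per_s * row["duration_s"]
                    + params.amp_noise_z * rng.standard_normal()
                )
                events.append((float(row["onset_s"]), float(amp), "bout"))
            else:
                events.append((float(row["onset_s"]), 0.0, "untriggered"))
    # spontaneous transients (Poisson; optional minimum separation)
    if params.spont_rate_hz > 0:
        times = []
        ts = 0.0
        while True:
            ts += rng.exponential(1.0 / params.spont_rate_hz)
            if ts >= params.session_s:
                break
            if params.spont_min_sep_s > 0 and times and (
                ts - times[-1] < params.spont_min_sep_s
            ):
                continue
            times.append(ts)
        for ts in times:
            events.append((ts, params.spont_amp_z, "spontaneous"))

    indicator = np.zeros(n)
    span = int(
        np.ceil((8.0 * params.tau_decay) * params.sample_rate)
    )  # kernel support, ~8 decay constants
    for time_s, amp_z, source in events:
        if amp_z == 0.0:
            continue
        i0 = int(np.ceil((time_s - t[0]) * params.sample_rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i0 + span, n)
        if i0 >= n:
            continue
        rel = t[i0:i1] - time_s
        indicator[i0:i1] += (
            params.sign
            * amp_z
            * params.dff_per_z
            * _kernel(rel, params.tau_rise, params.tau_decay)
        )

    bleach470 = params.f0_470 * (
        params.plateau_470 + (1 - params.plateau_470) * np.exp(-t / params.tau_470)
    )
    bleach405 = params.f0_405 * (
        params.plateau_405 + (1 - params.plateau_405) * np.exp(-t / params.tau_405)
    )
    artifact = gaussian_filter1d(
        rng.standard_normal(n), params.artifact_tau_s * params.sample_rate
    )
    sd = artifact.std()
    artifact = params.artifact_frac_sd * artifact / sd if sd > 0 else artifact

    # motion artifact is a shared fractional light loss, so it scales both
    # channels multiplicatively -- the regime isosbestic regression corrects
    ch470 = (
        bleach470 * (1.0 + indicator) * (1.0 + artifact)
        + params.noise_sd_470 * rng.standard_normal(n)
    )
    ch405 = (
        bleach405 * (1.0 + artifact)
        + params.noise_sd_405 * rng.standard_normal(n)
    )

    rec = PhotometryRecording(time=t, signal=ch470, reference=ch405)
    tr_df = pd.DataFrame(
        [(ts, amp, src) for ts, amp, src in events if amp != 0.0],
        columns=["time_s", "amp_z", "source"],
    ).sort_values("time_s", ignore_index=True)
    out = truth if truth is not None else SyntheticGroundTruth(
        bouts=pd.DataFrame(
            columns=["onset_s", "offset_s", "duration_s", "bout_type"]
        )
    )
    out.transients = tr_df
    out.components = {
        "bleach470": bleach470,
        "bleach405": bleach405,
        "artifact": artifact,
        "indicator": indicator,
    }
    out.params["photometry"] = params
    return rec, out


def simulate_session(
    behavior: BehaviorSimParams | None = None,
    photometry: PhotometrySimParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SimulatedSession:
    """Simulate one session end to end (pose + locked photometry)."""
    behavior = behavior if behavior is not None else BehaviorSimParams()
    photometry = photometry if photometry is not None else PhotometrySimParams()
    if photometry.session_s != behavior.session_s:
        photometry = replace(photometry, session_s=behavior.session_s)
    if rng is None:
        rng = np.random.default_rng(behavior.seed if seed is None else seed)
    track, truth = simulate_pose_session(behavior, rng)
    rec, truth = simulate_photometry_session(photometry, truth, rng)
    return SimulatedSession(pose=track, recording=rec, truth=truth)


def simulate_study(design: StudyDesign) -> dict[tuple[int, int], SimulatedSession]:
    """Simulate every subject × day cell of a study design.

    Seeds derive deterministically from (base_seed, subject, day). Per day,
    the transient coupling is scaled by ``habituation_delta**(day-1)``; on
    the drug day the bout rate and spontaneous transient rate are scaled by
    their multipliers.
    """
    out: dict[tuple[int, int], SimulatedSession] = {}
    for subject in range(1, design.n_subjects + 1):
        for day in range(1, design.days + 1):
            beh = replace(design.behavior)
            phot = replace(
                design.photometry,
                coupling_z_per_s=design.photometry.coupling_z_per_s
                * design.coupling_multiplier(day),
            )
            if design.drug_day is not None and day == design.drug_day:
                beh = replace(
                    beh,
                    bout_rate_per_min=beh.bout_rate_per_min
                    * design.drug_bout_rate_mult,
                )
                phot = replace(
                    phot,
                    spont_rate_hz=phot.spont_rate_hz
                    * design.drug_transient_rate_mult,
                )
            rng = np.random.default_rng(
                np.random.SeedSequence([design.base_seed, subject, day])
            )
            out[(subject, day)] = simulate_session(beh, phot, rng=rng)
    return out


def write_pose_csv(track: PoseTrack, path, scorer: str = "synthetic") -> None:
    """Write a PoseTrack in the three-row-header tracking dialect."""
    cols = pd.MultiIndex.from_tuples(
        [
            (scorer, name, coord)
            for name in track.point_names
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    n = track.n_frames
    data = np.empty((n, len(cols)))
    for j, _ in enumerate(track.point_names):
        data[:, 3 * j] = track.positions[:, j, 0]
        data[:, 3 * j + 1] = track.positions[:, j, 1]
        data[:, 3 * j + 2] = (
            track.confidence[:, j] if track.confidence is not None else 1.0
        )
    df = pd.DataFrame(data, columns=cols)
    df.index.name = "scorer"
    df.to_csv(path)


def write_photometry_csv(rec: PhotometryRecording, path) -> None:
    """Write a recording as delimited text (time_s, ch470[, ch405])."""
    data = {"time_s": rec.time, "ch470": rec.signal}
    if rec.reference is not None:
        data["ch405"] = rec.reference
    pd.DataFrame(data).to_csv(path, index=False)
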