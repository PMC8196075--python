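"""End-to-end session and study runners.

``run_session`` executes the full chain on one session — pose table →
speeds → mobility → bouts, photometry → ΔF/F → airPLS → Z → transients,
then peri-event alignment, per-bout metrics and session statistics — and
writes every artifact (bout table, transient table, aligned matrix, bout
metrics, stats report, heatmap/mean-trace figure) plus an echo of the fully
resolved configuration. ``run_study`` aggregates per-subject-per-day
sessions into per-day AUC-duration correlations, day-1-normalized transient
frequencies, day-wise bout counts and paired day comparisons.

Configuration lives in :class:`RunConfig`, loadable from YAML; defaults
reproduce the reference parameter set (10 fps; head 95%/1 SD and tail
99%/3 SD thresholds; 0.7 s bout gap; −5…−3 s baseline; 0–5 s post window;
Z ≥ 2.91).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, bouts, kinematics, photometry, stats
from .errors import ConfigError

__all__ = ["RunConfig", "SessionReport", "run_session", "run_study", "load_config"]


@dataclass
class RunConfig:
    """Fully resolved parameters for a session/study run."""

    fps: float = 10.0
    confidence_threshold: float | None = None
    head_quantile: float = 0.95
    head_sd_multiplier: float = 1.0
    tail_quantile: float = 0.99
    tail_sd_multiplier: float = 3.0
    gap_s: float = 0.7
    sensor_mode: str = "dual"  # 'dual' (isosbestic) or 'single'
    baseline_lambda: float = 5e4
    baseline_diff_order: int = 1
    baseline_max_iter: int = 50
    baseline_convergence: float = 0.001
    z_threshold: float = 2.91
    min_transient_samples: int = 1
    window: tuple[float, float] = (-5.0, 10.0)
    baseline_window: tuple[float, float] = (-5.0, -3.0)
    post_window: tuple[float, float] = (0.0, 5.0)
    pre_window: tuple[float, float] = (-3.0, 0.0)
    offset_s: float = 0.0
    bout_type: str = "full_body"  # bout type used for alignment and stats
    fdr_q: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_mode not in ("dual", "single"):
            raise ConfigError("sensor_mode must be 'dual' or 'single'")
        if self.bout_type not in bouts.BOUT_TYPES + ("any",):
            raise ConfigError(f"unknown bout_type {self.bout_type!r}")
        if self.gap_s <= 0:
            raise ConfigError("gap_s must be positive")

    def mobility_config(self) -> kinematics.MobilityThresholdConfig:
        return kinematics.MobilityThresholdConfig(
            per_point={
                kinematics.HEAD_POINT: kinematics.PointThreshold(
                    self.head_quantile, self.head_sd_multiplier
                ),
                kinematics.TAIL_POINT: kinematics.PointThreshold(
                    self.tail_quantile, self.tail_sd_multiplier
                ),
            }
        )

    def baseline_config(self) -> photometry.BaselineConfig:
        return photometry.BaselineConfig(
            lambda_=self.baseline_lambda,
            diff_order=self.baseline_diff_order,
            max_iter=self.baseline_max_iter,
            convergence=self.baseline_convergence,
        )

    def transient_config(self) -> photometry.TransientConfig:
        return photometry.TransientConfig(
            z_threshold=self.z_threshold, min_samples=self.min_transient_samples
        )

    def peri_event_config(self) -> alignment.PeriEventConfig:
        return alignment.PeriEventConfig(
            window=tuple(self.window),
            baseline=tuple(self.baseline_window),
            analysis_windows={
                "post": tuple(self.post_window),
                "pre": tuple(self.pre_window),
            },
            offset_s=self.offset_s,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file, validating field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("window", "baseline_window", "post_window", "pre_window"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass
class SessionReport:
    """Artifacts and headline numbers for one analyzed session."""

    bout_table: bouts.BoutTable
    bout_summary: bouts.BoutSummary
    photometry: photometry.PhotometryResult
    aligned: alignment.EventAlignedMatrix
    metrics: pd.DataFrame
    stats: dict
    config: dict
    files: dict = field(default_factory=dict)


def analyze_session(
    track: kinematics.PoseTrack,
    recording: photometry.PhotometryRecording,
    cfg: RunConfig | None = None,
    session_id: str = "session",
) -> SessionReport:
    """Run the full analysis chain on in-memory inputs."""
    if cfg is None:
        cfg = RunConfig()
    speeds = kinematics.compute_speeds(track)
    mobility = kinematics.classify_mobility(speeds, cfg.mobility_config())
    table = bouts.segment_bouts(mobility, gap_s=cfg.gap_s, session_id=session_id)
    summary = bouts.summarize_bouts(table)

    phot = photometry.process_recording(
        recording,
        sensor_mode=cfg.sensor_mode,
        baseline_cfg=cfg.baseline_config(),
        transient_cfg=cfg.transient_config(),
    )

    selected = (
        table
        if cfg.bout_type == "any"
        else bouts.BoutTable(
            bouts=table.of_type(cfg.bout_type),
            session_s=table.session_s,
            gap_s=table.gap_s,
            fps=table.fps,
            session_id=table.session_id,
        )
    )
    aligned = alignment.align_to_events(
        recording.time, phot.dff.dff, selected, cfg.peri_event_config()
    )
    metrics = alignment.bout_metrics(aligned)

    report_stats: dict = {
        "n_bouts_total": len(table),
        "n_bouts_selected": len(selected),
        "n_bouts_retained": int(aligned.n_retained),
        "transient_frequency_hz": phot.frequency_hz,
        "n_transients": len(phot.transients),
        "offset_s": cfg.offset_s,
    }
    ok = metrics[~metrics["excluded"]]
    if len(ok) >= 3 and ok["duration_s"].std() > 0 and ok["auc_post"].std() > 0:
        corr = stats.correlate_auc_duration(
            ok["duration_s"].to_numpy(), ok["auc_post"].to_numpy()
        )
        report_stats["auc_duration"] = dataclasses.asdict(corr)
        report_stats["positive_auc"] = stats.positive_auc_proportion(
            ok["auc_post"].to_numpy()
        )
    return SessionReport(
        bout_table=table,
        bout_summary=summary,
        photometry=phot,
        aligned=aligned,
        metrics=metrics,
        stats=report_stats,
        config=cfg.to_dict(),
    )


def run_session(
    cfg: RunConfig,
    pose_path,
    photometry_path,
    out_dir,
    session_id: str = "session",
) -> SessionReport:
    """Analyze one session from files and write all artifacts to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = kinematics.read_pose_table(
        pose_path, fps=cfg.fps, confidence_threshold=cfg.confidence_threshold
    )
    rec = photometry.read_photometry_table(photometry_path)
    report = analyze_session(track, rec, cfg, session_id=session_id)

    files = {}
    report.bout_table.to_csv(out / "bouts.csv")
    files["bouts"] = str(out / "bouts.csv")
    photometry.transients_to_dataframe(report.photometry.transients).to_csv(
        out / "transients.csv", index=False
    )
    files["transients"] = str(out / "transients.csv")
    aligned_df = pd.DataFrame(
        report.aligned.z, columns=np.round(report.aligned.rel_time, 6)
    )
    aligned_df.insert(0, "onset_s", report.aligned.events["onset_s"])
    aligned_df.to_csv(out / "aligned_matrix.csv", index=False)
    files["aligned_matrix"] = str(out / "aligned_matrix.csv")
    report.metrics.to_csv(out / "bout_metrics.csv", index=False)
    files["metrics"] = str(out / "bout_metrics.csv")
    with open(out / "stats.json", "w") as fh:
        json.dump(report.stats, fh, indent=2, default=float)
    files["stats"] = str(out / "stats.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(report.config, fh)
    files["config"] = str(out / "config.yaml")
    if report.aligned.n_retained:
        fig, _, _ = alignment.build_heatmap(report.aligned)
        fig.savefig(out / "heatmap.png", dpi=100)
        files["heatmap"] = str(out / "heatmap.png")
        import matplotlib.pyplot as plt

        plt.close(fig)
    report.files = files
    return report


def run_study(
    sessions: dict[tuple, SessionReport], cfg: RunConfig | None = None
) -> dict:
    """Aggregate per-(subject, day) session reports into study tables.

    Returns per-day pooled AUC–duration correlations (bouts pooled across
    subjects within a day), day-1-normalized transient frequencies,
    day-wise bout counts, and a paired day-1 vs last-day frequency test
    when enough subjects contribute.
    """
    if cfg is None:
        cfg = RunConfig()
    rows, freq_rows, count_rows = [], [], []
    for (subject, day), rep in sorted(sessions.items()):
        ok = rep.metrics[~rep.metrics["excluded"]]
        for _, r in ok.iterrows():
            rows.append(
                {
                    "subject": subject,
                    "day": day,
                    "duration_s": r["duration_s"],
                    "auc_post": r["auc_post"],
                }
            )
        freq_rows.append(
            {
                "subject": subject,
                "day": day,
                "frequency_hz": rep.stats["transient_frequency_hz"],
            }
        )
        count_rows.append(
            {
                "subject": subject,
                "day": day,
                "count": rep.stats["n_bouts_selected"],
            }
        )
    pooled = pd.DataFrame(rows)
    freqs = pd.DataFrame(freq_rows)
    counts = pd.DataFrame(count_rows)

    per_day = []
    for day, grp in pooled.groupby("day"):
        if len(grp) >= 3 and grp["duration_s"].std() > 0:
            c = stats.correlate_auc_duration(
                grp["duration_s"].to_numpy(), grp["auc_post"].to_numpy()
            )
            per_day.append(
                {
                    "day": day,
                    "n": c.n,
                    "r": c.r,
                    "p": c.p,
                    "slope": c.slope,
                    "slope_lo": c.slope_ci[0],
                    "slope_hi": c.slope_ci[1],
                    "significant": c.significant,
                }
            )
    per_day = pd.DataFrame(per_day)

    out = {
        "per_day_correlation": per_day,
        "normalized_frequency": stats.normalize_frequency_by_day(freqs),
        "bout_counts": counts,
    }
    days = sorted(freqs["day"].unique())
    if len(days) >= 2:
        first = freqs[freqs["day"] == days[0]].set_index("subject")["frequency_hz"]
        last = freqs[freqs["day"] == days[-1]].set_index("subject")["frequency_hz"]
        common = first.index.intersection(last.index)
        if len(common) >= 2 and (first[common] - last[common]).std() > 0:
            cmp = stats.paired_t(first[common].to_numpy(), last[common].to_numpy())
            out["day_first_vs_last_frequency"] = dataclasses.asdict(cmp)
    if len(per_day) >= 2:
        slopes = per_day.sort_values("day")["slope"].to_numpy()
        out["slope_trend_nonincreasing"] = bool(np.all(np.diff(slopes) <= 0))
    return out
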