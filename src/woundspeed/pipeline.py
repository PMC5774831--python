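"""End-to-end orchestration: load -> preprocess -> detect -> trace -> fit ->
velocity -> summarize, over single sequences and multi-condition studies.

All randomness (GP restart designs) derives from one study seed via
``numpy.random.SeedSequence``, so a fixed configuration and seed reproduce
byte-identical output tables.  Every output row carries a short hash of the
run configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionParams, closure_filter, detect_with_uncertainty, reference_point
from .gp import GPFit, fit_gp
from .io import FrameSequence, load_sequence, scharr_gradient
from .velocity import (
    ConditionSummary,
    VelocityProfile,
    area_slope,
    condition_snr,
    velocity_profile,
    weighted_mean_velocity,
)

__all__ = ["RunConfig", "SequenceResult", "StudyResult", "run_sequence", "run_study"]

log = logging.getLogger("woundspeed")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    params: DetectionParams = field(default_factory=DetectionParams)
    preprocess: str = "none"  # "none" | "scharr"
    grid_size: int = 101
    pixel_scale: float = 1.0
    interval: float = 1.0  # frame interval (h) when no timestamps are given
    baseline: str | None = None  # condition label used as SNR baseline
    seed: int = 0
    channel: str = "mean"

    def __post_init__(self) -> None:
        if self.preprocess not in ("none", "scharr"):
            raise ValueError("preprocess must be 'none' or 'scharr'")
        if self.grid_size < 3:
            raise ValueError("grid_size must be >= 3")

    @property
    def config_hash(self) -> str:
        payload = asdict(self)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.md5(text.encode()).hexdigest()[:8]


@dataclass
class SequenceResult:
    """Everything the pipeline derives from one time series."""

    measurements: pd.DataFrame
    profile: VelocityProfile
    gp_area: GPFit
    gp_perimeter: GPFit
    velocity_mean: float
    velocity_mean_std: float
    area_slope: float
    config_hash: str

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meas = self.measurements.copy()
        meas["config_hash"] = self.config_hash
        meas.to_csv(outdir / "measurements.csv", index=False)
        prof = self.profile.to_frame()
        prof["config_hash"] = self.config_hash
        prof.to_csv(outdir / "velocity_profile.csv", index=False)
        self.gp_area.to_json(outdir / "gp_area.json")
        self.gp_perimeter.to_json(outdir / "gp_perimeter.json")
        return outdir


@dataclass
class StudyResult:
    """Per-replicate metrics, group statistics and SNR for a study."""

    replicates: pd.DataFrame
    summary: ConditionSummary
    failures: pd.DataFrame
    config_hash: str

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for df, name in (
            (self.replicates, "replicates.csv"),
            (self.summary.summary, "summary.csv"),
        ):
            out = df.copy()
            out["config_hash"] = self.config_hash
            out.to_csv(outdir / name, index=False)
        if self.summary.snr is not None:
            snr = self.summary.snr.copy()
            snr["config_hash"] = self.config_hash
            snr.to_csv(outdir / "snr_comparison.csv", index=False)
        if len(self.failures):
            self.failures.to_csv(outdir / "failures.csv", index=False)
        return outdir


def run_sequence(
    seq: FrameSequence,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> SequenceResult:
    """Analyze one time series end to end.

    Per-frame detection with threshold-replication uncertainty, closure
    filtering, two GP fits (area, perimeter) and the derived velocity
    profile with precision-weighted mean velocity and OLS area slope.
    Detection must succeed in at least one of the first two frames (to place
    the gating reference point) and at least 3 retained measurements are
    needed for the GP fits.
    """
    config = config or RunConfig()
    params = config.params
    gp_seed = config.seed if seed is None else seed

    frames = seq.frames
    if config.preprocess == "scharr":
        frames = [scharr_gradient(f) for f in frames]

    # reference point from the first two frames (ungated detection)
    first_two = [
        detect_with_uncertainty(frames[i], params, reference=None, time=seq.times[i])
        for i in range(2)
    ]
    c1, c2 = first_two[0].centroid, first_two[1].centroid
    if c1 is None or c2 is None:
        log.warning("wound missing in frame %d; falling back to the single detected centre",
                    1 if c1 is None else 2)
    ref = reference_point(c1, c2)

    measurements = list(first_two)
    for i in range(2, len(frames)):
        measurements.append(
            detect_with_uncertainty(frames[i], params, reference=ref, time=seq.times[i])
        )
    for m in measurements:
        log.info("t=%.2f h: area=%.1f px^2 (var %.1f), perimeter=%.1f px (var %.2f)",
                 m.time, m.area, m.area_var, m.perimeter, m.perimeter_var)

    measurements = closure_filter(measurements, seq.n_pixels, params.closure_fraction)
    retained = [m for m in measurements if not m.closed]
    if len(retained) < 3:
        raise ValueError(f"only {len(retained)} retained measurements; cannot fit the GP model")

    times = np.array([m.time for m in retained])
    areas = np.array([m.area for m in retained])
    perims = np.array([m.perimeter for m in retained])
    ss = np.random.SeedSequence([gp_seed, 0])
    s_area, s_perim = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    gp_a = fit_gp(times, areas, np.array([m.area_var for m in retained]), seed=s_area)
    gp_p = fit_gp(times, perims, np.array([m.perimeter_var for m in retained]), seed=s_perim)
    log.info("GP fits: area lml=%.2f jitter=%.2e; perimeter lml=%.2f jitter=%.2e",
             gp_a.log_marginal_likelihood, gp_a.jitter,
             gp_p.log_marginal_likelihood, gp_p.jitter)

    profile = velocity_profile(
        gp_a, gp_p, grid_size=config.grid_size, pixel_scale=config.pixel_scale
    )
    v_mean, v_std = weighted_mean_velocity(profile)
    slope = area_slope(times, areas * config.pixel_scale**2)

    meas_df = pd.DataFrame(
        {
            "frame": np.arange(len(measurements)),
            "time_h": [m.time for m in measurements],
            "area_px2": [m.area for m in measurements],
            "area_var": [m.area_var for m in measurements],
            "perimeter_px": [m.perimeter for m in measurements],
            "perimeter_var": [m.perimeter_var for m in measurements],
            "closed": [m.closed for m in measurements],
            "cx": [m.centroid[1] if m.centroid else np.nan for m in measurements],
            "cy": [m.centroid[0] if m.centroid else np.nan for m in measurements],
            "n_found": [m.n_found for m in measurements],
        }
    )
    return SequenceResult(
        measurements=meas_df,
        profile=profile,
        gp_area=gp_a,
        gp_perimeter=gp_p,
        velocity_mean=v_mean,
        velocity_mean_std=v_std,
        area_slope=slope,
        config_hash=config.config_hash,
    )


def run_study(
    conditions: dict[str, list[FrameSequence]],
    config: RunConfig | None = None,
) -> StudyResult:
    """Analyze a multi-condition study.

    ``conditions`` maps condition labels to replicate sequences.  Replicates
    that fail (e.g. wound lost before 3 time points) are reported in the
    failure table and excluded; group statistics and — when
    ``config.baseline`` is set — SNR per metric are computed from the rest.
    """
    config = config or RunConfig()
    if len(conditions) < 1:
        raise ValueError("no conditions given")
    rows, fails = [], []
    for label in conditions:
        label_key = int(hashlib.md5(label.encode()).hexdigest()[:8], 16)
        for j, seq in enumerate(conditions[label]):
            rep_seed = int(np.random.SeedSequence([config.seed, label_key, j])
                           .generate_state(1)[0] % 2**31)
            try:
                res = run_sequence(seq, config, seed=rep_seed)
            except (ValueError, RuntimeError) as exc:
                log.warning("replicate %s/%d failed: %s", label, j, exc)
                fails.append({"condition": label, "replicate": j, "error": str(exc)})
                continue
            rows.append(
                {
                    "condition": label,
                    "replicate": j,
                    "velocity": res.velocity_mean,
                    "velocity_std": res.velocity_mean_std,
                    "area_slope": res.area_slope,
                }
            )
    replicates = pd.DataFrame(rows)
    if replicates.empty:
        raise ValueError("every replicate failed; no study statistics")
    summary = condition_snr(replicates, baseline=config.baseline)
    return StudyResult(
        replicates=replicates,
        summary=summary,
        failures=pd.DataFrame(fails, columns=["condition", "replicate", "error"]),
        config_hash=config.config_hash,
    )


def load_study(root: str | Path, config: RunConfig) -> dict[str, list[FrameSequence]]:
    """Read a ``study/<condition>/<replicate>/frame_*.tif`` directory tree."""
    root = Path(root)
    conditions: dict[str, list[FrameSequence]] = {}
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        reps = []
        for rep_dir in sorted(p for p in cond_dir.iterdir() if p.is_dir()):
            reps.append(
                load_sequence(
                    rep_dir,
                    interval=config.interval,
                    pixel_scale=config.pixel_scale,
                    channel=config.channel,
                )
            )
        if reps:
            conditions[cond_dir.name] = reps
    if not conditions:
        raise OSError(f"no condition directories under {root}")
    return conditions
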