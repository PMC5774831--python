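"""Concerted cell velocity and assay-quality statistics.

The velocity of the advancing cell front is the rate of wound-area closure
normalized by the wound perimeter,

    v(t) = -(d/dt A_hat(t)) / P_hat(t),

evaluated on the GP posterior means of area and perimeter; the sign
convention makes a shrinking (healing) wound positive.  For a front moving
at constant normal speed this quantity equals that speed for *any* wound
shape — unlike the raw area slope, whose magnitude scales with the wound
perimeter and therefore confounds speed with geometry.

The derivative is a second-order central difference on a uniform time grid;
the velocity standard deviation follows by first-order (independent-error)
propagation of the GP posterior standard deviations:

    sigma_Adot = sqrt(sigma_A(t+h)^2 + sigma_A(t-h)^2) / (2h)
    sigma_v^2  = (sigma_Adot / P)^2 + (Adot * sigma_P / P^2)^2

Summary statistics per time series are the precision-weighted mean velocity
(weights 1/sigma_v^2) and the OLS slope of the measured areas; per condition
the group mean/SD of each metric and, against a designated baseline
condition, the signal-to-noise ratio SNR = (mu_cond - mu_base) / sd_base.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .gp import GPFit, predict

__all__ = [
    "VelocityProfile",
    "ConditionSummary",
    "velocity_profile",
    "weighted_mean_velocity",
    "area_slope",
    "condition_snr",
]

#: default number of uniform grid points for posterior prediction
DEFAULT_GRID_SIZE = 101
#: precision weights are capped here so a zero-sigma point cannot dominate
MAX_WEIGHT = 1e12


@dataclass
class VelocityProfile:
    """Velocity with uncertainty on a uniform time grid.

    ``area``/``perimeter`` (and stds) cover the full grid; the velocity is
    defined on the interior grid points (central differences need both
    neighbours), i.e. ``grid[1:-1]``.
    """

    grid: np.ndarray  # full uniform time grid, h
    area: np.ndarray  # px^2
    area_std: np.ndarray
    perimeter: np.ndarray  # px
    perimeter_std: np.ndarray
    velocity: np.ndarray  # px/h (or um/h when scaled), on grid[1:-1]
    velocity_std: np.ndarray

    @property
    def interior_grid(self) -> np.ndarray:
        return self.grid[1:-1]

    def to_frame(self) -> pd.DataFrame:
        v = np.full(len(self.grid), np.nan)
        vs = np.full(len(self.grid), np.nan)
        v[1:-1] = self.velocity
        vs[1:-1] = self.velocity_std
        return pd.DataFrame(
            {
                "time_h": self.grid,
                "area": self.area,
                "area_std": self.area_std,
                "perimeter": self.perimeter,
                "perimeter_std": self.perimeter_std,
                "velocity": v,
                "velocity_std": vs,
            }
        )


def velocity_profile(
    gp_area: GPFit,
    gp_perimeter: GPFit,
    grid: np.ndarray | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    pixel_scale: float = 1.0,
) -> VelocityProfile:
    """Posterior velocity profile on a uniform time grid.

    By default the grid spans the area fit's training range with
    ``grid_size`` points.  Area/perimeter keep native pixel units scaled by
    ``pixel_scale``/``pixel_scale**2``; with a pixel scale in um/px the
    velocity comes out in um/h.
    """
    if grid is None:
        lo, hi = gp_area.train_range
        grid = np.linspace(lo, hi, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
        if len(grid) < 3:
            raise ValueError("grid needs at least 3 points for central differences")
        h = np.diff(grid)
        if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12) or h[0] <= 0:
            raise ValueError("grid must be uniformly spaced and increasing")
    h = float(grid[1] - grid[0])

    a_mean, a_std = predict(gp_area, grid)
    p_mean, p_std = predict(gp_perimeter, grid)
    if (p_mean <= 0).any():
        raise ValueError(
            "predicted perimeter is non-positive on the grid; "
            "wound closed or the fit is invalid there"
        )
    a_dot = (a_mean[2:] - a_mean[:-2]) / (2 * h)
    a_dot_std = np.sqrt(a_std[2:] ** 2 + a_std[:-2] ** 2) / (2 * h)
    p_in, p_in_std = p_mean[1:-1], p_std[1:-1]
    v = -a_dot / p_in
    v_var = (a_dot_std / p_in) ** 2 + (a_dot * p_in_std / p_in**2) ** 2
    s = float(pixel_scale)
    return VelocityProfile(
        grid=grid,
        area=a_mean * s * s,
        area_std=a_std * s * s,
        perimeter=p_mean * s,
        perimeter_std=p_std * s,
        velocity=v * s,
        velocity_std=np.sqrt(v_var) * s,
    )


def weighted_mean_velocity(profile: VelocityProfile) -> tuple[float, float]:
    """Precision-weighted mean velocity over the profile's interior grid.

    Weights are the velocity precisions ``1/sigma_v^2`` (capped at
    ``MAX_WEIGHT`` so an exactly-zero sigma cannot swallow the average);
    the reported standard deviation is ``(sum w)^(-1/2)``.
    """
    v = profile.velocity
    s = profile.velocity_std
    if len(v) == 0:
        raise ValueError("empty velocity profile")
    with np.errstate(divide="ignore"):
        w = np.where(s > 0, 1.0 / np.square(s), np.inf)
    w = np.minimum(w, MAX_WEIGHT)
    wsum = float(w.sum())
    return float((w * v).sum() / wsum), float(wsum ** -0.5)


def area_slope(times: np.ndarray, areas: np.ndarray) -> float:
    """OLS slope of measured wound area vs time (the conventional readout)."""
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(t) < 2:
        raise ValueError("area slope needs at least 2 measurements")
    if np.ptp(t) == 0:
        raise ValueError("all times equal; slope undefined")
    return float(np.polyfit(t, a, 1)[0])


@dataclass
class ConditionSummary:
    """Group statistics per condition and SNR against the baseline."""

    replicates: pd.DataFrame  # condition, replicate, velocity, velocity_std, area_slope
    summary: pd.DataFrame  # condition x (n, velocity_mean, velocity_sd, area_slope_mean, area_slope_sd)
    snr: pd.DataFrame | None  # condition x metric SNR table (baseline rows excluded)
    baseline: str | None


def condition_snr(
    replicate_metrics: pd.DataFrame,
    baseline: str | None = None,
) -> ConditionSummary:
    """Summarize a multi-condition study and compute SNR vs the baseline.

    ``replicate_metrics`` needs columns ``condition``, ``velocity`` and
    ``area_slope`` (one row per replicate).  For each non-baseline condition
    and each metric, SNR = (mean_cond - mean_baseline) / sd_baseline; with a
    zero baseline SD the SNR is undefined and reported as NaN.
    """
    req = {"condition", "velocity", "area_slope"}
    missing = req - set(replicate_metrics.columns)
    if missing:
        raise ValueError(f"replicate metrics missing columns {sorted(missing)}")
    grp = replicate_metrics.groupby("condition", sort=False)
    summary = grp.agg(
        n=("velocity", "size"),
        velocity_mean=("velocity", "mean"),
        velocity_sd=("velocity", lambda x: x.std(ddof=1)),
        area_slope_mean=("area_slope", "mean"),
        area_slope_sd=("area_slope", lambda x: x.std(ddof=1)),
    ).reset_index()

    snr = None
    if baseline is not None:
        if baseline not in set(summary["condition"]):
            raise ValueError(f"baseline condition {baseline!r} not present")
        base = summary.set_index("condition").loc[baseline]
        if base["n"] < 2:
            raise ValueError("baseline needs at least 2 replicates")
        rows = []
        for _, row in summary.iterrows():
            if row["condition"] == baseline:
                continue
            rows.append(
                {
                    "condition": row["condition"],
                    "snr_velocity": _snr(row["velocity_mean"], base["velocity_mean"], base["velocity_sd"]),
                    "snr_area_slope": _snr(
                        row["area_slope_mean"], base["area_slope_mean"], base["area_slope_sd"]
                    ),
                }
            )
        snr = pd.DataFrame(rows)
    return ConditionSummary(
        replicates=replicate_metrics.reset_index(drop=True),
        summary=summary,
        snr=snr,
        baseline=baseline,
    )


def _snr(mu_cond: float, mu_base: float, sd_base: float) -> float:
    if not sd_base > 0:
        return float("nan")
    return float((mu_cond - mu_base) / sd_base)
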