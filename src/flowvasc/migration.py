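"""Flow-parallel migration statistics from nuclear tracking under flow.

Velocities are forward differences at the native frame interval.  The
sign convention is declared in all outputs: positive parallel velocity
means migration WITH the flow, so collective migration against flow
shows up as a negative mean.  The replicate (independent experiment),
not the cell, is the unit of analysis for population curves and their
bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import TrackSet
from .estimation import BootstrapEstimate, bootstrap_mean_difference

logger = logging.getLogger(__name__)

SIGN_CONVENTION = "positive v_par = with flow"

#: tracks shorter than this many frames are excluded from velocity
#: statistics (spurious short tracks otherwise dominate step counts)
MIN_TRACK_FRAMES = 10


@dataclass
class VelocityCurve:
    """Per-time-bin mean flow-parallel velocity and total speed.

    ``df`` columns: t_center, v_par, speed, n_steps, n_replicates and
    bootstrap 95% CI bounds per quantity.  Bins without data are absent
    rather than zero.
    """

    condition: str
    df: pd.DataFrame
    bin_hours: float
    flow: tuple[float, float]
    sign_convention: str = SIGN_CONVENTION

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out.insert(0, "condition", self.condition)
        return out


@dataclass
class TrajectoryEnsemble:
    """Start-normalized resampled trajectories for rose-style plots.

    ``df`` columns: condition, replicate, traj, t, x, y (µm, every
    trajectory starts at (0, 0)); ``colors`` holds the mean parallel
    velocity per trajectory for colour mapping.
    """

    df: pd.DataFrame
    colors: pd.DataFrame
    n_per_replicate: int
    window: tuple[float, float]
    seed: int

    @property
    def n_trajectories(self) -> int:
        return len(self.colors)


# ---------------------------------------------------------------------------


def step_velocities(track: pd.DataFrame) -> pd.DataFrame:
    """Forward-difference velocity per consecutive sample pair.

    Expects columns t (h), x, y (µm) for a single track; gaps in the
    frame sequence are handled by dividing by the actual time step.
    Returns columns t_mid, vx, vy.
    """
    if len(track) < 2:
        raise ValueError("velocity needs at least 2 points")
    t = track["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-increasing times within a track")
    vx = np.diff(track["x"].to_numpy(dtype=float)) / dt
    vy = np.diff(track["y"].to_numpy(dtype=float)) / dt
    return pd.DataFrame({"t_mid": t[:-1] + dt / 2, "vx": vx, "vy": vy})


def parallel_decomposition(vx, vy, flow: tuple[float, float]) -> pd.DataFrame:
    """Decompose step velocities relative to the flow direction.

    v_par = v · u (positive = with flow), v_perp = magnitude of the
    orthogonal component; v_par² + v_perp² = speed².
    """
    u = np.asarray(flow, dtype=float)
    norm = np.hypot(*u)
    if norm == 0:
        raise ValueError("zero flow vector")
    if not np.isclose(norm, 1.0, atol=1e-8):
        raise ValueError("flow direction must be a unit vector")
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    v_par = vx * u[0] + vy * u[1]
    speed = np.hypot(vx, vy)
    v_perp = np.sqrt(np.maximum(speed**2 - v_par**2, 0.0))
    return pd.DataFrame({"v_par": v_par, "v_perp": v_perp, "speed": speed})


def _step_table(ts: TrackSet, flow: tuple[float, float],
                min_frames: int = MIN_TRACK_FRAMES,
                per_track_mean: bool = False) -> pd.DataFrame:
    """All step velocities of a track set, flow-decomposed and labelled.

    With ``per_track_mean`` each track contributes its within-track mean
    instead of its raw steps (alternative averaging order)."""
    parts = []
    for key, grp in ts.iter_tracks():
        if len(grp) < max(min_frames, 2):
            continue
        v = step_velocities(grp)
        dec = parallel_decomposition(v["vx"], v["vy"], flow)
        step = pd.concat([v, dec], axis=1)
        step["condition"], step["replicate"], step["population"], step["track"] = key
        parts.append(step)
    if not parts:
        raise ValueError("no tracks pass the minimum-length filter")
    steps = pd.concat(parts, ignore_index=True)
    if per_track_mean:
        steps = (steps.groupby(["condition", "replicate", "population", "track"])
                 [["t_mid", "v_par", "speed"]].mean().reset_index())
    return steps


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                  n_boot: int) -> tuple[float, float]:
    if values.size == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))


def population_velocity_curve(ts: TrackSet, flow: tuple[float, float],
                              bin_hours: float = 1.0,
                              min_frames: int = MIN_TRACK_FRAMES,
                              n_boot: int = 1000, seed: int = 0,
                              per_track_mean: bool = False
                              ) -> dict[str, VelocityCurve]:
    """Mean v_par and speed per time bin for each condition.

    Steps are pooled within each replicate and time bin, then averaged
    across replicates (the replicate is the unit of analysis); 95% CIs
    come from bootstrapping over replicates.
    """
    if bin_hours <= 0:
        raise ValueError("bin width must be positive")
    steps = _step_table(ts, flow, min_frames, per_track_mean)
    steps["bin"] = np.floor(steps["t_mid"] / bin_hours).astype(int)
    rng = np.random.default_rng(seed)
    curves: dict[str, VelocityCurve] = {}
    per_rep = (steps.groupby(["condition", "replicate", "bin"])
               .agg(v_par=("v_par", "mean"), speed=("speed", "mean"),
                    n_steps=("v_par", "size")).reset_index())
    for cond, grp in per_rep.groupby("condition"):
        rows = []
        for b, bin_grp in grp.groupby("bin"):
            vp = bin_grp["v_par"].to_numpy()
            spd = bin_grp["speed"].to_numpy()
            vp_lo, vp_hi = _bootstrap_ci(vp, rng, n_boot)
            sp_lo, sp_hi = _bootstrap_ci(spd, rng, n_boot)
            rows.append({"t_center": (b + 0.5) * bin_hours,
                         "v_par": vp.mean(), "speed": spd.mean(),
                         "n_steps": int(bin_grp["n_steps"].sum()),
                         "n_replicates": len(bin_grp),
                         "v_par_lo": vp_lo, "v_par_hi": vp_hi,
                         "speed_lo": sp_lo, "speed_hi": sp_hi})
        curves[cond] = VelocityCurve(condition=cond,
                                     df=pd.DataFrame(rows).sort_values("t_center")
                                     .reset_index(drop=True),
                                     bin_hours=bin_hours, flow=tuple(flow))
    return curves


def bootstrap_trajectories(ts: TrackSet, flow: tuple[float, float],
                           n_per_replicate: int = 100,
                           window: tuple[float, float] = (0.0, 5.0),
                           seed: int = 0) -> TrajectoryEnsemble:
    """Resample tracks with replacement per replicate, clip them to the
    time window and normalize each to start at (0, 0).

    With the experimental design of 100 tracks per replicate and 4
    replicates this yields 400 trajectories per condition.  The colour
    value of a trajectory is its mean flow-parallel velocity over the
    clipped part (negative = against flow).
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty time window")
    rng = np.random.default_rng(seed)
    out = []
    colors = []
    traj_id = 0
    for (cond, rep), grp in ts.df.groupby(["condition", "replicate"]):
        tracks = []
        for tr, tdf in grp.groupby(["population", "track"]):
            clip = tdf[(tdf["t"] >= lo) & (tdf["t"] <= hi)]
            if len(clip) >= 2:
                tracks.append(clip)
        if not tracks:
            raise ValueError(f"no track intersects the window in "
                             f"condition {cond!r} replicate {rep!r}")
        pick = rng.integers(0, len(tracks), size=n_per_replicate)
        for i in pick:
            clip = tracks[i]
            x = clip["x"].to_numpy() - clip["x"].iloc[0]
            y = clip["y"].to_numpy() - clip["y"].iloc[0]
            t = clip["t"].to_numpy()
            v = step_velocities(pd.DataFrame({"t": t, "x": x, "y": y}))
            dec = parallel_decomposition(v["vx"], v["vy"], flow)
            out.append(pd.DataFrame({"condition": cond, "replicate": rep,
                                     "traj": traj_id, "t": t, "x": x, "y": y}))
            colors.append({"condition": cond, "replicate": rep, "traj": traj_id,
                           "v_par_mean": float(dec["v_par"].mean())})
            traj_id += 1
    return TrajectoryEnsemble(df=pd.concat(out, ignore_index=True),
                              colors=pd.DataFrame(colors),
                              n_per_replicate=n_per_replicate,
                              window=window, seed=seed)


@dataclass
class MosaicComparison:
    """Two-population (dye channel) comparison within mosaic cultures."""

    curves: dict[str, VelocityCurve]          # population -> curve
    contrasts: dict[str, BootstrapEstimate]   # v_par and speed contrasts
    populations: tuple[str, str]              # difference = first - second


def mosaic_compare(ts: TrackSet, flow: tuple[float, float],
                   populations: tuple[str, str] | None = None,
                   bin_hours: float = 1.0, min_frames: int = MIN_TRACK_FRAMES,
                   n_boot: int = 5000, seed: int = 0) -> MosaicComparison:
    """Velocity curves per population plus bootstrap mean differences of
    the replicate-wise time-averaged v_par and total speed.

    Every replicate must contain both populations; the difference is
    first population minus second.
    """
    pops = populations or tuple(sorted(ts.df["population"].unique()))
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations, got {pops}")
    reps = sorted(ts.df["replicate"].unique())
    for rep in reps:
        present = set(ts.df.loc[ts.df["replicate"] == rep, "population"])
        for p in pops:
            if p not in present:
                raise ValueError(f"population {p!r} missing from replicate {rep}")
    steps = _step_table(ts, flow, min_frames)
    per_rep = (steps.groupby(["population", "replicate"])
               .agg(v_par=("v_par", "mean"), speed=("speed", "mean"))
               .reset_index())
    curves = {}
    for p in pops:
        sub = ts.df[ts.df["population"] == p].copy()
        sub["condition"] = p
        pc = population_velocity_curve(TrackSet(sub, ts.frame_interval), flow,
                                       bin_hours=bin_hours, min_frames=min_frames,
                                       seed=seed)
        curves[p] = pc[p]
    contrasts = {}
    for metric in ("v_par", "speed"):
        a = per_rep.loc[per_rep["population"] == pops[0], metric].to_numpy()
        b = per_rep.loc[per_rep["population"] == pops[1], metric].to_numpy()
        contrasts[metric] = bootstrap_mean_difference(a, b, n_boot=n_boot, seed=seed)
    return MosaicComparison(curves=curves, contrasts=contrasts, populations=pops)
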