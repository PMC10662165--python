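"""Arena-trajectory personality metrics.

Behavioural trials record a fish's 2-D position through the front glass of its
arena at a fixed frame cadence (six frames per minute by default); frames where
the fish is buried in the sand carry no position (detected flag 0).  From these
trajectories this module computes the activity metrics (distance travelled,
95% and 50% utilization-distribution areas, circular turning-angle statistics,
time out of the refuge), the trajectory-based exploration metrics (time near a
novel object, minimum distance to it), and the boldness latency record.

Positions are in cm internally; Distance is reported in m and areas in m**2.
All metrics are computed only for trials where the fish was detected outside
the sand for at least 20 s; below that exposure the trial's metrics are
missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FRAMES_PER_MINUTE_DEFAULT = 6


@dataclass
class Trajectory:
    """Frame-indexed 2-D arena positions for one trial.

    t_seconds strictly increasing; x/y are NaN where detected == 0.
    """

    trial_id: str
    t_seconds: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    detected: np.ndarray
    duration_s: float
    frames_per_minute: int = FRAMES_PER_MINUTE_DEFAULT

    def __post_init__(self):
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n = len(self.t_seconds)
        if not (len(self.x_cm) == len(self.y_cm) == len(self.detected) == n):
            raise ValueError("frame arrays must have equal length")
        if n > 1 and np.any(np.diff(self.t_seconds) <= 0):
            raise ValueError("t_seconds must be strictly increasing")

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    def detected_xy(self) -> np.ndarray:
        return np.column_stack([self.x_cm[self.detected], self.y_cm[self.detected]])


@dataclass
class ActivityMetrics:
    distance_m: float
    area_m2: float
    core_area_m2: float
    mean_angle_rad: float
    kappa_angle: float
    time_out_s: float


@dataclass
class ExplorationMetrics:
    interactions: int
    time_out_s: float
    min_distance_cm: float
    time_toy_s: float


@dataclass
class BoldnessRecord:
    latency_s: float
    buried_at_stimulus: bool
    censored: bool = False


@dataclass
class AggressionRecord:
    bites: int
    rams: int
    charges: int

    def __post_init__(self):
        for name in ("bites", "rams", "charges"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))


# ---------------------------------------------------------------------------
# Exposure filter
# ---------------------------------------------------------------------------

def detected_seconds(traj: Trajectory) -> float:
    """Seconds of above-sand exposure implied by the detected-frame count."""
    return traj.n_detected / traj.frames_per_minute * 60.0


def passes_exposure_filter(traj: Trajectory, min_seconds: float = 20.0) -> bool:
    """True when the fish was detected outside the sand for >= min_seconds."""
    return detected_seconds(traj) >= min_seconds


# ---------------------------------------------------------------------------
# Per-minute reduction and path metrics
# ---------------------------------------------------------------------------

def per_minute_positions(traj: Trajectory) -> pd.DataFrame:
    """One representative position per minute with >= 1 detected frame.

    The representative is the component-wise median of that minute's detected
    frames (robust to single-frame detector glitches); minutes with no
    detected frame are absent from the output.
    """
    mask = traj.detected
    if not mask.any():
        return pd.DataFrame(columns=["minute", "x_cm", "y_cm"]).astype(
            {"minute": int, "x_cm": float, "y_cm": float})
    minute = np.floor(traj.t_seconds[mask] / 60.0).astype(int)
    df = pd.DataFrame({"minute": minute, "x_cm": traj.x_cm[mask],
                       "y_cm": traj.y_cm[mask]})
    out = df.groupby("minute", sort=True).median().reset_index()
    return out


def total_distance(pos: pd.DataFrame) -> float:
    """Cumulative Euclidean distance (m) between consecutive minute positions.

    Gaps (buried minutes) contribute one straight-line segment between the
    flanking available positions.
    """
    if len(pos) < 2:
        warnings.warn("fewer than 2 minute positions; distance set to 0")
        return 0.0
    dx = np.diff(pos["x_cm"].to_numpy())
    dy = np.diff(pos["y_cm"].to_numpy())
    return float(np.hypot(dx, dy).sum() / 100.0)


def turning_angles(pos: pd.DataFrame) -> np.ndarray:
    """Signed angles between successive displacement vectors, in (-pi, pi].

    Counter-clockwise positive (x right, y up).  Zero-length displacements are
    skipped.  Fewer than 3 positions yield an empty array.
    """
    if len(pos) < 3:
        return np.empty(0)
    xy = pos[["x_cm", "y_cm"]].to_numpy()
    steps = np.diff(xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    steps = steps[lengths > 0]
    if len(steps) < 2:
        return np.empty(0)
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    d = np.diff(headings)
    return _wrap_angle(d)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(a + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def circular_mean(angles) -> float:
    """Direction of the mean resultant vector."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    return float(np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()))


#: kappa returned when the mean resultant length is numerically 1
KAPPA_CAP = 1e6


def vonmises_kappa(angles) -> float:
    """Maximum-likelihood Von Mises concentration (Best-Fisher approximation).

    Piecewise inverse of the Bessel ratio A1(kappa) = I1/I0 in the mean
    resultant length R; R ~ 0 maps to 0 and R ~ 1 to KAPPA_CAP.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least two angles")
    rbar = float(np.hypot(np.sin(angles).mean(), np.cos(angles).mean()))
    if rbar < 1e-12:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        return KAPPA_CAP
    if rbar < 0.53:
        k = 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)
    return float(min(k, KAPPA_CAP))


# ---------------------------------------------------------------------------
# Utilization-distribution areas
# ---------------------------------------------------------------------------

def utilization_area(pos: pd.DataFrame, p: float = 0.95, grid_size: int = 200,
                     bandwidth_cm: float | None = None) -> float:
    """Area (m**2) of the p-volume contour of a Gaussian kernel UD.

    A bivariate Gaussian kernel density is evaluated on a grid over the
    position extent padded by three bandwidths; cells are accumulated in
    decreasing density order until they hold probability mass p, and the
    covered cell area is returned.  The default bandwidth is the reference
    ("href") bandwidth sigma_hat * n**(-1/6) per axis, sigma_hat being the
    mean of the axis standard deviations.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    n = len(pos)
    if n < 5:
        warnings.warn("fewer than 5 positions; utilization area undefined")
        return float("nan")
    xy = pos[["x_cm", "y_cm"]].to_numpy(dtype=float)
    if bandwidth_cm is None:
        sd = 0.5 * (xy[:, 0].std(ddof=1) + xy[:, 1].std(ddof=1))
        if sd == 0:
            warnings.warn("degenerate (constant) positions; area 0")
            return 0.0
        bandwidth_cm = sd * n ** (-1.0 / 6.0)
    h = float(bandwidth_cm)
    pad = 3.0 * h
    gx = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_size)
    gy = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_size)
    dxc = gx[1] - gx[0]
    dyc = gy[1] - gy[0]
    # evaluate the KDE one grid row at a time to bound memory
    density = np.empty((grid_size, grid_size))
    inv2h2 = 1.0 / (2.0 * h * h)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    for i in range(grid_size):
        d2 = (X[i][:, None] - xy[None, :, 0]) ** 2 + (Y[i][:, None] - xy[None, :, 1]) ** 2
        density[i] = np.exp(-d2 * inv2h2).sum(axis=1)
    density /= density.sum()
    flat = np.sort(density.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, p) + 1)
    area_cm2 = n_cells * dxc * dyc
    return float(area_cm2 / 1e4)


# ---------------------------------------------------------------------------
# Time-based metrics
# ---------------------------------------------------------------------------

def time_out(traj: Trajectory, test_duration_s: float | None = None) -> float:
    """Seconds outside the sand: detected-frame fraction times test duration."""
    duration = traj.duration_s if test_duration_s is None else test_duration_s
    expected = duration / 60.0 * traj.frames_per_minute
    if expected <= 0:
        return 0.0
    return float(traj.n_detected / expected * duration)


def exploration_metrics(traj: Trajectory, object_xy, radius_cm: float = 6.0,
                        manual_interactions: int = 0,
                        test_duration_s: float | None = None) -> ExplorationMetrics:
    """Novel-object trial metrics: TimeOut, MinDistance, TimeToy, Interactions.

    TimeToy is the fraction of detected frames within ``radius_cm`` of the
    object centroid, scaled to trial duration the same way as TimeOut, so
    TimeToy <= TimeOut always holds.
    """
    if manual_interactions < 0 or manual_interactions != int(manual_interactions):
        raise ValueError("manual_interactions must be a non-negative integer")
    duration = traj.duration_s if test_duration_s is None else test_duration_s
    ox, oy = float(object_xy[0]), float(object_xy[1])
    tout = time_out(traj, duration)
    if traj.n_detected == 0:
        return ExplorationMetrics(interactions=int(manual_interactions),
                                  time_out_s=tout, min_distance_cm=float("nan"),
                                  time_toy_s=0.0)
    xy = traj.detected_xy()
    dist = np.hypot(xy[:, 0] - ox, xy[:, 1] - oy)
    expected = duration / 60.0 * traj.frames_per_minute
    time_toy = float((dist <= radius_cm).sum() / expected * duration)
    return ExplorationMetrics(
        interactions=int(manual_interactions),
        time_out_s=tout,
        min_distance_cm=float(dist.min()),
        time_toy_s=time_toy,
    )


def boldness_latency(emergence_time_s: float | None,
                     buried_at_stimulus: bool,
                     observation_end_s: float | None = None) -> BoldnessRecord:
    """Emergence latency after a simulated predator attack.

    A fish that never buried scores 0 (already exposed); a buried fish that
    emerged scores its emergence time; a buried fish that never emerged is
    recorded at the observation window end with a censored flag.
    """
    if not buried_at_stimulus:
        return BoldnessRecord(latency_s=0.0, buried_at_stimulus=False)
    if emergence_time_s is None:
        if observation_end_s is None:
            raise ValueError("censored record needs the observation window end")
        return BoldnessRecord(latency_s=float(observation_end_s),
                              buried_at_stimulus=True, censored=True)
    if emergence_time_s < 0:
        raise ValueError("emergence time must be >= 0")
    return BoldnessRecord(latency_s=float(emergence_time_s),
                          buried_at_stimulus=True)


# ---------------------------------------------------------------------------
# Trial-level assembly
# ---------------------------------------------------------------------------

def activity_metrics(traj: Trajectory, test_duration_s: float | None = None,
                     min_exposure_s: float = 20.0) -> ActivityMetrics | None:
    """All activity metrics for one open-field trial, or None below the
    20-s exposure filter."""
    if not passes_exposure_filter(traj, min_exposure_s):
        return None
    pos = per_minute_positions(traj)
    angles = turning_angles(pos)
    if angles.size >= 2:
        mean_angle = circular_mean(angles)
        kappa = vonmises_kappa(angles)
    else:
        mean_angle, kappa = float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        area = utilization_area(pos, 0.95)
        core = utilization_area(pos, 0.50)
        dist = total_distance(pos)
    return ActivityMetrics(
        distance_m=dist, area_m2=area, core_area_m2=core,
        mean_angle_rad=mean_angle, kappa_angle=kappa,
        time_out_s=time_out(traj, test_duration_s),
    )


def trajectory_from_frame(df: pd.DataFrame, trial_id: str | None = None,
                          duration_s: float | None = None,
                          frames_per_minute: int = FRAMES_PER_MINUTE_DEFAULT) -> Trajectory:
    """Build a Trajectory from a tidy frame (t_seconds, x_cm, y_cm, detected)."""
    df = df.sort_values("t_seconds")
    tid = trial_id if trial_id is not None else str(df["trial_id"].iloc[0]) if "trial_id" in df else ""
    dur = duration_s if duration_s is not None else float(
        df["t_seconds"].iloc[-1] + 60.0 / frames_per_minute)
    det = df["detected"].to_numpy().astype(bool)
    x = df["x_cm"].to_numpy(dtype=float).copy()
    y = df["y_cm"].to_numpy(dtype=float).copy()
    x[~det] = np.nan
    y[~det] = np.nan
    return Trajectory(trial_id=tid, t_seconds=df["t_seconds"].to_numpy(dtype=float),
                      x_cm=x, y_cm=y, detected=det, duration_s=dur,
                      frames_per_minute=frames_per_minute)
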