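"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be simulated here: acoustic
detection time series of free-living fish with individual-specific chronotypes
(awakening offset relative to sunrise, rest onset relative to sunset),
environmental day covariates, multi-trait laboratory trial tables with
specified between- and within-individual covariance, and arena trajectories
with Von Mises turning and burial bouts.  The generators return the latent
quantities (true offsets, state sequences, random intercepts, covariances)
alongside the observable tables, so recovery by the downstream estimators can
be verified against the truth.

All randomness flows from the ``seed`` field of each config via
``numpy.random.default_rng``; identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trajectory import Trajectory

TRAITS_DEFAULT = ("exploration", "activity", "boldness", "aggressiveness")


def _minutes(clock: str) -> float:
    """Clock string 'HH:MM' -> minutes from midnight."""
    h, m = clock.split(":")
    return int(h) * 60.0 + float(m)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class ChronoSimConfig:
    """Free-living chronotype simulation.

    Wake/rest offsets are in minutes relative to sunrise/sunset; per-bin
    detection counts are ZIP(pi_zero_active, lambda_active) while Active and
    Poisson(lambda_rest) while Rest (buried fish are acoustically silent, so
    lambda_rest defaults to 0).
    """

    n_individuals: int = 30
    n_days: int = 14
    bin_minutes: int = 5
    mu_wake: float = 20.0
    sd_wake_between: float = 30.0
    sd_wake_within: float = 10.0
    mu_rest: float = -10.0
    sd_rest_between: float = 30.0
    sd_rest_within: float = 10.0
    beta_env: dict = field(default_factory=lambda: {"light": 0.0, "temperature": 0.0, "waves": 0.0})
    lambda_active: float = 4.0
    pi_zero_active: float = 0.2
    lambda_rest: float = 0.0
    sunrise_time: str = "07:00"
    sunset_time: str = "19:00"
    start_date: str = "2022-05-01"
    seed: int = 0

    def validate(self) -> None:
        for name in ("sd_wake_between", "sd_wake_within", "sd_rest_between", "sd_rest_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.lambda_active > self.lambda_rest >= 0):
            raise ValueError("require lambda_active > lambda_rest >= 0")
        if not (0 <= self.pi_zero_active < 1):
            raise ValueError("pi_zero_active must be in [0, 1)")
        if 1440 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 1440")
        if self.n_individuals < 1 or self.n_days < 1:
            raise ValueError("need at least one individual and one day")
        # degenerate-schedule guard: P(realized rest time <= wake time) > 1%
        gap_mean = (_minutes(self.sunset_time) + self.mu_rest
                    - _minutes(self.sunrise_time) - self.mu_wake)
        beta = np.array(list(self.beta_env.values()), dtype=float)
        gap_var = (self.sd_wake_between ** 2 + self.sd_wake_within ** 2
                   + self.sd_rest_between ** 2 + self.sd_rest_within ** 2)
        gap_sd = np.sqrt(gap_var + 2.0 * float(beta @ beta))
        p_degenerate = norm.cdf(0.0, loc=gap_mean, scale=max(gap_sd, 1e-12))
        if p_degenerate > 0.01:
            raise ValueError(
                f"degenerate schedule: P(rest <= wake) = {p_degenerate:.3f} > 1%")


@dataclass
class TraitSimConfig:
    """Laboratory multi-trait trial simulation.

    y[i, t, trait] = mu + beta * covariates + u[i, trait] + b[batch] + e,
    with individual rows u ~ MVN(0, Sigma_ind) and residual rows
    e ~ MVN(0, Sigma_e).  Body size defaults mirror the study cohort
    (15.30 +/- 2.43 cm); batches hold 12 individuals.
    """

    n_individuals: int = 40
    n_trials: int = 4
    trait_names: tuple = TRAITS_DEFAULT
    mu: np.ndarray | None = None
    Sigma_ind: np.ndarray | None = None
    Sigma_e: np.ndarray | None = None
    beta_size: np.ndarray | None = None
    beta_condition: np.ndarray | None = None
    beta_day: np.ndarray | None = None
    sd_batch: float = 0.2
    batch_size: int = 12
    size_mean: float = 15.30
    size_sd: float = 2.43
    lw_a: float = 0.0085
    lw_b: float = 3.10
    seed: int = 0

    def __post_init__(self):
        k = len(self.trait_names)
        if self.mu is None:
            self.mu = np.zeros(k)
        if self.Sigma_ind is None:
            self.Sigma_ind = 0.3 * np.eye(k)
        if self.Sigma_e is None:
            self.Sigma_e = 0.7 * np.eye(k)
        for name in ("beta_size", "beta_condition", "beta_day"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(k))
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma_ind = np.asarray(self.Sigma_ind, dtype=float)
        self.Sigma_e = np.asarray(self.Sigma_e, dtype=float)
        self.beta_size = np.asarray(self.beta_size, dtype=float)
        self.beta_condition = np.asarray(self.beta_condition, dtype=float)
        self.beta_day = np.asarray(self.beta_day, dtype=float)

    def validate(self) -> None:
        k = len(self.trait_names)
        if self.n_trials not in (2, 3, 4):
            raise ValueError("n_trials must be 2, 3, or 4")
        for name, S in (("Sigma_ind", self.Sigma_ind), ("Sigma_e", self.Sigma_e)):
            S = np.asarray(S, dtype=float)
            if S.shape != (k, k) or not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"{name} must be a symmetric {k}x{k} matrix")
            if np.linalg.eigvalsh(S).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.sd_batch < 0 or self.size_sd < 0:
            raise ValueError("sd_batch and size_sd must be >= 0")


@dataclass
class TrajSimConfig:
    """Correlated-random-walk arena trajectory with burial bouts.

    The arena is the 80 x 40 cm frontal plane of the aquarium; six frames per
    minute mirrors the video pipeline cadence.  p_bury / p_emerge are
    per-minute switching probabilities of the burial bout process.
    """

    arena_width_cm: float = 80.0
    arena_height_cm: float = 40.0
    step_mean_cm: float = 5.0
    kappa_turn: float = 2.0
    mu_turn: float = 0.0
    p_bury: float = 0.02
    p_emerge: float = 0.10
    duration_min: float = 60.0
    frames_per_minute: int = 6
    object_xy: tuple | None = None
    start_buried: bool = False
    trial_id: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.arena_width_cm <= 0 or self.arena_height_cm <= 0:
            raise ValueError("arena dimensions must be > 0")
        for name in ("p_bury", "p_emerge"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.kappa_turn < 0:
            raise ValueError("kappa_turn must be >= 0")
        if self.step_mean_cm < 0:
            raise ValueError("step_mean_cm must be >= 0")
        if self.object_xy is not None:
            ox, oy = self.object_xy
            if not (0 <= ox <= self.arena_width_cm and 0 <= oy <= self.arena_height_cm):
                raise ValueError("object must lie inside the arena")


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset (fields vary by generator)."""

    wake_offsets: np.ndarray | None = None          # a_i, minutes
    rest_offsets: np.ndarray | None = None
    realized_wake: np.ndarray | None = None         # (n_ind, n_days), minutes rel. sunrise
    realized_rest: np.ndarray | None = None         # minutes rel. sunset
    state_sequences: dict | None = None             # individual -> per-bin 0/1
    mode: str | None = None
    trait_names: tuple | None = None
    u: np.ndarray | None = None                     # individual intercepts (n, k)
    batch_effects: np.ndarray | None = None
    Sigma_ind: np.ndarray | None = None
    Sigma_e: np.ndarray | None = None
    r_ind: dict | None = None                       # pair -> true between-ind correlation
    coupling_beta: float | None = None
    coupling_trait: str | None = None


def pair_correlations(Sigma: np.ndarray, names) -> dict:
    out = {}
    d = np.sqrt(np.diag(Sigma))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            denom = d[i] * d[j]
            out[(names[i], names[j])] = float(Sigma[i, j] / denom) if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Chronotype dataset
# ---------------------------------------------------------------------------

def gen_chronotype_dataset(cfg: ChronoSimConfig):
    """Simulate per-individual acoustic detection series with known chronotypes.

    Returns (detections, env, truth): a tidy detections table
    (individual_id, timestamp), a daily environment table
    (date, light, temperature, waves; standardised units), and the
    GroundTruth (true offsets, realized daily times, per-bin state
    sequences).

    Each individual-day follows a deterministic diurnal schedule: Rest from
    midnight until the realized wake time, Active until the realized rest
    time, Rest afterwards.  realized wake = sunrise + a_i + beta.x_day + eps
    with a_i ~ N(mu_wake, sd_wake_between^2), eps ~ N(0, sd_wake_within^2)
    (rest onset analogous, relative to sunset).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_individuals, cfg.n_days
    dates = pd.date_range(cfg.start_date, periods=d, freq="D")
    cov_names = list(cfg.beta_env.keys())
    beta = np.array([cfg.beta_env[c] for c in cov_names], dtype=float)
    X_env = rng.standard_normal((d, len(cov_names)))
    env = pd.DataFrame(X_env, columns=cov_names)
    env.insert(0, "date", dates.date)

    a = rng.normal(cfg.mu_wake, cfg.sd_wake_between, size=n)
    r = rng.normal(cfg.mu_rest, cfg.sd_rest_between, size=n)
    eps_w = rng.normal(0.0, cfg.sd_wake_within, size=(n, d))
    eps_r = rng.normal(0.0, cfg.sd_rest_within, size=(n, d))
    env_shift = X_env @ beta
    realized_wake = a[:, None] + env_shift[None, :] + eps_w        # rel. sunrise
    realized_rest = r[:, None] + env_shift[None, :] + eps_r        # rel. sunset

    sunrise_min = _minutes(cfg.sunrise_time)
    sunset_min = _minutes(cfg.sunset_time)
    bins_per_day = 1440 // cfg.bin_minutes
    bin_starts_min = np.arange(bins_per_day) * cfg.bin_minutes

    ids = [f"F{i:03d}" for i in range(n)]
    start_ts = pd.Timestamp(cfg.start_date)
    states = {}
    id_chunks, ts_chunks = [], []
    for i in range(n):
        wake_abs = sunrise_min + realized_wake[i]                 # (d,)
        rest_abs = sunset_min + realized_rest[i]
        active = ((bin_starts_min[None, :] >= wake_abs[:, None])
                  & (bin_starts_min[None, :] < rest_abs[:, None]))  # (d, bpd)
        states[ids[i]] = active.astype(int).ravel()
        pois = rng.poisson(cfg.lambda_active, size=active.shape)
        keep = rng.random(active.shape) >= cfg.pi_zero_active
        counts = np.where(active, pois * keep, 0)
        if cfg.lambda_rest > 0:
            counts = np.where(active, counts,
                              rng.poisson(cfg.lambda_rest, size=active.shape))
        flat = counts.ravel()
        bin_start_s = (np.arange(d)[:, None] * 86400.0
                       + bin_starts_min[None, :] * 60.0).ravel()
        base_s = np.repeat(bin_start_s, flat)
        offs = rng.uniform(0.0, cfg.bin_minutes * 60.0, size=base_s.size)
        ts_chunks.append(np.sort(base_s + offs))
        id_chunks.append(np.full(base_s.size, ids[i]))
    all_s = np.concatenate(ts_chunks) if ts_chunks else np.empty(0)
    detections = pd.DataFrame({
        "individual_id": np.concatenate(id_chunks) if id_chunks else [],
        "timestamp": start_ts + pd.to_timedelta(all_s, unit="s"),
    })
    truth = GroundTruth(
        wake_offsets=a, rest_offsets=r,
        realized_wake=realized_wake, realized_rest=realized_rest,
        state_sequences=states, mode="schedule",
    )
    return detections, env, truth


def gen_markov_series(T: int, lam_active: float = 4.0, pi_zero_active: float = 0.2,
                      diag: float = 0.95, lam_rest: float = 0.0,
                      pi_zero_rest: float = 0.0, seed: int = 0):
    """Free Markov-switching ZIP count series (decoder stress-test mode).

    States switch by a symmetric 2x2 chain with the given diagonal
    persistence; emissions are ZIP in the Active state and
    Poisson(lam_rest)/ZIP in Rest.  Returns (counts, states).
    """
    if not 0 < diag < 1:
        raise ValueError("diag must be in (0, 1)")
    rng = np.random.default_rng(seed)
    states = np.empty(T, dtype=int)
    s = int(rng.integers(2))
    for t in range(T):
        states[t] = s
        if rng.random() > diag:
            s = 1 - s
    lam = np.array([lam_rest, lam_active])
    pz = np.array([pi_zero_rest, pi_zero_active])
    pois = rng.poisson(lam[states])
    keep = rng.random(T) >= pz[states]
    counts = pois * keep
    return counts.astype(int), states


# ---------------------------------------------------------------------------
# Personality trial dataset
# ---------------------------------------------------------------------------

def gen_personality_dataset(cfg: TraitSimConfig):
    """Simulate a long-format laboratory trial table plus ground truth.

    Columns: individual_id, batch, day, sex, size_cm, weight_g, condition,
    trait, value.  Exactly n_individuals * n_trials * n_traits rows.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, t, k = cfg.n_individuals, cfg.n_trials, len(cfg.trait_names)

    size = rng.normal(cfg.size_mean, cfg.size_sd, size=n)
    size = np.clip(size, 5.0, None)
    weight = cfg.lw_a * size ** cfg.lw_b * np.exp(rng.normal(0, 0.08, size=n))
    condition = (cfg.lw_a * size ** cfg.lw_b) / weight
    sex = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    batch = np.arange(n) // cfg.batch_size
    n_batches = batch.max() + 1

    u = rng.multivariate_normal(np.zeros(k), cfg.Sigma_ind, size=n,
                                method="cholesky" if _is_pd(cfg.Sigma_ind) else "svd")
    b = rng.normal(0.0, cfg.sd_batch, size=(n_batches, k))
    z_size = _zscore(size)
    z_cond = _zscore(condition)

    rows = []
    for i in range(n):
        for trial in range(t):
            day = trial + 1
            e = rng.multivariate_normal(np.zeros(k), cfg.Sigma_e,
                                        method="cholesky" if _is_pd(cfg.Sigma_e) else "svd")
            y = (cfg.mu + cfg.beta_size * z_size[i] + cfg.beta_condition * z_cond[i]
                 + cfg.beta_day * day + u[i] + b[batch[i]] + e)
            for j, trait in enumerate(cfg.trait_names):
                rows.append((f"F{i:03d}", int(batch[i]), day, sex[i],
                             float(size[i]), float(weight[i]), float(condition[i]),
                             trait, float(y[j])))
    table = pd.DataFrame(rows, columns=[
        "individual_id", "batch", "day", "sex", "size_cm", "weight_g",
        "condition", "trait", "value"])
    truth = GroundTruth(
        trait_names=tuple(cfg.trait_names), u=u, batch_effects=b,
        Sigma_ind=np.asarray(cfg.Sigma_ind), Sigma_e=np.asarray(cfg.Sigma_e),
        r_ind=pair_correlations(np.asarray(cfg.Sigma_ind), cfg.trait_names),
    )
    return table, truth


def _is_pd(S) -> bool:
    try:
        np.linalg.cholesky(np.asarray(S, dtype=float))
        return True
    except np.linalg.LinAlgError:
        return False


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# Arena trajectory
# ---------------------------------------------------------------------------

def gen_trajectory(cfg: TrajSimConfig) -> Trajectory:
    """Correlated random walk in the arena, reflected at walls, with burial.

    Turning angles are Von Mises(mu_turn, kappa_turn); step lengths are
    exponential with mean step_mean_cm.  Burial bouts switch by a per-frame
    Markov chain derived from the per-minute p_bury/p_emerge; buried frames
    are flagged undetected and carry no position.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fpm = cfg.frames_per_minute
    n_frames = int(round(cfg.duration_min * fpm))
    dt = 60.0 / fpm
    p_bury_f = 1.0 - (1.0 - cfg.p_bury) ** (1.0 / fpm)
    p_emerge_f = 1.0 - (1.0 - cfg.p_emerge) ** (1.0 / fpm)

    w, h = cfg.arena_width_cm, cfg.arena_height_cm
    x, y = w / 2.0, h / 2.0
    heading = rng.uniform(-np.pi, np.pi)
    buried = bool(cfg.start_buried)

    t_s = np.arange(n_frames) * dt
    xs = np.full(n_frames, np.nan)
    ys = np.full(n_frames, np.nan)
    det = np.zeros(n_frames, dtype=bool)
    for f in range(n_frames):
        if buried:
            if rng.random() < p_emerge_f:
                buried = False
        else:
            if rng.random() < p_bury_f:
                buried = True
        if not buried:
            turn = rng.vonmises(cfg.mu_turn, cfg.kappa_turn) if cfg.kappa_turn > 0 \
                else rng.uniform(-np.pi, np.pi)
            heading += turn
            step = rng.exponential(cfg.step_mean_cm) if cfg.step_mean_cm > 0 else 0.0
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            x, heading = _reflect(x, heading, w, axis="x")
            y, heading = _reflect(y, heading, h, axis="y")
            xs[f], ys[f] = x, y
            det[f] = True
    return Trajectory(trial_id=cfg.trial_id, t_seconds=t_s, x_cm=xs, y_cm=ys,
                      detected=det, duration_s=cfg.duration_min * 60.0,
                      frames_per_minute=fpm)


def _reflect(coord, heading, limit, axis):
    """Reflect a coordinate into [0, limit], mirroring the heading on bounce."""
    reflected = False
    for _ in range(64):
        if coord < 0:
            coord = -coord
            reflected = True
        elif coord > limit:
            coord = 2 * limit - coord
            reflected = True
        else:
            break
    if reflected:
        heading = -heading if axis == "y" else np.pi - heading
    return coord, heading


# ---------------------------------------------------------------------------
# Joint chronotype-personality dataset
# ---------------------------------------------------------------------------

def gen_joint_dataset(chrono_cfg: ChronoSimConfig, trait_cfg: TraitSimConfig,
                      coupling_beta: float = 0.0):
    """Coupled wild + laboratory simulation with a known chronotype link.

    The aggressiveness individual intercepts are shifted by
    ``coupling_beta * (wake offset - mu_wake)``, creating a known
    chronotype-aggressiveness association; other traits stay uncoupled.
    Returns (detections, env, trials, truth).
    """
    if chrono_cfg.n_individuals != trait_cfg.n_individuals:
        raise ValueError("chrono and trait configs must share n_individuals")
    if "aggressiveness" not in trait_cfg.trait_names:
        raise ValueError("trait config must include aggressiveness")
    detections, env, chrono_truth = gen_chronotype_dataset(chrono_cfg)
    trials, trait_truth = gen_personality_dataset(trait_cfg)

    k_aggr = list(trait_cfg.trait_names).index("aggressiveness")
    shift = coupling_beta * (chrono_truth.wake_offsets - chrono_cfg.mu_wake)
    ids = [f"F{i:03d}" for i in range(trait_cfg.n_individuals)]
    shift_map = dict(zip(ids, shift))
    mask = trials["trait"] == "aggressiveness"
    trials.loc[mask, "value"] += trials.loc[mask, "individual_id"].map(shift_map)
    u = trait_truth.u.copy()
    u[:, k_aggr] += shift

    truth = GroundTruth(
        wake_offsets=chrono_truth.wake_offsets,
        rest_offsets=chrono_truth.rest_offsets,
        realized_wake=chrono_truth.realized_wake,
        realized_rest=chrono_truth.realized_rest,
        state_sequences=chrono_truth.state_sequences, mode=chrono_truth.mode,
        trait_names=trait_truth.trait_names, u=u,
        batch_effects=trait_truth.batch_effects,
        Sigma_ind=trait_truth.Sigma_ind, Sigma_e=trait_truth.Sigma_e,
        r_ind=trait_truth.r_ind,
        coupling_beta=coupling_beta, coupling_trait="aggressiveness",
    )
    return detections, env, trials, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_detections_csv(detections: pd.DataFrame, path) -> None:
    out = detections.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def write_env_csv(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index=False)


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({
        "trial_id": traj.trial_id,
        "t_seconds": traj.t_seconds,
        "x_cm": traj.x_cm,
        "y_cm": traj.y_cm,
        "detected": traj.detected.astype(int),
    }).to_csv(path, index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, dict):
            return {str(k): default(v) for k, v in o.items()}
        return o
    payload = {}
    for key, value in asdict(truth).items():
        if value is None:
            continue
        if isinstance(value, dict):
            payload[key] = {str(k): default(v) for k, v in value.items()}
        else:
            payload[key] = default(value)
    with open(path, "w") as fh:
        json.dump(payload, fh)
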