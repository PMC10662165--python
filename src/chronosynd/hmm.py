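"""Two-state zero-inflated-Poisson hidden Markov model for acoustic detection series.

Buried (resting) razorfish are acoustically silent, so the per-bin detection
counts of a tagged fish alternate between a near-silent Rest regime and an
Active regime with zero-inflated Poisson counts (tag collisions and detection
dropouts produce excess zeros even while the fish is up).  This module turns a
raw detection timestamp series into daily chronotype observations:

1. discretise detections into 5-min bins aligned to local midnight,
2. fit a 2-state ZIP-HMM by Baum-Welch EM (multi-start),
3. decode the Rest/Active state path (Viterbi by default),
4. read off, per local day, the awakening time relative to sunrise and the
   rest onset relative to sunset.

States are canonically ordered by expected detection count: state 0 is Rest,
state 1 is Active (larger ``(1 - pi_zero) * lambda``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

REST, ACTIVE = 0, 1


# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class ZipHmmParams:
    """Parameters of the two-state ZIP-HMM.

    delta    : initial state distribution, shape (2,)
    gamma    : transition matrix, rows (from-state) sum to 1, shape (2, 2)
    lam      : Poisson mean per state, shape (2,)
    pi_zero  : structural-zero probability per state, shape (2,), in [0, 1)
    """

    delta: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    pi_zero: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.pi_zero = np.asarray(self.pi_zero, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.delta.shape != (2,) or self.gamma.shape != (2, 2):
            raise ValueError("delta must be (2,), gamma must be (2, 2)")
        if not np.allclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ValueError("delta must lie on the simplex")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("gamma rows must sum to 1")
        if np.any(self.delta < -1e-12) or np.any(self.gamma < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if np.any(self.lam < 0):
            raise ValueError("lambda must be >= 0")
        if np.any(self.pi_zero < 0) or np.any(self.pi_zero >= 1):
            raise ValueError("pi_zero must be in [0, 1)")

    @property
    def expected_counts(self) -> np.ndarray:
        """Per-state expected detections per bin, (1 - pi_zero) * lambda."""
        return (1.0 - self.pi_zero) * self.lam

    def ordered(self) -> "ZipHmmParams":
        """Return an equivalent model with states sorted so Active is state 1."""
        order = np.argsort(self.expected_counts)
        if np.array_equal(order, [0, 1]):
            return self
        return ZipHmmParams(
            delta=self.delta[order],
            gamma=self.gamma[np.ix_(order, order)],
            lam=self.lam[order],
            pi_zero=self.pi_zero[order],
        )


@dataclass
class BinnedSeries:
    """Detection counts per contiguous, midnight-aligned time bin."""

    individual_id: str
    bin_starts: pd.DatetimeIndex
    counts: np.ndarray
    bin_minutes: int = 5
    n_dropped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_starts) != len(self.counts):
            raise ValueError("bin_starts and counts must align")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class StatePath:
    """Decoded Rest/Active path with per-bin posterior P(Active)."""

    states: np.ndarray
    posterior_active: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        self.posterior_active = np.asarray(self.posterior_active, dtype=float)
        if self.states.shape != self.posterior_active.shape:
            raise ValueError("states and posteriors must align")


@dataclass
class HmmFit:
    """Fitted ZIP-HMM with convergence diagnostics."""

    params: ZipHmmParams
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_detections(timestamps, window_start, window_end, bin_minutes: int = 5,
                   individual_id: str = "") -> BinnedSeries:
    """Discretise detection timestamps into fixed-width bins.

    Bins are left-closed right-open, aligned to the midnight of
    ``window_start``'s date, and cover [window_start, window_end).  Detections
    outside the window are dropped (count recorded on the result); unsorted
    input is tolerated.  The sum of the returned counts equals the number of
    in-window detections.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    if window_end <= window_start:
        raise ValueError("window_end must be after window_start")
    ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps))).sort_values()
    in_window = ts[(ts >= window_start) & (ts < window_end)]
    n_dropped = len(ts) - len(in_window)

    origin = window_start.normalize()
    step = pd.Timedelta(minutes=bin_minutes)
    # snap the window to whole bins relative to midnight
    start_bin = origin + ((window_start - origin) // step) * step
    n_bins = int(-(-(window_end - start_bin) // step))  # ceil division
    edges = start_bin + step * np.arange(n_bins + 1)
    edges = pd.DatetimeIndex(edges)
    counts, _ = np.histogram(
        in_window.asi8, bins=edges.asi8.astype("float64")
    )
    return BinnedSeries(
        individual_id=individual_id,
        bin_starts=edges[:-1],
        counts=counts,
        bin_minutes=bin_minutes,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# ZIP emission
# ---------------------------------------------------------------------------

def zip_log_pmf(count, lam, pi_zero):
    """Log pmf of the zero-inflated Poisson, computed stably in log space.

    log[ pi_zero * 1{x=0} + (1 - pi_zero) * Poisson(x; lambda) ]
    """
    x = np.asarray(count)
    if np.any(x < 0) or not np.issubdtype(np.asarray(x).dtype, np.integer) and np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    lam = float(lam)
    pi_zero = float(pi_zero)
    if lam < 0 or not (0 <= pi_zero < 1):
        raise ValueError("require lambda >= 0 and pi_zero in [0, 1)")
    xf = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        if lam == 0.0:
            log_pois = np.where(xf == 0, 0.0, -np.inf)
        else:
            log_pois = xf * np.log(lam) - lam - gammaln(xf + 1.0)
        out = np.log1p(-pi_zero) + log_pois
        if pi_zero > 0:
            out = np.where(xf == 0, np.logaddexp(np.log(pi_zero), out), out)
    return out if out.ndim else float(out)


def _log_emissions(params: ZipHmmParams, counts: np.ndarray) -> np.ndarray:
    """(T, 2) matrix of per-bin log emission probabilities."""
    return np.column_stack([
        zip_log_pmf(counts, params.lam[s], params.pi_zero[s]) for s in (0, 1)
    ])


# ---------------------------------------------------------------------------
# Forward / backward / Viterbi inner loops
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fb_core(B, delta, gamma):  # pragma: no cover - exercised via wrappers
    """Scaled forward-backward for 2 states.

    B is the emission likelihood matrix with each row scaled so its max is 1;
    the row-max log offsets are added back by the caller.  Returns the offset
    log-likelihood, posterior state probabilities, and the expected transition
    count matrix.
    """
    T = B.shape[0]
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a0 = delta[0] * B[0, 0]
    a1 = delta[1] * B[0, 1]
    c0 = a0 + a1
    alpha[0, 0] = a0 / c0
    alpha[0, 1] = a1 / c0
    c[0] = c0
    for t in range(1, T):
        a0 = (alpha[t - 1, 0] * gamma[0, 0] + alpha[t - 1, 1] * gamma[1, 0]) * B[t, 0]
        a1 = (alpha[t - 1, 0] * gamma[0, 1] + alpha[t - 1, 1] * gamma[1, 1]) * B[t, 1]
        ct = a0 + a1
        alpha[t, 0] = a0 / ct
        alpha[t, 1] = a1 / ct
        c[t] = ct
    beta0 = 1.0
    beta1 = 1.0
    post = np.empty((T, 2))
    post[T - 1, 0] = alpha[T - 1, 0]
    post[T - 1, 1] = alpha[T - 1, 1]
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb0 = B[t + 1, 0] * beta0
        bb1 = B[t + 1, 1] * beta1
        # expected transitions i -> j at t, unnormalised by c[t+1]
        x00 = alpha[t, 0] * gamma[0, 0] * bb0
        x01 = alpha[t, 0] * gamma[0, 1] * bb1
        x10 = alpha[t, 1] * gamma[1, 0] * bb0
        x11 = alpha[t, 1] * gamma[1, 1] * bb1
        ct1 = c[t + 1]
        xi[0, 0] += x00 / ct1
        xi[0, 1] += x01 / ct1
        xi[1, 0] += x10 / ct1
        xi[1, 1] += x11 / ct1
        nb0 = (gamma[0, 0] * bb0 + gamma[0, 1] * bb1) / ct1
        nb1 = (gamma[1, 0] * bb0 + gamma[1, 1] * bb1) / ct1
        beta0, beta1 = nb0, nb1
        post[t, 0] = alpha[t, 0] * beta0
        post[t, 1] = alpha[t, 1] * beta1
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return ll, post, xi


@njit(cache=False)
def _viterbi_core(logB, log_delta, log_gamma):  # pragma: no cover
    T = logB.shape[0]
    back = np.empty((T, 2), dtype=np.int64)
    v0 = log_delta[0] + logB[0, 0]
    v1 = log_delta[1] + logB[0, 1]
    for t in range(1, T):
        c00 = v0 + log_gamma[0, 0]
        c10 = v1 + log_gamma[1, 0]
        if c00 >= c10:
            n0 = c00 + logB[t, 0]
            back[t, 0] = 0
        else:
            n0 = c10 + logB[t, 0]
            back[t, 0] = 1
        c01 = v0 + log_gamma[0, 1]
        c11 = v1 + log_gamma[1, 1]
        if c01 >= c11:
            n1 = c01 + logB[t, 1]
            back[t, 1] = 0
        else:
            n1 = c11 + logB[t, 1]
            back[t, 1] = 1
        v0, v1 = n0, n1
    states = np.empty(T, dtype=np.int64)
    states[T - 1] = 0 if v0 >= v1 else 1
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    return states


def _forward_backward(params: ZipHmmParams, counts: np.ndarray):
    logB = _log_emissions(params, counts)
    offset = logB.max(axis=1)
    B = np.exp(logB - offset[:, None])
    ll, post, xi = _fb_core(B, params.delta, params.gamma)
    return ll + offset.sum(), post, xi


def forward_loglik(params: ZipHmmParams, counts) -> float:
    """Log-likelihood of a count series under the model (scaled forward pass)."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("need at least one bin")
    ll, _, _ = _forward_backward(params, counts)
    return float(ll)


def viterbi_decode(params: ZipHmmParams, counts) -> StatePath:
    """Global most-probable state path plus forward-backward posteriors."""
    counts = np.asarray(counts, dtype=int)
    params = params.ordered()
    logB = _log_emissions(params, counts)
    with np.errstate(divide="ignore"):
        states = _viterbi_core(
            logB, np.log(params.delta + 1e-300), np.log(params.gamma + 1e-300)
        )
    _, post, _ = _forward_backward(params, counts)
    return StatePath(states=np.asarray(states), posterior_active=post[:, ACTIVE])


def posterior_decode(params: ZipHmmParams, counts) -> StatePath:
    """Local (per-bin posterior) decoding; alternative to Viterbi."""
    counts = np.asarray(counts, dtype=int)
    params = params.ordered()
    _, post, _ = _forward_backward(params, counts)
    return StatePath(
        states=(post[:, ACTIVE] > 0.5).astype(int),
        posterior_active=post[:, ACTIVE],
    )


# ---------------------------------------------------------------------------
# Baum-Welch EM
# ---------------------------------------------------------------------------

def _em_once(counts, params, max_iter, tol):
    """Run EM from a single start; returns HmmFit (states unordered)."""
    zero = counts == 0
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, post, xi = _forward_backward(params, counts)
        trace.append(ll)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        # M-step
        delta = post[0] / post[0].sum()
        gamma = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        lam = np.empty(2)
        pi_zero = np.empty(2)
        for s in (0, 1):
            w = post[:, s]
            lam_s, pz_s = params.lam[s], params.pi_zero[s]
            # latent structural-zero responsibility for zero counts
            if pz_s > 0:
                p_pois0 = np.exp(-lam_s)
                z = pz_s / (pz_s + (1.0 - pz_s) * p_pois0)
            else:
                z = 0.0
            z_t = np.where(zero, z, 0.0)
            w_sum = w.sum()
            w_pois = w * (1.0 - z_t)
            w_pois_sum = w_pois.sum()
            pi_zero[s] = np.clip((w * z_t).sum() / max(w_sum, 1e-300), 0.0, 1.0 - 1e-9)
            lam[s] = (w_pois * counts).sum() / max(w_pois_sum, 1e-300)
        params = ZipHmmParams(delta=delta, gamma=gamma, lam=np.maximum(lam, 1e-10),
                              pi_zero=pi_zero)
    return HmmFit(params=params, loglik=ll, n_iter=it, converged=converged,
                  loglik_trace=np.asarray(trace))


def _initial_params(counts, rng, jitter=0.0):
    """Two-means style split of the counts into low/high regimes."""
    positive = counts[counts > 0]
    hi = positive.mean() if positive.size else 1.0
    lo = 0.05
    if jitter:
        hi = max(hi * np.exp(rng.normal(0, jitter)), 0.1)
        lo = abs(lo + rng.normal(0, 0.05 * jitter))
    p_zero_hi = min(max((counts == 0).mean() * 0.5, 0.05), 0.8)
    diag = min(max(0.9 + (rng.uniform(-0.08, 0.08) if jitter else 0.0), 0.5), 0.99)
    return ZipHmmParams(
        delta=np.array([0.5, 0.5]),
        gamma=np.array([[diag, 1 - diag], [1 - diag, diag]]),
        lam=np.array([max(lo, 1e-3), hi]),
        pi_zero=np.array([0.0, p_zero_hi]),
    )


def fit_zip_hmm(counts, init: ZipHmmParams | None = None, max_iter: int = 200,
                tol: float = 1e-6, n_starts: int = 5, seed: int = 0) -> HmmFit:
    """Fit the 2-state ZIP-HMM by Baum-Welch EM with seeded multi-start.

    The EM alternates forward-backward E-steps (with an inner latent-zero
    responsibility for the ZIP mixture) and closed-form M-steps; the
    log-likelihood is non-decreasing up to numerical tolerance.  The best of
    ``n_starts`` restarts is returned, states ordered so Active is state 1.
    """
    counts = np.asarray(counts, dtype=int)
    if np.all(counts == 0):
        raise ValueError("degenerate series: no active bins detectable")
    if counts.size < 50:
        warnings.warn("fewer than 50 bins; HMM fit may be unstable")
    rng = np.random.default_rng(seed)
    fits = []
    if init is not None:
        fits.append(_em_once(counts, init, max_iter, tol))
    starts = n_starts if init is None else max(n_starts - 1, 0)
    for k in range(starts):
        p0 = _initial_params(counts, rng, jitter=0.0 if k == 0 else 0.5)
        fits.append(_em_once(counts, p0, max_iter, tol))
    best = max(fits, key=lambda f: f.loglik)
    if not best.converged:
        warnings.warn("ZIP-HMM EM did not converge within max_iter")
    return replace(best, params=best.params.ordered())


# ---------------------------------------------------------------------------
# Chronotype extraction
# ---------------------------------------------------------------------------

@dataclass
class ChronotypeObservation:
    """One day's chronotype: activity onset/offset relative to solar events."""

    individual_id: str
    date: object
    awakening_min: float   # minutes relative to sunrise; negative = earlier
    rest_onset_min: float  # minutes relative to sunset


def extract_daily_chronotype(path: StatePath, binned: BinnedSeries,
                             solar: pd.DataFrame) -> list[ChronotypeObservation]:
    """Per-day awakening and rest-onset times from a decoded state path.

    For each local day covered by the bins: awakening is the start of the
    first Active bin preceded by at least one Rest bin since midnight, minus
    that date's sunrise; rest onset is the start of the first Rest bin after
    the day's last Active bin, minus sunset; both in minutes.  Days lacking
    either transition yield no observation.

    ``solar`` must have columns date, sunrise, sunset (timestamps or "HH:MM").
    """
    if len(path.states) != len(binned.counts):
        raise ValueError("state path and binned series must align")
    solar = solar.copy()
    solar["date"] = pd.to_datetime(solar["date"]).dt.date
    solar = solar.set_index("date")

    frame = pd.DataFrame({
        "start": binned.bin_starts,
        "state": path.states,
    })
    frame["date"] = frame["start"].dt.date
    out: list[ChronotypeObservation] = []
    for date, day in frame.groupby("date", sort=True):
        states = day["state"].to_numpy()
        starts = day["start"].to_numpy()
        active_idx = np.flatnonzero(states == ACTIVE)
        rest_idx = np.flatnonzero(states == REST)
        if active_idx.size == 0 or rest_idx.size == 0:
            continue
        # first Active bin preceded by >=1 Rest bin since midnight
        wake_cands = active_idx[active_idx > rest_idx[0]]
        if wake_cands.size == 0:
            continue
        wake_i = wake_cands[0]
        # first Rest bin after the last Active bin
        last_active = active_idx[-1]
        rest_cands = rest_idx[rest_idx > last_active]
        if rest_cands.size == 0:
            continue
        rest_i = rest_cands[0]
        if date not in solar.index:
            raise KeyError(f"no solar entry for date {date}")
        row = solar.loc[date]
        sunrise = _solar_timestamp(date, row["sunrise"])
        sunset = _solar_timestamp(date, row["sunset"])
        wake_min = (pd.Timestamp(starts[wake_i]) - sunrise).total_seconds() / 60.0
        rest_min = (pd.Timestamp(starts[rest_i]) - sunset).total_seconds() / 60.0
        out.append(ChronotypeObservation(
            individual_id=binned.individual_id, date=date,
            awakening_min=wake_min, rest_onset_min=rest_min,
        ))
    return out


def _solar_timestamp(date, value) -> pd.Timestamp:
    ts = pd.Timestamp(f"{date} {value}") if isinstance(value, str) else pd.Timestamp(value)
    if ts.date() != date:
        ts = pd.Timestamp.combine(pd.Timestamp(date).date(), ts.time())
    return ts


def solar_events(dates, latitude_deg: float, longitude_deg: float,
                 utc_offset_hours: float = 0.0) -> pd.DataFrame:
    """Approximate sunrise/sunset per date from standard solar geometry.

    Convenience helper (NOAA-style equations, ~1-min accuracy); field studies
    should supply observed solar tables instead.
    """
    rows = []
    for d in pd.to_datetime(pd.Index(dates)):
        doy = d.dayofyear
        g = 2.0 * np.pi / 365.0 * (doy - 1 + 0.5)
        eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                           - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))
        decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
                - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
                - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
        lat = np.deg2rad(latitude_deg)
        cos_ha = (np.cos(np.deg2rad(90.833)) / (np.cos(lat) * np.cos(decl))
                  - np.tan(lat) * np.tan(decl))
        ha = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
        offset_min = utc_offset_hours * 60.0
        sunrise_min = 720.0 - 4.0 * (longitude_deg + ha) - eqtime + offset_min
        sunset_min = 720.0 - 4.0 * (longitude_deg - ha) - eqtime + offset_min
        rows.append({
            "date": d.date(),
            "sunrise": (d.normalize() + pd.Timedelta(minutes=sunrise_min)),
            "sunset": (d.normalize() + pd.Timedelta(minutes=sunset_min)),
        })
    return pd.DataFrame(rows)
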