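"""Linear mixed models for repeatability and individual behavioural scores.

The repeated-measures designs here are Gaussian random-intercept models

    y = X beta + u_individual + u_batch + e,

with individuals (optionally) nested in experimental batches.  The module
fits them by profiled REML/ML: the variance ratios gamma = sigma_u^2 /
sigma_e^2 are optimised numerically while beta and sigma_e^2 are profiled out
in closed form via the Woodbury identity, which makes a fit cheap enough for
parametric-bootstrap confidence intervals with thousands of refits.

Provided on top of the fits:

* adjusted repeatability R = V_ind0 / (V_ind0 + V_e0) with a parametric
  bootstrap CI, and significance from the AIC drop of the model without the
  individual term (> 2 points);
* bidirectional (backward + forward) AIC stepwise reduction of the fixed
  structure with a 2-point cut-off;
* per-individual scores: the conditional mode (BLUP) of each individual's
  random intercept and a simulation-based SD from its conditional
  distribution.

Fixed covariates are z-scaled by default ("scaled and normalized" fixed
structure); ML log-likelihoods are used for AIC comparisons, REML for the
reported variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = np.log(1e-8), np.log(1e6)


@dataclass
class LmmSpec:
    """Model specification: response column, fixed terms, random terms.

    The intercept is always included.  ``random`` is a subset of
    {"individual", "batch"} naming columns of the data.
    """

    response: str
    fixed: tuple = ()
    random: tuple = ("individual",)
    scale_fixed: bool = True

    def __post_init__(self):
        self.fixed = tuple(self.fixed)
        self.random = tuple(self.random)
        if not set(self.random) <= {"individual", "batch"}:
            raise ValueError("random terms must be a subset of {individual, batch}")


@dataclass
class LmmFit:
    """Fitted random-intercept LMM (REML variances, ML log-lik for AIC)."""

    spec: LmmSpec
    beta: pd.Series
    beta_ci: pd.DataFrame            # columns ci_low, ci_high (2.5% / 97.5%)
    V_ind0: float
    V_batch: float
    V_e0: float
    loglik_reml: float
    loglik_ml: float
    aic: float                       # ML-based; k = p + variance comps + residual
    n_obs: int
    n_individuals: int
    _design: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _build_design(data: pd.DataFrame, spec: LmmSpec):
    df = data.copy()
    y = df[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        df = df.loc[keep]
        y = y[keep]
    if y.std(ddof=0) == 0:
        raise ValueError("zero-variance response")
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.fixed:
        col = df[term]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    if spec.scale_fixed and X.shape[1] > 1:
        for j in range(1, X.shape[1]):
            sd = X[:, j].std(ddof=0)
            if sd == 0:
                raise ValueError(f"aliased (constant) fixed term: {names[j]}")
            X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns via QR pivoting on correlations
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise ValueError(f"singular design; aliased terms: {bad or names}")

    codes = {}
    if "individual" in spec.random:
        codes["individual"] = pd.factorize(df["individual_id"])[0]
    if "batch" in spec.random:
        codes["batch"] = pd.factorize(df["batch"])[0]
    n_ind_col = df["individual_id"].nunique() if "individual_id" in df else n
    return X, np.asarray(names), y, codes, n_ind_col, df


def _random_blocks(codes: dict, n: int):
    """Indicator matrix Z (dense) and per-column component labels."""
    zs, labels, sizes = [], [], {}
    for comp, c in codes.items():
        q = c.max() + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), c] = 1.0
        zs.append(Z)
        labels += [comp] * q
        sizes[comp] = q
    if zs:
        return np.hstack(zs), np.asarray(labels), sizes
    return np.zeros((n, 0)), np.asarray([]), sizes


# ---------------------------------------------------------------------------
# Profiled likelihood core
# ---------------------------------------------------------------------------

class _Profile:
    """Caches the cross-products needed to evaluate the profiled deviance."""

    def __init__(self, X, y, Z, labels, comps):
        self.X, self.y, self.Z = X, y, Z
        self.labels = labels
        self.comps = comps                       # ordered component names
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, gammas):
        """Return (logdet_Vtilde, A=X'Vt^-1 X, c=X'Vt^-1 y, yVy)."""
        if self.q == 0:
            return 0.0, self.XtX, self.Xty, self.yty, None
        d = np.empty(self.q)
        for comp, g in zip(self.comps, gammas):
            d[self.labels == comp] = g
        ds = np.sqrt(d)
        M = np.eye(self.q) + (ds[:, None] * self.ZtZ * ds[None, :])
        L = np.linalg.cholesky(M)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        W = ds[:, None] * self.ZtX
        wy = ds * self.Zty
        MW = np.linalg.solve(L, W)
        Mwy = np.linalg.solve(L, wy)
        A = self.XtX - MW.T @ MW
        c = self.Xty - MW.T @ Mwy
        yVy = self.yty - float(Mwy @ Mwy)
        return logdet, A, c, yVy, (d, L)

    def deviance(self, log_gammas, reml):
        gammas = np.exp(np.clip(log_gammas, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
        logdet, A, c, yVy, _ = self._core(gammas)
        try:
            La = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return 1e12
        beta = np.linalg.solve(A, c)
        rss = max(yVy - float(c @ beta), 1e-12)
        n, p = self.n, self.p
        if reml:
            s2 = rss / (n - p)
            logdetA = 2.0 * np.log(np.diag(La)).sum()
            return ((n - p) * (np.log(2 * np.pi * s2) + 1.0)
                    + logdet + logdetA)
        s2 = rss / n
        return n * (np.log(2 * np.pi * s2) + 1.0) + logdet

    def solve(self, gammas, reml):
        """beta-hat, sigma_e^2, cov(beta), and the deviance at gammas."""
        logdet, A, c, yVy, aux = self._core(gammas)
        beta = np.linalg.solve(A, c)
        rss = max(yVy - float(c @ beta), 1e-12)
        n, p = self.n, self.p
        s2 = rss / (n - p) if reml else rss / n
        cov_beta = s2 * np.linalg.inv(A)
        dev = self.deviance(np.log(np.maximum(gammas, 1e-300)), reml) \
            if self.q else self.deviance(np.empty(0), reml)
        return beta, s2, cov_beta, dev, aux


def _optimise(profile: _Profile, reml: bool):
    k = len(profile.comps)
    if k == 0:
        return np.empty(0)
    best = None
    for start in ([np.log(0.5)] * k, [np.log(0.05)] * k, [np.log(5.0)] * k):
        res = minimize(profile.deviance, np.asarray(start), args=(reml,),
                       method="L-BFGS-B",
                       bounds=[(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * k)
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(np.clip(best.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def fit_lmm(spec: LmmSpec, data: pd.DataFrame) -> LmmFit:
    """Fit the random-intercept LMM; REML variances, ML deviance for AIC.

    ``data`` must carry the response column, every fixed-term column, and
    ``individual_id`` / ``batch`` as needed by the random terms.  Wald CIs at
    2.5% / 97.5% are reported for the fixed coefficients.
    """
    X, names, y, codes, n_ind, df = _build_design(data, spec)
    Z, labels, sizes = _random_blocks(codes, len(y))
    comps = list(codes.keys())
    prof = _Profile(X, y, Z, labels, comps)

    g_reml = _optimise(prof, reml=True)
    beta, s2_reml, cov_beta, dev_reml = prof.solve(g_reml, reml=True)[:4]
    g_ml = _optimise(prof, reml=False)
    _, s2_ml, _, dev_ml = prof.solve(g_ml, reml=False)[:4]

    var = dict(zip(comps, g_reml * s2_reml))
    p = X.shape[1]
    k = p + len(comps) + 1
    aic = dev_ml + 2.0 * k

    se = np.sqrt(np.diag(cov_beta))
    zq = norm.ppf(0.975)
    beta_s = pd.Series(beta, index=names, name="estimate")
    ci = pd.DataFrame({"ci_low": beta - zq * se, "ci_high": beta + zq * se},
                      index=names)
    fit = LmmFit(
        spec=spec,
        beta=beta_s, beta_ci=ci,
        V_ind0=float(var.get("individual", 0.0)),
        V_batch=float(var.get("batch", 0.0)),
        V_e0=float(s2_reml),
        loglik_reml=-0.5 * dev_reml,
        loglik_ml=-0.5 * dev_ml,
        aic=float(aic),
        n_obs=len(y),
        n_individuals=int(n_ind),
        _design={
            "X": X, "y": y, "names": names, "codes": codes, "comps": comps,
            "gammas": g_reml, "profile": prof, "beta": beta, "s2": s2_reml,
            "data_index": df.index, "individual_levels":
                pd.factorize(df["individual_id"])[1] if "individual" in codes else None,
        },
    )
    return fit


def _refit_without(fit: LmmFit, drop_random: str) -> float:
    """ML AIC of the model with one random term removed (constrained model)."""
    spec = fit.spec
    new_random = tuple(r for r in spec.random if r != drop_random)
    d = fit._design
    codes = {k: v for k, v in d["codes"].items() if k != drop_random}
    Z, labels, _ = _random_blocks(codes, len(d["y"]))
    prof = _Profile(d["X"], d["y"], Z, labels, list(codes.keys()))
    g = _optimise(prof, reml=False)
    dev = prof.solve(g, reml=False)[3] if len(codes) else prof.deviance(np.empty(0), False)
    k = d["X"].shape[1] + len(codes) + 1
    return float(dev + 2.0 * k)


# ---------------------------------------------------------------------------
# Stepwise AIC reduction of the fixed structure
# ---------------------------------------------------------------------------

def stepwise_aic(spec: LmmSpec, data: pd.DataFrame, candidate_fixed=None,
                 cutoff: float = 2.0):
    """Bidirectional single-term elimination/addition on ML AIC.

    Parsimony rule with a 2-point cut-off: the simpler of two nested models is
    preferred unless the richer one improves the AIC by more than ``cutoff``.
    Concretely, a single-term drop is accepted when it worsens the AIC by at
    most ``cutoff`` points, and a single-term addition only when it improves
    the AIC by more than ``cutoff``.  Among eligible moves the one with the
    lowest resulting AIC wins, drops before adds and lexicographic term order
    breaking ties, so the trace is deterministic.  Returns
    (reduced LmmSpec, fitted LmmFit, trace).
    """
    candidates = sorted(set(spec.fixed) | set(candidate_fixed or ()))
    current = tuple(sorted(spec.fixed))

    def fit_with(terms):
        s = LmmSpec(response=spec.response, fixed=tuple(terms),
                    random=spec.random, scale_fixed=spec.scale_fixed)
        return s, fit_lmm(s, data)

    cur_spec, cur_fit = fit_with(current)
    trace = [{"action": "start", "terms": current, "aic": cur_fit.aic}]
    seen = {current}
    while True:
        moves = []
        for term in sorted(current):
            moves.append(("drop", term, tuple(t for t in current if t != term)))
        for term in candidates:
            if term not in current:
                moves.append(("add", term, tuple(sorted(current + (term,)))))
        best = None
        for action, term, terms in moves:
            if terms in seen:
                continue
            try:
                s, f = fit_with(terms)
            except ValueError:
                continue
            delta = f.aic - cur_fit.aic
            eligible = (delta <= cutoff) if action == "drop" else (delta < -cutoff)
            if not eligible:
                continue
            key = (f.aic, 0 if action == "drop" else 1, term)
            if best is None or key < best[0]:
                best = (key, action, term, s, f)
        if best is None:
            break
        _, action, term, cur_spec, cur_fit = best
        current = cur_spec.fixed
        seen.add(current)
        trace.append({"action": action, "term": term, "terms": current,
                      "aic": cur_fit.aic})
    return cur_spec, cur_fit, trace


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityEstimate:
    R: float
    ci_low: float
    ci_high: float
    significant: bool
    delta_aic_vs_constrained: float
    n_boot: int


def repeatability_point(V_ind0: float, V_e0: float) -> float:
    """R = V_ind0 / (V_ind0 + V_e0); batch variance excluded by definition."""
    tot = V_ind0 + V_e0
    if tot <= 0:
        raise ValueError("V_ind0 + V_e0 must be > 0")
    return float(V_ind0 / tot)


def simulate_from_fit(fit: LmmFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from the fitted model (parametric bootstrap)."""
    d = fit._design
    mu = d["X"] @ d["beta"]
    y = mu + rng.normal(0.0, np.sqrt(fit.V_e0), size=len(mu))
    codes = d["codes"]
    if "individual" in codes and fit.V_ind0 > 0:
        c = codes["individual"]
        y = y + rng.normal(0.0, np.sqrt(fit.V_ind0), size=c.max() + 1)[c]
    if "batch" in codes and fit.V_batch > 0:
        c = codes["batch"]
        y = y + rng.normal(0.0, np.sqrt(fit.V_batch), size=c.max() + 1)[c]
    return y


def adjusted_repeatability(fit: LmmFit, n_boot: int = 1000,
                           seed: int = 0) -> RepeatabilityEstimate:
    """Adjusted repeatability with parametric-bootstrap CI and AIC significance.

    The CI refits the model on ``n_boot`` datasets simulated from the fitted
    parameters and takes the 2.5/97.5 percentiles of the refitted R.
    Significance requires the constrained model (individual term removed) to
    carry an AIC more than 2 points above the full model.
    """
    if "individual" not in fit.spec.random:
        raise ValueError("repeatability needs the individual random term")
    R = repeatability_point(fit.V_ind0, fit.V_e0)
    aic_constrained = _refit_without(fit, "individual")
    delta = aic_constrained - fit.aic

    rng = np.random.default_rng(seed)
    d = fit._design
    codes = d["codes"]
    Z, labels, _ = _random_blocks(codes, len(d["y"]))
    comps = list(codes.keys())
    boot = np.empty(n_boot)
    for b in range(n_boot):
        yb = simulate_from_fit(fit, rng)
        prof = _Profile(d["X"], yb, Z, labels, comps)
        g = _optimise(prof, reml=True)
        _, s2, _, _ = prof.solve(g, reml=True)[:4]
        var = dict(zip(comps, g * s2))
        boot[b] = repeatability_point(var.get("individual", 0.0), s2)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RepeatabilityEstimate(
        R=R, ci_low=float(lo), ci_high=float(hi),
        significant=bool(delta > 2.0),
        delta_aic_vs_constrained=float(delta), n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Individual scores (conditional modes of the random effects)
# ---------------------------------------------------------------------------

@dataclass
class IndividualScore:
    individual_id: str
    score: float
    sd: float


def individual_scores(fit: LmmFit, n_sim: int = 1000, seed: int = 0) -> pd.DataFrame:
    """BLUP-style per-individual scores with simulation-based SDs.

    The score is the conditional mode (mean, for a Gaussian model) of each
    individual's random intercept given the data and the fitted parameters;
    the SD is that of ``n_sim`` draws from the conditional distribution,
    mirroring the posterior-simulation procedure used for behavioural scores.
    Returns a frame with columns individual_id, score, sd.
    """
    if "individual" not in fit.spec.random:
        raise ValueError("fit has no individual random term")
    d = fit._design
    prof: _Profile = d["profile"]
    gammas = d["gammas"]
    comps = d["comps"]
    s2 = fit.V_e0
    r = d["y"] - d["X"] @ d["beta"]
    Z = prof.Z
    q = Z.shape[1]
    dvec = np.empty(q)
    for comp, g in zip(comps, gammas):
        dvec[prof.labels == comp] = g
    if q == 0 or fit.V_ind0 <= 0:
        levels = d["individual_levels"]
        out = pd.DataFrame({"individual_id": list(levels),
                            "score": 0.0, "sd": 0.0})
        return out
    ds = np.sqrt(dvec)
    M = np.eye(q) + ds[:, None] * prof.ZtZ * ds[None, :]
    Minv = np.linalg.inv(M)
    Vt_inv_r = r - Z @ (ds * (Minv @ (ds * (Z.T @ r))))
    u_mean_all = dvec * (Z.T @ Vt_inv_r)
    ZtVtZ = prof.ZtZ - (prof.ZtZ * ds[None, :]) @ Minv @ (ds[:, None] * prof.ZtZ)
    cond_var_all = s2 * (dvec - dvec ** 2 * np.diag(ZtVtZ))
    cond_var_all = np.maximum(cond_var_all, 0.0)

    ind_mask = prof.labels == "individual"
    u_mean = u_mean_all[ind_mask]
    u_sd = np.sqrt(cond_var_all[ind_mask])
    rng = np.random.default_rng(seed)
    draws = rng.normal(u_mean[None, :], u_sd[None, :], size=(n_sim, u_mean.size))
    sds = draws.std(axis=0, ddof=1)
    levels = d["individual_levels"]
    return pd.DataFrame({"individual_id": list(levels),
                         "score": u_mean, "sd": sds})
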