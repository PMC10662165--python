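"""Behavioural syndromes: between- vs within-individual trait correlations.

A phenotypic correlation between two repeatedly measured traits mixes two
levels: a between-individual correlation r_ind (do individuals with high
average trait 1 also have high average trait 2?) and a within-individual
residual correlation r_e.  Only r_ind captures a behavioural syndrome.  The
decomposition uses a bivariate Gaussian random-intercept model

    y[i, t, :] = B' x[i, t] + u[i, :] + e[i, t, :],
    u ~ MVN(0, Sigma_ind),   e ~ MVN(0, Sigma_e),

sampled by a conjugate Gibbs sampler (normal updates for fixed and individual
effects, inverse-Wishart updates for both covariance matrices).  Responses are
standardised to unit variance internally — correlations are scale-invariant —
which makes the weak inverse-Wishart prior scale exactly 0.5 * I (half the
phenotypic variance) with nu = 3 degrees of freedom.

A trait pair forms a syndrome when the r_ind credible interval excludes zero.

The module also fits the chronotype-personality association: each trait's LMM
refitted with standardised awakening and rest-onset scores as fixed
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .mixed import LmmSpec, fit_lmm

TRAIT_PAIRS = (
    ("exploration", "activity"),
    ("exploration", "boldness"),
    ("exploration", "aggressiveness"),
    ("activity", "boldness"),
    ("activity", "aggressiveness"),
    ("boldness", "aggressiveness"),
)


@dataclass
class ChainConfig:
    """Gibbs chain settings; defaults give 1000 stored draws."""

    iterations: int = 13000
    burn_in: int = 3000
    thin: int = 10
    seed: int = 0
    prior_nu: float = 3.0
    prior_scale_factor: float = 0.5   # times the observed phenotypic variance
    beta_prior_var: float = 1e8

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class BivariatePosterior:
    """Stored MCMC draws for one trait pair."""

    trait_pair: tuple
    Sigma_ind: np.ndarray    # (draws, 2, 2)
    Sigma_e: np.ndarray      # (draws, 2, 2)
    beta: np.ndarray         # (draws, p, 2)
    beta_names: tuple
    chain: ChainConfig


@dataclass
class SyndromeEstimate:
    trait_pair: tuple
    r_ind: float
    r_ind_ci: tuple
    r_e: float
    r_e_ci: tuple
    r_phe: float
    r_phe_ci: tuple
    is_syndrome: bool
    n_draws_used: int
    n_draws_skipped: int


def _pair_matrix(data: pd.DataFrame, trait_x: str, trait_y: str, fixed):
    """Wide (individual, day) x [trait_x, trait_y, covariates] observations."""
    idx_cols = ["individual_id", "day"]
    keep = data[data["trait"].isin([trait_x, trait_y])]
    wide = keep.pivot_table(index=idx_cols, columns="trait", values="value",
                            aggfunc="first").reset_index()
    if trait_x not in wide or trait_y not in wide:
        raise ValueError("both traits must be observed")
    wide = wide.dropna(subset=[trait_x, trait_y])
    if fixed:
        cov = data[idx_cols + list(fixed)].drop_duplicates(idx_cols)
        wide = wide.merge(cov, on=idx_cols, how="left").dropna(subset=list(fixed))
    return wide


def fit_bivariate(data: pd.DataFrame, trait_x: str, trait_y: str,
                  fixed=(), chain: ChainConfig | None = None) -> BivariatePosterior:
    """Gibbs sampler for the bivariate random-intercept model of a trait pair.

    ``data`` is a long trial table (individual_id, day, trait, value, plus any
    fixed-covariate columns).  Trials missing either trait are dropped; at
    least 15 individuals with overlapping observations are recommended.
    """
    chain = chain or ChainConfig()
    wide = _pair_matrix(data, trait_x, trait_y, fixed)
    n_ind = wide["individual_id"].nunique()
    if len(wide) < 2 * n_ind or n_ind < 2:
        raise ValueError("insufficient overlapping trials for the pair")

    Y = wide[[trait_x, trait_y]].to_numpy(dtype=float)
    # standardise responses; correlations are unaffected
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    cols = [np.ones(len(wide))]
    names = ["intercept"]
    for term in fixed:
        v = wide[term].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"aliased (constant) fixed term: {term}")
        cols.append((v - v.mean()) / sd)
        names.append(term)
    X = np.column_stack(cols)
    p = X.shape[1]
    codes, levels = pd.factorize(wide["individual_id"])
    N = len(levels)
    n_obs = len(Y)

    rng = np.random.default_rng(chain.seed)
    nu0 = chain.prior_nu
    S0 = chain.prior_scale_factor * np.eye(2)
    tau2 = chain.beta_prior_var

    # group individuals by trial count so the u-update is vectorised
    counts = np.bincount(codes, minlength=N)
    groups = {}
    for c in np.unique(counts):
        groups[int(c)] = np.flatnonzero(counts == c)
    XtX = X.T @ X

    B = np.zeros((p, 2))
    u = np.zeros((N, 2))
    Sig_i = 0.3 * np.eye(2)
    Sig_e = 0.7 * np.eye(2)

    n_store = chain.n_stored
    Sind_draws = np.empty((n_store, 2, 2))
    Se_draws = np.empty((n_store, 2, 2))
    B_draws = np.empty((n_store, p, 2))
    stored = 0

    sum_by_ind = np.zeros((N, 2))
    for it in range(chain.iterations):
        Se_inv = np.linalg.inv(Sig_e)
        Si_inv = np.linalg.inv(Sig_i)

        # --- individual effects ---
        R = Y - X @ B
        sum_by_ind[:] = 0.0
        np.add.at(sum_by_ind, codes, R)
        for c, idx in groups.items():
            prec = c * Se_inv + Si_inv
            cov = np.linalg.inv(prec)
            L = np.linalg.cholesky(cov)
            mean = sum_by_ind[idx] @ (cov @ Se_inv).T
            z = rng.standard_normal((len(idx), 2))
            u[idx] = mean + z @ L.T
        # --- fixed effects ---
        Ydot = Y - u[codes]
        P = np.kron(Se_inv, XtX) + np.eye(2 * p) / tau2
        ell = (X.T @ Ydot @ Se_inv).T.ravel()     # column-major stack (trait-major)
        Pc = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, ell)
        z = rng.standard_normal(2 * p)
        bvec = mean + np.linalg.solve(Pc.T, z)
        B = bvec.reshape(2, p).T
        # --- covariance matrices ---
        Su = u.T @ u
        Sig_i = invwishart.rvs(df=nu0 + N, scale=S0 + Su, random_state=rng)
        E = Y - X @ B - u[codes]
        Sig_e = invwishart.rvs(df=nu0 + n_obs, scale=S0 + E.T @ E,
                               random_state=rng)
        if not (np.all(np.isfinite(Sig_i)) and np.all(np.isfinite(Sig_e))):
            raise RuntimeError(f"chain divergence at iteration {it}")

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 \
                and stored < n_store:
            Sind_draws[stored] = Sig_i
            Se_draws[stored] = Sig_e
            B_draws[stored] = B
            stored += 1

    return BivariatePosterior(
        trait_pair=(trait_x, trait_y),
        Sigma_ind=Sind_draws[:stored], Sigma_e=Se_draws[:stored],
        beta=B_draws[:stored], beta_names=tuple(names), chain=chain,
    )


def correlations(post: BivariatePosterior) -> SyndromeEstimate:
    """Posterior summaries of r_ind, r_e, r_phe for a fitted pair.

    Per draw: r_ind from Sigma_ind, r_e from Sigma_e, r_phe from their sum;
    zero-variance draws are skipped (and must stay below 1% of the chain).
    The syndrome flag is set when the r_ind 95% credible interval excludes 0.
    """
    def corr(S):
        v1, v2 = S[:, 0, 0], S[:, 1, 1]
        ok = (v1 > 0) & (v2 > 0)
        r = np.full(len(S), np.nan)
        r[ok] = S[ok, 0, 1] / np.sqrt(v1[ok] * v2[ok])
        return r

    r_ind = corr(post.Sigma_ind)
    r_e = corr(post.Sigma_e)
    r_phe = corr(post.Sigma_ind + post.Sigma_e)
    ok = np.isfinite(r_ind) & np.isfinite(r_e) & np.isfinite(r_phe)
    skipped = int((~ok).sum())
    if skipped >= 0.01 * len(ok) and skipped > 0:
        raise RuntimeError(f"{skipped} degenerate draws (>1% of chain)")
    r_ind, r_e, r_phe = r_ind[ok], r_e[ok], r_phe[ok]

    def summ(r):
        lo, hi = np.percentile(r, [2.5, 97.5])
        return float(r.mean()), (float(lo), float(hi))

    ri, ri_ci = summ(r_ind)
    re_, re_ci = summ(r_e)
    rp, rp_ci = summ(r_phe)
    return SyndromeEstimate(
        trait_pair=post.trait_pair,
        r_ind=ri, r_ind_ci=ri_ci, r_e=re_, r_e_ci=re_ci,
        r_phe=rp, r_phe_ci=rp_ci,
        is_syndrome=bool(ri_ci[0] > 0 or ri_ci[1] < 0),
        n_draws_used=int(ok.sum()), n_draws_skipped=skipped,
    )


def screen_pairs(data: pd.DataFrame, pairs=TRAIT_PAIRS, fixed=(),
                 chain: ChainConfig | None = None) -> pd.DataFrame:
    """Syndrome screen over the listed trait pairs; one row per pair."""
    rows = []
    for tx, ty in pairs:
        post = fit_bivariate(data, tx, ty, fixed=fixed, chain=chain)
        est = correlations(post)
        rows.append({
            "pair": f"{tx}-{ty}",
            "r_ind": est.r_ind, "r_ind_low": est.r_ind_ci[0],
            "r_ind_high": est.r_ind_ci[1],
            "r_e": est.r_e, "r_e_low": est.r_e_ci[0], "r_e_high": est.r_e_ci[1],
            "r_phe": est.r_phe, "r_phe_low": est.r_phe_ci[0],
            "r_phe_high": est.r_phe_ci[1],
            "is_syndrome": est.is_syndrome,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chronotype-personality association
# ---------------------------------------------------------------------------

def chronotype_trait_association(trials: pd.DataFrame,
                                 chronotype_scores: pd.DataFrame,
                                 traits=None,
                                 base_fixed=("size_cm", "condition", "day"),
                                 random=("individual", "batch")) -> pd.DataFrame:
    """Refit each trait LMM with chronotype scores as fixed covariates.

    ``chronotype_scores`` carries one row per individual with columns
    individual_id, awakening, rest_onset (the random-effect chronotype
    scores).  Each trait model adds standardised awakening and rest-onset to
    the base fixed structure; a coefficient is flagged significant when its
    95% CI excludes zero.  Fewer than 10 overlapping individuals triggers a
    warning but the analysis still runs.
    """
    import warnings as _w

    traits = traits if traits is not None else sorted(trials["trait"].unique())
    merged = trials.merge(chronotype_scores, on="individual_id", how="inner")
    n_overlap = merged["individual_id"].nunique()
    if n_overlap == 0:
        raise ValueError("no individuals overlap between datasets")
    if n_overlap < 10:
        _w.warn(f"only {n_overlap} overlapping individuals")
    rows = []
    for trait in traits:
        sub = merged[merged["trait"] == trait]
        spec = LmmSpec(response="value",
                       fixed=tuple(base_fixed) + ("awakening", "rest_onset"),
                       random=tuple(random), scale_fixed=True)
        fit = fit_lmm(spec, sub)
        for term in ("awakening", "rest_onset"):
            lo = fit.beta_ci.loc[term, "ci_low"]
            hi = fit.beta_ci.loc[term, "ci_high"]
            rows.append({
                "trait": trait, "covariate": term,
                "estimate": float(fit.beta[term]),
                "ci_low": float(lo), "ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            })
    return pd.DataFrame(rows)
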