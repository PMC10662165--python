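"""Trait scores from behavioural metric matrices.

Each personality trait is measured by several correlated metrics per trial
(e.g. exploration by Interactions, TimeOut, MinDistance, TimeToy).  A PCA on
the z-scored metrics collapses each trait's metrics to its first principal
component, which serves as the trial-level trait score.  Scores are oriented
by an anchor metric whose loading is forced positive (TimeOut for exploration,
Distance for activity, Bites for aggressiveness), so that higher scores mean
"more of the trait".  Boldness is a single metric (emergence latency, lower =
bolder) and is used raw, log(1+x)-transformed.

The condition index is the ratio of the allometrically predicted weight
(a * L^b) to the observed fresh weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: anchor metric per PCA-scored trait (loading forced positive)
ANCHOR_METRICS = {
    "exploration": "TimeOut",
    "activity": "Distance",
    "aggressiveness": "Bites",
}

#: traits whose raw responses are log(1+x)-transformed before analysis
LOG_TRANSFORMED_TRAITS = ("boldness", "aggressiveness")


@dataclass
class TraitScores:
    """PC1 scores with provenance: loadings, explained variance, column stats."""

    trait: str
    scores: pd.Series            # indexed like the input rows
    loadings: pd.Series          # unit-norm, indexed by metric
    variance_explained: float
    explained_ratios: np.ndarray
    column_means: pd.Series
    column_sds: pd.Series


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each column to mean 0, sample (n-1) SD 1.

    Raises on constant columns, naming the offending metric.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    sds = matrix.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) after filtering: {constant}")
    return (matrix - matrix.mean()) / sds


def pc1_scores(matrix: pd.DataFrame, anchor_metric: str,
               trait: str = "", standardize: bool = True) -> TraitScores:
    """First-principal-component trait scores of a trial x metric matrix.

    Rows with any missing metric are dropped (listwise per trait).  The
    principal axes come from the eigendecomposition of the column covariance;
    scores and loadings are flipped, if needed, so the anchor metric loads
    positively.
    """
    if anchor_metric not in matrix.columns:
        raise ValueError(f"anchor metric {anchor_metric!r} not in columns")
    clean = matrix.dropna(axis=0, how="any")
    means = clean.mean()
    sds = clean.std(ddof=1)
    Z = zscore_columns(clean) if standardize else clean - means
    X = Z.to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    if evals.sum() <= 0:
        raise ValueError("rank-0 matrix: no variance to decompose")
    pc1 = evecs[:, order[0]]
    anchor_ix = list(clean.columns).index(anchor_metric)
    if pc1[anchor_ix] < 0:
        pc1 = -pc1
    scores = X @ pc1
    ratios = evals / evals.sum()
    return TraitScores(
        trait=trait,
        scores=pd.Series(scores, index=clean.index, name="pc1"),
        loadings=pd.Series(pc1, index=clean.columns, name="loading"),
        variance_explained=float(ratios[0]),
        explained_ratios=ratios,
        column_means=means,
        column_sds=sds,
    )


def condition_index(length_cm, weight_g, lw_a: float, lw_b: float,
                    invert: bool = False):
    """Body condition: predicted allometric weight over fresh weight.

    predicted = a * length^b.  ``invert=True`` returns the conventional
    relative-condition orientation (fresh / predicted) instead.
    """
    length = np.asarray(length_cm, dtype=float)
    weight = np.asarray(weight_g, dtype=float)
    if np.any(length <= 0) or np.any(weight <= 0):
        raise ValueError("length and weight must be > 0")
    predicted = lw_a * length ** lw_b
    ratio = weight / predicted if invert else predicted / weight
    return float(ratio) if ratio.ndim == 0 else ratio


def log_transform_if_needed(trait: str, values):
    """log(1+x) for boldness/aggressiveness responses; other traits untouched.

    Latency and agonistic counts contain legitimate zeros, hence log1p rather
    than log.  Negative values are rejected.
    """
    values = np.asarray(values, dtype=float)
    if trait.lower() not in LOG_TRANSFORMED_TRAITS:
        return values
    if np.any(values < 0):
        raise ValueError(f"{trait} values must be >= 0 for the log transform")
    return np.log1p(values)


def score_trait_table(metrics: pd.DataFrame, trait: str) -> TraitScores:
    """Score one trait from a wide per-trial metric table.

    ``metrics`` has one row per trial observation and one column per metric of
    the trait; count-valued aggressiveness metrics are log(1+x)-transformed
    before z-scoring.
    """
    if trait not in ANCHOR_METRICS:
        raise ValueError(f"trait {trait!r} is not PCA-scored (anchors: "
                         f"{sorted(ANCHOR_METRICS)})")
    mat = metrics.copy()
    if trait == "aggressiveness":
        mat = pd.DataFrame(
            {c: log_transform_if_needed(trait, mat[c]) for c in mat.columns},
            index=mat.index)
    return pc1_scores(mat, ANCHOR_METRICS[trait], trait=trait)
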