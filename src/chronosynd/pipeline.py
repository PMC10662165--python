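"""End-to-end orchestration: simulate -> chronotypes -> repeatability ->
syndromes -> chronotype-personality association.

The pipeline mirrors the study design: personality traits are scored from
repeated laboratory trials, chronotypes are decoded from acoustic detection
series of the same individuals after release, and the two are joined through
the dataset rules (>= 2 laboratory trial days per trait; >= 7 tracked days in
the wild).  Every stage derives its seed from a single root seed via
``numpy.random.SeedSequence``, so runs are reproducible from (config, seed)
and stages are independently replayable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hmm, mixed, syndrome as syndrome_mod, synthetic

logger = logging.getLogger("chronosynd")


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    out_dir: str = "chronosynd_run"
    seed: int = 0
    n_individuals: int = 30
    n_days: int = 14
    bin_minutes: int = 5
    coupling_beta: float = 0.0
    min_trials: int = 2
    min_tracking_days: int = 7
    min_exposure_s: float = 20.0
    n_boot: int = 200
    hmm_starts: int = 3
    chain: dict = field(default_factory=lambda: {
        "iterations": 4000, "burn_in": 1000, "thin": 3})
    stages: tuple = ("simulate", "chronotype", "repeatability",
                     "syndrome", "association")
    chrono: dict = field(default_factory=dict)   # ChronoSimConfig overrides
    traits: dict = field(default_factory=dict)   # TraitSimConfig overrides

    def validate(self) -> None:
        if self.min_trials < 1 or self.min_tracking_days < 1:
            raise ValueError("filter values must be positive")
        if self.min_exposure_s < 0:
            raise ValueError("min_exposure_s must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must contain a seed key")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Dataset rules
# ---------------------------------------------------------------------------

def build_datasets(trials: pd.DataFrame, tracking_days: pd.DataFrame,
                   min_trials: int = 2, min_tracking_days: int = 7):
    """Apply the laboratory / laboratory+wild membership rules.

    * laboratory dataset: per trait, individuals with at least ``min_trials``
      distinct trial days;
    * laboratory+wild dataset: additionally at least ``min_tracking_days``
      tracked days (``tracking_days`` columns: individual_id, n_days).

    Returns (lab, lab_wild, exclusions) where the first two are filtered
    copies of ``trials`` and ``exclusions`` counts dropped records per rule.
    """
    required = {"individual_id", "trait", "day", "value"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing column(s): {sorted(missing)}")
    if not {"individual_id", "n_days"} <= set(tracking_days.columns):
        raise ValueError("tracking_days needs columns individual_id, n_days")

    day_counts = (trials.groupby(["trait", "individual_id"])["day"]
                  .nunique().rename("n_trials").reset_index())
    keep = day_counts[day_counts["n_trials"] >= min_trials]
    lab = trials.merge(keep[["trait", "individual_id"]],
                       on=["trait", "individual_id"], how="inner")
    tracked = set(tracking_days.loc[
        tracking_days["n_days"] >= min_tracking_days, "individual_id"])
    lab_wild = lab[lab["individual_id"].isin(tracked)].copy()
    exclusions = {
        "trials_dropped_min_trials": int(len(trials) - len(lab)),
        "trials_dropped_min_tracking": int(len(lab) - len(lab_wild)),
    }
    for name, n in exclusions.items():
        if n:
            logger.info("filter %s dropped %d records", name, n)
    return lab, lab_wild, exclusions


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def decode_chronotypes(detections: pd.DataFrame, solar: pd.DataFrame,
                       start, n_days: int, bin_minutes: int = 5,
                       n_starts: int = 3, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-individual HMM fit + decode + daily chronotype extraction.

    Returns (observations frame with individual_id/date/awakening_min/
    rest_onset_min, fitted params per individual).
    """
    start = pd.Timestamp(start)
    end = start + pd.Timedelta(days=n_days)
    obs_rows = []
    fits = {}
    for ind, sub in detections.groupby("individual_id", sort=True):
        binned = hmm.bin_detections(sub["timestamp"], start, end,
                                    bin_minutes=bin_minutes, individual_id=str(ind))
        if np.all(binned.counts == 0):
            logger.info("individual %s has no detections; skipped", ind)
            continue
        fit = hmm.fit_zip_hmm(binned.counts, n_starts=n_starts, seed=seed)
        path = hmm.viterbi_decode(fit.params, binned.counts)
        fits[str(ind)] = fit
        for ob in hmm.extract_daily_chronotype(path, binned, solar):
            obs_rows.append({
                "individual_id": ob.individual_id, "date": ob.date,
                "awakening_min": ob.awakening_min,
                "rest_onset_min": ob.rest_onset_min,
            })
    return pd.DataFrame(obs_rows), fits


def chronotype_scores(observations: pd.DataFrame, env: pd.DataFrame,
                      min_days: int = 7, n_sim: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Individual chronotype scores from LMMs on the daily observations.

    One LMM per metric (awakening, rest onset) with the daily environmental
    covariates as fixed effects and individual as random effect; the score is
    each individual's predicted random effect.  Individuals with fewer than
    ``min_days`` observed days are dropped.  Returns one row per individual
    with columns individual_id, awakening, awakening_sd, rest_onset,
    rest_onset_sd.
    """
    counts = observations.groupby("individual_id")["date"].nunique()
    keep = counts[counts >= min_days].index
    dropped = observations["individual_id"].nunique() - len(keep)
    if dropped:
        logger.info("chronotype filter dropped %d individuals (<%d days)",
                    dropped, min_days)
    obs = observations[observations["individual_id"].isin(keep)].copy()
    env = env.copy()
    env["date"] = pd.to_datetime(env["date"]).dt.date
    obs["date"] = pd.to_datetime(obs["date"]).dt.date
    merged = obs.merge(env, on="date", how="left")
    env_terms = tuple(c for c in env.columns if c != "date")
    n_missing = merged[list(env_terms)].isna().any(axis=1).sum()
    if n_missing:
        logger.info("dropped %d days lacking environmental covariates", n_missing)
        merged = merged.dropna(subset=list(env_terms))

    out = None
    for metric, col in (("awakening", "awakening_min"),
                        ("rest_onset", "rest_onset_min")):
        spec = mixed.LmmSpec(response=col, fixed=env_terms,
                             random=("individual",), scale_fixed=True)
        fit = mixed.fit_lmm(spec, merged)
        scores = mixed.individual_scores(fit, n_sim=n_sim, seed=seed)
        scores = scores.rename(columns={"score": metric, "sd": f"{metric}_sd"})
        out = scores if out is None else out.merge(scores, on="individual_id")
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run report.

    Outputs (CSV tables and the JSON report) are written under
    ``cfg.out_dir``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    chrono_cfg = synthetic.ChronoSimConfig(
        n_individuals=cfg.n_individuals, n_days=cfg.n_days,
        bin_minutes=cfg.bin_minutes, seed=stage_seed(cfg.seed, "simulate"),
        **cfg.chrono)
    trait_cfg = synthetic.TraitSimConfig(
        n_individuals=cfg.n_individuals, seed=stage_seed(cfg.seed, "simulate-traits"),
        **cfg.traits)

    detections, env, trials, truth = synthetic.gen_joint_dataset(
        chrono_cfg, trait_cfg, coupling_beta=cfg.coupling_beta)
    synthetic.write_detections_csv(detections, out / "detections.csv")
    synthetic.write_env_csv(env, out / "env.csv")
    synthetic.write_trials_csv(trials, out / "trials.csv")
    synthetic.write_ground_truth_json(truth, out / "ground_truth.json")
    report["stages"]["simulate"] = {
        "n_detections": int(len(detections)),
        "n_trial_rows": int(len(trials)),
    }
    if "chronotype" not in cfg.stages:
        _write_report(report, out)
        return report

    solar = pd.DataFrame({
        "date": pd.date_range(chrono_cfg.start_date, periods=cfg.n_days).date,
        "sunrise": chrono_cfg.sunrise_time,
        "sunset": chrono_cfg.sunset_time,
    })
    observations, fits = decode_chronotypes(
        detections, solar, chrono_cfg.start_date, cfg.n_days,
        bin_minutes=cfg.bin_minutes, n_starts=cfg.hmm_starts,
        seed=stage_seed(cfg.seed, "hmm"))
    observations.to_csv(out / "chronotype_observations.csv", index=False)
    scores = chronotype_scores(observations, env,
                               min_days=cfg.min_tracking_days,
                               seed=stage_seed(cfg.seed, "chronoscores"))
    scores.to_csv(out / "chronotype_scores.csv", index=False)
    report["stages"]["chronotype"] = {
        "n_observations": int(len(observations)),
        "n_scored_individuals": int(len(scores)),
        "mean_awakening_min": float(observations["awakening_min"].mean()),
        "mean_rest_onset_min": float(observations["rest_onset_min"].mean()),
    }

    tracking = (observations.groupby("individual_id")["date"].nunique()
                .rename("n_days").reset_index())
    lab, lab_wild, exclusions = build_datasets(
        trials, tracking, cfg.min_trials, cfg.min_tracking_days)
    report["stages"]["datasets"] = {
        **exclusions,
        "n_lab_individuals": int(lab["individual_id"].nunique()),
        "n_lab_wild_individuals": int(lab_wild["individual_id"].nunique()),
    }

    if "repeatability" in cfg.stages:
        rep_rows = []
        for trait in sorted(lab["trait"].unique()):
            sub = lab[lab["trait"] == trait]
            spec = mixed.LmmSpec(response="value",
                                 fixed=("size_cm", "condition", "day"),
                                 random=("individual", "batch"))
            fit = mixed.fit_lmm(spec, sub)
            est = mixed.adjusted_repeatability(
                fit, n_boot=cfg.n_boot,
                seed=stage_seed(cfg.seed, f"boot-{trait}"))
            rep_rows.append({"trait": trait, "R": est.R,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "significant": est.significant,
                             "delta_aic": est.delta_aic_vs_constrained})
        rep = pd.DataFrame(rep_rows)
        rep.to_csv(out / "repeatability.csv", index=False)
        report["stages"]["repeatability"] = rep.to_dict(orient="records")

    if "syndrome" in cfg.stages:
        chain = syndrome_mod.ChainConfig(
            seed=stage_seed(cfg.seed, "gibbs"), **cfg.chain)
        synd = syndrome_mod.screen_pairs(
            lab, pairs=[p for p in syndrome_mod.TRAIT_PAIRS
                        if {p[0], p[1]} <= set(lab["trait"].unique())],
            chain=chain)
        synd.to_csv(out / "syndromes.csv", index=False)
        report["stages"]["syndrome"] = synd.to_dict(orient="records")

    if "association" in cfg.stages:
        assoc = syndrome_mod.chronotype_trait_association(lab_wild, scores)
        assoc.to_csv(out / "association.csv", index=False)
        report["stages"]["association"] = assoc.to_dict(orient="records")

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    logger.info("report written to %s", path)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Timestamp,)):
        return o.isoformat()
    return str(o)
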