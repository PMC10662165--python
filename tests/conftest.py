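import numpy as np
import pandas as pd
import pytest

import chronosynd as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def personality_single_trait():
    """Balanced one-trait table with known variance components (R_true=0.4)."""
    cfg = cs.TraitSimConfig(
        n_individuals=50, n_trials=4, trait_names=("activity",),
        Sigma_ind=np.array([[0.4]]), Sigma_e=np.array([[0.6]]),
        sd_batch=0.0, seed=3)
    table, truth = cs.gen_personality_dataset(cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def chronotype_small():
    """10 fish x 10 days of simulated detections plus solar table."""
    cfg = cs.ChronoSimConfig(n_individuals=10, n_days=10, seed=7)
    detections, env, truth = cs.gen_chronotype_dataset(cfg)
    solar = pd.DataFrame({
        "date": pd.date_range(cfg.start_date, periods=cfg.n_days).date,
        "sunrise": cfg.sunrise_time,
        "sunset": cfg.sunset_time,
    })
    return cfg, detections, env, truth, solar


def random_trajectory_frame(rng, n_minutes=30, fpm=6, p_missing=0.2):
    """Tidy frame of random detected/undetected positions for oracle tests."""
    n = n_minutes * fpm
    t = np.arange(n) * (60.0 / fpm)
    det = rng.random(n) > p_missing
    x = np.where(det, rng.uniform(0, 80, n), np.nan)
    y = np.where(det, rng.uniform(0, 40, n), np.nan)
    return pd.DataFrame({"trial_id": "t0", "t_seconds": t, "x_cm": x,
                         "y_cm": y, "detected": det.astype(int)})
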