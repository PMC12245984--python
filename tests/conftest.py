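from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from t1dpred.cohort import Participant
from t1dpred.features import load_lms_tables, load_score_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_participant(
    pid="P1",
    entry=date(2012, 6, 1),
    age=10.0,
    gender="female",
    bmi=18.0,
    grs2=12.0,
    abs_=("GADA",),
    glucose=(4.8, 7.0, 7.5, 6.5, 5.9),
    cpeptide=(1.5, 3.3, 4.5, 4.2, 3.6),
    hba1c=34.0,
    followup=3.0,
    event="censored",
) -> Participant:
    return Participant(
        id=pid,
        entry_date=entry,
        age=age,
        gender=gender,
        bmi=bmi,
        grs2=grs2,
        autoantibodies=frozenset(abs_),
        ogtt_glucose=tuple(glucose),
        ogtt_cpeptide=tuple(cpeptide),
        hba1c=hba1c,
        followup_time=followup,
        event=event,
    )


@pytest.fixture(scope="session")
def registry():
    return load_score_registry()


@pytest.fixture(scope="session")
def lms():
    return load_lms_tables()


def simulate_ph_frame(
    n: int,
    beta: dict[str, float],
    shape: float = 1.2,
    scale: float = 8.0,
    censor_rate: float = 0.0,
    seed: int = 0,
    admin: float | None = None,
) -> pd.DataFrame:
    """Minimal Weibull proportional-hazards dataset for fitting tests.

    Covariates are iid standard normal (binary if the name ends in ``_bin``);
    the linear predictor is ``sum(beta_v * x_v)``.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    eta = np.zeros(n)
    for name, b in beta.items():
        x = (
            (rng.uniform(size=n) < 0.5).astype(float)
            if name.endswith("_bin")
            else rng.standard_normal(n)
        )
        cols[name] = x
        eta += b * x
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)
    t_cens = (
        rng.exponential(1.0 / censor_rate, size=n)
        if censor_rate > 0
        else np.full(n, np.inf)
    )
    if admin is not None:
        t_cens = np.minimum(t_cens, admin)
    df = pd.DataFrame(cols)
    df["followup_time"] = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    df["event"] = (t_event <= t_cens).astype(int)
    df["true_time"] = t_event
    return df
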