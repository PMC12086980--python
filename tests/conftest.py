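import numpy as np
import pytest

from metareg.config import ModelConfig
from metareg.data import (
    AnalysisDataset,
    ArmRecord,
    ComparisonObservation,
    TrialRecord,
)
from metareg.indicators import INTERVENTION_INDICATORS
from metareg.simulate import GeneratorConfig, generate


def make_indicators(**overrides) -> dict[str, int]:
    """A valid intervention indicator dict (participation=1 keeps the
    at-least-one-mechanism rule satisfied) with selected overrides."""
    base = {k: 0 for k in INTERVENTION_INDICATORS}
    base["participation"] = 1
    base.update(overrides)
    return base


def make_toy_trial(
    trial_id: str = "T1",
    n_active: int = 2,
    categories: tuple[str, ...] = ("short", "medium"),
    ses: tuple[float, ...] | float = 0.3,
    with_control: bool = True,
    md: float = 0.1,
    trial_vals: dict | None = None,
) -> AnalysisDataset:
    """Small hand-built dataset: one trial, n_active arms, each observed at
    the given follow-up categories (vs control, or vs the first active arm)."""
    weeks = {"short": 20.0, "medium": 52.0, "long": 80.0}
    tvals = {"age_12_18": 0, "high_income": 1, "mixed_ses": 1}
    tvals.update(trial_vals or {})
    arms = {}
    arm_ids = []
    for a in range(n_active):
        aid = f"{trial_id}a{a + 1}"
        arms[aid] = ArmRecord(
            arm_id=aid, trial_id=trial_id, is_control=False,
            indicators=make_indicators(school=a % 2),
        )
        arm_ids.append(aid)
    if with_control:
        cid = f"{trial_id}c"
        arms[cid] = ArmRecord(arm_id=cid, trial_id=trial_id, is_control=True)
        arm_ids.append(cid)
        comparisons = [(aid, cid) for aid in arm_ids[:-1]]
    else:
        comparisons = [(aid, arm_ids[0]) for aid in arm_ids[1:]]
    trial = TrialRecord(trial_id=trial_id, arm_ids=tuple(arm_ids), **tvals)
    obs = []
    k = 0
    for aid, ref in comparisons:
        for cat in categories:
            se = ses if np.isscalar(ses) else ses[k]
            obs.append(
                ComparisonObservation(
                    trial_id=trial_id, arm_id=aid, reference_arm_id=ref,
                    followup_weeks=weeks[cat], followup_category=cat,
                    rob_high=0, md=md, se=float(se), scale="zbmi",
                )
            )
            k += 1
    ds = AnalysisDataset(trials={trial_id: trial}, arms=arms, observations=obs)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset reused by fitting tests."""
    cfg = GeneratorConfig(n_trials=60, seed=11)
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(seed=7, chains=2, draws=600, warmup=400)
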