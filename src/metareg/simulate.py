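"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study conditions of the real evidence base: ~204
trials yielding ~250 intervention-vs-reference comparisons and ~295
time-point observations once multi-arm trials and multi-follow-up reporting
are included; indicator marginals near the observed coding table; a
between-trial heterogeneity SD of 0.08 zBMI units with the exchangeable
tau^2 / tau^2/2 covariance across (arm, follow-up) effects; residuals
correlated 0.8 across follow-up times of the same comparison; and standard
errors on the zBMI scale (lognormal, median 0.05). True coefficients default
to the posterior means of the primary analysis so effect sizes are
realistic. Every latent quantity (coefficients, random effects, residuals)
is recorded so parameter recovery is checkable, and generation is
deterministic given the seed.

Indicators are generated independently at their marginals (no dependence
structure); screening tests plant correlated pairs explicitly instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    AnalysisDataset,
    ArmRecord,
    ComparisonObservation,
    TrialRecord,
    WEEKS_PER_MONTH,
    categorize_followup,
)
from .indicators import (
    ALL_INDICATORS,
    INTERVENTION_INDICATORS,
    MECHANISM_INDICATORS,
    TIME_INDICATORS,
    TRIAL_INDICATORS,
)
from .mapping import ArmSummary, LMSReference, bmi_from_zbmi, synthetic_reference
from .model import Design, build_design, random_effect_structure, within_trial_covariance

#: Indicator marginal probabilities matching the coding table of the source
#: evidence base (fractions of arms / trials / time points with value 1).
DEFAULT_MARGINALS: dict[str, float] = {
    "school": 0.708,
    "home": 0.424,
    "community": 0.280,
    "individual": 0.476,
    "electronic": 0.212,
    "diet_and_pa": 0.548,
    "pa_only": 0.272,
    "multi_strategy": 0.644,
    "duration_long": 0.500,
    "intensity_high": 0.608,
    "integration": 0.472,
    "flexibility_choice": 0.464,
    "fun_factor": 0.612,
    "resonance": 0.524,
    "participation": 0.672,
    "education": 0.740,
    "social_env": 0.696,
    "physical_env": 0.316,
    "age_12_18": 0.265,
    "high_income": 0.858,
    "mixed_ses": 0.770,
    "rob_high": 0.241,
}

#: True coefficients (uncentred scale) defaulting to the primary-analysis
#: posterior means; indicators with estimates near zero are set to 0.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.037,
    "home": 0.033,
    "pa_only": -0.227,
    "multi_strategy": -0.040,
    "integration": -0.028,
    "physical_env": 0.050,
    "age_12_18": -0.284,
    "high_income": -0.049,
    "medium": -0.036,
    "long": -0.019,
}

#: Follow-up category sampling weights (short, medium, long).
DEFAULT_CATEGORY_WEIGHTS = (0.27, 0.39, 0.34)

_CATEGORY_WEEK_RANGES = {
    "short": (12.0, 9.0 * WEEKS_PER_MONTH),
    "medium": (9.0 * WEEKS_PER_MONTH, 15.0 * WEEKS_PER_MONTH),
    "long": (15.0 * WEEKS_PER_MONTH, 30.0 * WEEKS_PER_MONTH),
}


@dataclass
class GeneratorConfig:
    n_trials: int = 204
    #: fraction of trials with a second intervention arm (both vs control)
    multi_arm_fraction: float = 0.25
    #: fraction of trials with two active arms and no control (an
    #: active-vs-active comparison)
    active_comparison_fraction: float = 0.02
    #: fraction of comparisons observed at two follow-up categories
    multi_followup_fraction: float = 0.18
    category_weights: tuple[float, float, float] = DEFAULT_CATEGORY_WEIGHTS
    marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    tau: float = 0.080
    rho_time: float = 0.8
    rho_arm: float = 0.5
    #: lognormal SE distribution on the zBMI scale
    se_median: float = 0.05
    se_sigma: float = 0.5
    planted_interactions: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.marginals.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"marginal for {k!r} outside [0, 1]: {v}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.se_median <= 0:
            raise ValueError("se_median must be positive")
        if not 0.0 <= self.rho_time < 1.0:
            raise ValueError("rho_time must be in [0, 1)")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthRecord:
    """Every latent quantity behind a generated dataset."""

    coefficients: pd.Series           # uncentred scale, by design column
    tau: float
    interactions: list[tuple[str, str]]
    random_effects: dict[str, dict[tuple[str, str], float]]
    residuals: np.ndarray             # per observation
    seed: int

    def on_design(self, design: Design) -> pd.Series:
        """Truth re-expressed on a (possibly centred) design's scale: the
        centred intercept is alpha_unc + sum(coef * centring mean)."""
        vals = pd.Series(0.0, index=design.columns)
        for name, v in self.coefficients.items():
            if name in vals.index:
                vals[name] = v
        vals["intercept"] = self.coefficients.get("intercept", 0.0) + float(
            vals.to_numpy()[1:] @ design.centering[1:]
        )
        return vals


def _draw_intervention_indicators(rng, marginals) -> dict[str, int]:
    p_both = marginals["diet_and_pa"]
    p_pa = marginals["pa_only"]
    u = rng.random()
    both, pa = int(u < p_both), int(p_both <= u < p_both + p_pa)
    out = {"diet_and_pa": both, "pa_only": pa}
    plain = [
        k for k in INTERVENTION_INDICATORS
        if k not in ("diet_and_pa", "pa_only") and k not in MECHANISM_INDICATORS
    ]
    for k in plain:
        out[k] = int(rng.random() < marginals[k])
    for _ in range(1000):
        mech = {k: int(rng.random() < marginals[k]) for k in MECHANISM_INDICATORS}
        if any(mech.values()):
            break
    out.update(mech)
    return out


def generate(config: GeneratorConfig) -> tuple[AnalysisDataset, TruthRecord]:
    """Generate a dataset and its truth record.

    Observations are y = X theta + Z u + eps with X the uncentred design
    including any planted interactions, u the exchangeable (arm, category)
    random effects (u = tau/sqrt(2) * (z_k + z_shared) per trial), and eps
    multivariate normal under the within-trial residual covariance.
    """
    rng = np.random.default_rng(config.seed)
    m = config.marginals
    cats = np.array(["short", "medium", "long"])
    weights = np.asarray(config.category_weights, float)
    weights = weights / weights.sum()

    trials: dict[str, TrialRecord] = {}
    arms: dict[str, ArmRecord] = {}
    observations: list[ComparisonObservation] = []

    for t in range(config.n_trials):
        tid = f"T{t:04d}"
        tvals = {k: int(rng.random() < m[k]) for k in TRIAL_INDICATORS}
        u = rng.random()
        if u < config.active_comparison_fraction:
            layout = "active_pair"
        elif u < config.active_comparison_fraction + config.multi_arm_fraction:
            layout = "multi_arm"
        else:
            layout = "two_arm"

        arm_ids = []
        n_active = 2 if layout in ("active_pair", "multi_arm") else 1
        for a in range(n_active):
            aid = f"{tid}a{a + 1}"
            arms[aid] = ArmRecord(
                arm_id=aid, trial_id=tid, is_control=False,
                indicators=_draw_intervention_indicators(rng, m),
            )
            arm_ids.append(aid)
        if layout != "active_pair":
            cid = f"{tid}c"
            arms[cid] = ArmRecord(arm_id=cid, trial_id=tid, is_control=True)
            arm_ids.append(cid)
            comparisons = [(aid, cid) for aid in arm_ids[:-1]]
        else:
            comparisons = [(arm_ids[0], arm_ids[1])]

        trials[tid] = TrialRecord(trial_id=tid, arm_ids=tuple(arm_ids), **tvals)

        for aid, ref in comparisons:
            n_cat = 2 if rng.random() < config.multi_followup_fraction else 1
            chosen = rng.choice(cats, size=n_cat, replace=False, p=weights)
            for cat in sorted(chosen, key=list(cats).index):
                lo, hi = _CATEGORY_WEEK_RANGES[cat]
                weeks = float(rng.uniform(lo, hi))
                # guard against landing exactly on an open boundary
                weeks = min(max(weeks, lo), np.nextafter(hi, lo))
                se = float(rng.lognormal(np.log(config.se_median), config.se_sigma))
                observations.append(
                    ComparisonObservation(
                        trial_id=tid, arm_id=aid, reference_arm_id=ref,
                        followup_weeks=weeks,
                        followup_category=categorize_followup(weeks),
                        rob_high=int(rng.random() < m["rob_high"]),
                        md=0.0, se=se, scale="zbmi",
                    )
                )

    dataset = AnalysisDataset(trials=trials, arms=arms, observations=observations)
    dataset.validate()

    design = build_design(dataset, config.planted_interactions, center=False)
    theta = pd.Series(0.0, index=design.columns, dtype=float)
    for name, v in config.true_coefficients.items():
        if name not in theta.index:
            raise ValueError(f"true coefficient for unknown column {name!r}")
        theta[name] = v
    mean = design.X @ theta.to_numpy()

    # latent draws, trial by trial
    controls = {a.arm_id for a in arms.values() if a.is_control}
    by_trial: dict[str, list[int]] = {}
    for i, obs in enumerate(observations):
        by_trial.setdefault(obs.trial_id, []).append(i)
    y = mean.copy()
    residuals = np.zeros(len(observations))
    random_effects: dict[str, dict[tuple[str, str], float]] = {}
    for tid, idx in by_trial.items():
        obs = [observations[i] for i in idx]
        keys: list[tuple[str, str]] = []
        for o in obs:
            for aid in (o.arm_id, o.reference_arm_id):
                if aid not in controls and (aid, o.followup_category) not in keys:
                    keys.append((aid, o.followup_category))
        shared = rng.standard_normal()
        uvals = {
            k: config.tau / np.sqrt(2.0) * (rng.standard_normal() + shared)
            for k in keys
        }
        random_effects[tid] = uvals
        R = within_trial_covariance(obs, config.rho_time, config.rho_arm)
        eps = np.linalg.cholesky(R) @ rng.standard_normal(len(obs))
        for j, (i, o) in enumerate(zip(idx, obs)):
            re = uvals[(o.arm_id, o.followup_category)]
            if o.reference_arm_id not in controls:
                re -= uvals[(o.reference_arm_id, o.followup_category)]
            residuals[i] = eps[j]
            y[i] = mean[i] + re + eps[j]

    dataset.observations = [
        dataclasses.replace(o, md=float(y[i])) for i, o in enumerate(observations)
    ]
    truth = TruthRecord(
        coefficients=theta,
        tau=config.tau,
        interactions=list(config.planted_interactions),
        random_effects=random_effects,
        residuals=residuals,
        seed=config.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Forward simulation of arm summaries (for the outcome-mapping oracle)


def generate_arm_summaries(
    scale: str,
    n_arms: int = 5,
    n_individuals: int = 10_000,
    mu_range: tuple[float, float] = (-0.5, 1.0),
    sigma_range: tuple[float, float] = (0.8, 1.3),
    thresholds: tuple[float, ...] = (1.036433, 1.644854),
    ref: LMSReference | None = None,
    seed: int = 0,
) -> list[tuple[ArmSummary, float, float]]:
    """Simulate arms with known zBMI distributions and report them on the
    requested scale. Returns (summary, true_mu, true_sigma) triples for
    round-trip testing of the outcome mappers."""
    rng = np.random.default_rng(seed)
    ref = ref or synthetic_reference()
    lo, hi = ref.age_range
    out = []
    for _ in range(n_arms):
        mu = float(rng.uniform(*mu_range))
        sigma = float(rng.uniform(*sigma_range))
        z = rng.normal(mu, sigma, size=n_individuals)
        age_mean, age_sd = 10.0, 1.5
        ages = np.clip(
            rng.normal(age_mean, age_sd, size=n_individuals), lo, hi
        )
        sexes = (rng.random(n_individuals) < 0.5).astype(int)
        if scale == "bmi":
            bmi = bmi_from_zbmi(z, ages, sexes, ref)
            summary = ArmSummary(
                scale="bmi", mean=float(bmi.mean()), sd=float(bmi.std(ddof=1)),
                n=n_individuals, age_mean=age_mean, age_sd=age_sd,
                prop_male=0.5,
            )
        elif scale == "percentile":
            from scipy.stats import norm

            pct = 100.0 * norm.cdf(z)
            summary = ArmSummary(
                scale="percentile", mean=float(pct.mean()),
                sd=float(pct.std(ddof=1)), n=n_individuals,
            )
        elif scale == "prevalence":
            props = {
                float(thr): float(np.mean(z > thr)) for thr in thresholds
            }
            summary = ArmSummary(scale="prevalence", n=n_individuals,
                                 proportions=props)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        out.append((summary, mu, sigma))
    return out
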