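"""Canonical indicator names for the three coding levels.

The analysis codes every intervention arm, trial and time point with binary
indicators. Intervention-level indicators describe what the intervention is
and how it is delivered; trial-level indicators describe the population; and
time-point-level indicators describe the follow-up category and the
risk-of-bias judgement attached to each result.

Behaviour targeted is coded as two dummies (``diet_and_pa``, ``pa_only``)
with diet-alone as the implicit reference level, so the two are mutually
exclusive. Follow-up category is likewise coded as two dummies (``medium``,
``long``) with short-term as the reference.
"""

from __future__ import annotations

# Intervention-arm level (coded per active arm; control arms are not coded).
INTERVENTION_INDICATORS: tuple[str, ...] = (
    "school",
    "home",
    "community",
    "individual",
    "electronic",
    "diet_and_pa",
    "pa_only",
    "multi_strategy",
    "duration_long",
    "intensity_high",
    "integration",
    "flexibility_choice",
    "fun_factor",
    "resonance",
    "participation",
    "education",
    "social_env",
    "physical_env",
)

# Trial level (constant across all arms and observations of a trial).
TRIAL_INDICATORS: tuple[str, ...] = ("age_12_18", "high_income", "mixed_ses")

# Time-point level (vary with follow-up time within a trial).
TIME_INDICATORS: tuple[str, ...] = ("medium", "long", "rob_high")

ALL_INDICATORS: tuple[str, ...] = (
    INTERVENTION_INDICATORS + TRIAL_INDICATORS + TIME_INDICATORS
)

#: Mutually exclusive dummy pairs (two-dummy codings of three-level factors).
MUTEX_PAIRS: tuple[tuple[str, str], ...] = (
    ("medium", "long"),
    ("diet_and_pa", "pa_only"),
)

#: Mechanism-of-action indicators: a plausible intervention engages at least
#: one explicit mechanism.
MECHANISM_INDICATORS: tuple[str, ...] = (
    "participation",
    "education",
    "social_env",
    "physical_env",
)

#: Behaviour-targeted dummies (for interaction stage construction).
BEHAVIOUR_INDICATORS: tuple[str, ...] = ("diet_and_pa", "pa_only")

AGE_INDICATOR = "age_12_18"


def level_of(name: str) -> str:
    """Return the coding level ('intervention', 'trial' or 'time') of an indicator."""
    if name in INTERVENTION_INDICATORS:
        return "intervention"
    if name in TRIAL_INDICATORS:
        return "trial"
    if name in TIME_INDICATORS:
        return "time"
    raise KeyError(f"unknown indicator: {name!r}")
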