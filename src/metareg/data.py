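"""Dataset schema, validation, CSV I/O and the deterministic coding rules.

The unit of analysis is a *comparison observation*: a mean difference (MD) in
change from baseline in zBMI between an intervention arm and a reference arm
of the same trial, at one follow-up time, with its standard error. Datasets
include multi-arm trials (several interventions vs one control, or
active-vs-active comparisons) and multi-follow-up trials (the same comparison
observed at several times).

CSV layout (one row per observation)
------------------------------------
Required columns::

    trial_id, arm_id, reference_arm_id, ref_is_control,
    followup_weeks, md, se, scale, rob_high,
    age_12_18, high_income, mixed_ses,
    <18 intervention indicator columns for the intervention arm>,
    ref_<indicator> columns (blank when the reference is a control arm)

``scale`` records the scale the trial originally reported on
(zbmi/bmi/percentile/prevalence); ``md``/``se`` are always on the zBMI scale
after mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .indicators import (
    INTERVENTION_INDICATORS,
    TIME_INDICATORS,
    TRIAL_INDICATORS,
)

# Declared unit convention: 1 month = 365.25/84 weeks (= 4.348...), i.e. a
# twelfth of a Julian year expressed in 7-day weeks.
WEEKS_PER_MONTH = 365.25 / 84.0

VALID_SCALES = ("zbmi", "bmi", "percentile", "prevalence")
FOLLOWUP_CATEGORIES = ("short", "medium", "long")

#: Category boundaries in weeks: short = [12 wk, 9 mo), medium = [9, 15) mo,
#: long = >= 15 mo.
_MIN_FOLLOWUP_WEEKS = 12.0
_SHORT_UPPER_WEEKS = 9.0 * WEEKS_PER_MONTH
_MEDIUM_UPPER_WEEKS = 15.0 * WEEKS_PER_MONTH

#: Time-point selection targets (weeks): midpoint of the short and medium
#: intervals, and 24 months for the open-ended long interval.
SELECTION_TARGET_WEEKS = {
    "short": 0.5 * (_MIN_FOLLOWUP_WEEKS + _SHORT_UPPER_WEEKS),
    "medium": 0.5 * (_SHORT_UPPER_WEEKS + _MEDIUM_UPPER_WEEKS),
    "long": 24.0 * WEEKS_PER_MONTH,
}


class ValidationError(ValueError):
    """A dataset violates the schema or an invariant; message names the row."""


def categorize_followup(followup_weeks: float) -> str:
    """Assign a follow-up time (weeks) to the short/medium/long category.

    Short is 12 weeks to <9 months, medium 9 to <15 months, long >= 15
    months. Follow-ups under 12 weeks are outside the analysis domain.
    """
    if followup_weeks < _MIN_FOLLOWUP_WEEKS:
        raise ValueError(
            f"follow-up of {followup_weeks:g} weeks is below the 12-week minimum"
        )
    if followup_weeks < _SHORT_UPPER_WEEKS:
        return "short"
    if followup_weeks < _MEDIUM_UPPER_WEEKS:
        return "medium"
    return "long"


def dichotomize_duration(duration_weeks: float, median_weeks: float = 30.33) -> int:
    """Code intervention duration as long (1, >= median) vs short (0).

    The default median of 30.33 weeks is the median duration across all coded
    interventions in the source reviews; pass ``median_weeks`` to recompute
    it for another dataset. The boundary is inclusive: a duration equal to
    the median codes as long.
    """
    if duration_weeks <= 0 or median_weeks <= 0:
        raise ValueError("durations must be positive")
    return int(duration_weeks >= median_weeks)


def select_timepoints(df: pd.DataFrame) -> pd.DataFrame:
    """Reduce to one observation per (trial, arm, reference, category).

    Within each group, keep the observation whose follow-up time is closest
    to the category's target (interval midpoint for short/medium, 24 months
    for long); ties go to the earlier time.
    """
    if "followup_category" not in df.columns:
        df = df.assign(
            followup_category=df["followup_weeks"].map(categorize_followup)
        )
    targets = df["followup_category"].map(SELECTION_TARGET_WEEKS)
    dist = (df["followup_weeks"] - targets).abs()
    order = df.assign(_dist=dist).sort_values(
        ["_dist", "followup_weeks"], kind="mergesort"
    )
    keep = order.groupby(
        ["trial_id", "arm_id", "reference_arm_id", "followup_category"],
        sort=False,
    ).head(1)
    return keep.drop(columns="_dist").sort_index()


# ---------------------------------------------------------------------------
# Record types


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    age_12_18: int
    high_income: int
    mixed_ses: int
    arm_ids: tuple[str, ...] = ()

    def indicator_values(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in TRIAL_INDICATORS}


@dataclass(frozen=True)
class ArmRecord:
    arm_id: str
    trial_id: str
    is_control: bool
    #: intervention-level indicator values; empty for control arms
    indicators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_control and self.indicators:
            raise ValidationError(
                f"control arm {self.arm_id!r} carries intervention indicators"
            )
        if not self.is_control:
            missing = set(INTERVENTION_INDICATORS) - set(self.indicators)
            if missing:
                raise ValidationError(
                    f"arm {self.arm_id!r} missing indicators: {sorted(missing)}"
                )
            bad = {
                k: v for k, v in self.indicators.items() if v not in (0, 1)
            }
            if bad:
                raise ValidationError(
                    f"arm {self.arm_id!r} has non-binary indicator values: {bad}"
                )

    def indicator_vector(self) -> np.ndarray:
        if self.is_control:
            return np.zeros(len(INTERVENTION_INDICATORS))
        return np.array(
            [self.indicators[k] for k in INTERVENTION_INDICATORS], dtype=float
        )


@dataclass(frozen=True)
class ComparisonObservation:
    trial_id: str
    arm_id: str
    reference_arm_id: str
    followup_weeks: float
    followup_category: str
    rob_high: int
    md: float
    se: float
    scale: str

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(
                f"observation ({self.trial_id}, {self.arm_id}, "
                f"{self.followup_weeks} wk) has se <= 0"
            )
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown outcome scale {self.scale!r}")
        if self.followup_category != categorize_followup(self.followup_weeks):
            raise ValidationError(
                f"followup_category {self.followup_category!r} inconsistent "
                f"with followup_weeks={self.followup_weeks:g}"
            )

    def time_vector(self) -> np.ndarray:
        """Time-level indicator values (medium, long, rob_high)."""
        return np.array(
            [
                float(self.followup_category == "medium"),
                float(self.followup_category == "long"),
                float(self.rob_high),
            ]
        )


@dataclass
class AnalysisDataset:
    trials: dict[str, TrialRecord]
    arms: dict[str, ArmRecord]
    observations: list[ComparisonObservation]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def n_comparisons(self) -> int:
        return len(
            {(o.trial_id, o.arm_id, o.reference_arm_id) for o in self.observations}
        )

    def validate(self) -> None:
        for obs in self.observations:
            if obs.trial_id not in self.trials:
                raise ValidationError(f"observation references unknown trial {obs.trial_id!r}")
            for a in (obs.arm_id, obs.reference_arm_id):
                if a not in self.arms:
                    raise ValidationError(f"observation references unknown arm {a!r}")
                if self.arms[a].trial_id != obs.trial_id:
                    raise ValidationError(
                        f"arm {a!r} does not belong to trial {obs.trial_id!r}"
                    )
            if self.arms[obs.arm_id].is_control:
                raise ValidationError(
                    f"intervention side of a comparison is a control arm: {obs.arm_id!r}"
                )
        seen: set[tuple] = set()
        for obs in self.observations:
            key = (obs.trial_id, obs.arm_id, obs.reference_arm_id, obs.followup_category)
            if key in seen:
                raise ValidationError(
                    f"multiple observations per (trial, arm, reference, category): {key}"
                )
            seen.add(key)
        for t in self.trials.values():
            if len(t.arm_ids) < 2:
                raise ValidationError(f"trial {t.trial_id!r} has fewer than 2 arms")

    def indicator_frame(self) -> pd.DataFrame:
        """Intervention-level indicator matrix over active arms (arms x 18)."""
        rows = {
            a.arm_id: [a.indicators[k] for k in INTERVENTION_INDICATORS]
            for a in self.arms.values()
            if not a.is_control
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(INTERVENTION_INDICATORS)
        ).sort_index()

    def describe(self) -> pd.DataFrame:
        """Counts and percentages of each indicator, in the style of a coding table."""
        out = []
        ind = self.indicator_frame()
        for k in INTERVENTION_INDICATORS:
            n = int(ind[k].sum())
            out.append(("intervention", k, n, 100.0 * n / len(ind)))
        for k in TRIAL_INDICATORS:
            n = sum(getattr(t, k) for t in self.trials.values())
            out.append(("trial", k, n, 100.0 * n / self.n_trials))
        tv = np.array([o.time_vector() for o in self.observations])
        for j, k in enumerate(TIME_INDICATORS):
            n = int(tv[:, j].sum())
            out.append(("time", k, n, 100.0 * n / self.n_observations))
        return pd.DataFrame(out, columns=["level", "indicator", "n", "percent"])


# ---------------------------------------------------------------------------
# CSV round trip

_REQUIRED_COLUMNS = (
    ["trial_id", "arm_id", "reference_arm_id", "ref_is_control",
     "followup_weeks", "md", "se", "scale", "rob_high"]
    + list(TRIAL_INDICATORS)
    + list(INTERVENTION_INDICATORS)
)


def to_frame(dataset: AnalysisDataset) -> pd.DataFrame:
    """Flatten a dataset to the canonical one-row-per-observation frame."""
    rows = []
    for obs in dataset.observations:
        arm = dataset.arms[obs.arm_id]
        ref = dataset.arms[obs.reference_arm_id]
        trial = dataset.trials[obs.trial_id]
        row: dict = {
            "trial_id": obs.trial_id,
            "arm_id": obs.arm_id,
            "reference_arm_id": obs.reference_arm_id,
            "ref_is_control": int(ref.is_control),
            "followup_weeks": obs.followup_weeks,
            "followup_category": obs.followup_category,
            "md": obs.md,
            "se": obs.se,
            "scale": obs.scale,
            "rob_high": obs.rob_high,
        }
        row.update(trial.indicator_values())
        for k in INTERVENTION_INDICATORS:
            row[k] = arm.indicators[k]
        for k in INTERVENTION_INDICATORS:
            row[f"ref_{k}"] = np.nan if ref.is_control else ref.indicators[k]
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: AnalysisDataset, path) -> None:
    to_frame(dataset).to_csv(path, index=False)


def from_frame(df: pd.DataFrame) -> AnalysisDataset:
    """Assemble and validate a dataset from the canonical frame."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    for col in list(INTERVENTION_INDICATORS) + list(TRIAL_INDICATORS) + ["rob_high", "ref_is_control"]:
        vals = df[col].dropna().unique()
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise ValidationError(f"non-binary values in column {col!r}: {bad}")
    bad_se = df.index[df["se"] <= 0].tolist()
    if bad_se:
        raise ValidationError(f"se <= 0 in rows {bad_se}")

    trials: dict[str, TrialRecord] = {}
    arms: dict[str, ArmRecord] = {}
    observations: list[ComparisonObservation] = []
    trial_arms: dict[str, set] = {}

    def _register_arm(arm_id, trial_id, is_control, indicators):
        rec = ArmRecord(
            arm_id=str(arm_id),
            trial_id=str(trial_id),
            is_control=bool(is_control),
            indicators=indicators,
        )
        prev = arms.get(rec.arm_id)
        if prev is not None and prev != rec:
            raise ValidationError(
                f"arm {arm_id!r} coded inconsistently across rows"
            )
        arms[rec.arm_id] = rec
        trial_arms.setdefault(str(trial_id), set()).add(str(arm_id))

    for idx, row in df.iterrows():
        tid = str(row["trial_id"])
        tvals = {k: int(row[k]) for k in TRIAL_INDICATORS}
        prev = trials.get(tid)
        if prev is not None and prev.indicator_values() != tvals:
            raise ValidationError(
                f"trial-level indicators vary within trial {tid!r} (row {idx})"
            )
        trials[tid] = TrialRecord(trial_id=tid, **tvals)

        _register_arm(
            row["arm_id"], tid, False,
            {k: int(row[k]) for k in INTERVENTION_INDICATORS},
        )
        if int(row["ref_is_control"]):
            ref_cols = [row.get(f"ref_{k}") for k in INTERVENTION_INDICATORS]
            if any(pd.notna(v) and v != "" for v in ref_cols):
                raise ValidationError(
                    f"control reference arm carries indicators (row {idx})"
                )
            _register_arm(row["reference_arm_id"], tid, True, {})
        else:
            _register_arm(
                row["reference_arm_id"], tid, False,
                {k: int(row[f"ref_{k}"]) for k in INTERVENTION_INDICATORS},
            )

        weeks = float(row["followup_weeks"])
        cat = row.get("followup_category")
        if pd.isna(cat) or cat is None:
            cat = categorize_followup(weeks)
        observations.append(
            ComparisonObservation(
                trial_id=tid,
                arm_id=str(row["arm_id"]),
                reference_arm_id=str(row["reference_arm_id"]),
                followup_weeks=weeks,
                followup_category=str(cat),
                rob_high=int(row["rob_high"]),
                md=float(row["md"]),
                se=float(row["se"]),
                scale=str(row["scale"]),
            )
        )

    trials = {
        tid: TrialRecord(
            trial_id=tid,
            arm_ids=tuple(sorted(trial_arms[tid])),
            **{k: getattr(t, k) for k in TRIAL_INDICATORS},
        )
        for tid, t in trials.items()
    }
    ds = AnalysisDataset(trials=trials, arms=arms, observations=observations)
    ds.validate()
    return ds


def read_dataset(
    path, config: ModelConfig | None = None
) -> tuple[AnalysisDataset, pd.DataFrame]:
    """Read, validate and (optionally) subset a dataset CSV.

    Returns the dataset and a validation report listing rows dropped by the
    outcome-scale subset filter, with reasons. Schema violations raise
    :class:`ValidationError` naming the offending row or column.
    """
    # round_trip float parsing so write -> read is the exact identity
    df = pd.read_csv(path, float_precision="round_trip")
    dropped = []
    if config is not None and config.outcome_subset != "all":
        keep_scales = {
            "zbmi_only": {"zbmi"},
            "bmi_only": {"bmi"},
            "zbmi_and_percentile": {"zbmi", "percentile"},
        }[config.outcome_subset]
        mask = df["scale"].isin(keep_scales)
        for idx in df.index[~mask]:
            dropped.append(
                (idx, f"scale {df.loc[idx, 'scale']!r} outside subset "
                      f"{config.outcome_subset!r}")
            )
        df = df[mask].reset_index(drop=True)
    report = pd.DataFrame(dropped, columns=["row", "reason"])
    return from_frame(df), report
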