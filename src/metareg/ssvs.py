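"""Stochastic search variable selection (SSVS) over interaction terms.

Candidate interaction coefficients get a two-component mixture prior: a
narrow "spike" Normal(0, spike_sd^2) representing exclusion and a wide
"slab" Normal(0, slab_sd^2) representing inclusion, governed by a latent
Bernoulli(p_incl) indicator per candidate that is sampled within the Gibbs
scheme. The posterior mean of the indicator is the candidate's inclusion
frequency; candidates selected more than half the time enter the final
model.

The stepwise procedure fits (i) the model with no interactions, then runs
SSVS over (ii) interactions of age with every other indicator and (iii)
interactions of the behaviour-targeted dummies with every other indicator,
and takes the union of candidates selected more than 50% of the time in
stages (ii) and (iii).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .data import AnalysisDataset
from .indicators import (
    AGE_INDICATOR,
    ALL_INDICATORS,
    BEHAVIOUR_INDICATORS,
    MUTEX_PAIRS,
)
from .model import FitResult, SsvsSpec, build_design, fit, interaction_name

SELECTION_THRESHOLD = 0.5


@dataclass
class SpikeSlabConfig:
    candidates: list[tuple[str, str]]
    p_incl: float = 0.5
    spike_sd: float = 0.01
    slab_sd: float = 1.0
    threshold: float = SELECTION_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.p_incl < 1.0:
            raise ValueError("p_incl must be in (0, 1)")
        if self.spike_sd <= 0 or self.slab_sd <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass
class SelectionResult:
    table: pd.DataFrame  # index: candidate label; inclusion_frequency, selected, coef stats
    fit: FitResult

    @property
    def selected(self) -> list[tuple[str, str]]:
        labels = self.table.index[self.table["selected"]]
        return [tuple(lbl.split(":")) for lbl in labels]


def candidate_pairs(
    anchor: str, indicators: tuple[str, ...] = ALL_INDICATORS
) -> list[tuple[str, str]]:
    """All (anchor, other) interaction candidates, excluding self-pairings and
    mutually exclusive dummy partners (reference-level pairings)."""
    excluded = {anchor}
    for a, b in MUTEX_PAIRS:
        if anchor == a:
            excluded.add(b)
        elif anchor == b:
            excluded.add(a)
    return [(anchor, other) for other in indicators if other not in excluded]


def age_candidates() -> list[tuple[str, str]]:
    return candidate_pairs(AGE_INDICATOR)


def behaviour_candidates() -> list[tuple[str, str]]:
    out = []
    for anchor in BEHAVIOUR_INDICATORS:
        out.extend(candidate_pairs(anchor))
    return out


def run_ssvs(
    dataset: AnalysisDataset,
    config: SpikeSlabConfig,
    model_config: ModelConfig,
    base_interactions: list[tuple[str, str]] | None = None,
) -> SelectionResult:
    """Run SSVS over candidate interactions on top of the main-effects model.

    ``base_interactions`` (if any) enter with the ordinary coefficient prior;
    the candidates get the spike-and-slab prior. Returns per-candidate
    posterior inclusion frequencies, the selected flag (frequency strictly
    above the threshold) and shrunken coefficient summaries.
    """
    base = list(base_interactions or [])
    all_interactions = base + list(config.candidates)
    design = build_design(dataset, all_interactions, center=model_config.center)
    cand_labels = [interaction_name(a, b) for a, b in config.candidates]
    idx = np.array([design.column_index(lbl) for lbl in cand_labels])
    spec = SsvsSpec(
        indices=idx,
        spike_sd=config.spike_sd,
        slab_sd=config.slab_sd,
        p_incl=config.p_incl,
    )
    res = fit(dataset, model_config, ssvs=spec, design=design)
    freq = res.inclusion.mean(axis=(0, 1))
    coef = res.theta[:, :, idx]
    table = pd.DataFrame(
        {
            "inclusion_frequency": freq,
            "selected": freq > config.threshold,
            "coef_mean": coef.mean(axis=(0, 1)),
            "coef_ci_low": np.percentile(coef, 2.5, axis=(0, 1)),
            "coef_ci_high": np.percentile(coef, 97.5, axis=(0, 1)),
        },
        index=cand_labels,
    )
    return SelectionResult(table=table, fit=res)


@dataclass
class StepwiseResult:
    no_interaction_fit: FitResult
    age_stage: SelectionResult
    behaviour_stage: SelectionResult
    final_interactions: list[tuple[str, str]] = field(default_factory=list)


def stepwise_selection(
    dataset: AnalysisDataset,
    model_config: ModelConfig,
    p_incl: float = 0.5,
    spike_sd: float = 0.01,
    slab_sd: float = 1.0,
) -> StepwiseResult:
    """Three-stage interaction selection; stages run independently and the
    final list is the union of candidates selected in stages (ii) and (iii),
    de-duplicated by canonical interaction label."""
    stage1 = fit(dataset, model_config)
    stage2 = run_ssvs(
        dataset,
        SpikeSlabConfig(age_candidates(), p_incl, spike_sd, slab_sd),
        model_config,
    )
    stage3 = run_ssvs(
        dataset,
        SpikeSlabConfig(behaviour_candidates(), p_incl, spike_sd, slab_sd),
        model_config,
    )
    seen: dict[str, tuple[str, str]] = {}
    for pair in stage2.selected + stage3.selected:
        seen.setdefault(interaction_name(*pair), pair)
    return StepwiseResult(
        no_interaction_fit=stage1,
        age_stage=stage2,
        behaviour_stage=stage3,
        final_interactions=list(seen.values()),
    )
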