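"""Exhaustive profiling of plausible indicator combinations.

After fitting, the model predicts a zBMI mean difference for any vector of
indicator values. This module enumerates every *plausible* combination —
excluding impossible ones (a follow-up both medium- and long-term, an
intervention targeting both 'physical activity alone' and 'diet and physical
activity') and requiring at least one mechanism-of-action indicator — and
profiles the predictions: the best (most negative MD) and worst rows, the
typical indicator values in the best and worst 1% of combinations, the
fraction of combinations predicting benefit (MD < 0), and subgroup-restricted
searches with trial- or time-level indicators pinned.

With the default 24 indicators the grid has 2^16 * 3 * 3 * 15 = 8,847,360
rows; enumeration is chunked so the full grid never needs to be materialised
at once.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .indicators import (
    ALL_INDICATORS,
    MECHANISM_INDICATORS,
    MUTEX_PAIRS,
)
from .model import Design, FitResult, interaction_name


class ContradictionError(ValueError):
    """A fixed assignment is inconsistent with the plausibility rules."""


@dataclass(frozen=True)
class PlausibilityRules:
    """Rule set defining which indicator vectors are plausible."""

    indicators: tuple[str, ...] = ALL_INDICATORS
    mutex_pairs: tuple[tuple[str, str], ...] = MUTEX_PAIRS
    at_least_one: tuple[tuple[str, ...], ...] = (MECHANISM_INDICATORS,)

    def satisfied(self, rows: np.ndarray) -> np.ndarray:
        """Boolean mask of rows satisfying every rule (for oracle checks)."""
        idx = {c: i for i, c in enumerate(self.indicators)}
        ok = np.ones(len(rows), bool)
        for a, b in self.mutex_pairs:
            ok &= ~((rows[:, idx[a]] == 1) & (rows[:, idx[b]] == 1))
        for group in self.at_least_one:
            ok &= rows[:, [idx[g] for g in group]].any(axis=1)
        return ok


def _build_blocks(
    rules: PlausibilityRules, fixed: dict[str, int] | None
) -> list[tuple[list[int], np.ndarray]]:
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(rules.indicators)
    if unknown:
        raise KeyError(f"fixed assignment names unknown indicators: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(rules.indicators)}
    assigned: set[str] = set()
    blocks: list[tuple[list[int], np.ndarray]] = []

    for pair in rules.mutex_pairs:
        vals = [(0, 0), (1, 0), (0, 1)]
        vals = [
            v
            for v in vals
            if all(fixed.get(pair[k], v[k]) == v[k] for k in range(2))
        ]
        if not vals:
            raise ContradictionError(f"fixed assignment contradicts mutex pair {pair}")
        blocks.append(([idx[c] for c in pair], np.array(vals, np.uint8)))
        assigned.update(pair)

    for group in rules.at_least_one:
        if assigned & set(group):
            raise ValueError("rule groups must not overlap mutex pairs")
        choices = [
            ((fixed[c],) if c in fixed else (0, 1)) for c in group
        ]
        vals = [v for v in itertools.product(*choices) if any(v)]
        if not vals:
            raise ContradictionError(
                f"fixed assignment contradicts at-least-one group {group}"
            )
        blocks.append(([idx[c] for c in group], np.array(vals, np.uint8)))
        assigned.update(group)

    for c in rules.indicators:
        if c not in assigned:
            vals = [(fixed[c],)] if c in fixed else [(0,), (1,)]
            blocks.append(([idx[c]], np.array(vals, np.uint8)))
    return blocks


def count_plausible(
    rules: PlausibilityRules = PlausibilityRules(),
    fixed: dict[str, int] | None = None,
) -> int:
    """Closed-form row count: the product of per-block admissible value counts."""
    return math.prod(len(vals) for _, vals in _build_blocks(rules, fixed))


def enumerate_plausible(
    rules: PlausibilityRules = PlausibilityRules(),
    fixed: dict[str, int] | None = None,
    chunk_size: int = 1 << 16,
) -> Iterator[np.ndarray]:
    """Yield the grid of plausible rows in deterministic order, in chunks.

    Rows are uint8 arrays with columns in ``rules.indicators`` order. The
    k-th plausible row is reconstructed from k by mixed-radix decoding over
    the rule blocks, so enumeration is O(rows) memory-free and repeatable.
    """
    blocks = _build_blocks(rules, fixed)
    bases = np.array([len(vals) for _, vals in blocks], np.int64)
    total = int(bases.prod())
    strides = np.ones(len(blocks), np.int64)
    for i in range(len(blocks) - 2, -1, -1):
        strides[i] = strides[i + 1] * bases[i + 1]
    ncol = len(rules.indicators)
    for start in range(0, total, chunk_size):
        ids = np.arange(start, min(start + chunk_size, total), dtype=np.int64)
        out = np.empty((len(ids), ncol), np.uint8)
        for (cols, vals), stride, base in zip(blocks, strides, bases):
            digits = (ids // stride) % base
            out[:, cols] = vals[digits]
        yield out


def full_grid(
    rules: PlausibilityRules = PlausibilityRules(),
    fixed: dict[str, int] | None = None,
    max_rows: int = 1 << 24,
) -> np.ndarray:
    """Materialise the whole grid (guarded against accidental huge arrays)."""
    n = count_plausible(rules, fixed)
    if n > max_rows:
        raise MemoryError(f"grid has {n} rows; use enumerate_plausible")
    return np.vstack(list(enumerate_plausible(rules, fixed)))


# ---------------------------------------------------------------------------
# Prediction


def predict_combination(
    rows: np.ndarray,
    coefficients: pd.Series,
    centering: pd.Series | None = None,
    interactions: list[tuple[str, str]] | None = None,
    indicators: tuple[str, ...] = ALL_INDICATORS,
) -> np.ndarray:
    """De-centred linear predictor for indicator rows (smaller = more
    beneficial).

    ``coefficients`` is indexed by design column names ('intercept', the
    indicator names, and canonical interaction labels); ``centering`` holds
    the per-column means recorded at design construction, so the centred
    intercept is converted to its uncentred equivalent
    alpha_c - sum(coef * mean) before prediction.
    """
    rows = np.atleast_2d(np.asarray(rows, float))
    if rows.shape[1] != len(indicators):
        raise ValueError(
            f"rows have {rows.shape[1]} columns, expected {len(indicators)}"
        )
    interactions = list(interactions or [])
    idx = {c: i for i, c in enumerate(indicators)}
    alpha = float(coefficients.get("intercept", 0.0))
    if centering is not None:
        for name, m in centering.items():
            if name != "intercept":
                alpha -= float(coefficients[name]) * float(m)
    pred = np.full(len(rows), alpha)
    for name in indicators:
        if name in coefficients.index:
            pred += float(coefficients[name]) * rows[:, idx[name]]
    for a, b in interactions:
        label = interaction_name(a, b)
        pred += float(coefficients[label]) * rows[:, idx[a]] * rows[:, idx[b]]
    return pred


def predict_from_fit(rows: np.ndarray, result: FitResult) -> np.ndarray:
    """Predict using a fit's posterior-mean coefficients and centring record."""
    design: Design = result.design
    coef = result.posterior_mean()
    centering = pd.Series(design.centering, index=design.columns)
    return predict_combination(
        rows, coef, centering=centering, interactions=design.interactions
    )


# ---------------------------------------------------------------------------
# Extremes


@dataclass
class ExtremeProfile:
    n_rows: int
    tail_n: int
    best_md: float
    worst_md: float
    best_rows: pd.DataFrame
    worst_rows: pd.DataFrame
    prevalence_best: pd.Series
    prevalence_worst: pd.Series
    fraction_beneficial: float
    fixed: dict[str, int] = field(default_factory=dict)


def find_extremes(
    coefficients: pd.Series,
    centering: pd.Series | None = None,
    interactions: list[tuple[str, str]] | None = None,
    rules: PlausibilityRules = PlausibilityRules(),
    fixed: dict[str, int] | None = None,
    tail: float = 0.01,
    chunk_size: int = 1 << 16,
) -> ExtremeProfile:
    """Profile the prediction surface over the plausible grid.

    Reports the argmin/argmax rows (all ties), per-indicator prevalence of
    value 1 within the best and worst ``tail`` fractions (tail size
    ceil(tail * N), boundary value inclusive), and the fraction of rows
    predicting a beneficial effect (MD < 0).
    """
    n = count_plausible(rules, fixed)
    preds = np.empty(n, float)
    pos = 0
    for chunk in enumerate_plausible(rules, fixed, chunk_size):
        preds[pos:pos + len(chunk)] = predict_combination(
            chunk, coefficients, centering, interactions, rules.indicators
        )
        pos += len(chunk)

    k = max(1, math.ceil(tail * n))
    lo_cut = np.partition(preds, k - 1)[k - 1]
    hi_cut = np.partition(preds, n - k)[n - k]
    best_md, worst_md = float(preds.min()), float(preds.max())

    ncol = len(rules.indicators)
    sums_lo = np.zeros(ncol)
    sums_hi = np.zeros(ncol)
    n_lo = n_hi = 0
    best_rows, worst_rows = [], []
    pos = 0
    for chunk in enumerate_plausible(rules, fixed, chunk_size):
        p = preds[pos:pos + len(chunk)]
        lo_mask = p <= lo_cut
        hi_mask = p >= hi_cut
        sums_lo += chunk[lo_mask].sum(axis=0)
        sums_hi += chunk[hi_mask].sum(axis=0)
        n_lo += int(lo_mask.sum())
        n_hi += int(hi_mask.sum())
        best_rows.append(chunk[p == best_md])
        worst_rows.append(chunk[p == worst_md])
        pos += len(chunk)

    cols = list(rules.indicators)
    return ExtremeProfile(
        n_rows=n,
        tail_n=k,
        best_md=best_md,
        worst_md=worst_md,
        best_rows=pd.DataFrame(np.vstack(best_rows), columns=cols),
        worst_rows=pd.DataFrame(np.vstack(worst_rows), columns=cols),
        prevalence_best=pd.Series(sums_lo / n_lo, index=cols),
        prevalence_worst=pd.Series(sums_hi / n_hi, index=cols),
        fraction_beneficial=float(np.mean(preds < 0)),
        fixed=dict(fixed or {}),
    )


def extremes_from_fit(
    result: FitResult,
    rules: PlausibilityRules = PlausibilityRules(),
    fixed: dict[str, int] | None = None,
    tail: float = 0.01,
) -> ExtremeProfile:
    design = result.design
    return find_extremes(
        result.posterior_mean(),
        centering=pd.Series(design.centering, index=design.columns),
        interactions=design.interactions,
        rules=rules,
        fixed=fixed,
        tail=tail,
    )


def subgroup_search(
    coefficients: pd.Series,
    subgroup: dict[str, int],
    centering: pd.Series | None = None,
    interactions: list[tuple[str, str]] | None = None,
    rules: PlausibilityRules = PlausibilityRules(),
    tail: float = 0.01,
) -> ExtremeProfile:
    """Extreme profile with subgroup indicators (age group, income status,
    SES, follow-up category) pinned to the given values."""
    return find_extremes(
        coefficients,
        centering=centering,
        interactions=interactions,
        rules=rules,
        fixed=subgroup,
        tail=tail,
    )
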