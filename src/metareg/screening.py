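"""Pre-model reduction of the indicator set.

Two screens are applied to the intervention-level indicator matrix before
modelling: (i) collinearity — pairs with absolute Pearson (phi) correlation
of at least 0.5 are flagged for dropping or merging; (ii) near-constant
agreement — pairs giving identical responses more than 80% of the time are
flagged. Merging combines two indicators into their logical OR under a
combined label. Indicators marked as protected (e.g. deemed important by
stakeholders) are never dropped automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_THRESHOLD = 0.5       # inclusive: |r| >= 0.5 flags
AGREEMENT_THRESHOLD = 0.8  # strict: agreement > 0.8 flags


@dataclass
class ScreeningReport:
    correlations: pd.DataFrame
    agreements: pd.DataFrame
    constant_columns: list[str]
    collinear_pairs: list[tuple[str, str, float]]
    concordant_pairs: list[tuple[str, str, float]]
    #: pair -> action in {'drop:<name>', 'merge', 'keep'}
    actions: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        seen, out = set(), []
        for a, b, _ in self.collinear_pairs + self.concordant_pairs:
            if (a, b) not in seen:
                seen.add((a, b))
                out.append((a, b))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        corr = {(a, b): r for a, b, r in self.collinear_pairs}
        agr = {(a, b): g for a, b, g in self.concordant_pairs}
        for pair in self.flagged_pairs:
            a, b = pair
            rows.append(
                {
                    "indicator_a": a,
                    "indicator_b": b,
                    "correlation": corr.get(pair, self.correlations.loc[a, b]),
                    "agreement": agr.get(pair, self.agreements.loc[a, b]),
                    "flag_collinear": pair in corr,
                    "flag_concordant": pair in agr,
                    "action": self.actions.get(pair, "keep"),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "indicator_a", "indicator_b", "correlation", "agreement",
                "flag_collinear", "flag_concordant", "action",
            ],
        )


def correlation_matrix(indicators: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson (phi) correlations of binary indicator columns.

    Constant columns produce NaN rows/columns (they carry no pairwise
    information and are reported separately by :func:`flag_pairs`); the
    diagonal is 1 for non-constant columns.
    """
    X = indicators.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 arms to correlate indicators")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr, float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=indicators.columns, columns=indicators.columns)


def agreement_matrix(indicators: pd.DataFrame) -> pd.DataFrame:
    """Fraction of arms on which each pair of indicators gives the same response."""
    X = indicators.to_numpy(float)
    n = X.shape[0]
    eq = np.empty((X.shape[1], X.shape[1]))
    for j in range(X.shape[1]):
        eq[j] = (X == X[:, [j]]).mean(axis=0)
    return pd.DataFrame(eq, index=indicators.columns, columns=indicators.columns)


def flag_pairs(
    indicators: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    agreement_threshold: float = AGREEMENT_THRESHOLD,
    protected: set[str] | frozenset[str] = frozenset(),
    actions: dict[tuple[str, str], str] | None = None,
) -> ScreeningReport:
    """Run both screens and assemble the report.

    The collinearity boundary is inclusive (|r| >= r_threshold flags) and the
    agreement boundary strict (> agreement_threshold flags). ``actions`` maps
    a flagged (a, b) pair to 'drop:<name>', 'merge' or 'keep'; unset pairs
    default to 'keep' (report-only) and a drop of a protected indicator is
    rejected.
    """
    cols = list(indicators.columns)
    corr = correlation_matrix(indicators)
    agr = agreement_matrix(indicators)
    constant = [c for c in cols if indicators[c].nunique() <= 1]

    collinear, concordant = [], []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= r_threshold:
                collinear.append((a, b, float(r)))
            g = agr.loc[a, b]
            if g > agreement_threshold:
                concordant.append((a, b, float(g)))

    resolved: dict[tuple[str, str], str] = {}
    flagged = {(a, b) for a, b, _ in collinear} | {(a, b) for a, b, _ in concordant}
    for pair in flagged:
        action = (actions or {}).get(pair, "keep")
        if action.startswith("drop:"):
            victim = action.split(":", 1)[1]
            if victim not in pair:
                raise ValueError(f"drop target {victim!r} not in pair {pair}")
            if victim in protected:
                raise ValueError(f"indicator {victim!r} is protected from dropping")
        elif action not in ("merge", "keep"):
            raise ValueError(f"unknown action {action!r} for pair {pair}")
        resolved[pair] = action

    return ScreeningReport(
        correlations=corr,
        agreements=agr,
        constant_columns=constant,
        collinear_pairs=collinear,
        concordant_pairs=concordant,
        actions=resolved,
    )


def merge_indicators(
    indicators: pd.DataFrame, a: str, b: str, label: str | None = None
) -> pd.DataFrame:
    """Replace indicators a and b by their logical OR under a combined label."""
    label = label or f"{a}_or_{b}"
    merged = (indicators[a].astype(int) | indicators[b].astype(int)).astype(int)
    out = indicators.drop(columns=[a, b])
    out[label] = merged
    return out


def apply_actions(indicators: pd.DataFrame, report: ScreeningReport) -> pd.DataFrame:
    """Apply the report's drop/merge actions to the indicator matrix."""
    out = indicators.copy()
    for (a, b), action in report.actions.items():
        if action == "merge" and a in out.columns and b in out.columns:
            out = merge_indicators(out, a, b)
        elif action.startswith("drop:"):
            victim = action.split(":", 1)[1]
            if victim in out.columns:
                out = out.drop(columns=[victim])
    return out
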