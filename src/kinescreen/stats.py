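"""Per-joint, per-segment two-group comparisons of movement levels.

Workflow: a Shapiro–Wilk screen per group decides whether the movement
distributions can be treated as normal (they typically cannot), and group
differences are then tested with the two-sample Wilcoxon rank-sum
(Mann–Whitney U) test. The groups are independent samples of different
sizes, so the unpaired rank-sum test is the statistically valid default; a
``paired`` escape hatch runs the signed-rank test on equal-length paired
data for completeness.

Significance tiers follow the conventional star notation: ``*`` for
p < 0.05, ``**`` for p < 0.01, ``***`` for p < 0.001, ``ns`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTable
from .skeleton import SEGMENT_LABELS

#: Per-group sample size above which the tie-corrected normal approximation
#: replaces the exact rank-sum distribution.
EXACT_MAX_N = 20


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class NormalityScreen:
    normal: bool | None  # None when screening was skipped
    p_values: tuple[float, ...]
    skipped: bool = False


@dataclass(frozen=True)
class JointComparison:
    joint: int
    segment: str
    median_asd: float
    median_td: float
    statistic: float
    p_value: float
    tier: str
    direction: str  # which group shows higher median movement ("ASD"/"TD"/"none")


def normality_screen(*groups: Sequence[float], alpha: float = 0.05) -> NormalityScreen:
    """Shapiro–Wilk normality screen across groups.

    The data are called non-normal if any group rejects at ``alpha``. Groups
    with fewer than 3 finite values cannot be screened; the result is then
    flagged as skipped with ``normal=None``.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[np.isfinite(g)] for g in cleaned]
    if any(len(g) < 3 for g in cleaned):
        return NormalityScreen(normal=None, p_values=(), skipped=True)
    ps = tuple(float(sps.shapiro(g).pvalue) for g in cleaned)
    return NormalityScreen(normal=all(p >= alpha for p in ps), p_values=ps)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_MAX_N`` untied observations, and the tie-corrected normal
    approximation (without continuity correction in the tied case handled
    by scipy) otherwise. Returns ``(U, p)`` with U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_joint(
    table: FeatureTable,
    joint: int,
    segment: str,
    paired: bool = False,
) -> JointComparison:
    """Compare ASD vs TD movement for one (joint, segment) cell."""
    col = table.values[(joint, segment)]
    is_asd = table.groups.loc[col.index] == "ASD"
    x = col[is_asd].dropna().to_numpy()
    y = col[~is_asd].dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"joint={joint}, segment={segment!r}: a group has no values")
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"joint={joint}, segment={segment!r}: need >= 2 values per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison requires equal group sizes")
        res = sps.wilcoxon(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = rank_sum_test(x, y)
    med_asd, med_td = float(np.median(x)), float(np.median(y))
    if med_asd > med_td:
        direction = "ASD"
    elif med_td > med_asd:
        direction = "TD"
    else:
        direction = "none"
    return JointComparison(
        joint=joint,
        segment=segment,
        median_asd=med_asd,
        median_td=med_td,
        statistic=stat,
        p_value=p,
        tier=significance_tier(p),
        direction=direction,
    )


def compare_all(
    table: FeatureTable,
    fdr: bool = False,
    paired: bool = False,
) -> pd.DataFrame:
    """Run the two-group comparison on every (joint, segment) column.

    No multiple-testing correction is applied by default; ``fdr=True`` adds
    a Benjamini–Hochberg adjusted p-value column (``p_adj``) and re-derives
    the tiers from it.
    """
    rows = [
        compare_joint(table, joint, segment, paired=paired)
        for joint, segment in table.values.columns
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if fdr:
        df["p_adj"] = sps.false_discovery_control(df["p_value"].to_numpy(), method="bh")
        df["tier"] = [significance_tier(p) for p in df["p_adj"]]
    return df


def comparison_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot comparison results into a joint x segment grid of tiers.

    Cells show the tier with a +/- prefix for the direction (``+`` = ASD
    higher), mirroring a significance-annotated summary figure.
    """
    def cell(row: pd.Series) -> str:
        if row["tier"] == "ns":
            return "ns"
        sign = "+" if row["direction"] == "ASD" else "-"
        return sign + row["tier"]

    out = results.assign(cell=results.apply(cell, axis=1)).pivot(
        index="joint", columns="segment", values="cell"
    )
    order = [s for s in SEGMENT_LABELS if s in out.columns]
    return out[order]
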