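"""CAT versus fixed short-form comparison statistics.

Given a calibrated bank and a cohort's responses, this module scores each
fixed scale (EAP on that scale's items only), runs fixed-length CAT at the
matching length, and summarizes the contrast the way item-banking studies
report it: per-arm mean (SD) of the per-person SEs, per-arm marginal
reliability, percent change, a paired t statistic with Cohen's d = t/√n,
cross-arm correlations of the trait estimates, and the mean CAT length
needed to match each fixed scale's achieved accuracy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .engine import PriorGrid, StopRule, run_cat_posthoc, simulate_cohort
from .irt import BankArrays, ItemBank, ResponseMatrix, marginal_reliability

__all__ = [
    "Arm",
    "ComparisonRow",
    "Direction",
    "compare_scale_with_cat",
    "PersonScores",
    "fixed_scale_eval",
    "fixed_length_cat_eval",
    "percent_change",
    "paired_effect",
    "estimate_correlations",
    "equal_accuracy_length",
]


class Direction(str, enum.Enum):
    DECREASE = "DECREASE"
    INCREASE = "INCREASE"


class Arm(str, enum.Enum):
    P_AND_P = "P_AND_P"
    CAT = "CAT"


@dataclass(frozen=True)
class ComparisonRow:
    """One fixed-scale-vs-CAT contrast at a common test length."""

    scale_id: str
    length: int
    pp_mean_se: float
    pp_sd_se: float
    cat_mean_se: float
    cat_sd_se: float
    pp_mr: float
    cat_mr: float
    se_decrease_pct: float
    mr_increase_pct: float
    t_stat: float
    cohens_d: float


@dataclass
class PersonScores:
    """Per-person trait estimates and SEs for one scoring arm."""

    label: str
    theta: NDArray[np.float64]
    se: NDArray[np.float64]
    included: NDArray[np.bool_]

    @property
    def mean_se(self) -> float:
        return float(self.se[self.included].mean())

    @property
    def mr(self) -> float:
        return marginal_reliability(self.se[self.included])

    @property
    def per_person_reliability(self) -> NDArray[np.float64]:
        return 1.0 - self.se**2


def fixed_scale_eval(
    X: ResponseMatrix,
    bank: ItemBank,
    scale_items: list[str],
    grid: PriorGrid | None = None,
    label: str = "",
) -> PersonScores:
    """Score every respondent with a fixed item subset only (EAP).

    Respondents with no observed response on the subset are excluded from
    cohort summaries (their ``included`` flag is False).
    """
    if not scale_items:
        raise ValueError("scale_items must be nonempty")
    sub = bank.subset(scale_items)
    arrays = BankArrays.from_bank(sub)
    grid = grid or PriorGrid.default()
    cols = [X.item_ids.index(i) for i in scale_items]
    codes = X.codes[:, cols]

    from .engine import eap_estimate_batch

    theta, se, _ = eap_estimate_batch(codes, arrays, grid=grid)
    included = np.isfinite(se)
    return PersonScores(label or "+".join(scale_items[:1]) + f"[{len(scale_items)}]",
                        theta, se, included)


def fixed_length_cat_eval(
    X: ResponseMatrix,
    bank: ItemBank,
    L: int,
    grid: PriorGrid | None = None,
    label: str = "",
) -> PersonScores:
    """Score every respondent with a fixed-length adaptive test of L items."""
    if L > len(bank):
        raise ValueError(f"length {L} exceeds bank size {len(bank)}")
    arrays = BankArrays.from_bank(bank)
    grid = grid or PriorGrid.default()
    cols = [X.item_ids.index(i) for i in bank.item_ids]
    codes = X.codes[:, cols]
    rule = StopRule.fixed_length(L)

    n = X.n_respondents
    theta = np.zeros(n)
    se = np.full(n, np.inf)
    included = np.zeros(n, dtype=bool)
    for i in range(n):
        if np.isnan(codes[i]).all():
            continue
        res = run_cat_posthoc(codes[i], bank, rule, grid=grid, arrays=arrays)
        theta[i], se[i] = res.theta_hat, res.se_final
        included[i] = np.isfinite(se[i])
    return PersonScores(label or f"CAT[{L}]", theta, se, included)


def compare_scale_with_cat(
    X: ResponseMatrix,
    bank: ItemBank,
    scale_items: list[str],
    scale_id: str = "",
    grid: PriorGrid | None = None,
) -> ComparisonRow:
    """Score one fixed scale and an equal-length CAT, paired on respondents.

    The paired t and Cohen's d = t/√n are computed on the per-person SE
    differences (fixed minus adaptive), so positive values mean the
    adaptive arm is more precise.
    """
    L = len(scale_items)
    pp = fixed_scale_eval(X, bank, scale_items, grid=grid, label=scale_id)
    cat = fixed_length_cat_eval(X, bank, L, grid=grid)
    ok = pp.included & cat.included
    t, d = paired_effect(pp.se[ok] - cat.se[ok])
    pp_mean, cat_mean = float(pp.se[ok].mean()), float(cat.se[ok].mean())
    pp_mr = marginal_reliability(pp.se[ok])
    cat_mr = marginal_reliability(cat.se[ok])
    return ComparisonRow(
        scale_id=scale_id or pp.label,
        length=L,
        pp_mean_se=pp_mean,
        pp_sd_se=float(pp.se[ok].std(ddof=1)),
        cat_mean_se=cat_mean,
        cat_sd_se=float(cat.se[ok].std(ddof=1)),
        pp_mr=pp_mr,
        cat_mr=cat_mr,
        se_decrease_pct=percent_change(pp_mean, cat_mean, Direction.DECREASE),
        mr_increase_pct=percent_change(pp_mr, cat_mr, Direction.INCREASE),
        t_stat=t,
        cohens_d=d,
    )


def percent_change(before: float, after: float, direction: Direction) -> float:
    """Percent change relative to the 'before' arm, on the 0-100 scale.

    DECREASE reports (before − after)/before × 100 (e.g. error reduction);
    INCREASE reports (after − before)/before × 100 (e.g. reliability gain).
    """
    if before <= 0:
        raise ValueError("'before' must be positive")
    direction = Direction(direction)
    if direction is Direction.DECREASE:
        return (before - after) / before * 100.0
    return (after - before) / before * 100.0


def paired_effect(diffs: ArrayLike) -> tuple[float, float]:
    """Paired t statistic and Cohen's d from per-person paired differences.

    t = mean(d) / (sd(d)/√n) and d = t/√n (the standardized mean
    difference of paired observations). Zero-variance differences give an
    infinite-t signal (d is then 0 when the mean is also 0).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0:
        return (np.inf if mean != 0 else np.nan), (np.inf if mean != 0 else 0.0)
    t = mean / (sd / np.sqrt(n))
    return float(t), float(t / np.sqrt(n))


def estimate_correlations(theta_sets: dict[str, ArrayLike]) -> pd.DataFrame:
    """Means, SDs and pairwise Pearson correlations of named estimate vectors.

    Returns a DataFrame with 'mean' and 'sd' rows followed by the
    correlation matrix (aligned by position; all vectors must have the same
    length ≥ 3).
    """
    lengths = {k: len(np.asarray(v)) for k, v in theta_sets.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"misaligned estimate vectors: {lengths}")
    if next(iter(lengths.values())) < 3:
        raise ValueError("need at least 3 respondents")
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in theta_sets.items()})
    corr = df.corr()
    summary = pd.DataFrame([df.mean(), df.std(ddof=1)], index=["mean", "sd"])
    return pd.concat([summary, corr])


def equal_accuracy_length(
    X: ResponseMatrix,
    bank: ItemBank,
    target_se: float,
    grid: PriorGrid | None = None,
):
    """Mean CAT length needed to reach a fixed scale's achieved accuracy.

    Runs the SE-threshold rule at ``target_se`` (typically the mean SE a
    paper-and-pencil scale attains at full length) and returns the cohort
    simulation result; respondents for whom the bank runs out before the
    target are counted in ``n_exhausted``.
    """
    if target_se <= 0:
        raise ValueError("target_se must be positive")
    return simulate_cohort(X, bank, StopRule.se(target_se), grid=grid)
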