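"""Item-bank screening: unidimensionality, sampling adequacy, weak items, DIF.

The screening pipeline mirrors standard item-banking practice for
patient-reported-outcome style instruments:

1. principal-component loading filter on the pooled item pool (items whose
   loading on the first principal component falls below 0.4 are dropped),
2. unidimensionality diagnostics on the retained items — first/second
   eigenvalue ratio (> 4) and first-factor variance share (> 20%) of the
   Pearson correlation matrix, plus the Kaiser–Meyer–Olkin statistic,
3. after IRT calibration, a discrimination filter (a < 0.8 dropped), and
4. a gender-DIF scan: per item, ordinal (proportional-odds) logistic
   regressions of the response on the trait estimate (M1) versus trait +
   group + trait×group (M3); the item is flagged when the McFadden
   pseudo-R² gain exceeds 0.02.

Correlations are Pearson on the raw integer codes with pairwise-complete
observations; a polychoric option is deliberately out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .calibration import CalibrationResult
from .irt import ResponseMatrix

__all__ = [
    "ScreeningReport",
    "DIFResult",
    "pca_first_loadings",
    "apply_loading_filter",
    "kmo",
    "unidimensionality_check",
    "eigen_summary",
    "apply_discrimination_filter",
    "dif_scan",
]

LOADING_THRESHOLD = 0.4
DISCRIMINATION_THRESHOLD = 0.8
DIF_R2_THRESHOLD = 0.02


@dataclass
class ScreeningReport:
    loadings: dict[str, float] = field(default_factory=dict)
    kmo: float = np.nan
    eigen1: float = np.nan
    eigen2: float = np.nan
    eigen_ratio: float = np.nan
    variance_pct_first: float = np.nan
    dropped_items: dict[str, str] = field(default_factory=dict)  # id -> reason code

    def drop(self, item_id: str, reason: str) -> None:
        assert reason in {"LOW_LOADING", "LOW_DISCRIMINATION", "DIF"}
        self.dropped_items[item_id] = reason


@dataclass
class DIFResult:
    item_id: str
    delta_r2: float
    flagged: bool
    r2_trait_only: float = np.nan
    r2_full: float = np.nan


def _pairwise_corr(X: ResponseMatrix) -> pd.DataFrame:
    df = pd.DataFrame(X.codes, columns=X.item_ids)
    const = df.columns[df.std(skipna=True).fillna(0.0) == 0.0].tolist()
    if const:
        warnings.warn(f"constant items excluded from correlations: {const}", stacklevel=3)
        df = df.drop(columns=const)
    return df.corr(method="pearson")  # pairwise-complete by construction


def pca_first_loadings(X: ResponseMatrix) -> dict[str, float]:
    """Loadings of every item on the first principal component.

    First-eigenvector components of the item Pearson correlation matrix,
    scaled by √λ₁ and oriented so the majority of loadings is positive.
    Constant items have undefined correlations and get a NaN loading (which
    the loading filter then drops).
    """
    if X.n_items < 3:
        raise ValueError("need at least 3 items for PCA screening")
    R = _pairwise_corr(X)
    vals, vecs = np.linalg.eigh(R.to_numpy())
    v1 = vecs[:, -1]
    if (v1 > 0).sum() < (v1 < 0).sum():
        v1 = -v1
    loadings = v1 * np.sqrt(max(vals[-1], 0.0))
    out = dict.fromkeys(X.item_ids, np.nan)
    out.update(dict(zip(R.columns, loadings)))
    return out


def apply_loading_filter(
    loadings: dict[str, float], threshold: float = LOADING_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Partition items into (retained, dropped) at loading < threshold (strict).

    NaN loadings (constant items) are dropped.
    """
    retained, dropped = [], []
    for iid, lo in loadings.items():
        if np.isnan(lo) or lo < threshold:
            dropped.append(iid)
        else:
            retained.append(iid)
    return retained, dropped


def kmo(X: ResponseMatrix | ArrayLike) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σr² / (Σr² + Σq²) over off-diagonal entries, where q are the
    anti-image partial correlations from the inverse correlation matrix.
    A singular correlation matrix is ridge-regularized with a warning.
    """
    if isinstance(X, ResponseMatrix):
        R = _pairwise_corr(X).to_numpy()
    else:
        R = np.asarray(X, dtype=float)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; ridge-regularizing", stacklevel=2)
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(R.shape[0]))
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def eigen_summary(eigen1: float, eigen2: float, n_items: int) -> tuple[float, float]:
    """(first/second eigenvalue ratio, first-factor variance percentage)."""
    return eigen1 / eigen2, eigen1 / n_items * 100.0


@dataclass
class UnidimResult:
    eigen1: float
    eigen2: float
    ratio: float
    variance_pct: float
    eigenvalues: NDArray[np.float64] = field(repr=False, default=None)

    @property
    def passes(self) -> bool:
        return self.ratio > 4.0 and self.variance_pct > 20.0


def unidimensionality_check(X: ResponseMatrix) -> UnidimResult:
    """Eigenvalue-based unidimensionality diagnostics.

    Descending eigenvalues of the item correlation matrix; the pool counts
    as essentially unidimensional when λ₁/λ₂ > 4 and the first factor
    explains > 20% of total variance.
    """
    if X.n_items < 3:
        raise ValueError("need at least 3 items")
    R = _pairwise_corr(X).to_numpy()
    vals = np.sort(np.linalg.eigvalsh(R))[::-1]
    ratio, pct = eigen_summary(vals[0], vals[1], R.shape[0])
    return UnidimResult(
        eigen1=float(vals[0]),
        eigen2=float(vals[1]),
        ratio=float(ratio),
        variance_pct=float(pct),
        eigenvalues=vals,
    )


def apply_discrimination_filter(
    result: CalibrationResult, threshold: float = DISCRIMINATION_THRESHOLD
) -> tuple[list[str], dict[str, float]]:
    """Partition a calibrated bank at discrimination a < threshold (strict).

    Returns (retained ids, {dropped id: its a}).
    """
    retained, dropped = [], {}
    for item in result.bank:
        if item.a < threshold:
            dropped[item.item_id] = item.a
        else:
            retained.append(item.item_id)
    return retained, dropped


# ---------------------------------------------------------------------------
# DIF


def _mcfadden_r2(endog: NDArray, exog: NDArray) -> float:
    """McFadden pseudo-R² of a proportional-odds logistic fit.

    The null log-likelihood is the intercept-only ordinal model, whose MLE
    reproduces the observed category proportions exactly.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    counts = np.bincount(endog.astype(int))
    counts = counts[counts > 0]
    ll_null = float(np.sum(counts * np.log(counts / counts.sum())))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, exog, distr="logit")
        try:
            fit = model.fit(method="lbfgs", maxiter=200, disp=False)
            llf = float(fit.llf)
        except Exception:  # separation or failed line search
            warnings.warn("ordinal fit failed; falling back to bfgs", stacklevel=3)
            fit = model.fit(method="bfgs", maxiter=200, disp=False)
            llf = float(fit.llf)
    if not np.isfinite(llf) or llf < ll_null - 1e-6:
        llf = ll_null  # degenerate fit: report no improvement
    return 1.0 - llf / ll_null


def dif_scan(
    X: ResponseMatrix,
    group: ArrayLike,
    trait: ArrayLike,
    threshold: float = DIF_R2_THRESHOLD,
) -> list[DIFResult]:
    """Logistic-regression DIF scan over every item.

    For each item, compares the trait-only proportional-odds model against
    the model adding group and trait×group (covering uniform and
    non-uniform DIF jointly); the effect size is the McFadden pseudo-R²
    difference, flagged when strictly above ``threshold`` (default 0.02).
    Categories unobserved in the pooled sample are collapsed.
    """
    group = np.asarray(group)
    trait = np.asarray(trait, dtype=float)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"DIF scan needs exactly 2 groups, got {levels.size}")
    g = (group == levels[1]).astype(float)
    if g.sum() == 0 or g.sum() == g.size:
        raise ValueError("both groups must be nonempty")

    results = []
    for j, iid in enumerate(X.item_ids):
        col = X.codes[:, j]
        obs = ~np.isnan(col)
        y = col[obs]
        # collapse to consecutive codes over observed categories
        cats = np.unique(y.astype(int))
        y = np.searchsorted(cats, y.astype(int)).astype(float)
        if cats.size < 2:
            results.append(DIFResult(iid, 0.0, False))
            continue
        th, gr = trait[obs], g[obs]
        exog1 = th[:, None]
        exog3 = np.column_stack([th, gr, th * gr])
        r2_1 = _mcfadden_r2(y, exog1)
        r2_3 = _mcfadden_r2(y, exog3)
        delta = max(r2_3 - r2_1, 0.0)
        results.append(
            DIFResult(iid, delta, bool(delta > threshold), r2_trait_only=r2_1, r2_full=r2_3)
        )
    return results
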