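"""Polytomous item response theory primitives.

Two response models for ordered-category items:

* **GRM** (graded response model): cumulative category probabilities are
  two-parameter logistic functions of the latent trait θ with ordered
  thresholds ``b_1 < ... < b_{m-1}``; category probabilities are adjacent
  differences of the cumulative curves.
* **GPCM** (generalized partial credit model): category probabilities are a
  softmax over cumulative step sums ``Σ_{v≤t} D·a·(θ − δ_v)`` with step
  parameters δ that need not be ordered.

On top of the response functions the module provides Fisher item/test
information, the information-based standard error SE(θ) = 1/√ΣI(θ), the
cohort marginal reliability MR = 1 − (mean SE)², and response-pattern
log-likelihoods — the quantities every later stage (calibration, adaptive
testing, evaluation) is built from.

Internally category codes run 0..m−1; file I/O shifts 1-based Likert codes
on read (see :mod:`catlab.io`). The logistic scaling constant ``D`` defaults
to 1.0 (logistic metric) and may be set to 1.7 for the normal-ogive metric.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


class Model(str, enum.Enum):
    """Polytomous response-model family."""

    GRM = "GRM"
    GPCM = "GPCM"


class CategoryIndexError(IndexError):
    """Raised when a cumulative-category index is outside 1..m-1."""


class InvalidItemError(ValueError):
    """Raised when item parameters violate model constraints."""


@dataclass(frozen=True)
class ItemParams:
    """Parameters of one polytomous item.

    Parameters
    ----------
    item_id : str
        Unique identifier within a bank.
    scale_id : str
        Source instrument the item belongs to.
    model : Model
        Response-model family (GRM or GPCM).
    m : int
        Number of ordered response categories; scores run 0..m-1.
    a : float
        Discrimination (slope); must be positive.
    thresholds : tuple of float
        m-1 location parameters: ordered difficulties b_t for the GRM,
        step parameters delta_v for the GPCM.
    D : float
        Logistic scaling constant (1.0 logistic metric, 1.7 normal-ogive).
    """

    item_id: str
    scale_id: str
    model: Model
    m: int
    a: float
    thresholds: tuple[float, ...]
    D: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        if self.m < 2:
            raise InvalidItemError(f"{self.item_id}: need m >= 2 categories, got {self.m}")
        if len(self.thresholds) != self.m - 1:
            raise InvalidItemError(
                f"{self.item_id}: expected {self.m - 1} thresholds, got {len(self.thresholds)}"
            )
        if not self.a > 0:
            raise InvalidItemError(f"{self.item_id}: discrimination must be > 0, got {self.a}")
        if not self.D > 0:
            raise InvalidItemError(f"{self.item_id}: D must be > 0, got {self.D}")
        if self.model is Model.GRM and np.any(np.diff(self.thresholds) < 0):
            raise InvalidItemError(
                f"{self.item_id}: GRM thresholds must be nondecreasing, got {self.thresholds}"
            )


@dataclass
class ItemBank:
    """Ordered collection of items with unique ids."""

    items: list[ItemParams]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("item bank must be nonempty")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, key: int | str) -> ItemParams:
        if isinstance(key, str):
            return self.items[self.index(key)]
        return self.items[key]

    def index(self, item_id: str) -> int:
        for i, it in enumerate(self.items):
            if it.item_id == item_id:
                return i
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def max_m(self) -> int:
        return max(it.m for it in self.items)

    def subset(self, item_ids) -> "ItemBank":
        return ItemBank([self[i] for i in item_ids], provenance=self.provenance)


@dataclass
class ResponseMatrix:
    """Respondent × item ordinal codes, NaN marking missing answers.

    Codes are 0-based: valid entries for item j lie in 0..m_j-1.
    """

    respondent_ids: list[str]
    item_ids: list[str]
    codes: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.respondent_ids), len(self.item_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.respondent_ids)} respondents x {len(self.item_ids)} items"
            )

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def missing_mask(self) -> NDArray[np.bool_]:
        return np.isnan(self.codes)

    def validate_against(self, bank: ItemBank) -> None:
        """Check every observed code is within its item's category range."""
        for j, iid in enumerate(self.item_ids):
            item = bank[iid]
            col = self.codes[:, j]
            obs = col[~np.isnan(col)]
            if obs.size and (obs.min() < 0 or obs.max() > item.m - 1):
                raise ValueError(
                    f"item {iid}: observed codes outside 0..{item.m - 1}"
                )

    def column(self, item_id: str) -> NDArray[np.float64]:
        return self.codes[:, self.item_ids.index(item_id)]


# ---------------------------------------------------------------------------
# response functions


def grm_cumulative(theta: float, item: ItemParams, t: int) -> float:
    """P(X >= t | theta) for a GRM item; t in 1..m-1 (P(X>=0)=1, P(X>=m)=0)."""
    if item.model is not Model.GRM:
        raise InvalidItemError(f"{item.item_id}: grm_cumulative requires a GRM item")
    if not 1 <= t <= item.m - 1:
        raise CategoryIndexError(f"category index t={t} outside 1..{item.m - 1}")
    z = item.D * item.a * (theta - item.thresholds[t - 1])
    return float(_expit(z))


def _expit(z):
    # scipy.special.expit without the import cost at call sites
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _grm_cumulative_all(theta: ArrayLike, item: ItemParams) -> NDArray[np.float64]:
    """Cumulative curves incl. the P(X>=0)=1 and P(X>=m)=0 boundaries.

    Returns shape (..., m+1): index t holds P(X>=t).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.thresholds)
    z = item.D * item.a * (theta[:, None] - b)
    inner = _expit(z)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    return np.concatenate([ones, inner, zeros], axis=-1)


def grm_category_probs(theta: ArrayLike, item: ItemParams) -> NDArray[np.float64]:
    """Category probabilities P(X = t | theta) for t = 0..m-1 under the GRM."""
    scalar = np.ndim(theta) == 0
    cum = _grm_cumulative_all(theta, item)
    probs = cum[..., :-1] - cum[..., 1:]
    if np.any(probs < -1e-12):
        raise InvalidItemError(
            f"{item.item_id}: negative category probability (non-monotone thresholds?)"
        )
    out = np.clip(probs, 0.0, 1.0)
    return out[0] if scalar else out


def gpcm_category_probs(theta: ArrayLike, item: ItemParams) -> NDArray[np.float64]:
    """Category probabilities under the GPCM (softmax over cumulative steps).

    Uses the delta_0 = 0 convention (the t = 0 exponent is 0) and log-sum-exp
    normalization, stable for step arguments up to about +/-700.
    """
    if item.model is not Model.GPCM:
        raise InvalidItemError(f"{item.item_id}: gpcm_category_probs requires a GPCM item")
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    d = np.asarray(item.thresholds)
    steps = item.D * item.a * (theta[:, None] - d)  # (n, m-1)
    exps = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    exps -= exps.max(axis=1, keepdims=True)  # log-sum-exp shift
    w = np.exp(exps)
    probs = w / w.sum(axis=1, keepdims=True)
    return probs[0] if scalar else probs


def category_probs(theta: ArrayLike, item: ItemParams) -> NDArray[np.float64]:
    """Dispatch to the item's model family."""
    if item.model is Model.GRM:
        return grm_category_probs(theta, item)
    return gpcm_category_probs(theta, item)


# ---------------------------------------------------------------------------
# information / standard error / reliability


def item_information(theta: ArrayLike, item: ItemParams) -> float | NDArray[np.float64]:
    """Fisher information of one item at theta: sum_t (dP_t/dtheta)^2 / P_t.

    Closed forms: for the GRM the category derivative is the difference of
    cumulative-curve derivatives D·a·P*(1−P*); for the GPCM the information
    is D²a²·Var(T | theta) with T the category score.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if item.model is Model.GRM:
        cum = _grm_cumulative_all(theta, item)  # (n, m+1)
        dcum = item.D * item.a * cum * (1.0 - cum)
        probs = cum[:, :-1] - cum[:, 1:]
        dprob = dcum[:, :-1] - dcum[:, 1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 1e-300, dprob**2 / np.maximum(probs, 1e-300), 0.0)
        info = terms.sum(axis=1)
    else:
        probs = gpcm_category_probs(theta, item)
        t = np.arange(item.m)
        mean_t = probs @ t
        var_t = probs @ (t**2) - mean_t**2
        info = (item.D * item.a) ** 2 * var_t
    info = np.maximum(info, 0.0)
    return float(info[0]) if scalar else info


def test_information(theta: ArrayLike, items) -> float | NDArray[np.float64]:
    """Test information: the sum of item informations over a nonempty item set."""
    items = list(items)
    if not items:
        raise ValueError("test_information requires a nonempty item set")
    return sum(item_information(theta, it) for it in items)


def standard_error(theta: ArrayLike, items) -> float | NDArray[np.float64]:
    """SE(theta) = 1/sqrt(test information); inf where information is zero."""
    info = np.asarray(test_information(theta, items), dtype=float)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
    return float(se) if se.ndim == 0 else se


def se_from_information(info: float) -> float:
    """Reciprocal square root of test information, inf at zero information."""
    return 1.0 / np.sqrt(info) if info > 0 else np.inf


def marginal_reliability(se_values: ArrayLike) -> float:
    """Marginal reliability MR = 1 − (mean SE)² over a cohort of final SEs."""
    se = np.asarray(se_values, dtype=float)
    if se.size == 0:
        raise ValueError("marginal_reliability requires at least one SE value")
    return float(1.0 - np.mean(se) ** 2)


def response_loglik(pattern: ArrayLike, theta: float, items) -> float:
    """Log-likelihood of one response pattern at theta; missing (NaN) skipped."""
    pattern = np.asarray(pattern, dtype=float)
    items = list(items)
    if pattern.shape != (len(items),):
        raise ValueError("pattern length must match number of items")
    observed = ~np.isnan(pattern)
    if not observed.any():
        warnings.warn("all-missing response pattern: log-likelihood is 0", stacklevel=2)
        return 0.0
    ll = 0.0
    for x, item in zip(pattern[observed], (it for it, o in zip(items, observed) if o)):
        p = category_probs(theta, item)[int(x)]
        ll += np.log(max(p, 1e-300))
    return float(ll)


# ---------------------------------------------------------------------------
# vectorized bank-level evaluation (used by calibration and the CAT engine)


@dataclass
class BankArrays:
    """Padded parameter arrays for vectorized whole-bank computations."""

    a: NDArray[np.float64]  # (J,)
    D: NDArray[np.float64]  # (J,)
    thresholds: NDArray[np.float64]  # (J, max_m-1), NaN-padded
    m: NDArray[np.int_]  # (J,)
    is_grm: NDArray[np.bool_]  # (J,)
    item_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_bank(cls, bank: ItemBank) -> "BankArrays":
        J = len(bank)
        maxm = bank.max_m
        thr = np.full((J, maxm - 1), np.nan)
        for j, it in enumerate(bank):
            thr[j, : it.m - 1] = it.thresholds
        return cls(
            a=np.array([it.a for it in bank]),
            D=np.array([it.D for it in bank]),
            thresholds=thr,
            m=np.array([it.m for it in bank]),
            is_grm=np.array([it.model is Model.GRM for it in bank]),
            item_ids=bank.item_ids,
        )


def bank_category_probs(thetas: ArrayLike, arrays: BankArrays) -> NDArray[np.float64]:
    """Category probabilities for every item at every theta.

    Returns shape (K, J, max_m); entries beyond an item's m are 0.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    K, J = thetas.size, arrays.a.size
    maxm = arrays.thresholds.shape[1] + 1
    out = np.zeros((K, J, maxm))

    cat = np.arange(maxm)
    valid = cat[None, :] < arrays.m[:, None]  # (J, maxm)

    if arrays.is_grm.any():
        jg = np.where(arrays.is_grm)[0]
        b = arrays.thresholds[jg]  # (Jg, maxm-1)
        z = arrays.D[jg, None] * arrays.a[jg, None] * (thetas[:, None, None] - b)
        cum_inner = np.where(np.isnan(b), 0.0, _expit(np.nan_to_num(z)))
        cum = np.concatenate(
            [np.ones((K, jg.size, 1)), cum_inner, np.zeros((K, jg.size, 1))], axis=2
        )
        probs = np.clip(cum[:, :, :-1] - cum[:, :, 1:], 0.0, 1.0)
        # collapse the padded tail: P(X >= t)=0 there already, diffs are 0
        out[:, jg, :] = probs * valid[jg][None, :, :]

    if (~arrays.is_grm).any():
        jp = np.where(~arrays.is_grm)[0]
        d = arrays.thresholds[jp]
        steps = arrays.D[jp, None] * arrays.a[jp, None] * (thetas[:, None, None] - d)
        steps = np.where(np.isnan(d), -np.inf, steps)  # padded steps unreachable
        exps = np.concatenate(
            [np.zeros((K, jp.size, 1)), np.cumsum(np.nan_to_num(steps, neginf=0.0), axis=2)],
            axis=2,
        )
        exps = np.where(valid[jp][None, :, :], exps, -np.inf)
        exps -= exps.max(axis=2, keepdims=True)
        w = np.exp(exps)
        out[:, jp, :] = w / w.sum(axis=2, keepdims=True)

    return out


def bank_information(thetas: ArrayLike, arrays: BankArrays) -> NDArray[np.float64]:
    """Fisher information of every item at every theta; shape (K, J)."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    K, J = thetas.size, arrays.a.size
    info = np.zeros((K, J))

    if arrays.is_grm.any():
        jg = np.where(arrays.is_grm)[0]
        b = arrays.thresholds[jg]
        z = arrays.D[jg, None] * arrays.a[jg, None] * (thetas[:, None, None] - b)
        cum_inner = np.where(np.isnan(b), 0.0, _expit(np.nan_to_num(z)))
        cum = np.concatenate(
            [np.ones((K, jg.size, 1)), cum_inner, np.zeros((K, jg.size, 1))], axis=2
        )
        da = (arrays.D[jg] * arrays.a[jg])[None, :, None]
        dcum = da * cum * (1.0 - cum)
        probs = cum[:, :, :-1] - cum[:, :, 1:]
        dprob = dcum[:, :, :-1] - dcum[:, :, 1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 1e-300, dprob**2 / np.maximum(probs, 1e-300), 0.0)
        info[:, jg] = terms.sum(axis=2)

    if (~arrays.is_grm).any():
        jp = np.where(~arrays.is_grm)[0]
        probs = bank_category_probs(thetas, arrays)[:, jp, :]
        maxm = probs.shape[2]
        t = np.arange(maxm)
        mean_t = probs @ t
        var_t = probs @ (t**2) - mean_t**2
        info[:, jp] = (arrays.D[jp] * arrays.a[jp])[None, :] ** 2 * np.maximum(var_t, 0.0)

    return info


def pattern_log_likelihood(
    codes: NDArray[np.float64], log_probs: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Log-likelihood of each respondent's pattern at each grid node.

    Parameters
    ----------
    codes : (N, J) float array, NaN = missing.
    log_probs : (K, J, max_m) log category probabilities on the grid.

    Returns
    -------
    (N, K) array of log-likelihoods.
    """
    N, J = codes.shape
    K = log_probs.shape[0]
    ll = np.zeros((N, K))
    obs = ~np.isnan(codes)
    x = np.nan_to_num(codes).astype(int)
    for j in range(J):
        rows = obs[:, j]
        if rows.any():
            ll[rows] += log_probs[:, j, x[rows, j]].T
    return ll
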