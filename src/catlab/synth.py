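"""Synthetic item banks, traits and response matrices.

The generator emulates the statistical structure of a pooled
problematic-mobile-phone-use item pool: seven source scales with Likert
category counts (16 items × 7, 10 × 4, 20 × 4, 11 × 5, 16 × 5, 11 × 5,
14 × 5 — 98 items in all), discriminations from a truncated normal with
mean 1.26 and SD 0.31 on [0.87, 2.36], ordered thresholds spanning roughly
[−2.4, 3.6], and a standard-normal latent trait. Optional plans plant
group-shifted items (DIF ground truth) and weak, nearly trait-unrelated
items (loading-filter ground truth), so every screening and CAT stage can
be tested end to end without external data.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; the same seed reproduces the same bank/cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from scipy.stats import truncnorm

from .irt import ItemBank, ItemParams, Model, ResponseMatrix, category_probs

__all__ = ["SynthSpec", "generate_bank", "generate_thetas", "simulate_responses",
           "inject_dif", "simulate_two_group_responses", "DEFAULT_LAYOUT"]

# (scale id, number of items, Likert categories) of the seven pooled scales
DEFAULT_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("NMP", 16, 7),
    ("SAPS", 10, 4),
    ("SPAI", 20, 4),
    ("MPAS", 11, 5),
    ("MPATS", 16, 5),
    ("SASC", 11, 5),
    ("SASCA", 14, 5),
)

MIN_THRESHOLD_GAP = 0.2


@dataclass(frozen=True)
class SynthSpec:
    """Generating conditions for a synthetic item pool and cohort."""

    scale_layout: tuple[tuple[str, int, int], ...] = DEFAULT_LAYOUT
    model: Model = Model.GRM
    a_range: tuple[float, float] = (0.87, 2.36)
    a_mean_sd: tuple[float, float] = (1.26, 0.31)
    threshold_span: tuple[float, float] = (-2.4, 3.6)
    n_respondents: int = 885
    theta_mean_sd: tuple[float, float] = (0.0, 1.0)
    dif_plan: tuple[tuple[str, float], ...] = ()  # (item id, threshold shift)
    weak_item_plan: tuple[str, ...] = ()  # items made nearly trait-unrelated
    D: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.threshold_span
        max_cats = max(m for _, _, m in self.scale_layout)
        if hi - lo < (max_cats - 2) * MIN_THRESHOLD_GAP:
            raise ValueError("threshold span too narrow for the category layout")
        if self.a_range[0] >= self.a_range[1]:
            raise ValueError("invalid discrimination range")


def _draw_thresholds(rng: np.random.Generator, k: int, lo: float, hi: float) -> NDArray:
    """k sorted thresholds in [lo, hi] with gaps >= MIN_THRESHOLD_GAP."""
    for _ in range(1000):
        t = np.sort(rng.uniform(lo, hi, size=k))
        if k < 2 or np.diff(t).min() >= MIN_THRESHOLD_GAP:
            return t
    # pathological span: fall back to jittered equal spacing
    base = np.linspace(lo, hi, k + 2)[1:-1]
    return base + rng.uniform(-0.05, 0.05, size=k)


def generate_bank(spec: SynthSpec) -> ItemBank:
    """Draw an item bank matching the spec's parameter envelope."""
    rng = np.random.default_rng(spec.seed)
    mu, sd = spec.a_mean_sd
    lo, hi = spec.a_range
    a_dist = truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)

    items = []
    for scale_id, n_items, m in spec.scale_layout:
        for i in range(1, n_items + 1):
            iid = f"{scale_id}_{i}"
            a = float(a_dist.ppf(rng.uniform()))
            if iid in spec.weak_item_plan:
                a = float(rng.uniform(0.05, 0.15))  # nearly flat response curves
            thr = _draw_thresholds(rng, m - 1, *spec.threshold_span)
            items.append(
                ItemParams(iid, scale_id, spec.model, m, a, tuple(thr), D=spec.D)
            )
    return ItemBank(items, provenance=f"synthetic seed={spec.seed}")


def generate_thetas(n: int, spec: SynthSpec, seed: int | None = None) -> NDArray:
    """n latent-trait draws from the cohort prior (normal, default N(0,1))."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    mu, sd = spec.theta_mean_sd
    return rng.normal(mu, sd, size=n)


def simulate_responses(
    bank: ItemBank,
    thetas: NDArray,
    seed: int = 0,
    respondent_prefix: str = "R",
) -> ResponseMatrix:
    """Draw one ordinal response per person-item from the model probabilities."""
    rng = np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    codes = np.empty((n, len(bank)))
    for j, item in enumerate(bank):
        probs = category_probs(thetas, item)  # (n, m)
        u = rng.uniform(size=n)
        codes[:, j] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return ResponseMatrix(
        respondent_ids=[f"{respondent_prefix}{i + 1:04d}" for i in range(n)],
        item_ids=bank.item_ids,
        codes=codes,
    )


def inject_dif(
    bank: ItemBank,
    plan: dict[str, float] | tuple[tuple[str, float], ...],
    a_multiplier: dict[str, float] | None = None,
) -> tuple[ItemBank, ItemBank]:
    """Group-specific bank pair with planted DIF.

    Group A keeps the bank as-is; group B's copies of the planned items get
    all thresholds shifted by the stated amount (uniform DIF) and/or the
    discrimination multiplied (non-uniform DIF).
    """
    plan = dict(plan)
    a_multiplier = a_multiplier or {}
    missing = (set(plan) | set(a_multiplier)) - set(bank.item_ids)
    if missing:
        raise KeyError(f"items not in bank: {sorted(missing)}")
    items_b = []
    for item in bank:
        shift = plan.get(item.item_id, 0.0)
        mult = a_multiplier.get(item.item_id, 1.0)
        if shift or mult != 1.0:
            items_b.append(
                replace(
                    item,
                    thresholds=tuple(b + shift for b in item.thresholds),
                    a=item.a * mult,
                )
            )
        else:
            items_b.append(item)
    return bank, ItemBank(items_b, provenance=bank.provenance + " +DIF")


def simulate_two_group_responses(
    bank_a: ItemBank,
    bank_b: ItemBank,
    thetas: NDArray,
    group: NDArray,
    seed: int = 0,
) -> ResponseMatrix:
    """Responses where group-B members answer under the shifted bank."""
    group = np.asarray(group).astype(bool)
    ra = simulate_responses(bank_a, np.asarray(thetas), seed=seed)
    rb = simulate_responses(bank_b, np.asarray(thetas), seed=seed + 1)
    codes = np.where(group[:, None], rb.codes, ra.codes)
    return ResponseMatrix(ra.respondent_ids, ra.item_ids, codes)
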