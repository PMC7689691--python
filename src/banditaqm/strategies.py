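"""Batched allocation policies: equal allocation (EA), deterministic
probability matching (DPM) and randomized probability matching (RPM,
i.e. batched Thompson sampling).

Each policy maps the current per-treatment success probabilities to a plan
— a per-treatment count of installations to allocate this decision — whose
counts are nonnegative and sum exactly to the batch size.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Policy names accepted in configuration.
STRATEGIES = ("ea", "dpm", "rpm")

AllocationPlan = dict[str, int]


def _check_batch(batch: int) -> None:
    if batch < 0:
        raise ValidationError("batch must be >= 0")


def _check_simplex(probs: Mapping[str, float]) -> list[str]:
    if not probs:
        raise ValidationError("empty probability vector")
    labels = sorted(probs)
    p = np.array([probs[t] for t in labels], dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("success probabilities must form a simplex")
    return labels


def allocate_equal(
    treatments: Sequence[str], batch: int, rng: np.random.Generator
) -> AllocationPlan:
    """Balanced split: floor(batch/k) everywhere, remainder to random arms.

    With 3 treatments and a batch of 10 this yields a permutation of
    (4, 3, 3), the extra unit landing on one uniformly chosen treatment.
    """
    if len(treatments) < 1:
        raise ValidationError("need at least one treatment")
    _check_batch(batch)
    labels = sorted(treatments)
    k = len(labels)
    plan = {t: batch // k for t in labels}
    extras = rng.choice(k, size=batch % k, replace=False)
    for idx in extras:
        plan[labels[idx]] += 1
    return plan


def allocate_deterministic(
    probs: Mapping[str, float], batch: int, rng: np.random.Generator
) -> AllocationPlan:
    """Greedy: the whole batch goes to the most probably best treatment.

    Exact ties for the maximum are broken uniformly at random (seeded), so
    symmetric starting information yields a reproducible choice.
    """
    _check_batch(batch)
    labels = _check_simplex(probs)
    pmax = max(probs[t] for t in labels)
    tied = [t for t in labels if probs[t] == pmax]
    winner = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return {t: (batch if t == winner else 0) for t in labels}


def allocate_randomized(
    probs: Mapping[str, float], batch: int, rng: np.random.Generator
) -> AllocationPlan:
    """Thompson-style: one multinomial draw with cell probabilities ``probs``.

    Sampling (rather than rounding batch*p) preserves the occasional
    allocation to low-probability treatments that gives the policy its
    exploratory character.
    """
    _check_batch(batch)
    labels = _check_simplex(probs)
    p = np.clip(np.array([probs[t] for t in labels], dtype=float), 0.0, None)
    counts = rng.multinomial(batch, p / p.sum())
    return {t: int(c) for t, c in zip(labels, counts)}


def allocate(
    strategy: str,
    probs: Mapping[str, float],
    batch: int,
    rng: np.random.Generator,
) -> AllocationPlan:
    """Dispatch on a strategy name from :data:`STRATEGIES`."""
    if strategy == "ea":
        return allocate_equal(sorted(probs), batch, rng)
    if strategy == "dpm":
        return allocate_deterministic(probs, batch, rng)
    if strategy == "rpm":
        return allocate_randomized(probs, batch, rng)
    raise ValidationError(f"unknown strategy {strategy!r}; valid: {STRATEGIES}")
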