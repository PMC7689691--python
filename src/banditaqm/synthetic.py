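"""Seeded synthetic treatment pools with the case study's structure.

The Barnstable County monitoring database behind the case study is not
publicly deposited, so the generator recreates its statistical skeleton:
three treatment pools of roughly 220, 152 and 597 installations whose
long-run mean N effluent concentrations are 12.7, 23 and 18.2 mg/L, and a
nonstationary variant in which Treatment A's first 33 installations average
about 22 mg/L and the remaining 187 about 11 mg/L.

Performances are drawn i.i.d. log-normal, parameterised by the
natural-scale mean ``m`` and coefficient of variation ``cv`` through the
moment identities ``m = exp(mu + sigma^2/2)`` and
``cv^2 = exp(sigma^2) - 1``.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CHRONOLOGICAL, SHUFFLED, TreatmentPool
from .errors import ConfigError

#: Pool sizes of the three treatment technologies in the case study.
DEFAULT_POOL_SIZES = {"A": 220, "B": 152, "C": 597}
#: Long-run mean N effluent concentration (mg/L) per treatment.
DEFAULT_MEANS = {"A": 12.7, "B": 23.0, "C": 18.2}
#: Default coefficient of variation of installation performances.
DEFAULT_CV = 0.25
#: Treatment A's recorded change point: early segment size and segment means.
DEFAULT_CHANGE_POINT = {"n_early": 33, "early_mean": 22.0, "late_mean": 11.0}


@dataclass(frozen=True)
class ChangePoint:
    """Abrupt two-segment nonstationarity in a treatment's pool order."""

    n_early: int
    early_mean: float
    late_mean: float


@dataclass(frozen=True)
class TreatmentSpec:
    pool_size: int
    target_mean: float
    cv: float = DEFAULT_CV
    change_point: ChangePoint | None = None

    def validate(self, label: str) -> list[str]:
        problems = []
        if self.pool_size < 1:
            problems.append(f"{label}: pool_size must be >= 1")
        if not (self.target_mean > 0 and math.isfinite(self.target_mean)):
            problems.append(f"{label}: target_mean must be a positive finite mg/L value")
        if not (self.cv >= 0 and math.isfinite(self.cv)):
            problems.append(f"{label}: cv must be finite and >= 0")
        cp = self.change_point
        if cp is not None:
            if not 0 < cp.n_early < self.pool_size:
                problems.append(f"{label}: change_point.n_early must lie in (0, pool_size)")
            if cp.early_mean <= 0 or cp.late_mean <= 0:
                problems.append(f"{label}: change_point segment means must be > 0")
        return problems


@dataclass(frozen=True)
class GeneratorConfig:
    """Per-treatment generator settings plus the global seed."""

    treatments: Mapping[str, TreatmentSpec]
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.treatments:
            problems.append("at least one treatment must be configured")
        for label, spec in self.treatments.items():
            problems.extend(spec.validate(label))
        if problems:
            raise ConfigError(problems)

    @property
    def best_treatment(self) -> str:
        """Label with the minimum long-run mean (the true best arm)."""
        return min(self.treatments, key=lambda t: self.treatments[t].target_mean)


def default_generator_config(seed: int = 0, cv: float = DEFAULT_CV) -> GeneratorConfig:
    """The case-study configuration (sizes 220/152/597, means 12.7/23/18.2,
    Treatment A change point 33 @ 22 mg/L then 187 @ 11 mg/L)."""
    treatments = {}
    for label in ("A", "B", "C"):
        cp = None
        if label == "A":
            cp = ChangePoint(**DEFAULT_CHANGE_POINT)
        treatments[label] = TreatmentSpec(
            pool_size=DEFAULT_POOL_SIZES[label],
            target_mean=DEFAULT_MEANS[label],
            cv=cv,
            change_point=cp,
        )
    return GeneratorConfig(treatments=treatments, seed=seed)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching a natural-scale mean and CV."""
    try:
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
    except ValueError as exc:
        raise ConfigError(f"mean={mean}, cv={cv}: {exc}") from exc
    if not (math.isfinite(mu) and math.isfinite(sigma2)):
        raise ConfigError(f"mean={mean}, cv={cv} yield nonfinite log-normal parameters")
    return mu, math.sqrt(sigma2)


def _draw_segment(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean, dtype=float)
    mu, sigma = lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size=n)


def _treatment_rngs(config: GeneratorConfig, seed: int | None):
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    labels = sorted(config.treatments)
    children = root.spawn(len(labels))
    return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def generate_stationary(
    config: GeneratorConfig, seed: int | None = None
) -> dict[str, TreatmentPool]:
    """I.i.d. pools at each treatment's long-run mean, in shuffled mode.

    Change-point entries are ignored here: the stationary data set is by
    construction order-free, and each long-run ``target_mean`` already
    pools any segments (e.g. Treatment A's (33*22 + 187*11)/220 = 12.65
    ~ 12.7 mg/L).
    """
    config.validate()
    rngs = _treatment_rngs(config, seed)
    pools = {}
    for label in sorted(config.treatments):
        spec = config.treatments[label]
        values = _draw_segment(rngs[label], spec.pool_size, spec.target_mean, spec.cv)
        pools[label] = TreatmentPool(label, values, mode=SHUFFLED)
    return pools


def generate_nonstationary(
    config: GeneratorConfig, seed: int | None = None
) -> dict[str, TreatmentPool]:
    """Chronological pools; change-point treatments switch segment means.

    A treatment with a change point emits ``n_early`` values at
    ``early_mean`` followed by ``pool_size - n_early`` values at
    ``late_mean``, in that order.  Treatments without a change point are
    i.i.d. as in :func:`generate_stationary` but delivered in generation
    (chronological) order.
    """
    config.validate()
    if not any(s.change_point for s in config.treatments.values()):
        raise ConfigError("nonstationary generation needs at least one change_point")
    rngs = _treatment_rngs(config, seed)
    pools = {}
    for label in sorted(config.treatments):
        spec = config.treatments[label]
        rng = rngs[label]
        cp = spec.change_point
        if cp is None:
            values = _draw_segment(rng, spec.pool_size, spec.target_mean, spec.cv)
        else:
            early = _draw_segment(rng, cp.n_early, cp.early_mean, spec.cv)
            late = _draw_segment(rng, spec.pool_size - cp.n_early, cp.late_mean, spec.cv)
            values = np.concatenate([early, late])
        pools[label] = TreatmentPool(label, values, mode=CHRONOLOGICAL)
    return pools


def pools_to_frame(pools: Mapping[str, TreatmentPool]) -> pd.DataFrame:
    """Tabulate pools in the monitoring-CSV schema (one row per installation).

    Synthetic record dates encode generation order (one day apart) so a
    chronological re-load reproduces the pool order exactly.
    """
    base = _dt.date(2000, 1, 1)
    rows = []
    for label in sorted(pools):
        pool = pools[label]
        for i, value in enumerate(pool.performances):
            rows.append(
                {
                    "installation_id": f"{label}-{i:04d}",
                    "treatment_id": label,
                    "record_date": (base + _dt.timedelta(days=i)).isoformat(),
                    "n_effluent_mg_l": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["installation_id", "treatment_id",
                                       "record_date", "n_effluent_mg_l"])


def write_pools_csv(pools: Mapping[str, TreatmentPool], path) -> None:
    pools_to_frame(pools).to_csv(path, index=False)
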