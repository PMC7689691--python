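"""Sequential bandit experiments and the sensitivity/replicate grid.

One experiment: seed each treatment's posterior with a few starting
installations, then for each of ``n_decisions`` decisions allocate a batch
of installations with the chosen policy, consume them from the treatment
pools, refit all posteriors from scratch on the accumulated data, and
record the success probabilities and cumulative performance.

The sensitivity grid crosses dataset modes x strategies x starting-value
permutations x replicates (default 2 x 3 x 6 x 5 = 180 experiments) with
deterministic per-coordinate seeds, so results are independent of
execution order and of the number of worker processes.
"""

from __future__ import annotations

import itertools
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SHUFFLED, TreatmentPool
from .errors import ValidationError
from .posterior import (
    McmcSettings,
    PriorSpec,
    fit_posteriors,
    success_probabilities,
)
from .strategies import STRATEGIES, allocate

log = logging.getLogger(__name__)

#: Dataset modes of the sensitivity grid.
MODES = ("stationary", "nonstationary")
#: Starting-value multiset whose 3! permutations form the default grid axis.
DEFAULT_STARTING_SET = (1, 3, 17)
#: R-hat above this threshold raises a nonconvergence warning record.
DEFAULT_RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for one sequential experiment."""

    starting_values: Mapping[str, int]
    strategy: str = "rpm"
    dataset_mode: str = "stationary"
    n_decisions: int = 20
    batch: int = 10
    seed: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    compare_on: str = "natural_mean"
    include_starts_in_metrics: bool = True
    rhat_threshold: float = DEFAULT_RHAT_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_decisions < 1:
            raise ValidationError("n_decisions must be >= 1")
        if self.batch < 1:
            raise ValidationError("batch must be >= 1")
        if not self.starting_values or any(
            v < 1 for v in self.starting_values.values()
        ):
            raise ValidationError("starting_values must all be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; valid: {STRATEGIES}"
            )
        if self.dataset_mode not in MODES:
            raise ValidationError(f"dataset_mode must be one of {MODES}")


@dataclass
class DecisionRecord:
    """State after one decision (index 0 is the initialization step)."""

    decision_index: int
    allocation: dict[str, int]
    sampled_values: dict[str, np.ndarray]
    success_probs: dict[str, float]
    cumulative_total: float
    cumulative_mean: float
    n_consumed: int
    rhat: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: list[DecisionRecord]
    total_sum: float
    final_success_probs: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    coordinates: dict = field(default_factory=dict)

    @property
    def n_allocated(self) -> int:
        return sum(
            sum(r.allocation.values()) for r in self.records if r.decision_index > 0
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per decision x treatment."""
        rows = []
        for rec in self.records:
            for t in sorted(rec.success_probs):
                rows.append(
                    {
                        **self.coordinates,
                        "decision": rec.decision_index,
                        "treatment": t,
                        "allocated": rec.allocation.get(t, 0),
                        "success_prob": rec.success_probs[t],
                        "cumulative_total": rec.cumulative_total,
                        "cumulative_mean": rec.cumulative_mean,
                        "n_consumed": rec.n_consumed,
                    }
                )
        return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig, pools: Mapping[str, TreatmentPool]
) -> ExperimentResult:
    """Run one sequential experiment over fresh copies of ``pools``.

    Strategy randomness and MCMC randomness are drawn from separate
    streams spawned from ``config.seed``, so changing the sampler effort
    leaves the allocation sequence's random choices untouched.
    """
    labels = sorted(pools)
    missing = [t for t in config.starting_values if t not in pools]
    if missing:
        raise ValidationError(f"starting_values name unknown treatments: {missing}")
    pools = {t: pools[t].fresh() for t in labels}

    root = np.random.SeedSequence(config.seed)
    strategy_ss, mcmc_ss = root.spawn(2)
    rng_strategy = np.random.default_rng(strategy_ss)
    mcmc_children = mcmc_ss.spawn(config.n_decisions + 1)

    data: dict[str, list[float]] = {t: [] for t in labels}
    consumed: list[float] = []
    n_start = 0

    def metrics() -> tuple[float, float, int]:
        count = len(consumed) if config.include_starts_in_metrics else len(consumed) - n_start
        values = consumed if config.include_starts_in_metrics else consumed[n_start:]
        total = float(np.sum(values)) if values else 0.0
        mean = total / count if count else float("nan")
        return total, mean, count

    warnings: list[str] = []
    records: list[DecisionRecord] = []

    def refit(decision: int):
        fits = fit_posteriors(
            data, config.prior, config.mcmc, seed=mcmc_children[decision]
        )
        rhat = {t: fits[t].rhat() for t in labels}
        for t, d in rhat.items():
            worst = max(d.values())
            if worst > config.rhat_threshold:
                warnings.append(
                    f"decision {decision}, treatment {t}: R-hat {worst:.3f} "
                    f"exceeds {config.rhat_threshold}"
                )
        probs = success_probabilities(fits, config.compare_on)
        return probs, rhat

    # Decision 0: starting installations only, empty allocation.
    start_samples = {}
    for t in labels:
        k = int(config.starting_values.get(t, 0))
        vals = pools[t].draw(k)
        start_samples[t] = vals
        data[t].extend(vals.tolist())
        consumed.extend(vals.tolist())
    n_start = len(consumed)
    probs, rhat = refit(0)
    total, mean, count = metrics()
    records.append(
        DecisionRecord(0, {t: 0 for t in labels}, start_samples, probs,
                       total, mean, count, rhat)
    )

    for d in range(1, config.n_decisions + 1):
        plan = allocate(config.strategy, probs, config.batch, rng_strategy)
        sampled = {}
        for t in labels:
            vals = pools[t].draw(plan.get(t, 0))
            sampled[t] = vals
            data[t].extend(vals.tolist())
            consumed.extend(vals.tolist())
        probs, rhat = refit(d)
        total, mean, count = metrics()
        records.append(DecisionRecord(d, plan, sampled, probs, total, mean, count, rhat))

    return ExperimentResult(
        config=config,
        records=records,
        total_sum=records[-1].cumulative_total,
        final_success_probs=records[-1].success_probs,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Sensitivity grid


def starting_value_permutations(
    treatments: Sequence[str], values: Sequence[int] = DEFAULT_STARTING_SET
) -> list[dict[str, int]]:
    """All distinct assignments of ``values`` to ``treatments`` (3! = 6
    for the default {1, 3, 17} set)."""
    if len(values) != len(treatments):
        raise ValidationError("need one starting value per treatment")
    labels = sorted(treatments)
    seen, perms = set(), []
    for perm in itertools.permutations(values):
        if perm in seen:
            continue
        seen.add(perm)
        perms.append(dict(zip(labels, perm)))
    return perms


def grid_plan(
    modes: Sequence[str] = MODES,
    strategies: Sequence[str] = STRATEGIES,
    permutations: Sequence[Mapping[str, int]] | None = None,
    replicates: int = 5,
    treatments: Sequence[str] = ("A", "B", "C"),
) -> list[dict]:
    """Enumerate grid coordinates (default 2 x 3 x 6 x 5 = 180)."""
    if permutations is None:
        permutations = starting_value_permutations(treatments)
    coords = []
    for mode, strategy, (ip, perm), rep in itertools.product(
        modes, strategies, enumerate(permutations), range(replicates)
    ):
        coords.append(
            {
                "dataset_mode": mode,
                "strategy": strategy,
                "perm_index": ip,
                "starting_values": dict(perm),
                "replicate": rep,
            }
        )
    return coords


def _coordinate_seeds(base_seed: int, coord: dict) -> tuple[int, int]:
    """Deterministic (experiment, pool) seeds for one grid coordinate.

    The pool seed ignores the replicate in nonstationary mode so every
    replicate walks the same chronological sequence, whereas stationary
    replicates reshuffle; this is what gives DPM its zero replicate
    variance on a fixed sequence.
    """
    mode_i = MODES.index(coord["dataset_mode"])
    strat_i = STRATEGIES.index(coord["strategy"])
    key = (mode_i, strat_i, coord["perm_index"], coord["replicate"])
    exp_seed = int(
        np.random.SeedSequence(base_seed, spawn_key=(1, *key)).generate_state(1)[0]
        & 0x7FFFFFFF
    )
    pool_key = (2, mode_i, coord["replicate"]) if coord["dataset_mode"] == "stationary" else (2, mode_i)
    pool_seed = int(
        np.random.SeedSequence(base_seed, spawn_key=pool_key).generate_state(1)[0]
        & 0x7FFFFFFF
    )
    return exp_seed, pool_seed


def _run_coordinate(args):
    base_config, pool_factory, base_seed, coord = args
    exp_seed, pool_seed = _coordinate_seeds(base_seed, coord)
    pools = pool_factory(coord["dataset_mode"], pool_seed)
    config = replace(
        base_config,
        starting_values=coord["starting_values"],
        strategy=coord["strategy"],
        dataset_mode=coord["dataset_mode"],
        seed=exp_seed,
    )
    result = run_experiment(config, pools)
    result.coordinates = {
        "dataset_mode": coord["dataset_mode"],
        "strategy": coord["strategy"],
        "perm_index": coord["perm_index"],
        "starting_values": "-".join(
            str(coord["starting_values"][t]) for t in sorted(coord["starting_values"])
        ),
        "replicate": coord["replicate"],
        "seed": exp_seed,
    }
    return result


def run_grid(
    base_config: ExperimentConfig,
    pool_factory: Callable[[str, int], Mapping[str, TreatmentPool]],
    modes: Sequence[str] = MODES,
    strategies: Sequence[str] = STRATEGIES,
    permutations: Sequence[Mapping[str, int]] | None = None,
    replicates: int = 5,
    treatments: Sequence[str] = ("A", "B", "C"),
    n_jobs: int = 1,
    on_error: str = "record",
) -> tuple[list[ExperimentResult], list[dict]]:
    """Run the full sensitivity grid.

    ``pool_factory(mode, seed)`` must return fresh cursor-0 pools; for
    synthetic studies use :func:`synthetic_pool_factory`.  Failures are
    recorded with their grid coordinates and the grid continues (set
    ``on_error='raise'`` to abort instead).  Results are deterministic
    given ``base_config.seed`` and independent of ``n_jobs``.
    """
    coords = grid_plan(modes, strategies, permutations, replicates, treatments)
    tasks = [(base_config, pool_factory, base_config.seed, c) for c in coords]
    results: list[ExperimentResult] = []
    failures: list[dict] = []

    def handle(coord, fn, *args):
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - grid must keep going
            if on_error == "raise":
                raise
            log.error("experiment failed at %s: %s", coord, exc)
            failures.append({**coord, "error": f"{type(exc).__name__}: {exc}"})
            return
        results.append(result)
        log.info(
            "experiment done: mode=%s strategy=%s perm=%s replicate=%d "
            "final_probs=%s warnings=%d",
            coord["dataset_mode"], coord["strategy"], coord["perm_index"],
            coord["replicate"],
            {t: round(p, 3) for t, p in result.final_success_probs.items()},
            len(result.warnings),
        )
        for w in result.warnings:
            log.warning("%s/%s/perm%d/rep%d: %s", coord["dataset_mode"],
                        coord["strategy"], coord["perm_index"],
                        coord["replicate"], w)

    if n_jobs > 1:
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            futures = [(c, pool.submit(_run_coordinate, t)) for c, t in zip(coords, tasks)]
            for coord, fut in futures:
                handle(coord, fut.result)
    else:
        for coord, task in zip(coords, tasks):
            handle(coord, _run_coordinate, task)
    return results, failures


class SyntheticPoolFactory:
    """Adapt a :class:`~banditaqm.synthetic.GeneratorConfig` to run_grid.

    The pool *values* are fixed by the generator's own seed, mirroring a
    finite observational data set; the call's ``seed`` argument only
    reshuffles the stationary sequence (replicates walk new permutations
    of the same installations) and is ignored for the fixed chronological
    nonstationary sequence.  A picklable class so grids can fan out to
    worker processes.
    """

    def __init__(self, generator_config):
        self.generator_config = generator_config

    def __call__(self, mode: str, seed: int):
        from .synthetic import generate_nonstationary, generate_stationary

        if mode == "stationary":
            pools = generate_stationary(self.generator_config)
            rng = np.random.default_rng(seed)
            return {
                t: TreatmentPool(
                    t,
                    pools[t].performances[rng.permutation(len(pools[t]))],
                    mode=SHUFFLED,
                )
                for t in sorted(pools)
            }
        return generate_nonstationary(self.generator_config)


def synthetic_pool_factory(generator_config) -> SyntheticPoolFactory:
    return SyntheticPoolFactory(generator_config)


class RecordsPoolFactory:
    """Adapt loaded installation records to run_grid (reshuffles the
    stationary data set per replicate seed; chronological order is fixed)."""

    def __init__(self, records, treatments=None):
        self.records = list(records)
        self.treatments = treatments

    def __call__(self, mode: str, seed: int):
        from .data import build_pools

        pool_mode = SHUFFLED if mode == "stationary" else "chronological"
        return build_pools(
            self.records, mode=pool_mode, seed=seed, treatments=self.treatments
        )


def records_pool_factory(records, treatments=None) -> RecordsPoolFactory:
    return RecordsPoolFactory(records, treatments)


# ---------------------------------------------------------------------------
# Metrics


def percent_reduction(reference_total: float, strategy_total: float) -> float:
    """Percent reduction of a strategy's total vs a reference total.

    Returns the unrounded value; reports round to the nearest integer
    percent in addition.
    """
    if not reference_total > 0:
        raise ValidationError("reference total must be > 0")
    return 100.0 * (reference_total - strategy_total) / reference_total


@dataclass
class GridSummary:
    """Replicate-aggregated curves.

    ``probabilities``: per (mode, strategy, permutation, decision,
    treatment) mean and variance across replicates of the success
    probability.  ``performance``: same grouping without treatment, for
    the cumulative mean and total.  Variances are population variances
    (ddof=0); the convention is fixed here rather than configurable
    per-call so all reports agree.
    """

    probabilities: pd.DataFrame
    performance: pd.DataFrame
    replicates: int


def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    frames = [r.to_frame() for r in results]
    if not frames:
        raise ValidationError("no experiment results to tabulate")
    return pd.concat(frames, ignore_index=True)


def summarize_replicates(results: Sequence[ExperimentResult] | pd.DataFrame) -> GridSummary:
    """Mean and variance across replicates of probabilities and performance."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = results_to_frame(list(results))
    if df.empty:
        raise ValidationError("no experiment results to summarize")
    keys = ["dataset_mode", "strategy", "perm_index", "starting_values"]
    for k in keys:
        if k not in df.columns:
            df = df.assign(**{k: "-"})
    reps = int(df.get("replicate", pd.Series([0])).nunique())

    probs = (
        df.groupby(keys + ["decision", "treatment"], dropna=False)["success_prob"]
        .agg(prob_mean="mean", prob_var=lambda s: s.var(ddof=0))
        .reset_index()
    )
    perf_src = df.drop_duplicates(subset=keys + ["decision", "replicate"]) if "replicate" in df else df
    perf = (
        perf_src.groupby(keys + ["decision"], dropna=False)[
            ["cumulative_mean", "cumulative_total"]
        ]
        .agg(["mean", lambda s: s.var(ddof=0)])
        .reset_index()
    )
    perf.columns = [
        "_".join(filter(None, map(str, c))).replace("<lambda_0>", "var")
        if isinstance(c, tuple)
        else c
        for c in perf.columns
    ]
    return GridSummary(probabilities=probs, performance=perf, replicates=reps)
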