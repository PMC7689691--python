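"""Configuration parsing/validation, run manifests and report generation."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .experiment import (
    DEFAULT_STARTING_SET,
    MODES,
    ExperimentConfig,
    percent_reduction,
)
from .posterior import COMPARE_MODES, McmcSettings, PriorSpec
from .strategies import STRATEGIES
from .synthetic import (
    ChangePoint,
    DEFAULT_CV,
    GeneratorConfig,
    TreatmentSpec,
    default_generator_config,
)


@dataclass(frozen=True)
class RunSpec:
    """Validated run settings: the experiment template, generator and grid axes."""

    experiment: ExperimentConfig
    generator: GeneratorConfig
    replicates: int = 5
    strategies: tuple[str, ...] = STRATEGIES
    modes: tuple[str, ...] = MODES
    starting_set: tuple[int, ...] = DEFAULT_STARTING_SET
    seed: int = 0

    def to_dict(self) -> dict:
        exp, gen = self.experiment, self.generator
        out = {
            "seed": self.seed,
            "experiment": {
                "decisions": exp.n_decisions,
                "batch": exp.batch,
                "starting_values": list(self.starting_set),
                "replicates": self.replicates,
                "strategies": list(self.strategies),
                "modes": list(self.modes),
                "compare_on": exp.compare_on,
                "include_starts_in_metrics": exp.include_starts_in_metrics,
                "rhat_threshold": exp.rhat_threshold,
            },
            "prior": {
                "mu": [exp.prior.mu_low, exp.prior.mu_high],
                "tau": [exp.prior.tau_low, exp.prior.tau_high],
            },
            "mcmc": {
                "chains": exp.mcmc.n_chains,
                "samples": exp.mcmc.n_samples,
                "burnin": exp.mcmc.n_burnin,
            },
            "generator": {
                "treatments": {},
            },
        }
        for label, spec in gen.treatments.items():
            entry = {
                "pool_size": spec.pool_size,
                "mean_mg_l": spec.target_mean,
                "cv": spec.cv,
            }
            if spec.change_point is not None:
                entry["change_point"] = {
                    "n_early": spec.change_point.n_early,
                    "early_mean_mg_l": spec.change_point.early_mean,
                    "late_mean_mg_l": spec.change_point.late_mean,
                }
            out["generator"]["treatments"][label] = entry
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


_TOP_KEYS = {"seed", "experiment", "prior", "mcmc", "generator"}
_EXP_KEYS = {
    "decisions", "batch", "starting_values", "replicates", "strategies",
    "modes", "compare_on", "include_starts_in_metrics", "rhat_threshold",
}


def validate_config(raw: str | Mapping | None) -> RunSpec:
    """Parse + validate a YAML config, filling the case-study defaults.

    An empty config yields the full default design: 20 decisions of batch
    10, priors U(-10,10)/U(0,5), 3 chains of 10 000 draws after 50 000
    burn-in, 5 replicates, the 6 permutations of {1,3,17}, all three
    strategies in both dataset modes, and the default generator.  All
    problems are aggregated into a single :class:`ConfigError`.
    """
    if raw is None:
        cfg: dict = {}
    elif isinstance(raw, str):
        cfg = yaml.safe_load(raw) or {}
    else:
        cfg = dict(raw)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")

    problems: list[str] = []
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")

    seed = cfg.get("seed", 0)
    exp_cfg = cfg.get("experiment") or {}
    if not isinstance(exp_cfg, dict):
        problems.append("experiment section must be a mapping")
        exp_cfg = {}
    unknown = set(exp_cfg) - _EXP_KEYS
    if unknown:
        problems.append(f"unknown experiment key(s): {sorted(unknown)}")

    decisions = exp_cfg.get("decisions", 20)
    batch = exp_cfg.get("batch", 10)
    starting_set = tuple(exp_cfg.get("starting_values", DEFAULT_STARTING_SET))
    replicates = exp_cfg.get("replicates", 5)
    strategies = tuple(exp_cfg.get("strategies", STRATEGIES))
    modes = tuple(exp_cfg.get("modes", MODES))
    compare_on = exp_cfg.get("compare_on", "natural_mean")
    include_starts = bool(exp_cfg.get("include_starts_in_metrics", True))
    rhat_threshold = float(exp_cfg.get("rhat_threshold", 1.1))

    if decisions < 1:
        problems.append("experiment.decisions must be >= 1")
    if batch < 1:
        problems.append("experiment.batch must be >= 1")
    if replicates < 1:
        problems.append("experiment.replicates must be >= 1")
    if any(v < 1 for v in starting_set):
        problems.append("experiment.starting_values must all be >= 1")
    for s in strategies:
        if s not in STRATEGIES:
            problems.append(f"unknown strategy {s!r}; valid: {list(STRATEGIES)}")
    for m in modes:
        if m not in MODES:
            problems.append(f"unknown dataset mode {m!r}; valid: {list(MODES)}")
    if compare_on not in COMPARE_MODES:
        problems.append(f"unknown compare_on {compare_on!r}; valid: {list(COMPARE_MODES)}")

    prior_cfg = cfg.get("prior") or {}
    mu_lo, mu_hi = prior_cfg.get("mu", (-10.0, 10.0))
    tau_lo, tau_hi = prior_cfg.get("tau", (0.0, 5.0))
    mcmc_cfg = cfg.get("mcmc") or {}
    chains = mcmc_cfg.get("chains", 3)
    samples = mcmc_cfg.get("samples", 10_000)
    burnin = mcmc_cfg.get("burnin", 50_000)

    gen_cfg = cfg.get("generator") or {}
    try:
        generator = _parse_generator(gen_cfg, seed)
        generator.validate()
    except ConfigError as exc:
        problems.extend(exc.problems)
        generator = default_generator_config(seed)

    prior = mcmc = experiment = None
    try:
        prior = PriorSpec(mu_lo, mu_hi, tau_lo, tau_hi)
    except Exception as exc:
        problems.append(f"prior: {exc}")
    try:
        mcmc = McmcSettings(chains, samples, burnin)
    except Exception as exc:
        problems.append(f"mcmc: {exc}")

    if not problems:
        labels = sorted(generator.treatments)
        if len(starting_set) != len(labels):
            problems.append(
                "experiment.starting_values must have one entry per treatment"
            )
        else:
            try:
                experiment = ExperimentConfig(
                    starting_values=dict(zip(labels, starting_set)),
                    strategy=strategies[0],
                    dataset_mode=modes[0],
                    n_decisions=decisions,
                    batch=batch,
                    seed=seed,
                    prior=prior,
                    mcmc=mcmc,
                    compare_on=compare_on,
                    include_starts_in_metrics=include_starts,
                    rhat_threshold=rhat_threshold,
                )
            except Exception as exc:
                problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    return RunSpec(
        experiment=experiment,
        generator=generator,
        replicates=int(replicates),
        strategies=strategies,
        modes=modes,
        starting_set=starting_set,
        seed=int(seed),
    )


def _parse_generator(gen_cfg: Mapping, seed: int) -> GeneratorConfig:
    if not gen_cfg:
        return default_generator_config(seed)
    if not isinstance(gen_cfg, Mapping):
        raise ConfigError("generator section must be a mapping")
    unknown = set(gen_cfg) - {"treatments", "seed", "cv"}
    if unknown:
        raise ConfigError(f"unknown generator key(s): {sorted(unknown)}")
    default_cv = float(gen_cfg.get("cv", DEFAULT_CV))
    trts = gen_cfg.get("treatments")
    if not trts:
        return default_generator_config(int(gen_cfg.get("seed", seed)), cv=default_cv)
    problems, specs = [], {}
    for label, entry in trts.items():
        entry = dict(entry or {})
        unknown = set(entry) - {"pool_size", "mean_mg_l", "cv", "change_point"}
        if unknown:
            problems.append(f"generator.{label}: unknown key(s) {sorted(unknown)}")
            continue
        cp = None
        cp_cfg = entry.get("change_point")
        if cp_cfg:
            try:
                cp = ChangePoint(
                    n_early=int(cp_cfg["n_early"]),
                    early_mean=float(cp_cfg["early_mean_mg_l"]),
                    late_mean=float(cp_cfg["late_mean_mg_l"]),
                )
            except KeyError as exc:
                problems.append(f"generator.{label}.change_point missing {exc}")
        try:
            specs[label] = TreatmentSpec(
                pool_size=int(entry["pool_size"]),
                target_mean=float(entry["mean_mg_l"]),
                cv=float(entry.get("cv", default_cv)),
                change_point=cp,
            )
        except KeyError as exc:
            problems.append(f"generator.{label} missing key {exc}")
    if problems:
        raise ConfigError(problems)
    return GeneratorConfig(treatments=specs, seed=int(gen_cfg.get("seed", seed)))


# ---------------------------------------------------------------------------
# Manifest and report


@dataclass
class RunManifest:
    """Provenance of one grid run, written alongside the result CSVs."""

    config_digest: str
    version: str = __version__
    started: str = ""
    finished: str = ""
    experiments: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def report(decisions: pd.DataFrame) -> tuple[str, dict[str, pd.DataFrame]]:
    """Headline report from the tidy per-decision table.

    Per dataset mode: final success probabilities per strategy, mean total
    sums, percent reductions vs equal allocation (rounded and unrounded),
    and the maximum replicate variance of the success probabilities.  All
    numbers are recomputable from the emitted CSVs alone.
    """
    if decisions.empty:
        raise ConfigError("empty results table")
    df = decisions.copy()
    last = df["decision"].max()
    lines: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    finals = df[df["decision"] == last]
    totals = (
        finals.drop_duplicates(subset=["dataset_mode", "strategy", "perm_index", "replicate"])
        .groupby(["dataset_mode", "strategy"])["cumulative_total"]
        .mean()
        .reset_index(name="mean_total_mg_l")
    )
    tables["totals"] = totals
    probs = (
        finals.groupby(["dataset_mode", "strategy", "treatment"])["success_prob"]
        .mean()
        .reset_index(name="final_success_prob")
    )
    tables["final_probabilities"] = probs

    rep_var = (
        df.groupby(["dataset_mode", "strategy", "perm_index", "decision", "treatment"])[
            "success_prob"
        ]
        .var(ddof=0)
        .groupby(["dataset_mode", "strategy"])
        .max()
        .reset_index(name="max_replicate_variance")
    )
    tables["replicate_variance"] = rep_var

    reductions = []
    for mode, grp in totals.groupby("dataset_mode"):
        lines.append(f"Dataset mode: {mode}")
        by_strategy = dict(zip(grp["strategy"], grp["mean_total_mg_l"]))
        for strategy, total in sorted(by_strategy.items()):
            lines.append(f"  {strategy.upper():>4} mean total: {total:.1f} mg/L")
        if "ea" in by_strategy and len(by_strategy) > 1:
            ref = by_strategy["ea"]
            for strategy, total in sorted(by_strategy.items()):
                if strategy == "ea":
                    continue
                red = percent_reduction(ref, total)
                reductions.append(
                    {
                        "dataset_mode": mode,
                        "strategy": strategy,
                        "reduction_pct": red,
                        "reduction_pct_rounded": int(round(red)),
                    }
                )
                lines.append(
                    f"  {strategy.upper():>4} reduction vs EA: "
                    f"{round(red):.0f}% ({red:.2f}% unrounded)"
                )
        mode_probs = probs[probs["dataset_mode"] == mode]
        for strategy, grp2 in mode_probs.groupby("strategy"):
            pretty = ", ".join(
                f"{row.treatment}={row.final_success_prob:.3f}"
                for row in grp2.itertuples()
            )
            lines.append(f"  {strategy.upper():>4} final P(best): {pretty}")
        mode_var = rep_var[rep_var["dataset_mode"] == mode]
        for row in mode_var.itertuples():
            lines.append(
                f"  {row.strategy.upper():>4} max replicate variance: "
                f"{row.max_replicate_variance:.4f}"
            )
        lines.append("")
    if reductions:
        tables["reductions"] = pd.DataFrame(reductions)
    return "\n".join(lines), tables


def utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
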