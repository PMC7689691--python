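# Methods

## Model

Each wastewater treatment *i* is an arm of a bandit whose reward (to be
minimized) is the N effluent concentration of the next installation.
Installation performance is the life-cycle mean concentration of one
household system, modelled as

    x_ij ~ LogNormal(mu_i, tau_i),   mu_i ~ U(-10, 10),   tau_i ~ U(0, 5)

with `tau` the precision on the log scale. Working on installation means
(rather than raw repeat measurements) matches how the monitoring data are
summarised; the log-normal respects the positivity and right skew of
concentration data.

With flat priors the conditionals are exactly

    mu  | tau, y ~ Normal(ybar, 1/(n tau))   truncated to the mu box
    tau | mu,  y ~ Gamma(n/2 + 1, SS(mu)/2)  truncated to the tau box

(`y = log x`, `SS(mu) = sum (y_j - mu)^2`), so the sampler is a two-block
Gibbs sampler using inverse-CDF draws from the truncated conditionals.
There is nothing to tune and mixing is near-immediate; chains and
treatments advance in lock-step as vectorised array operations, which is
what makes per-decision refits cheap inside 20-decision experiments.

### Probability of success

At each decision the treatments' posterior draws are aligned index-by-index
and each draw is awarded to the arm with the minimum comparison value;
exact ties split the award equally, so the probabilities are an exact
simplex. The comparison scale is configurable because "minimum N
concentration" underdetermines it:

- `natural_mean` (default): exp(mu + 1/(2 tau)), the log-normal mean in
  mg/L — the scale on which "performance" is defined throughout;
- `log_mu`: raw mu (equivalent to the default only when tau is equal
  across arms);
- `predictive_draw`: a posterior-predictive concentration draw.

The default is deliberate: under-sampled arms have posterior mass at small
tau, and the 1/(2 tau) term correctly translates that uncertainty into
*large* (bad) mean concentrations rather than letting symmetric log-scale
noise hand them spurious wins.

### Convergence

`gelman_rubin` implements the classic potential-scale-reduction factor
from between/within-chain variances (identical chains give
sqrt((n-1)/n) ~ 1; diverged chains >> 1). Experiments do not abort on
nonconvergence; any fit with R-hat above the threshold (default 1.1) adds
a warning record carried in the result and manifest.

## Strategies

Per decision a batch of 10 installations is allocated:

- **EA** — floor division plus a uniformly random assignment of the
  remainder (a permutation of 4/3/3 for 3 arms), nonadaptive throughout;
- **DPM** — entire batch to the argmax probability, ties broken uniformly
  at random (seeded), the greedy/exploitative extreme;
- **RPM** — one multinomial draw of the batch with cell probabilities
  equal to the success probabilities (batched Thompson sampling). A
  multinomial draw, not deterministic rounding of batch x p, preserves the
  occasional exploration of low-probability arms that the policy's
  regret behaviour relies on.

## Experiments

An experiment consumes per-treatment pools *without replacement, in pool
order*. That design choice makes a data set a fixed sequence that
strategies sample through: replicates of a deterministic policy on a fixed
sequence are bit-identical (zero performance variance), while stationary
replicates differ only through a fresh seeded permutation of the same
values. Pool exhaustion is a hard error naming the treatment, not silent
recycling — experiment length is sized to the data.

Decision 0 records the initialization (starting values only, empty
allocation). Cumulative performance by default includes the starting
installations: with starts {1, 3, 17} and 20 x 10 allocations the
cumulative mean divides by 221. Both behaviours are supported
(`include_starts_in_metrics`); the default is the one under which a total
like 2976 mg/L reconciles with a converged cumulative mean of ~13.5 mg/L
(2976/221 = 13.47, whereas /200 does not match).

Randomness is split into named streams spawned from the experiment seed
(pool shuffle, strategy, MCMC), so e.g. raising sampler effort cannot
perturb the allocation sequence. Grid coordinates (mode x strategy x
starting permutation x replicate) derive their seeds directly from the
base seed and the coordinate, making results independent of execution
order and of `--jobs`.

## Synthetic generator

The generator emulates the case-study pools: sizes 220/152/597 with
long-run means 12.7/23/18.2 mg/L, and for the nonstationary variant an
abrupt change point in Treatment A (33 installations at ~22 mg/L, then 187
at ~11 mg/L — whose pooled mean, 12.65, is consistent with the stationary
12.7 target). Values are i.i.d. log-normal parameterised by natural-scale
mean and CV via the moment identities; `cv = 0` degenerates to constant
pools, which tests exploit.

No dispersion statistics exist for the original data, so the default
**cv = 0.25** is a calibration, not a reproduction: it is small enough
that the stationary qualitative results (rapid convergence on the best
arm, DPM <= RPM < EA in cumulative performance) emerge robustly at desk
scale. Two real-data features the generator does not emulate: serial
correlation or drift within a treatment beyond the single abrupt change
point, and any heterogeneity of dispersion between treatments. Passing
tests therefore demonstrate the *machinery* and the qualitative strategy
ranking, not quantitative agreement with the original monitoring data.

Note an interaction worth knowing: cv = 0.25 implies a log-scale precision
of about 16.5, above the tau prior's cap of 5, so tau posteriors
concentrate near the cap and posterior intervals for mu are conservatively
wide. This is faithful to the stated prior box and slows, but does not
prevent, convergence of the success probabilities.

## Problem sizes and numerical choices

- Default design: 20 decisions x batch 10 (200 allocations; 221 values
  consumed with default starts), grid 2 x 3 x 6 x 5 = 180 experiments.
- Reference sampler effort mirrors the original analysis (3 chains x
  10 000 retained after 50 000 burn-in). The suite and the acceptance
  script run the desk effort, 3 x 1000 after 300 burn-in: the exact-
  conditional Gibbs sampler attains R-hat < 1.05 there (asserted in
  tests), and the Monte-Carlo error of a tallied probability at 3000
  draws is below 0.01.
- The acceptance-scale reproduction runs the stationary half-grid
  (90 experiments of 20 decisions) plus a 30-experiment 2-decision grid;
  together a few minutes on one core.
- Ties in the argmin tally and the DPM argmax are exact floating-point
  ties; both are split/broken explicitly (equal shares / seeded uniform)
  to keep results well-defined.
- Replicate summary variances are population variances (ddof = 0), fixed
  as a convention rather than configurable.
- Truncated-normal and truncated-gamma draws use `ndtr`/`ndtri` and
  `gammainc`/`gammaincinv`; when the truncated-gamma span underflows
  (all conditional mass above the cap) the draw degenerates to the cap,
  which is the correct limit.

## Known limitations

- With very few observations an arm's posterior is prior-dominated; its
  success probability can plateau around 0.85-0.90 for the best arm's
  competitors until they are sampled. Consequently the "all six starting
  permutations exceed 0.90 by decision 2" behaviour reported for the
  original data reproduces only approximately on synthetic pools (the
  minimum permutation hovers at ~0.89; see the acceptance outputs) — the
  plateau is a property of the vague-prior model, not of the sampler.
  Similarly, whether equal allocation's best-arm probability attains
  exactly 1.0 (every posterior draw) by decision 13 depends on the
  realized pool permutation: the tally typically sits at 0.999 ± a few
  thousandths, touching 1.0 only for favourable consumed subsets.
- Treatment costs, multi-objective scoring, Gittins/UCB policies and
  smooth nonstationary drifts are out of scope.
- The chronological ordering key inherits whatever the record dates mean
  in the source data (upload date vs installation date is not
  distinguishable there).
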