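# Methods

## Model

`stimtag` models binned spike counts from a population of `U` units exposed
to a concatenated stimulus stream of `T` time bins. Each observation `m` is a
count `N_m` for a (time, unit) pair `(t(m), u(m))`; a pair may occur any
number of times `M_tu >= 0` (ragged designs — units recorded in different
sessions, seeing different subsets of the stimuli, are the intended use).

Counts are conditionally Poisson with a multiplicative rate and
per-observation gain noise:

    N_m      ~ Poisson( Lambda[t(m), u(m)] * theta_m )
    theta_m  ~ Gamma(s_u, s_u)                       (mean 1)
    Lambda[t, u] = lam0_u * prod_k lamz_{uk}^{z_tk} * prod_r lamx_{ur}^{x_tr}

`z_tk` are `K` independent binary Markov chains — latent, time-varying
"tags" of the stimulus, shared across every presentation of stimulus moment
`t` — with initial probabilities `pi_k` and 2x2 row-stochastic transition
matrices `A_k`. `x_tr` are `R` observed covariates entering through the same
multiplicative form. All rates are per bin (`dt` is carried only to report
spikes/s).

The tag gains carry a sparse hierarchical prior per tag:

    lamz_{uk} ~ Gamma(c_zk, c_zk * d_zk),   c_zk ~ Gamma(a_c, b_c),
                                            d_zk ~ Gamma(a_d, b_d)

so the population distribution of a tag's gains has mean `1/d` and variance
`1/(c d^2)`: when `c` is large and `d ~ 1` the tag is pinned at gain 1 (no
effect). The concentration `c` is learned per tag, which is what lets a model
given more tags than the data support switch the surplus ones off
(automatic relevance determination). Baselines get a non-sparse version of
the same hierarchy; covariate gains get independent `Gamma(a_x, b_x)` priors.

## Inference

Mean-field variational Bayes: gamma factors for every rate-like quantity,
Dirichlet factors for `(pi_k, A_k)`, and a structured chain posterior per tag
obtained by exact forward-backward smoothing against the expected log
evidence (the factorial-HMM factorization over chains). Because `z` is
binary, the expected multiplicative contribution of chain `k` at `(t, u)` is
`xi_k[t,0] + xi_k[t,1] E[lamz_uk]`; the product over chains (cache `F`) and
the covariate moment product `E[lamx^x]` (cache `G`, using
`E[lam^x] = Gamma(a+x)/Gamma(a) b^-x`) make every gamma update conjugate.

One sweep updates, in order: baselines; baseline hyperparameters; for each
tag in ascending index — gains, hyperparameters, chain Dirichlet parameters,
expected log evidence, forward-backward, cache `F`; covariate gains; cache
`G`; overdispersion. Convergence is declared when the fractional change of
the objective drops below `tol` (default 1e-4); the fit restarts
`n_restarts` times (default 10) from independent random chain
initializations (`xi` uniform in [0.3, 0.7] per bin and tag — symmetry
breaking without biasing any tag on or off) and keeps the best final
objective.

Numerical choices:

- All chain recursions run in log space; expected-log chain parameters from
  Dirichlet factors are sub-normalized, which the smoother absorbs into its
  normalizer. Two-slice marginals are renormalized per slice.
- The hierarchical `(c, d)` updates follow a Stirling lower bound on
  `log Gamma(c)`; the same bound is used in the reported objective, so every
  closed-form update is an exact ascent step on that surrogate. Rates are
  floored at 1e-8 where the bound overshoots. The bound biases the
  hyperparameter posteriors by O(10%) (checked against small-`U` quadrature
  in the tests); the child gain posteriors it feeds are data-dominated.
- Covariate gains are the one non-conjugate family. The shape has the closed
  form `a_x + sum N_m x_m` — this is why covariates must be nonnegative;
  rescale each column to [0, 1]. The rate solves the transcendental
  stationarity condition of the objective; its derivative is strictly
  monotone, so the unique root is bracketed and found with Brent's method
  (closed form when the covariate is binary). A candidate is accepted only
  if it does not lower the local objective, keeping the sweep an ascent.
- The noise shapes `s_u` are point estimates, updated jointly with their
  theta factors by maximizing the profiled objective (substituting the
  optimal `q(theta_m) = Gamma(s + N_m, s + E[Lambda])` leaves an exact
  negative-binomial profile in `s`, maximized per unit by bounded scalar
  search in `log s`). Two alternatives fail structurally: a gamma factor for
  `s` driven by the Stirling bound collapses toward `s = 0` whenever more
  than half the counts are zero (its bias enters as `~1/s` per zero-count
  observation), and alternating point-`s` / theta updates converge
  geometrically slowly under strong shrinkage because the theta factors hide
  the dispersion misfit. The joint profiled update is still exact
  block-coordinate ascent on the same objective.
- Noise warm-up: for the first `noise_warmup` sweeps (default 10) the `s_u`
  stay at their initialization (the prior mean, default 10 — moderate,
  realistic gain noise). From a cold start the noise model and the tag
  chains race to explain the same variance, and an early-released noise
  model can absorb the stimulus-locked signal itself; freezing it at a
  realistic dispersion level lets the structured factors claim their
  variance first without leaving residual dispersion for spurious tags to
  latch onto. Convergence is never declared during warm-up.
- Chain blocks (Dirichlet parameters and forward-backward) are alternated a
  few times per sweep (`chain_inner_iters`, default 3): the pair converges
  to its own fixed point given the other factors, and single alternations
  let dying chains linger for tens of sweeps.
- Tag retirement at convergence: when the fractional-change criterion first
  fires, the fit proposes clamping each tag off in turn (gains pinned at 1,
  chain and hyperparameters reset to priors, everything free again from the
  next sweep) and races each proposal against the plain continuation for
  `retire_eval_sweeps` sweeps (default 5); a proposal is adopted only if it
  ends with the higher objective, and convergence is declared only when no
  retirement improves it. Rationale: coordinate ascent strands half-latched
  surplus tags on long plateaus — states that track residual noise at a few
  percent gain deviation, ascend by less than the stopping threshold per
  sweep, and die only after tens of further sweeps; the converged pruned
  state has a strictly higher bound whenever the tag was spurious, so these
  discrete jumps are pure model comparison under the same objective. The
  reported trace records one value per retirement round (the winner's), so
  it remains non-decreasing.

## Objective accounting

The reported objective is exact — Poisson terms, chain terms (log normalizer
and entropies from the smoother), Dirichlet and gamma cross-entropies and
entropies — except for the hierarchical prior cross-entropies, which use the
Stirling surrogate above, and the `s_u`, which enter at their point values
(their prior density is included; no entropy term). It is therefore a
surrogate evidence lower bound: monotone under every update the algorithm
performs, and within Stirling-bound accuracy of the true bound.

## Synthetic benchmark preset

`benchmark_preset` generates the validation experiment: `U = 100` units,
`T = 10,000` bins of `dt = 0.0333` s, `K = 3` binary tag chains with
`Gamma(1, 1)` gains, `R = 3` covariates, one presentation per (t, u). Scale
factors shrink `U` and `T` while keeping every distribution fixed; the
reduced scale used throughout the tests is `U = 50`, `T = 3000` (chosen so the full
fit with 10 restarts completes in minutes on one CPU).

Where the design leaves values open, the preset documents its choices:

- Baselines: gamma with population mean 10 spikes/s and shape 2 — a
  realistic heterogeneity for cortical units (most between 2 and 25
  spikes/s).
- Tag chains: persistent dynamics, `P(stay off) = 0.98`,
  `P(stay on) = 0.95` (dwell times of roughly 50 / 20 bins — seconds-long
  stimulus features at 30 frames/s), initialized at stationarity
  (on-probability 2/7).
- Covariates: binary Markov chains with symmetric persistence 0.95 and
  `Gamma(1, 1)` gains — as strong as the tags, but observed.
- Overdispersion: `s_u = 10` for every unit, i.e. gain noise with standard
  deviation ~0.32 — moderate, typical of cortical variability estimates.

What the generator emulates: ragged spontaneous designs (any `M_tu`),
realistic rate ranges, genuine overdispersion, covariates correlated in time.
What it does not: spike-history effects, inter-unit noise correlations,
non-stationary baselines, semi-Markov dwell times, continuous covariates.
Passing the recovery tests therefore shows the inference recovers the
model's own structure at realistic signal-to-noise — not that real cortical
data satisfy these assumptions.

## Default priors

Printed priors: baseline group `a_c = b_c = a_d = b_d = 1` (non-sparse);
tag groups `c ~ Gamma(2, 0.02)` (mean 100, deliberately vague) and
`d ~ Gamma(1, 1)`; covariates `Gamma(1, 1)`; noise shapes `s ~ Gamma(1,
0.1)` (weak, mean 10 — moderate overdispersion, ~30% gain standard
deviation); Dirichlet pseudocounts 1. The tag-`c` prior is
vague rather than sharp on purpose: the posterior concentration of an unused
tag must be free to grow with the data, and a sharp prior (say
`Gamma(100, 1)`) clamps `E[c]` near `100 + U/2`, capping the attainable
shrinkage of unused tags at a gain scatter of `1/sqrt(100 + U/2)` — about
9% at `U = 50`, which would leave "off" tags indistinguishable from weak
real ones. All priors are configurable.

## Tag-usage statistic

A tag counts as used when the mean absolute deviation of its fitted per-unit
gains from 1 exceeds 5% (`mean_u |E[lamz_uk]| - 1| > 0.05`). The population
mean gain `E[1/d_zk]` is reported alongside but is not the usage statistic:
under the benchmark's `Gamma(1, 1)` generative gains the population *mean*
is exactly 1, so a genuinely used tag can sit within a few percent of mean
gain 1 while individual units swing by a factor of 2 — the mean absolute
deviation separates the two regimes by an order of magnitude.

## Evaluation

- Normalized mutual information `I(X;Y)/sqrt(H(X) H(Y))` between a true tag
  series and an inferred one, with the joint estimated by averaging the
  posterior marginals across time (soft counts); the geometric-mean
  normalization keeps it in [0, 1], a constant series scores 0, and the
  score is invariant to 0/1 relabeling of either argument (an inferred tag
  may be the complement of a true one).
- True and inferred tags are matched by maximizing total pairwise NMI with
  the Hungarian algorithm (exact for any K).
- Rate reconstruction error: `sqrt(mean (f_i - f_a)^2) / sqrt(mean f_i *
  mean f_a)` across time bins — dimensionless, quoted as a percentage.
- Credible bands for `Lambda[t, u]` by Monte-Carlo sampling of all factors
  (gamma gains; Bernoulli tag states from the smoothed marginals).

## Known limitations

- Sequential coordinate ascent is order-dependent: relabeling the tags of
  the initialization relabels the trajectory exactly only if the sweep
  order is relabeled with it (`sweep(..., chain_order=...)`); with the fixed
  ascending order, permuted initializations can settle into slightly
  different local optima on weakly structured data.
- Retirement pruning removes surplus tags stranded in slow-dying transients,
  but occasionally (roughly one benchmark draw in six at the reduced scale) a
  surplus tag survives because the bound genuinely prefers it: a weak
  (~5% population gain) tag tracking residual structure wins its retirement
  race outright. This is the model's honest judgment under vague
  concentration priors at reduced data size, and it shrinks with more units
  or time bins.
- The NMI between a true chain and its match is bounded by the per-bin
  evidence, which grows with the number of units; at strongly scaled-down
  sizes a weak-gain chain may score in the 0.7-0.8 range even when its
  gains are recovered almost perfectly (correlation > 0.98). The soft
  estimator (posterior-averaged) is deliberately conservative: it charges
  the score for honest posterior uncertainty that hard-thresholded labels
  would hide.
- `s_u` is weakly identified at low rates (a fraction of a count per bin):
  the likelihood barely distinguishes `s = 50` from `s = infinity`, so the
  fitted values should be read as "dispersion needed", not as estimates of
  a physiological constant.
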