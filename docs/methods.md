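# Methods

## Model

A cell lineage accumulates driver mutations as a counting process whose
per-generation rate grows exponentially,

    mu(t) = mu0 * exp(b t),      b = a * s,

with `mu0` the initial driver-mutation rate (per cell per generation), `s`
the selective advantage coefficient of a mutated lineage and `a` a
dimensionless transform factor that converts selection strength into
curvature of the rate law. The two factors enter every observable only
through their product `b`, which is why fits return `b` and
`decompose_b` requires one factor to be fixed externally.

With time-varying but state-independent rate, the occupancy fractions
`p_j(t)` obey `dp_j/dt = mu(t)(p_{j-1} - p_j)`, whose solution is Poisson
with mean equal to the cumulative intensity

    lambda(t) = (mu0 / b) (exp(b t) - 1).

A stage carrying `k` drivers is treated as detectable in a pool of `N`
sensitive cells when its expected occupancy reaches one cell, `p_k = 1/N`.
Solving `lambda^k exp(-lambda) / k! = 1/N` for the smaller positive root
gives the detection threshold

    lambda_k = -k W0( -(k!)^(1/k) / (k N^(1/k)) ),

with `W0` the principal Lambert-W branch (scipy.special.lambertw). Dropping
the `exp(-lambda)` factor yields the linearized threshold
`(k!/N)^(1/k)`; published threshold tables print the linearized values
(verified row by row), so `linearized` is the default for table
reproduction while `exact` is available everywhere. The exact root stops
existing when even the modal occupancy `p_k(k)` is below `1/N` (Lambert-W
argument below −1/e); table generation marks such rows with a note instead
of aborting. Waiting times invert the intensity:
`t_k = ln(b lambda_k / mu0 + 1) / b` generations.

## Units and numerical choices

* Internal canonical time unit is cell generations; public outputs carry
  explicit units. Default generation time is 4 days, years are 365 days.
* Below `b = 1e-12` per generation the homogeneous-limit formulas
  (`lambda = mu0 t`, `t = lambda/mu0`) are used; `expm1`/`log1p` keep the
  general branch accurate, and continuity across the switch is tested to
  1e-6 relative.
* `N` means the sensitive-cell pool size (1e9–1e10). The candidate-gene
  count (30) is exposed only as the metadata constant `N_CAN_GENES`; the
  state space stays unbounded Poisson, no finite-sites cap.
* Thresholds are computed in log space via `gammaln`, so large `k` and `N`
  do not overflow.

## Oracles

Two independent routes validate the closed form:

1. **Master-equation integration** (`integrate_master_equation`). The
   truncated bidiagonal system is integrated with LSODA (scipy `odeint`)
   using an analytic banded Jacobian; the top state absorbs outflow so mass
   is conserved to 1e-9. Truncation defaults to
   `J = max(50, ceil(lambda_end + 10 sqrt(lambda_end)))`. Two variants:
   `eq5_time_rate` applies `mu(t)` uniformly across states and matches the
   Poisson solution to better than 1e-6 sup-norm on `t in [0, 4000]`
   generations for both patient parameter sets; `eq4_state_rates` freezes
   per-state rates `mu_i = mu(t_i)` at self-consistent expected transition
   times and is expected to deviate — the deviation shrinks monotonically
   as `b -> 0`, which the suite asserts empirically.
2. **Stochastic simulation** (`simulate_cell_mutations`,
   `first_passage_time`). By time-rescaling, each cell's count at `t_end`
   is Poisson(`lambda(t_end)`) and arrival epochs are sorted uniforms on
   `[0, lambda(t_end)]` mapped back through the inverse intensity; the
   k-th arrival in rescaled time is Gamma(k, 1), so pool first-passage is
   the mapped minimum of Gamma draws. Rejection (thinning) sampling is kept
   as a test-only cross-check. One seeded PCG64 stream draws cells in index
   order, so enlarging the pool extends a sample without reordering earlier
   cells' draws; results serialize deterministically for byte-level
   reproducibility checks. An in-memory cap of 1e8 draws guards the
   samplers; larger studies should rescale to a smaller pool.

The staircase times `t_i` solve `t_i = t_{i-1} + 1/mu(t_i)` (each holding
time averages the reciprocal rate at its end point). The plain
substitution iteration is not a contraction when `b/mu(t) > 1`, so the
residual is driven below 1e-8 by damped Newton steps (`f' = 1 + b/mu(t)`),
initialized from the waiting-time inverse at integer intensity; the
iteration trace is attached to any convergence error.

## Literature clocks

The Wright-Fisher clock `t_k = k ln(s/(u d^2)) / (2 s ln N)` and the
branching-process clock `t_k = (T/(k s)) ln(2 k s / u)` use these fixed
algebraic groupings, recorded in every result's `note` field: the
formulas' typography is corrupted in the available source text, so the
grouping is an interpretation, isolated behind named functions where an
alternative is a one-line change. The comparative-lesion-sequencing
interval is `Delta-T = F * T_founder`, and the growth clock
`t = T_gen ln(n)/r` is a generic exponential-growth timer: the source's own
growth formula is typographically unrecoverable, and the procedure behind
its published doubling-time figures (150/221 generations) is unstated, so
only this generic utility is provided. With `a = 1` and `mu0 = u d` the
rate law reduces to the Wright-Fisher model's `u d exp(s t)` (tested).

## Per-patient fitting

No fitting procedure is published for the per-patient parameters, so the
package defines one: minimize the sum of squared log-age residuals

    sum_i ( ln t_model(k_i; b, mu0) - ln t_obs,i )^2

over `(ln b, ln mu0)`. Log residuals stop the 20–35-year late stages from
dominating the 1–2-year early ones, and log parameters keep both scales
positive and well conditioned. Each fit runs Levenberg-Marquardt from a
deterministic 5x5 grid of starts (`ln mu0 in [ln 1e-8, ln 1e-4]`,
`ln b in [ln 1e-4, ln 1e-1]`) and keeps the best optimum; the surface is
smooth and the multi-start guards against the shallow valley along `b`.
Noiseless synthetic timelines are recovered to machine precision.

## Synthetic timelines

`generate_synthetic_timeline` draws observed stage ages as
`t_obs = t_model * exp(eps)`, `eps ~ N(0, sigma^2)` i.i.d. per stage,
redrawing the whole timeline if noise breaks the monotone stage order
(rare at the sigma = 0.1 used in the recovery study). It emulates a
clinician's retrospective stage dating with multiplicative error; it does
not emulate censoring, stage-dependent error, correlated errors within a
patient, or uncertainty in the driver counts themselves, so recovery
results bound what the fit can do under clean multiplicative noise only.

The recovery study uses the default colorectal stage map (microadenoma 3,
small adenoma 4, large adenoma 5, carcinoma 12 drivers) plus an early
carcinoma stage at 8 drivers, giving the five observations per timeline;
true parameters are the first patient's (`b = 0.0032`, `mu0 = 2e-5`),
`N = 1e10`, sigma = 0.1, 200 replicates. The suite asserts the *median
signed relative error* (a median-bias metric) of `b` within 5% and of
`mu0` within 25%. The spread of the estimator is larger than its bias:
with five log-time observations at sigma = 0.1 the Cramér-Rao floor on
`sd(ln b)` is about 0.097, i.e. a median *absolute* relative error of
roughly 6.5% that no estimator could beat under these conditions; the
fit's measured absolute medians are ~8% (b) and ~7% (mu0).

## Cohort summaries

`summarize_cohort` reports arithmetic means of mutation counts, `mu0` and
`s`. Published cohort rows truncate mean `s` at 4 decimals and round mean
`mu0` to 2 significant figures; both conventions are options with those
defaults.

## Packaged reference tables

`fixtures/table1–6.tsv` transcribe the published per-patient tables
(thresholds, stage timelines, parameters, size/time pairs, pancreatic
cohort). Known quirks carried as-is: the `N = 1e9` threshold column prints
its `k = 2` entry with a single significant digit (`5e-5`, vs the
computed 4.47e-5 — everything else in the column has three digits); the
second patient's `mu0` differs between its table row (2e-7) and the
body-text rate curve (1e-7), and the printed exponent 0.0016 conflicts
with `a*s = 0.0023` — both variants are stored
(`mu0_body_text`, `b_body_text`) and the `a*s` product is used wherever
that patient's parameters are needed, since the model defines `b = a*s`.
The `t_k` values 3165/3150 carry no stated unit and are stored but unused.
Published stage-timeline tables (waiting times like "7 y" for the
5-driver large adenoma) are treated as qualitative: the forward model from
the printed parameters reproduces their order of magnitude (5.6 y) but not
the exact printed ranges, and no procedure that would is stated.

## Problem sizes

Default test and validation sizes — ODE truncation up to J ≈ 2740 on a
41-point grid over 4000 generations, 1e5–1e6 simulated cells, 200-replicate
recovery with 25-start fits — run in well under a minute each and were
chosen as the smallest sizes at which the assertions' tolerances are
comfortably resolved.

## Known limitations

* No spatial structure, clonal interference, Wright-Fisher resampling or
  selection-driven expansion dynamics: selection acts only through the
  rate law's curvature.
* No finite-sites depletion: the driver supply never saturates.
* The detection convention `p_k = 1/N` is a first-detection heuristic on
  expected occupancy; the first-passage simulator quantifies its bias
  (the suite checks the simulated median against it at 15%).
* (s, a) are not separately identifiable from timing data.
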