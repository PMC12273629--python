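# Methods

## The models

`blastabc` models cell-lineage allocation in the pre-implantation mouse
embryo between the 8-cell morula (E2.5) and the late blastocyst (E4.5) as a
well-mixed compartment system.  Five host compartments are tracked:
blastomeres `B`, trophectoderm `T`, unspecified ICM `C`, primitive endoderm
`P` and epiblast `E`.  All host cells share one net per-capita growth rate
`alpha` (division minus death folded into a single constant).  The
transitions are irreversible:

    dB/dt = alpha*B - beta*B
    dT/dt = alpha*T + (1 - rho)*beta*B
    dC/dt = alpha*C + rho*beta*B - eta*(C+E)^m * C - zeta*P^l * C
    dP/dt = alpha*P + eta*(C+E)^m * C
    dE/dt = alpha*E + zeta*P^l * C

`beta` is the overall blastomere differentiation rate and `rho` the bias
toward the inside (unspecified ICM) fate.  PrE specification is driven by
FGF4 secreted by unspecified ICM and epiblast, hence the per-capita rate
`eta*(C+E)^m`; EPI specification is driven by feedback from the PrE
(plausibly basement-membrane deposition), hence `zeta*P^l`.  The integer
exponents `l, m ∈ {0, 1, 2}` let the data choose between no, linear and
nonlinear feedback; `l = 0` is the no-PrE-feedback alternative in which
unspecified ICM adopts the EPI fate at a constant rate.

Summing the equations gives `d(total)/dt = alpha*total` exactly — the
transition terms cancel pairwise.  This conservation property, the
non-negativity of solutions from non-negative starts, and the reduction of
the chimera system to the base system at zero donors are all enforced by
tests.

The chimera system adds donor embryonic stem cells, `D+` (Fgf4+/+) or `D-`
(Fgf4-/-), injected at the 8-cell stage.  Donors grow at their own net rate
`alpha_D`, Fgf4+/+ donors join the FGF4 pool (`eta*(C+E+D+)^m`), and both
genotypes crowd host blastomeres outward by depressing the ICM bias:

    rho_eff = rho0 / (1 + a*(D+ + D-)^n)

with the convention that `rho_eff = rho0` whenever no donors are present:
`n = 0` means donor-count-independent (but donor-triggered) crowding, and
without that convention `0^0 = 1` would let an `n = 0` crowding term act on
non-injected embryos, breaking the exact reduction to the base model.

Four variants express the competing hypotheses: `F` (FGF4 induction only,
donors grow at the host rate), `GF` (adds differential donor growth), `FC`
(adds crowding but keeps equal growth) and `GFC` (all three mechanisms).
The variant constraints are enforced at construction time, so an `F`
parameter set literally cannot carry a nonzero crowding factor.

Two reconstruction choices deserve note, both exposed so that a discrepancy
with other statements of the model is a one-line fix: the crowding function
carries the exponent `n` (with `n = 1`, the default, recovering the plain
hyperbolic form), and the chimera FGF4 term keeps the exponent `m` on the
enlarged pool, so the accepted nonlinear base model survives the `D+ = 0`
reduction.

## Numerical solution

The ODE systems are integrated with adaptive explicit Runge-Kutta (RK45,
`scipy.integrate.solve_ivp`) at `rtol = 1e-8` on a 0.1 h output grid over
[0, 48] h, initial condition `B(0) = 8`, everything else 0 (donors 10 or 15
for chimeras).  A fixed-step RK4 oracle at `h = 1e-3` h pins the solver to
relative error below 1e-5 in the tests.

Inside inference the closures switch to LSODA at `rtol = 1e-6`: prior
exploration routinely visits stiff corners (feedback coefficients near 1
with quadratic exponents give per-capita rates of order 1e4/h), where an
explicit method pays ~30x in step count for dynamics that relax instantly.
The two integrators agree to ~1e-6 relative on reference parameters.  The
right-hand side evaluates transition terms on the non-negative-clipped
state so transient undershoot cannot feed back; output values below zero by
more than the integration error scale raise an error, smaller undershoot is
clipped to 0.

## Stochastic simulation

Each ODE term maps to one reaction channel of a continuous-time Markov
chain (birth `X -> 2X` per species; the four transitions with the same
state-dependent propensities), simulated exactly with the Gillespie direct
method; propensities are recomputed after every event, and no tau-leaping
is used.  The net rate `alpha` is realised as pure birth by default — it
matches the mean with minimal variance; a `death_rate` knob splits it into
birth `alpha + d` and death `d` for sensitivity checks.  Ensembles spawn
per-replicate child seeds from one `SeedSequence`, so runs are reproducible
bit-for-bit and replicates are independent.  Closed-form checks: the Yule
pure-birth mean, and Binomial conversion counts for a one-reaction network.

## The summary statistic

Embryo snapshots carry no usable timestamps, so model and data are compared
in state space:

    S  = S1 + S2 + S3
    S1 = sum_n min_t sum_i (X_i(t) - x_i^(n))^2      (nearest-state distance)
    S2 = sum_i (max_t X_i(t) - max_n x_i^(n))^2      (matching maxima pins time scales)
    S3 = B(48)^2 + C(48)^2                           (late blastocyst is resolved)

`S1` sums (not averages) over observations; the minimum runs over the
discrete 0.1 h output grid; term weights default to (1, 1, 1) and are
configurable since no canonical relative weighting exists.  Only variables
present in the dataset's species map enter `S1`/`S2` (blastomeres are not
observable in fixed embryos); `S3` always uses the model's own `B` and `C`.
The acceptance rule is the closed inequality `S <= epsilon`.  An
independent brute-force implementation of the definition backs the
vectorised one in the tests, including the hand-computed toy value S = 50.

## Inference

ABC-MCMC follows the Marjoram scheme: start from the lowest-S point among
an initial batch of prior draws (200 by default, extended up to a budget of
1e5 until some draw satisfies `S <= epsilon`) — starting from the pilot
optimum rather than the first barely-acceptable draw keeps short chains out
of flat corners of the truncated support — then propose with a symmetric
kernel — componentwise Gaussian at 5% of the prior range for continuous
parameters, Gaussian in log10 for log-uniform ones, and for the discrete
exponents a lazy walk (±1 step with probability 0.3, hold otherwise,
holding at the ends rather than reflecting, since a reflecting boundary is
not symmetric on three values) — and accept iff the proposal is in the
prior support and its simulated `S` is within `epsilon`.  With uniform priors in
the sampled coordinates the Metropolis-Hastings ratio reduces to the
support check.

Priors (configurable; defaults chosen as biologically sensible ranges):
`alpha ~ U(0.01, 0.15) /h`, `beta ~ U(0.01, 1) /h`, `rho ~ U(0, 1)`,
`zeta, eta ~ log-U(1e-6, 1)`, `alpha_D ~ U(0.005, 0.15) /h`,
`a ~ U(0, 10)`, `l, m, n ~ discrete-U{0, 1, 2}`.

`epsilon` is set before any chain runs by a pilot rule: the q-quantile of
`S` over prior draws (q = 1% targets ~1% prior acceptance; the fits use
0.5–1% with 400–1,500 pilot draws).  Posterior point estimates are
componentwise medians, with discrete exponents summarised by their mode
(ties broken toward the larger exponent).

Model comparison uses plain rejection ABC at a *common* threshold; the
Bayes factor is the ratio of marginal acceptance rates (equal prior odds),
labelled on the Kass–Raftery scale (<3 barely worth mentioning, 3–20
positive, 20–150 strong).  Chimera fits hold the host parameters fixed at
the calibration values and infer only `(alpha_D, a, n)` — the two-stage
design the analysis follows throughout.

## Synthetic data

The generator replaces two unpublished calibration datasets, preserving
their statistical structure rather than their values:

* **cross-sectional snapshots** — each embryo gets a fixation time uniform
  on [0, 48] h which is then discarded; the observed columns are (T, C, P,
  E); defaults: 60 embryos;
* **endpoint chimera panels** — five conditions (non-injected, 10 or 15
  donors of either genotype), all at 48 h, donor- and host-EPI recorded
  separately; defaults: 10 embryos per condition.

Observation noise defaults to a multinomial re-draw of lineage identities
at the embryo's total — classification noise between lineages without
inventing extra cells; independent Poisson per lineage and noise-free modes
exist for sensitivity checks.  Counts can come from the ODE (default) or
from one Gillespie replicate per embryo.  Generating parameters:
`alpha = 0.06 /h`, `rho = 0.35`, `l = m = 2` (the fitted regime of the base
model), with `beta = 0.25 /h`, `zeta = 1.5e-3`, `eta = 5e-4` chosen once so
the 48 h endpoint is a realistic late blastocyst (~142 cells, 65% TE,
blastomeres and unspecified ICM exhausted, PrE:EPI ≈ 53:47); chimera
defaults `alpha_D = 0.02 /h`, `a = 0.05`, `n = 1` give a visible but
moderate crowding effect (`rho_eff` at 10 donors ≈ 0.23 vs 0.35).

What the generator does *not* emulate — segmentation and imaging error,
embryo attrition, litter structure, inter-embryo parameter variability —
bounds what green tests mean: they demonstrate that the pipeline recovers
its own generating process through the intended noise channel, not that
these parameter values describe real embryos.

One consequence is worth stating plainly: with time-implicit state-space
fitting and a free constant EPI rate, the no-feedback model (`l = 0`)
mimics the feedback model's cross-sectional cloud quite well, so the
rejection-ABC Bayes factor between them on default synthetic data is small
(~1.4–2) even though its direction is consistently correct.  Sharp
feedback-vs-none discrimination evidently needs the richer structure of a
real dataset; the suite therefore asserts the direction, not a magnitude.

## Endpoint chimera analysis

Composition summaries report per-condition, per-lineage means, s.d. and
s.e.m. of counts, ICM fractions (lineage / (C+P+E)) and whole-embryo
fractions; embryos with zero ICM cells are excluded from fraction averages
and counted in an exclusion column.  Hi/Lo chimerism classification runs
k-means (k-means++, 50 restarts, fixed seed) on the single scalar feature
donor-EPI / total-EPI, selecting k from {2, 3, 4} by mean silhouette and
labelling the higher-mean cluster "Hi" at k = 2; identical feature values
are a degenerate case returning k = 1 with silhouette undefined.  Overlay
tables tabulate each variant's predicted lineage numbers and ICM fractions
against observed condition means, including host-EPI for held-out
comparisons.

## Problem sizes

The shipped analyses and tests use: 60-embryo cross-sectional datasets,
50-embryo chimera panels, pilot calibrations of 400–1,500 draws, chains of
3,000–10,000 iterations, rejection runs of 150–300 acceptances, and
Gillespie ensembles of 500–5,000 replicates, chosen as the smallest sizes
at which the estimates' Monte-Carlo error is comfortably inside the
tolerances being checked.

## Known limitations

* Well-mixed compartments: no space, no cell sorting mechanics; crowding is
  a mean-field rate modification.
* FGF4 enters only through cell counts, not as a diffusible field.
* A single net growth rate per cell class; no stage-dependent rates.
* ABC thresholds are convention-relative: `epsilon` values are meaningful
  only together with the summary-statistic convention (sums over
  observations, unit weights) and the dataset's size and scale.
* The Hi/Lo silhouette value depends on the synthetic panel's noise
  realisation; only the clustering procedure, not a particular score, is
  reproducible.
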