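"""Likelihood-free parameter inference and model comparison.

Inference follows the Marjoram-style ABC-MCMC scheme: from a start point
satisfying ``S <= epsilon``, propose parameters with a symmetric kernel
(componentwise Gaussian for continuous parameters, lazy +/-1 moves on
{0, 1, 2} for the feedback exponents), simulate the deterministic model, and
accept iff the proposal is inside the prior support and the summary statistic
of the simulated trajectory is within ``epsilon`` of the data.  With uniform
(or log-uniform, sampled on the log scale) priors and symmetric proposals, the
Metropolis-Hastings correction reduces to the support check.

Model comparison uses rejection ABC: draw parameters i.i.d. from each model's
prior, accept when ``S <= epsilon`` at a *common* threshold, and report the
Bayes factor as the ratio of marginal acceptance rates (equal prior odds),
interpreted on the Kass-Raftery scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import BaseParams, ChimeraParams, Trajectory, injected_morula, solve
from .summary import CountDataset, summary_S

__all__ = [
    "Uniform",
    "LogUniform",
    "DiscreteUniform",
    "Fixed",
    "PriorSpec",
    "ABCConfig",
    "PosteriorSample",
    "ComparisonResult",
    "abc_mcmc",
    "rejection_abc",
    "bayes_factor",
    "posterior_median_params",
    "calibrate_epsilon",
    "make_base_model",
    "make_chimera_model",
    "kass_raftery_label",
    "DEFAULT_BASE_PRIORS",
    "DEFAULT_CHIMERA_PRIORS",
    "sample_prior",
    "in_support",
]


# ---------------------------------------------------------------------------
# Priors

class Uniform:
    """Uniform(lo, hi) prior with Gaussian random-walk proposals."""

    def __init__(self, lo: float, hi: float):
        if not lo < hi:
            raise ValueError("prior requires lo < hi")
        self.lo, self.hi = float(lo), float(hi)
        self.discrete = False

    def sample(self, rng: np.random.Generator) -> float:
        return rng.uniform(self.lo, self.hi)

    def in_support(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def default_scale(self) -> float:
        return 0.05 * (self.hi - self.lo)

    def propose(self, x: float, scale: float, rng: np.random.Generator) -> float:
        return x + scale * rng.standard_normal()


class LogUniform(Uniform):
    """Log-uniform prior: uniform in log10(x); proposals walk in log space."""

    def __init__(self, lo: float, hi: float):
        if lo <= 0:
            raise ValueError("log-uniform prior requires lo > 0")
        super().__init__(lo, hi)

    def sample(self, rng: np.random.Generator) -> float:
        return 10 ** rng.uniform(math.log10(self.lo), math.log10(self.hi))

    def default_scale(self) -> float:
        return 0.05 * (math.log10(self.hi) - math.log10(self.lo))

    def propose(self, x: float, scale: float, rng: np.random.Generator) -> float:
        return 10 ** (math.log10(x) + scale * rng.standard_normal())


class DiscreteUniform:
    """Uniform prior on a small set of integers (feedback exponents).

    The proposal is a lazy nearest-neighbour walk: with probability
    ``move_prob`` step to an adjacent value, otherwise hold.  Steps that
    would leave the support become holds, which keeps the kernel symmetric
    (a reflecting boundary would propose the interior value from an end
    twice as often as the reverse).  Holding most of the time also stops a
    single always-moving discrete coordinate from vetoing otherwise good
    joint proposals.
    """

    def __init__(self, values: Sequence[int] = (0, 1, 2), move_prob: float = 0.3):
        self.values = tuple(sorted(int(v) for v in values))
        self.move_prob = move_prob
        self.discrete = True

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.values))

    def in_support(self, x) -> bool:
        return x in self.values

    def default_scale(self) -> float:
        return 1.0

    def propose(self, x: int, scale: float, rng: np.random.Generator) -> int:
        if rng.random() >= self.move_prob:
            return x
        j = self.values.index(x) + int(rng.choice((-1, 1)))
        if j < 0 or j >= len(self.values):
            return x
        return self.values[j]


class Fixed:
    """Degenerate prior pinning a parameter to one value."""

    def __init__(self, value):
        self.value = value
        self.discrete = isinstance(value, (int, np.integer))

    def sample(self, rng: np.random.Generator):
        return self.value

    def in_support(self, x) -> bool:
        return x == self.value

    def default_scale(self) -> float:
        return 0.0

    def propose(self, x, scale, rng):
        return self.value


PriorSpec = Mapping[str, object]

#: Default priors for the base embryogenesis model (biologically sensible
#: ranges; rates on a log-uniform scale because they span decades).
DEFAULT_BASE_PRIORS: dict[str, object] = {
    "alpha": Uniform(0.01, 0.15),
    "beta": Uniform(0.01, 1.0),
    "rho": Uniform(0.0, 1.0),
    "zeta": LogUniform(1e-6, 1.0),
    "l": DiscreteUniform((0, 1, 2)),
    "eta": LogUniform(1e-6, 1.0),
    "m": DiscreteUniform((0, 1, 2)),
}

#: Default priors for the donor-specific parameters of chimera variants.
DEFAULT_CHIMERA_PRIORS: dict[str, object] = {
    "alpha_D": Uniform(0.005, 0.15),
    "a": Uniform(0.0, 10.0),
    "n": DiscreteUniform((0, 1, 2)),
}


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> dict:
    return {name: prior.sample(rng) for name, prior in priors.items()}


def in_support(priors: PriorSpec, theta: Mapping) -> bool:
    return all(prior.in_support(theta[name]) for name, prior in priors.items())


# ---------------------------------------------------------------------------
# Bookkeeping containers

@dataclass
class ABCConfig:
    """Settings for one ABC-MCMC run."""

    epsilon: float
    n_iterations: int = 10_000
    proposal_scales: Mapping[str, float] | None = None
    seed: int = 0
    thinning: int = 1
    burn_in: int = 0
    init_budget: int = 100_000
    init_draws: int = 200  # pilot draws scanned for the best starting point

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PosteriorSample:
    """Accepted parameter sets with acceptance bookkeeping."""

    accepted: list[dict]
    n_proposed: int
    epsilon: float
    chain_trace: pd.DataFrame | None = None

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted) / self.n_proposed if self.n_proposed else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accepted)


@dataclass(frozen=True)
class ComparisonResult:
    """Rejection-ABC Bayes factor between two models at a common epsilon."""

    model_a: str
    model_b: str
    epsilon: float
    acceptances_a: int
    proposals_a: int
    acceptances_b: int
    proposals_b: int
    bayes_factor: float = field(init=False, default=0.0)
    label: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if self.acceptances_b == 0:
            raise ZeroDivisionError("Bayes factor undefined: no acceptances for model B")
        if self.acceptances_a == 0:
            raise ZeroDivisionError("Bayes factor undefined: no acceptances for model A")
        rate_a = self.acceptances_a / self.proposals_a
        rate_b = self.acceptances_b / self.proposals_b
        bf = rate_a / rate_b
        object.__setattr__(self, "bayes_factor", bf)
        object.__setattr__(self, "label", kass_raftery_label(bf))


def kass_raftery_label(bf: float) -> str:
    """Qualitative evidence grade for a Bayes factor (model A over B)."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    b = max(bf, 1.0 / bf)
    if b < 3:
        return "barely worth mentioning"
    if b < 20:
        return "positive"
    if b < 150:
        return "strong"
    return "very strong"


# ---------------------------------------------------------------------------
# Simulator closures

Model = Callable[[Mapping], float]  # theta -> summary statistic S


def make_base_model(
    data: CountDataset,
    fixed: Mapping[str, float] | None = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
    rtol: float = 1e-6,
    method: str = "LSODA",
) -> Model:
    """Closure mapping base-model parameters to S against ``data``.

    ``fixed`` supplies parameters not present in theta.  LSODA is the default
    integrator here because prior exploration routinely visits stiff corners
    of parameter space.
    """
    fixed = dict(fixed or {})

    def model(theta: Mapping) -> float:
        p = BaseParams(**{**fixed, **theta})
        traj = solve(p, rtol=rtol, atol=1e-8, method=method)
        return summary_S(traj, data, weights)

    return model


def _split_panel(data: CountDataset) -> list[tuple[CountDataset, str, int]]:
    """Per-condition sub-datasets of a chimera panel with donor mapping."""
    out = []
    for condition in data.conditions:
        sub = data.subset(condition)
        if condition == "non-injected":
            mapping = {"T": "T", "C": "C", "P": "P", "E": "E"}
            genotype, n_donor = "plus", 0
        else:
            n_donor = int(condition[:2])
            genotype = "plus" if condition.endswith("+/+") else "minus"
            donor_sp = "D_plus" if genotype == "plus" else "D_minus"
            mapping = {"T": "T", "C": "C", "P": "P", "E_host": "E", "E_donor": donor_sp}
        out.append((CountDataset(sub.frame, mapping), f"{genotype}:{n_donor}", n_donor))
    return out


def make_chimera_model(
    data: CountDataset,
    base: BaseParams,
    variant: str = "GFC",
    weights: Sequence[float] = (1.0, 1.0, 1.0),
    rtol: float = 1e-6,
    method: str = "LSODA",
) -> Model:
    """Closure mapping donor parameters (alpha_D, a, n) to the panel-wide S.

    The base (host) parameters stay fixed at the values inferred from the
    non-injected calibration; S sums the per-condition statistics, each
    condition simulated from its own initial state.  Conditions without donor
    cells do not depend on theta, so their contribution is computed once and
    cached.
    """
    pieces = _split_panel(data)
    cache: dict[str, float] = {}

    def model(theta: Mapping) -> float:
        theta = dict(theta)
        if variant in ("F", "FC"):
            theta["alpha_D"] = base.alpha
        if variant in ("F", "GF"):
            theta["a"] = 0.0
        p = ChimeraParams(
            base=base,
            alpha_D=theta.get("alpha_D", base.alpha),
            a=theta.get("a", 0.0),
            n=int(theta.get("n", 1)),
            variant=variant,
        )
        total = 0.0
        for sub, tag, n_donor in pieces:
            if n_donor == 0:
                if tag not in cache:
                    traj = solve(base, rtol=rtol, atol=1e-8, method=method)
                    cache[tag] = summary_S(traj, sub, weights)
                total += cache[tag]
                continue
            genotype = tag.split(":")[0]
            initial = injected_morula(genotype, n_donor)
            traj = solve(p, initial=initial, rtol=rtol, atol=1e-8, method=method)
            total += summary_S(traj, sub, weights)
        return total

    return model


# ---------------------------------------------------------------------------
# Inference

class InitialisationError(RuntimeError):
    """No prior draw reached S <= epsilon within the budget."""


def _scales(priors: PriorSpec, override: Mapping[str, float] | None) -> dict:
    scales = {name: prior.default_scale() for name, prior in priors.items()}
    if override:
        scales.update(override)
    return scales


def abc_mcmc(model: Model, priors: PriorSpec, config: ABCConfig) -> PosteriorSample:
    """ABC-MCMC chain targeting the epsilon-truncated posterior.

    Accepts a move iff the proposal is in the prior support and its simulated
    summary statistic is within ``config.epsilon``.  The chain starts at the
    best (lowest-S) of ``config.init_draws`` pilot prior draws, provided that
    draw satisfies the threshold; otherwise sampling continues up to
    ``config.init_budget`` until some draw does.  Starting from the pilot
    optimum rather than the first barely-acceptable draw keeps short chains
    out of flat corners of the truncated support.  Returns the thinned,
    post-burn-in sample; ``chain_trace`` holds the full chain with the S
    value carried by the current state.
    """
    rng = np.random.default_rng(config.seed)
    scales = _scales(priors, config.proposal_scales)

    theta, s_cur = None, math.inf
    for i in range(config.init_budget):
        cand = sample_prior(priors, rng)
        s = model(cand)
        if s < s_cur:
            theta, s_cur = cand, s
        if s_cur <= config.epsilon and i + 1 >= config.init_draws:
            break
    if s_cur > config.epsilon:
        raise InitialisationError(
            f"no prior draw with S <= {config.epsilon:g} in {config.init_budget} "
            f"attempts (minimum S seen: {s_cur:g}); epsilon may be too small"
        )

    trace_rows = []
    accepted: list[dict] = []
    n_moves = 0
    for it in range(config.n_iterations):
        proposal = {
            name: prior.propose(theta[name], scales[name], rng)
            for name, prior in priors.items()
        }
        if in_support(priors, proposal):
            s_new = model(proposal)
            if s_new <= config.epsilon:
                theta, s_cur = proposal, s_new
                n_moves += 1
        trace_rows.append({**theta, "S": s_cur})
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            accepted.append(dict(theta))

    sample = PosteriorSample(
        accepted=accepted,
        n_proposed=config.n_iterations,
        epsilon=config.epsilon,
        chain_trace=pd.DataFrame(trace_rows),
    )
    sample.n_moves = n_moves
    return sample


def rejection_abc(
    model: Model,
    priors: PriorSpec,
    epsilon: float,
    target_acceptances: int = 500,
    max_proposals: int = 1_000_000,
    seed: int = 0,
) -> PosteriorSample:
    """Plain rejection ABC: i.i.d. prior draws accepted when S <= epsilon.

    Stops at ``target_acceptances``; the recorded number of proposals makes the
    acceptance rate an unbiased estimate of P(S <= epsilon) under the prior.
    """
    if target_acceptances < 1:
        raise ValueError("target_acceptances must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    accepted: list[dict] = []
    min_s = math.inf
    for n_proposed in range(1, max_proposals + 1):
        theta = sample_prior(priors, rng)
        s = model(theta)
        min_s = min(min_s, s)
        if s <= epsilon:
            accepted.append({**theta, "S": s})
            if len(accepted) >= target_acceptances:
                return PosteriorSample(accepted, n_proposed, epsilon)
    if not accepted:
        raise InitialisationError(
            f"no acceptances in {max_proposals} proposals (min S: {min_s:g})"
        )
    return PosteriorSample(accepted, max_proposals, epsilon)


def bayes_factor(
    sample_a: PosteriorSample,
    sample_b: PosteriorSample,
    epsilon: float | None = None,
    model_a: str = "A",
    model_b: str = "B",
) -> ComparisonResult:
    """Bayes factor of model A over model B from rejection-ABC bookkeeping."""
    if epsilon is None:
        epsilon = sample_a.epsilon
    if sample_a.epsilon != sample_b.epsilon:
        raise ValueError("samples must share a common epsilon")
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        epsilon=epsilon,
        acceptances_a=len(sample_a.accepted),
        proposals_a=sample_a.n_proposed,
        acceptances_b=len(sample_b.accepted),
        proposals_b=sample_b.n_proposed,
    )


def posterior_median_params(sample: PosteriorSample) -> dict:
    """Componentwise posterior median; discrete parameters take the mode.

    Ties between modal exponent values break toward the larger exponent.
    """
    if not sample.accepted:
        raise ValueError("empty posterior sample")
    frame = sample.to_frame().drop(columns=["S"], errors="ignore")
    out: dict = {}
    for col in frame.columns:
        values = frame[col]
        if values.dtype.kind in "iu" or set(values.unique()) <= {0, 1, 2}:
            counts = values.value_counts()
            best = counts.max()
            out[col] = int(max(v for v, c in counts.items() if c == best))
        else:
            out[col] = float(values.median())
    return out


def calibrate_epsilon(
    model: Model,
    priors: PriorSpec,
    quantile: float = 0.01,
    n_pilot: int = 500,
    seed: int = 0,
) -> float:
    """Set epsilon to a quantile of S over pilot prior draws.

    A 1% quantile targets roughly 1% prior acceptance, a common rule for
    choosing the ABC threshold before any chain is run.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    s_values = [model(sample_prior(priors, rng)) for _ in range(n_pilot)]
    return float(np.quantile(s_values, quantile))
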