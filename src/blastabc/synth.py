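"""Synthetic cell-count datasets with the structure the inference assumes.

Two study designs are emulated:

* a cross-sectional snapshot collection — embryos fixed at unknown stages
  spanning the 8-cell to late-blastocyst range, modelled as sampling times
  uniform on [0, 48] h that are then discarded (time-implicit data);
* endpoint chimera panels — embryos injected with 10 or 15 donor ESCs of
  either Fgf4 genotype (plus non-injected controls), all fixed at 48 h, with
  donor-derived and host-derived epiblast recorded separately.

Counts come from the deterministic model (or optionally one Gillespie
replicate per embryo) with an observation-noise model applied on top:

``multinomial``
    redraw lineage identities at the embryo's observed total — classification
    noise between lineages without inventing extra cells (the default);
``poisson``
    independent Poisson per lineage with the model value as mean;
``none``
    rounded model values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    BaseParams,
    ChimeraParams,
    EmbryoState,
    MORULA,
    injected_morula,
    solve,
)
from .stochastic import build_network, gillespie_run
from .summary import CONDITIONS, CountDataset

__all__ = ["SyntheticSpec", "generate_dataset", "generate_chimera_panel"]

NOISE_MODELS = ("multinomial", "poisson", "none")

#: Lineages recorded for cross-sectional host data (blastomeres are not
#: observable in fixed, stained embryos and C is the double-negative pool).
HOST_OBSERVED = ("T", "C", "P", "E")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    true_params: BaseParams | ChimeraParams
    n_embryos: int = 60
    sampling: str = "cross_sectional"  # or "endpoint"
    noise: str = "multinomial"
    seed: int = 0
    t_max: float = 48.0
    initial: EmbryoState = field(default=MORULA)
    stochastic: bool = False  # draw each embryo from one Gillespie replicate

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.sampling not in ("cross_sectional", "endpoint"):
            raise ValueError(f"unknown sampling design {self.sampling!r}")
        if self.noise not in NOISE_MODELS:
            raise ValueError(f"noise must be one of {NOISE_MODELS}")


def _apply_noise(values: np.ndarray, noise: str, rng: np.random.Generator) -> np.ndarray:
    """Observation noise on a vector of non-negative model counts."""
    if noise == "none":
        return np.round(values)
    if noise == "poisson":
        return rng.poisson(values).astype(float)
    total = int(np.round(values.sum()))
    if total == 0:
        return np.zeros_like(values)
    p = values / values.sum()
    return rng.multinomial(total, p).astype(float)


def _observe(
    state: EmbryoState,
    observed: Mapping[str, str],
    noise: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Project a model state onto observed columns and add noise.

    ``observed`` maps output column names to model species; noise redistributes
    counts among exactly these columns.
    """
    values = np.array([getattr(state, sp) for sp in observed.values()])
    noisy = _apply_noise(values, noise, rng)
    return dict(zip(observed.keys(), noisy))


def generate_dataset(spec: SyntheticSpec) -> CountDataset:
    """Generate a host-embryo count dataset according to ``spec``.

    Cross-sectional sampling draws one fixation time per embryo uniform on
    [0, t_max] and discards it; endpoint sampling fixes every embryo at
    ``t_max``.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    observed = {c: c for c in HOST_OBSERVED}

    if spec.sampling == "cross_sectional":
        times = np.sort(rng.uniform(0.0, spec.t_max, spec.n_embryos))
    else:
        times = np.full(spec.n_embryos, spec.t_max)

    rows = []
    if spec.stochastic:
        network = build_network(spec.true_params)
        for i, t in enumerate(times):
            traj = gillespie_run(network, spec.initial, spec.t_max, rng)
            state = traj.state_at(t)
            rows.append(
                {"embryo_id": f"emb{i:03d}", "condition": "non-injected"}
                | _observe(state, observed, spec.noise, rng)
            )
    else:
        traj = solve(spec.true_params, initial=spec.initial, t_max=spec.t_max)
        for i, t in enumerate(times):
            state = traj.state_at(t)
            rows.append(
                {"embryo_id": f"emb{i:03d}", "condition": "non-injected"}
                | _observe(state, observed, spec.noise, rng)
            )
    frame = pd.DataFrame(rows)
    return CountDataset(frame, {c: c for c in HOST_OBSERVED})


def _condition_setup(condition: str) -> EmbryoState:
    if condition == "non-injected":
        return MORULA
    n = int(condition[:2])
    genotype = "plus" if condition.endswith("+/+") else "minus"
    return injected_morula(genotype, n)


def generate_chimera_panel(
    params: ChimeraParams,
    n_per_condition: int = 10,
    seed: int = 0,
    noise: str = "multinomial",
    conditions: Sequence[str] = CONDITIONS,
    t_max: float = 48.0,
    stochastic: bool = False,
) -> CountDataset:
    """Endpoint (48 h) chimera titration panel across injection conditions.

    Each condition is simulated from the matching initial state (8 blastomeres
    plus 0, 10 or 15 donors of one genotype).  Donor-derived and host-derived
    epiblast are recorded separately for injected embryos; ``E`` is their sum.
    The dataset's species map assigns ``E`` (total EPI for non-injected rows)
    to the host epiblast and ``E_donor`` to the donor compartment.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if noise not in NOISE_MODELS:
        raise ValueError(f"noise must be one of {NOISE_MODELS}")
    rng = np.random.default_rng(seed)

    rows = []
    for condition in conditions:
        initial = _condition_setup(condition)
        donor_sp = "D_plus" if initial.D_plus > 0 else "D_minus"
        observed = {c: c for c in HOST_OBSERVED}
        if initial.donor_total > 0:
            observed = {"T": "T", "C": "C", "P": "P", "E_host": "E", "E_donor": donor_sp}
        network = build_network(params) if stochastic else None
        traj = None
        if not stochastic:
            traj = solve(params, initial=initial, t_max=t_max)
        for i in range(n_per_condition):
            if stochastic:
                state = gillespie_run(network, initial, t_max, rng).final_state
            else:
                state = traj.final_state
            counts = _observe(state, observed, noise, rng)
            if "E_host" in counts:
                counts["E"] = counts["E_host"] + counts["E_donor"]
            else:
                counts["E_host"] = counts["E"]
                counts["E_donor"] = 0.0
            rows.append(
                {"embryo_id": f"{condition}-{i:02d}", "condition": condition} | counts
            )
    frame = pd.DataFrame(rows)[
        ["embryo_id", "condition", "T", "C", "P", "E", "E_host", "E_donor"]
    ]
    # E_donor maps per-row to D_plus or D_minus; the per-condition mapping is
    # resolved by the fitting helpers, which split the panel by condition.
    return CountDataset(frame, {c: c for c in HOST_OBSERVED})
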