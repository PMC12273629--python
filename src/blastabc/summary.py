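"""State-space summary statistic for time-implicit cell-count data.

Embryo snapshots carry no timestamps (stages vary within and between
litters), so a model trajectory is compared to the data in state space rather
than as a time series.  The statistic is

    S = w1*S1 + w2*S2 + w3*S3

    S1 = sum_n  min_t  sum_i ( X_i(t) - x_i^(n) )^2
    S2 = sum_i ( max_t X_i(t) - max_n x_i^(n) )^2
    S3 = B(t_max)^2 + C(t_max)^2

where X_i(t) is the i-th observed model variable along the trajectory grid
and x_i^(n) the n-th observation of that variable.  S1 pulls the solution
through the cloud of observations with time implicit; S2 matches the
per-variable maxima, pinning down timescales; S3 penalises leftover
blastomeres and unspecified ICM at the final time, since a late blastocyst
should have resolved both.  Weights default to (1, 1, 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SPECIES, Trajectory

__all__ = [
    "CountObservation",
    "CountDataset",
    "summary_S",
    "summary_components",
    "distance_to_acceptance",
    "CONDITIONS",
]

#: Experimental conditions of the chimera panel.
CONDITIONS = ("non-injected", "10+/+", "15+/+", "10-/-", "15-/-")

#: Dataset columns that are not lineage counts.
_META_COLUMNS = ("embryo_id", "condition")


@dataclass(frozen=True)
class CountObservation:
    """Lineage counts for one embryo (a time-implicit snapshot)."""

    embryo_id: str
    counts: Mapping[str, int]
    condition: str = "non-injected"

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {k} in embryo {self.embryo_id}")


@dataclass(frozen=True)
class CountDataset:
    """Collection of per-embryo lineage counts plus the column→model mapping.

    ``species_order`` maps dataset count columns to model variables; e.g. the
    chimera panel maps ``E_donor`` to the relevant donor compartment.  Columns
    without a model counterpart stay out of the mapping and are ignored by the
    summary statistic.
    """

    frame: pd.DataFrame
    species_order: Mapping[str, str] = field(
        default_factory=lambda: {s: s for s in ("T", "C", "P", "E")}
    )

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise ValueError("dataset must contain at least one observation")
        missing = [c for c in self.species_order if c not in self.frame.columns]
        if missing:
            raise ValueError(f"mapped columns missing from dataset: {missing}")
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def count_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLUMNS]

    @property
    def observations(self) -> list[CountObservation]:
        return [
            CountObservation(
                str(row.get("embryo_id", i)),
                {c: row[c] for c in self.count_columns},
                str(row.get("condition", "non-injected")),
            )
            for i, row in self.frame.iterrows()
        ]

    def counts_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else list(self.species_order)
        return self.frame[cols].to_numpy(dtype=float)

    def subset(self, condition: str) -> "CountDataset":
        sub = self.frame[self.frame["condition"] == condition]
        if len(sub) == 0:
            raise KeyError(f"no observations with condition {condition!r}")
        return CountDataset(sub.copy(), self.species_order)

    @property
    def conditions(self) -> list[str]:
        if "condition" not in self.frame.columns:
            return ["non-injected"]
        return list(dict.fromkeys(self.frame["condition"]))

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path | io.TextIOBase,
        species_order: Mapping[str, str] | None = None,
    ) -> "CountDataset":
        frame = pd.read_csv(path)
        if species_order is None:
            species_order = {
                c: c for c in frame.columns if c in SPECIES and c not in _META_COLUMNS
            }
        return cls(frame, species_order)


def summary_components(
    traj: Trajectory,
    data: CountDataset,
) -> tuple[float, float, float]:
    """The three raw terms (S1, S2, S3) of the summary statistic."""
    cols = list(data.species_order)
    model_vars = [data.species_order[c] for c in cols]
    unknown = [v for v in model_vars if v not in SPECIES]
    if unknown:
        raise ValueError(f"species mapping targets unknown model variables: {unknown}")

    X = traj.columns(model_vars)  # (grid, k)
    obs = data.counts_matrix(cols)  # (n, k)

    # S1: per observation, squared distance to the nearest trajectory point.
    d2 = ((X[:, None, :] - obs[None, :, :]) ** 2).sum(axis=2)  # (grid, n)
    s1 = float(d2.min(axis=0).sum())

    # S2: squared mismatch of per-variable maxima.
    s2 = float(((X.max(axis=0) - obs.max(axis=0)) ** 2).sum())

    # S3: leftover blastomeres and unspecified ICM at the final time.
    final = traj.final_state
    s3 = float(final.B**2 + final.C**2)
    return s1, s2, s3


def summary_S(
    traj: Trajectory,
    data: CountDataset,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Weighted three-term state-space distance between model and data."""
    w1, w2, w3 = weights
    s1, s2, s3 = summary_components(traj, data)
    return w1 * s1 + w2 * s2 + w3 * s3


def distance_to_acceptance(S: float, epsilon: float) -> bool:
    """ABC acceptance test: ``S <= epsilon`` (closed threshold)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return S <= epsilon
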