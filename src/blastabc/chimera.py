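"""Endpoint analysis of chimera titration panels.

Covers the descriptive layer between raw per-embryo counts and the modelling:
per-condition lineage composition summaries (cell numbers and ICM /
whole-embryo fractions), classification of injected embryos into high- and
low-chimerism groups by k-means on the donor share of the epiblast, and
model-prediction overlay tables comparing each chimera-model variant to the
observed condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import ChimeraParams, injected_morula, solve
from .summary import CountDataset

__all__ = [
    "ChimerismClassification",
    "summarise_composition",
    "classify_chimerism",
    "overlay_model_predictions",
]

#: Lineages summarised per condition.
_LINEAGES = ("T", "C", "P", "E", "E_host", "E_donor")


def summarise_composition(data: CountDataset) -> pd.DataFrame:
    """Per-condition, per-lineage mean, s.d., s.e.m. of counts and fractions.

    ICM fraction = lineage / (E + P + C); whole-embryo fraction =
    lineage / (T + C + P + E).  Embryos with zero ICM cells are excluded from
    fraction means (their count statistics are kept) and reported in the
    ``n_excluded_icm`` column.
    """
    frame = data.frame.copy()
    if "condition" not in frame.columns:
        frame["condition"] = "non-injected"
    lineages = [c for c in _LINEAGES if c in frame.columns]
    icm = frame[["C", "P", "E"]].sum(axis=1)
    total = frame[["T", "C", "P", "E"]].sum(axis=1)

    rows = []
    for condition, grp in frame.groupby("condition", sort=False):
        g_icm = icm.loc[grp.index]
        g_total = total.loc[grp.index]
        ok = g_icm > 0
        for lineage in lineages:
            counts = grp[lineage].to_numpy(dtype=float)
            n = len(counts)
            icm_frac = grp.loc[ok, lineage] / g_icm[ok]
            emb_frac = grp.loc[ok, lineage] / g_total[ok]
            rows.append(
                {
                    "condition": condition,
                    "lineage": lineage,
                    "n": n,
                    "n_excluded_icm": int((~ok).sum()),
                    "count_mean": counts.mean(),
                    "count_sd": counts.std(ddof=1) if n > 1 else 0.0,
                    "count_sem": counts.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                    "icm_fraction_mean": float(icm_frac.mean()) if ok.any() else np.nan,
                    "icm_fraction_sem": (
                        float(icm_frac.std(ddof=1) / np.sqrt(ok.sum()))
                        if ok.sum() > 1
                        else 0.0
                    ),
                    "embryo_fraction_mean": (
                        float(emb_frac.mean()) if ok.any() else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChimerismClassification:
    """Hi/Lo chimerism grouping of injected embryos."""

    k: int
    labels: pd.Series  # "Hi" / "Lo" (or "cluster<i>" for k > 2), by embryo_id
    silhouette: float
    feature: pd.Series  # donor fraction of total EPI, by embryo_id
    silhouettes_by_k: Mapping[int, float]


def classify_chimerism(
    data: CountDataset,
    k_candidates: Sequence[int] = (2, 3, 4),
    seed: int = 0,
    n_restarts: int = 50,
) -> ChimerismClassification:
    """k-means Hi/Lo classification on the donor share of the epiblast.

    The feature is ``E_donor / (E_donor + E_host)`` per injected embryo.  Each
    candidate k is fit with k-means++ and ``n_restarts`` restarts; the k with
    the best mean silhouette wins.  For k = 2 the cluster with the higher mean
    donor fraction is labelled "Hi".  If every embryo has the same feature
    value the silhouette is undefined and k = 1 is returned.
    """
    frame = data.frame
    if not {"E_host", "E_donor"} <= set(frame.columns):
        raise ValueError("classification needs E_host and E_donor columns")
    injected = frame[frame["condition"] != "non-injected"]
    denom = injected["E_donor"] + injected["E_host"]
    injected = injected[denom > 0]
    feature = injected["E_donor"] / (injected["E_donor"] + injected["E_host"])
    feature.index = injected["embryo_id"]

    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    if len(feature) < max(k_candidates):
        raise ValueError(
            f"need at least {max(k_candidates)} embryos, got {len(feature)}"
        )
    x = feature.to_numpy().reshape(-1, 1)

    if np.ptp(x) == 0:  # degenerate: all features identical
        labels = pd.Series("Hi", index=feature.index)
        return ChimerismClassification(1, labels, float("nan"), feature, {})

    sils: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2:
            continue
        sils[k] = float(silhouette_score(x, lab))
        fits[k] = lab
    if not sils:
        labels = pd.Series("Hi", index=feature.index)
        return ChimerismClassification(1, labels, float("nan"), feature, {})

    best_k = max(sils, key=sils.get)
    lab = fits[best_k]
    if best_k == 2:
        hi_cluster = max((0, 1), key=lambda c: x[lab == c].mean())
        names = np.where(lab == hi_cluster, "Hi", "Lo")
    else:
        order = np.argsort([-x[lab == c].mean() for c in range(best_k)])
        rank = {c: r for r, c in enumerate(order)}
        names = np.array([f"cluster{rank[c]}" for c in lab])
    labels = pd.Series(names, index=feature.index)
    return ChimerismClassification(best_k, labels, sils[best_k], feature, sils)


def overlay_model_predictions(
    data: CountDataset,
    params_by_variant: Mapping[str, ChimeraParams],
    t_max: float = 48.0,
) -> pd.DataFrame:
    """Predicted vs observed lineage table per condition and model variant.

    For every condition present in the data (and every variant), solves the
    chimera model from the condition's initial state and tabulates predicted
    cell numbers and ICM fractions next to observed condition means.  Host EPI
    predictions are included for held-out comparisons against panels where
    donor and host EPI were scored separately.
    """
    obs = summarise_composition(data)
    rows = []
    for condition in data.conditions:
        if condition == "non-injected":
            initial = injected_morula("plus", 0)
            donor_sp = None
        else:
            n_donor = int(condition[:2])
            genotype = "plus" if condition.endswith("+/+") else "minus"
            initial = injected_morula(genotype, n_donor)
            donor_sp = "D_plus" if genotype == "plus" else "D_minus"
        for variant, params in params_by_variant.items():
            final = solve(params, initial=initial, t_max=t_max).final_state
            donor = getattr(final, donor_sp) if donor_sp else 0.0
            icm = final.C + final.P + final.E + donor
            pred = {
                "T": final.T,
                "C": final.C,
                "P": final.P,
                "E": final.E + donor,
                "E_host": final.E,
                "E_donor": donor,
            }
            for lineage, value in pred.items():
                o = obs[(obs["condition"] == condition) & (obs["lineage"] == lineage)]
                rows.append(
                    {
                        "condition": condition,
                        "variant": variant,
                        "lineage": lineage,
                        "predicted_count": value,
                        "predicted_icm_fraction": (
                            value / icm if lineage != "T" else np.nan
                        ),
                        "observed_count_mean": (
                            float(o["count_mean"].iloc[0]) if len(o) else np.nan
                        ),
                        "observed_icm_fraction_mean": (
                            float(o["icm_fraction_mean"].iloc[0]) if len(o) else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows)
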