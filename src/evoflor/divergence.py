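"""Among-group divergence matrices and evolvability-divergence comparison.

Realized divergence among populations (D_P) or species (D_S) is measured as
the among-group covariance matrix of ln trait means, estimated from the mixed
model

    z_ijkl = mu_i + p_ij + b_ijk + q_ijkl

(group, plant-within-group, blossom residual) on ln-transformed phenotypes.
On the ln scale the group-level covariances are proportional variances,
directly comparable to mean-scaled evolvabilities: the quadratic form
beta' D beta along a direction plays the same role for realized divergence as
beta' G beta plays for evolutionary potential, and both go through the same
projection kernel here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._gibbs import Term, run_gibbs
from .evolvability import (
    conditional_evolvability_along,
    eigen_summary,
    quadratic_form,
    repair_psd,
)

__all__ = [
    "DivergencePosterior",
    "fit_group_variance",
    "divergence_along",
    "evolvability_divergence_table",
    "fit_deviation",
]

logger = logging.getLogger(__name__)


@dataclass
class DivergencePosterior:
    """Posterior of the among-group covariance D (percent, ln scale)."""

    traits: list[str]
    level: str                      # "population" or "species"
    draws: np.ndarray               # (n_draws, k, k), percent units
    plant_draws: np.ndarray
    residual_draws: np.ndarray
    groups: list[str]

    @property
    def D(self) -> np.ndarray:
        return self.draws.mean(axis=0)


def fit_group_variance(
    records: pd.DataFrame,
    group_col: str = "group",
    traits: Sequence[str] = ("GAD", "GSD", "ASD"),
    level: str = "population",
    n_iter: int = 20_000,
    burnin: int = 5_000,
    thin: int = 15,
    seed: int = 0,
) -> DivergencePosterior:
    """Estimate D from a grouped phenotype table (ln-transformed internally).

    Requires >= 3 groups (the among-group variance is unidentifiable below
    that) and strictly positive trait values; zero values must be excluded
    before the fit, since they preclude ln-transformation.  Groups are
    ordered by first appearance, so the fit is invariant to renaming them.
    """
    traits = list(traits)
    if group_col not in records.columns:
        raise ValueError(f"grouped table lacks column {group_col!r}")
    Z = records[traits].to_numpy(dtype=float)
    if np.nanmin(Z) <= 0:
        raise ValueError(
            "non-positive trait values preclude ln-transformation; "
            "exclude those records or taxa first"
        )
    groups = pd.Categorical(
        records[group_col], categories=records[group_col].unique()
    )
    if len(groups.categories) < 3:
        raise ValueError("need at least 3 groups to estimate among-group variance")
    singletons = records.groupby(group_col)["plant"].nunique()
    lonely = singletons[singletons < 2].index.tolist()
    if lonely:
        logger.warning("groups with a single plant (components pooled): %s", lonely)

    Y = np.log(Z)
    plant = pd.Categorical(records["plant"], categories=records["plant"].unique())
    terms = [
        Term("D", groups.codes.astype(int), len(groups.categories)),
        Term("plant", plant.codes.astype(int), len(plant.categories)),
    ]
    res = run_gibbs(
        Y, terms, n_iter=n_iter, burnin=burnin, thin=thin, seed=seed
    )
    return DivergencePosterior(
        traits=traits,
        level=level,
        draws=100.0 * res.cov["D"],
        plant_draws=100.0 * res.cov["plant"],
        residual_draws=100.0 * res.cov["residual"],
        groups=list(groups.categories),
    )


def divergence_along(D: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    """beta' D beta: proportional among-group variance along a unit direction."""
    D = np.asarray(D, dtype=float)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    norm = np.linalg.norm(beta, axis=1, keepdims=True)
    out = quadratic_form(D, beta / norm)
    return float(out[0]) if np.asarray(beta).ndim == 1 or out.size == 1 else out


def evolvability_divergence_table(
    G: np.ndarray,
    D_by_level: dict[str, np.ndarray],
    gradients: np.ndarray,
    extra_axes: Optional[dict[str, np.ndarray]] = None,
    traits: Sequence[str] = ("GAD", "GSD", "ASD"),
) -> pd.DataFrame:
    """Evolvability, conditional evolvability and divergence per direction.

    Directions are the trait axes, g_min and g_max of G, plus the supplied
    random gradients — the plotting surface for divergence-vs-evolvability
    panels.  All matrices must share the trait order.
    """
    G = repair_psd(np.asarray(G, dtype=float))
    k = G.shape[0]
    for lvl, D in D_by_level.items():
        if np.asarray(D).shape != (k, k):
            raise ValueError(f"divergence matrix {lvl!r} has mismatched dimension")
    es = eigen_summary(G)
    directions: list[tuple[str, np.ndarray]] = [
        (traits[i], np.eye(k)[i]) for i in range(k)
    ]
    directions += [("g_min", es.g_min), ("g_max", es.g_max)]
    for name, ax in (extra_axes or {}).items():
        directions.append((name, np.asarray(ax, dtype=float)))
    gradients = np.atleast_2d(gradients)
    directions += [
        (f"beta{i + 1:04d}", gradients[i]) for i in range(gradients.shape[0])
    ]
    B = np.vstack([v / np.linalg.norm(v) for _, v in directions])
    out = pd.DataFrame({"direction": [n for n, _ in directions]})
    out["e"] = quadratic_form(G, B)
    out["c"] = conditional_evolvability_along(G, B)
    for lvl, D in D_by_level.items():
        out[f"d_{lvl}"] = quadratic_form(np.asarray(D, dtype=float), B)
    return out


def fit_deviation(group_means: pd.DataFrame) -> pd.DataFrame:
    """Per-group deviation from the pollen-transfer optimum GSD = GAD.

    Adds ``deviation = GSD - GAD`` (negative: anthers protrude beyond the
    stigmas, reducing autonomous selfing) paired with mean herkogamy ASD.
    """
    out = group_means.copy()
    out["deviation"] = out["GSD"] - out["GAD"]
    return out
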