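"""Multivariate animal model for mean-scaled G-matrix estimation.

The phenotype of trait i on blossom l of plant j measured on date k is

    z_ijkl = mu_i + a_ij + b_ij + d_ik + q_ijkl

with breeding values a ~ N(0, G (x) A) over the pedigree (A the additive
relationship matrix, (x) the Kronecker product), plant effects b ~ N(0, B),
date effects d ~ N(0, D_date), and blossom residuals q ~ N(0, Q).  Traits are
mean-scaled before fitting, so the diagonal of G is Houle's evolvability
I_A = V_A / mean^2, reported x100 as a percentage.

Fitting is by the collapsed Gibbs sampler in :mod:`evoflor._gibbs`; priors
default to weakly informative inverse-Wisharts (k+2 degrees of freedom,
diagonal scale = phenotypic variance / 4, i.e. prior mean at an equal split
of the phenotypic variance across the four components) and are configurable
through :class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._gibbs import run_animal_gibbs
from .pedigree import RelatednessMatrix

__all__ = [
    "DEFAULT_TRAITS",
    "ModelSpec",
    "GMatrixPosterior",
    "mean_scale",
    "fit_animal_model",
    "posterior_summary",
    "correlation_matrix",
]

DEFAULT_TRAITS = ("GAD", "GSD", "ASD")


@dataclass
class ModelSpec:
    """Chain settings and priors for the animal model.

    Defaults mirror the long production chain proportionally at desk scale:
    75,000 iterations, 25,000 burn-in, thinning 50, retaining ~1000 draws.
    """

    n_iter: int = 75_000
    burnin: int = 25_000
    thin: int = 50
    seed: int = 0
    traits: Sequence[str] = DEFAULT_TRAITS
    prior_df: Optional[float] = None
    prior_scales: dict = field(default_factory=dict)
    apply_mean_scaling: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= self.burnin:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")


@dataclass
class GMatrixPosterior:
    """Posterior draws of G, B, D_date, Q (percent mean-scaled) and trait means."""

    traits: list[str]
    trait_means: np.ndarray          # original units (mm)
    draws: dict[str, np.ndarray]     # 'G','B','D_date','Q' -> (n_draws, k, k), percent
    mu: np.ndarray                   # (n_draws, k), scaled-trait means
    ess: dict[str, float]
    chain: dict

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def G(self) -> np.ndarray:
        return self.draws["G"]

    def component_mean(self, name: str = "G") -> np.ndarray:
        return self.draws[name].mean(axis=0)

    def summary(self, component: str = "G") -> pd.DataFrame:
        return posterior_summary(self, component)

    def export(self) -> pd.DataFrame:
        """One retained draw per row: flattened lower triangles, labelled."""
        k = len(self.traits)
        cols, data = [], []
        for name, d in self.draws.items():
            for i in range(k):
                for j in range(i + 1):
                    cols.append(f"{name}[{self.traits[i]},{self.traits[j]}]")
                    data.append(d[:, i, j])
        for i, t in enumerate(self.traits):
            cols.append(f"mu[{t}]")
            data.append(self.mu[:, i])
        return pd.DataFrame(dict(zip(cols, data)))


def mean_scale(
    records: pd.DataFrame, traits: Sequence[str] = DEFAULT_TRAITS
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each trait by its sample mean; returns (scaled table, means).

    Variance components on the scaled data are mean-scaled (Houle's I_A);
    multiplied by 100 they are the percent units used throughout.
    """
    means = records[list(traits)].mean(skipna=True)
    if (means <= 0).any() or not np.isfinite(means).all():
        bad = means[(means <= 0) | ~np.isfinite(means)].index.tolist()
        raise ValueError(f"non-positive trait mean for {bad}; cannot mean-scale")
    out = records.copy()
    out[list(traits)] = records[list(traits)] / means
    return out, means


def fit_animal_model(
    records: pd.DataFrame,
    A: RelatednessMatrix,
    spec: ModelSpec | None = None,
) -> GMatrixPosterior:
    """Fit the animal model and return the mean-scaled posterior.

    ``records`` needs columns ``plant``, ``date``, ``blossom`` and the trait
    columns named in ``spec.traits`` (missing values allowed, as NaN).  Every
    plant must appear in ``A``; non-phenotyped pedigree members (e.g. the
    parents) are carried as breeding values without data.
    """
    spec = spec or ModelSpec()
    traits = list(spec.traits)
    for col in ("plant", "date", "blossom"):
        if col not in records.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    missing = set(records["plant"].astype(str)) - set(A.ids)
    if missing:
        raise ValueError(
            f"plants absent from the relationship matrix: {sorted(missing)[:5]}"
        )
    w = np.linalg.eigvalsh(A.values)
    if w[0] < -1e-8:
        raise ValueError(f"A is not positive semidefinite (min eigenvalue {w[0]:.3g})")

    if spec.apply_mean_scaling:
        scaled, means = mean_scale(records, traits)
    else:
        scaled, means = records, pd.Series(np.ones(len(traits)), index=traits)

    # canonical record order: pedigree position, then date, then blossom —
    # makes the fit invariant to row shuffles of the input table.
    a_index = {pid: i for i, pid in enumerate(A.ids)}
    scaled = scaled.assign(
        _aidx=scaled["plant"].astype(str).map(a_index)
    ).sort_values(["_aidx", "date", "blossom"], kind="stable")

    Y = scaled[traits].to_numpy(dtype=float)
    plant_idx = scaled["_aidx"].to_numpy(dtype=int)
    date_codes = pd.Categorical(scaled["date"]).codes.astype(int)

    res = run_animal_gibbs(
        Y,
        plant_idx,
        date_codes,
        A.values,
        n_iter=spec.n_iter,
        burnin=spec.burnin,
        thin=spec.thin,
        seed=spec.seed,
        prior_df=spec.prior_df,
        prior_scales=spec.prior_scales or None,
    )

    draws = {
        "G": 100.0 * res.cov["G"],
        "B": 100.0 * res.cov["B"],
        "D_date": 100.0 * res.cov["D_date"],
        "Q": 100.0 * res.cov["residual"],
    }
    ess = _effective_sizes(draws["G"], traits)
    return GMatrixPosterior(
        traits=traits,
        trait_means=means.to_numpy(dtype=float),
        draws=draws,
        mu=res.mu,
        ess=ess,
        chain={
            "n_iter": spec.n_iter,
            "burnin": spec.burnin,
            "thin": spec.thin,
            "seed": spec.seed,
        },
    )


def _effective_sizes(G_draws: np.ndarray, traits: Sequence[str]) -> dict[str, float]:
    import arviz as az

    out = {}
    for i, t in enumerate(traits):
        out[f"G[{t},{t}]"] = float(az.ess(G_draws[None, :, i, i]))
    return out


def posterior_summary(
    post: GMatrixPosterior | np.ndarray,
    component: str = "G",
    traits: Optional[Sequence[str]] = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Long-format posterior summary of one covariance component.

    One row per matrix element: variances and covariances in percent units,
    plus genetic correlations (computed per draw, then averaged — the order
    matters for nonlinear statistics).  Central quantile intervals.
    """
    if isinstance(post, GMatrixPosterior):
        draws = post.draws[component]
        traits = post.traits
    else:
        draws = np.asarray(post, dtype=float)
        if traits is None:
            traits = [f"t{i}" for i in range(draws.shape[1])]
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    k = draws.shape[1]
    for i in range(k):
        for j in range(i + 1):
            v = draws[:, i, j]
            kind = "variance" if i == j else "covariance"
            rows.append(
                dict(
                    row=traits[i], col=traits[j], kind=kind,
                    mean=float(v.mean()),
                    lower=float(np.quantile(v, lo)),
                    upper=float(np.quantile(v, hi)),
                )
            )
            if i != j:
                r = v / np.sqrt(draws[:, i, i] * draws[:, j, j])
                rows.append(
                    dict(
                        row=traits[i], col=traits[j], kind="correlation",
                        mean=float(r.mean()),
                        lower=float(np.quantile(r, lo)),
                        upper=float(np.quantile(r, hi)),
                    )
                )
    return pd.DataFrame(rows)


def correlation_matrix(G: np.ndarray) -> np.ndarray:
    """r_ij = G_ij / sqrt(G_ii G_jj); requires a strictly positive diagonal."""
    G = np.asarray(G, dtype=float)
    d = np.diag(G)
    if (d <= 0).any():
        raise ValueError("correlation undefined: non-positive diagonal entry")
    s = np.sqrt(d)
    return G / np.outer(s, s)
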