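"""Synthetic phenotype data with the statistical structure the models assume.

The breeding-experiment generator emulates a block-diallel greenhouse design:
blocks of parents crossed in all ordered combinations including selfs, a fixed
number of offspring raised per cross, and a fixed number of blossoms measured
per offspring on randomly assigned measurement dates.  Phenotypes follow

    z = mu_i * (1 + a + b + d + q)

where the deviations carry covariance G (x) A (breeding values, drawn by the
matrix-normal construction chol(A) Z chol(G)'), B (plant), D_date (date) and
Q (blossom residual), all supplied in percent mean-scaled units.  Because the
deviations are proportional, the mean-scaled covariance of the simulated data
matches the inputs by construction, making round-trip recovery tests exact in
expectation.

The group-level generator draws ln group means from N(ln mu, D/100) and layers
plant- and blossom-level lognormal noise beneath, for divergence-matrix tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import (
    CrossRecord,
    Pedigree,
    RelatednessMatrix,
    additive_relationship_matrix,
    build_pedigree,
    generate_block_diallel,
)

__all__ = [
    "SimulationTruth",
    "SimulatedExperiment",
    "simulate_breeding_experiment",
    "simulate_group_means",
    "dalechampia_truth",
]

TRAITS = ("GAD", "GSD", "ASD")


@dataclass
class SimulationTruth:
    """True parameter values and design constants behind a simulated dataset.

    Covariance components are in percent mean-scaled units (x100), matching
    the reporting convention of the fitted G.
    """

    mu: np.ndarray                   # trait means, mm
    G: np.ndarray                    # additive, percent mean-scaled
    B: np.ndarray                    # plant (non-genetic), percent
    D_date: np.ndarray               # measurement date, percent
    Q: np.ndarray                    # blossom residual, percent
    n_blocks: int = 10
    parents_per_block: int = 4
    offspring_per_cross: int = 2
    blossoms_per_offspring: int = 2
    n_dates: int = 20
    dropout: float = 0.05
    traits: tuple = TRAITS

    def __post_init__(self) -> None:
        for name in ("G", "B", "D_date", "Q"):
            M = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, M)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M)[0] < -1e-10:
                raise ValueError(f"{name} is not positive semidefinite")
        self.mu = np.asarray(self.mu, dtype=float)
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def to_json(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class SimulatedExperiment:
    phenotypes: pd.DataFrame
    pedigree: Pedigree
    A: RelatednessMatrix
    breeding_values: pd.DataFrame    # proportional deviations per individual
    truth: SimulationTruth


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Cholesky factor, falling back to an eigen square root on the PSD boundary."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return V * np.sqrt(np.maximum(w, 0.0))


def simulate_breeding_experiment(
    truth: SimulationTruth,
    seed: int | np.random.Generator = 0,
) -> SimulatedExperiment:
    """Simulate the full block-diallel experiment described by ``truth``.

    At the defaults (10 blocks x 4 parents, 2 offspring x 2 blossoms) this
    yields 160 crosses and 640 phenotype records before dropout; dropout
    removes records uniformly at random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(truth.traits)

    crosses = generate_block_diallel(truth.n_blocks, truth.parents_per_block)
    records: list[CrossRecord] = []
    for cr in crosses:
        for o in range(1, truth.offspring_per_cross + 1):
            records.append(
                CrossRecord(f"{cr.offspring_id}_O{o}", cr.sire_id, cr.dam_id, cr.block_id)
            )
    ped = build_pedigree(records)
    A = additive_relationship_matrix(ped)

    # breeding values with Cov(vec) = G (x) A (proportional scale)
    La = _psd_sqrt(A.values)
    Lg = _psd_sqrt(truth.G / 100.0)
    a = La @ rng.standard_normal((len(ped), k)) @ Lg.T

    offspring = [r.offspring_id for r in records]
    oidx = ped.index_of(offspring)
    b = rng.multivariate_normal(np.zeros(k), truth.B / 100.0, size=len(offspring))
    d_eff = rng.multivariate_normal(np.zeros(k), truth.D_date / 100.0, size=truth.n_dates)

    rows = []
    for i, rec in enumerate(records):
        dates = rng.integers(0, truth.n_dates, size=truth.blossoms_per_offspring)
        for l in range(truth.blossoms_per_offspring):
            q = rng.multivariate_normal(np.zeros(k), truth.Q / 100.0)
            dev = a[oidx[i]] + b[i] + d_eff[dates[l]] + q
            z = truth.mu * (1.0 + dev)
            rows.append(
                {
                    "plant": rec.offspring_id,
                    "sire": rec.sire_id,
                    "dam": rec.dam_id,
                    "date": f"D{dates[l] + 1:02d}",
                    "blossom": l + 1,
                    **dict(zip(truth.traits, z)),
                }
            )
    phen = pd.DataFrame(rows)
    if truth.dropout > 0:
        keep = rng.random(len(phen)) >= truth.dropout
        phen = phen.loc[keep].reset_index(drop=True)

    bv = pd.DataFrame(a, columns=list(truth.traits)).assign(id=ped.ids)
    return SimulatedExperiment(phen, ped, A, bv, truth)


def simulate_group_means(
    n_groups: int,
    D: np.ndarray,
    mu: Optional[np.ndarray] = None,
    within_noise: Optional[np.ndarray] = None,
    plants_per_group: int = 10,
    blossoms_per_plant: int = 2,
    seed: int | np.random.Generator = 0,
    traits: tuple = TRAITS,
    group_label: str = "group",
) -> pd.DataFrame:
    """Grouped phenotype table whose ln group means have covariance D/100.

    ``within_noise`` is a (plant-level, blossom-level) pair of percent-scale
    covariance matrices for the lognormal noise beneath the group means; by
    default both are 0.5% diagonal.
    """
    D = np.asarray(D, dtype=float)
    k = D.shape[0]
    if np.linalg.eigvalsh(0.5 * (D + D.T))[0] < -1e-10:
        raise ValueError("D is not positive semidefinite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu if mu is not None else np.full(k, 5.0), dtype=float)
    if within_noise is None:
        within_noise = (0.5 * np.eye(k), 0.5 * np.eye(k))
    Bw, Qw = (np.asarray(m, dtype=float) for m in within_noise)

    ln_means = np.log(mu) + rng.standard_normal((n_groups, k)) @ _psd_sqrt(D / 100.0).T
    rows = []
    for g in range(n_groups):
        gid = f"G{g + 1:03d}"
        for p in range(plants_per_group):
            pdev = rng.multivariate_normal(np.zeros(k), Bw / 100.0)
            for l in range(blossoms_per_plant):
                qdev = rng.multivariate_normal(np.zeros(k), Qw / 100.0)
                z = np.exp(ln_means[g] + pdev + qdev)
                rows.append(
                    {
                        group_label: gid,
                        "plant": f"{gid}_P{p + 1:02d}",
                        "blossom": l + 1,
                        **dict(zip(traits, z)),
                    }
                )
    return pd.DataFrame(rows)


def dalechampia_truth(**overrides) -> SimulationTruth:
    """Canonical simulation fixture for the *Dalechampia* blossom system.

    The additive G is the published mean-scaled estimate for gland-anther,
    gland-stigma and anther-stigma distances (percent units); trait means and
    the non-genetic components are plausible greenhouse values chosen once
    (see docs/methods.md) — herkogamy (ASD) is by far the most variable trait
    at every level.
    """
    params = dict(
        mu=np.array([5.0, 5.2, 2.8]),
        G=np.array(
            [
                [0.409, 0.193, 0.309],
                [0.193, 0.801, -0.591],
                [0.309, -0.591, 6.567],
            ]
        ),
        B=np.diag([0.6, 1.2, 9.0]),
        D_date=np.diag([0.15, 0.15, 0.5]),
        Q=np.diag([0.8, 1.6, 12.0]),
    )
    params.update(overrides)
    return SimulationTruth(**params)
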