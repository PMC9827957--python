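"""Hansen-Houle multivariate evolvability statistics.

For a mean-scaled additive genetic covariance matrix G and a unit-length
selection gradient beta:

* evolvability           e(beta) = beta' G beta
* conditional evolvability  c(beta) = (beta' G^-1 beta)^-1
* autonomy               a(beta) = c(beta) / e(beta)
* integration            i(beta) = 1 - a(beta)

e is the expected proportional response to unit-strength directional selection
along beta; c is the response when all orthogonal directions are held constant
by stabilizing selection.  With G in percent units (mean-scaled variance x
100), e and c are percentages; a and i are dimensionless fractions in (0, 1].

Directions "typical" of phenotype space are summarized by statistics over
gradients drawn uniformly from the unit sphere, and by the eigenstructure of G
(e_max / e_min are the leading / trailing eigenvalues; their eigenvectors
g_max / g_min are the most and least evolvable trait combinations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "evolvability_along",
    "conditional_evolvability_along",
    "autonomy_along",
    "integration_along",
    "conditional_on_subset",
    "random_unit_gradients",
    "summarize_over_gradients",
    "GradientSummary",
    "eigen_summary",
    "EigenSummary",
    "doubling_time",
    "posterior_stats",
    "repair_psd",
]

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-8  # x trace(G): floor applied to non-PD matrices before inversion


def _as_unit(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    norm = np.linalg.norm(beta, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-length selection gradient")
    if np.any(np.abs(norm - 1.0) > 1e-12):
        logger.warning("selection gradient not unit length; normalizing")
        beta = beta / norm
    return beta


def _check_symmetric(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be a square matrix")
    if not np.allclose(G, G.T, atol=1e-10 * (1 + np.abs(G).max())):
        raise ValueError("G must be symmetric")
    return 0.5 * (G + G.T)


def repair_psd(G: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Floor eigenvalues at ``floor * trace(G)`` so G can be inverted.

    Returns G unchanged when already comfortably positive definite.  Repairs
    are counted via a logged warning; posterior draws occasionally need this
    near the boundary of the PD cone.
    """
    G = _check_symmetric(G)
    w, V = np.linalg.eigh(G)
    lo = floor * np.trace(G)
    if w[0] >= lo:
        return G
    logger.warning("repaired non-PD matrix (min eigenvalue %.3g)", w[0])
    return (V * np.maximum(w, lo)) @ V.T


def quadratic_form(M: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """beta' M beta for one or many row-vector gradients (shared kernel)."""
    beta = np.atleast_2d(beta)
    return np.einsum("ij,jk,ik->i", beta, M, beta)


def evolvability_along(G: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    """e(beta) = beta' G beta, in G's units."""
    G = _check_symmetric(G)
    beta = _as_unit(beta)
    out = quadratic_form(G, beta)
    return float(out[0]) if np.asarray(beta).ndim == 1 else out


def conditional_evolvability_along(
    G: np.ndarray, beta: np.ndarray
) -> float | np.ndarray:
    """c(beta) = (beta' G^-1 beta)^-1; equals e(beta) iff beta is an eigenvector."""
    G = _check_symmetric(G)
    w = np.linalg.eigvalsh(G)
    if w[0] <= _EIG_FLOOR * np.trace(G):
        raise np.linalg.LinAlgError(
            "G is singular or nearly so; apply repair_psd() before inverting"
        )
    beta = _as_unit(beta)
    out = 1.0 / quadratic_form(np.linalg.inv(G), beta)
    return float(out[0]) if np.asarray(beta).ndim == 1 else out


def autonomy_along(G: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    """a(beta) = c(beta)/e(beta), the fraction of variance free of other directions."""
    e = evolvability_along(G, beta)
    c = conditional_evolvability_along(G, beta)
    return c / e


def integration_along(G: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    return 1.0 - autonomy_along(G, beta)


def conditional_on_subset(
    G: np.ndarray, focal, conditioning
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Conditional (Schur-complement) variance of focal traits given others.

    Returns ``(c, a)``: the conditional covariance of the focal block given
    the conditioning block, ``G_ff - G_fc G_cc^-1 G_cf``, and the per-focal
    autonomy ``diag(c)/diag(G_ff)``.  Scalars when there is one focal trait.
    For a single focal trait with all remaining traits conditioning, c equals
    ``1/(G^-1)_ff``.
    """
    G = _check_symmetric(G)
    focal = np.atleast_1d(np.asarray(focal, dtype=int))
    conditioning = np.atleast_1d(np.asarray(conditioning, dtype=int))
    if np.intersect1d(focal, conditioning).size:
        raise ValueError("focal and conditioning trait sets overlap")
    Gff = G[np.ix_(focal, focal)]
    Gfc = G[np.ix_(focal, conditioning)]
    Gcc = G[np.ix_(conditioning, conditioning)]
    C = Gff - Gfc @ np.linalg.solve(Gcc, Gfc.T)
    a = np.diag(C) / np.diag(Gff)
    if focal.size == 1:
        return float(C[0, 0]), float(a[0])
    return C, a


def random_unit_gradients(
    k: int, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """n directions uniform on the unit (k-1)-sphere (normalized Gaussians)."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 gradients in k >= 2 dimensions")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    b = rng.standard_normal((n, k))
    return b / np.linalg.norm(b, axis=1, keepdims=True)


@dataclass
class GradientSummary:
    """Per-gradient e, c, a, i plus their means and medians."""

    e: np.ndarray
    c: np.ndarray
    a: np.ndarray
    i: np.ndarray

    def table(self) -> pd.DataFrame:
        rows = {}
        for name in ("e", "c", "a", "i"):
            v = getattr(self, name)
            rows[name] = {"mean": float(np.mean(v)), "median": float(np.median(v))}
        return pd.DataFrame(rows).T

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"e": self.e, "c": self.c, "a": self.a, "i": self.i}
        )


def summarize_over_gradients(G: np.ndarray, gradients: np.ndarray) -> GradientSummary:
    """Evolvability statistics along a fixed set of unit gradients."""
    gradients = np.atleast_2d(np.asarray(gradients, dtype=float))
    if gradients.shape[0] < 2:
        raise ValueError("need at least 2 gradients to summarize")
    G = repair_psd(G)
    beta = _as_unit(gradients)
    e = quadratic_form(G, beta)
    c = 1.0 / quadratic_form(np.linalg.inv(G), beta)
    a = c / e
    return GradientSummary(e=e, c=c, a=a, i=1.0 - a)


@dataclass
class EigenSummary:
    e_mean: float
    e_min: float
    e_max: float
    g_min: np.ndarray
    g_max: np.ndarray


def eigen_summary(G: np.ndarray) -> EigenSummary:
    """Mean/extreme evolvabilities and the trailing/leading eigenvectors.

    Eigenvector signs follow the convention that the largest-magnitude
    component is positive.
    """
    G = _check_symmetric(G)
    w, V = np.linalg.eigh(G)

    def _signed(v: np.ndarray) -> np.ndarray:
        return v * np.sign(v[np.argmax(np.abs(v))])

    return EigenSummary(
        e_mean=float(np.trace(G) / G.shape[0]),
        e_min=float(w[0]),
        e_max=float(w[-1]),
        g_min=_signed(V[:, 0]),
        g_max=_signed(V[:, -1]),
    )


def doubling_time(e: float) -> float:
    """Generations of unit-strength selection to double the mean: ln(2)/e.

    ``e`` must be a fraction per generation (divide percent values by 100).
    """
    if e <= 0:
        raise ValueError("evolvability must be positive")
    return float(np.log(2) / e)


def posterior_stats(
    draws: np.ndarray, gradients: np.ndarray, ci: float = 0.95
) -> pd.DataFrame:
    """Posterior mean and central CI of each scalar evolvability statistic.

    Each statistic is computed per posterior draw of G (the gradient set held
    fixed across draws), then summarized over draws.  Rows: e_mean, e_min,
    e_max, c_mean, c_median, a_mean, a_median, i_mean, i_median.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3:
        raise ValueError("draws must have shape (n_draws, k, k)")
    per_draw: dict[str, list[float]] = {
        k: [] for k in (
            "e_mean", "e_min", "e_max",
            "c_mean", "c_median", "a_mean", "a_median", "i_mean", "i_median",
        )
    }
    for Gd in draws:
        es = eigen_summary(Gd)
        gs = summarize_over_gradients(Gd, gradients)
        per_draw["e_mean"].append(es.e_mean)
        per_draw["e_min"].append(es.e_min)
        per_draw["e_max"].append(es.e_max)
        per_draw["c_mean"].append(float(np.mean(gs.c)))
        per_draw["c_median"].append(float(np.median(gs.c)))
        per_draw["a_mean"].append(float(np.mean(gs.a)))
        per_draw["a_median"].append(float(np.median(gs.a)))
        per_draw["i_mean"].append(float(np.mean(gs.i)))
        per_draw["i_median"].append(float(np.median(gs.i)))
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    out = {
        name: {
            "mean": float(np.mean(v)),
            "lower": float(np.quantile(v, lo)),
            "upper": float(np.quantile(v, hi)),
        }
        for name, v in per_draw.items()
    }
    return pd.DataFrame(out).T
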