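"""Gibbs sampler for multivariate Gaussian mixed models with covariance components.

The model for a k-variate record r is

    y_r = mu + sum_t u_{t, level_t(r)} + e_r,      e_r ~ N(0, Q)

where each random term t has level effects u_{t,1..L_t} with

    Cov(u_{t,j}, u_{t,m}) = A_{t,jm} V_t

for a known structure matrix A_t (the additive relationship matrix for the
"animal" term; the identity for plant, date, or group terms) and an unknown
k x k covariance component V_t.  The sampler alternates

1. data augmentation of missing trait values (conditional Gaussians per
   missingness pattern),
2. conjugate Gaussian updates of mu (flat prior) and of every level effect,
3. conjugate inverse-Wishart updates of each V_t and of the residual Q.

Level effects within a term are conditionally independent given the others
whenever their A-inverse entry is zero, so updates are vectorized over colour
classes of the A-inverse adjacency graph (identity-structured terms form a
single class).  Inverse-Wishart draws use the Bartlett decomposition driven by
a single numpy Generator so runs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["Term", "GibbsResult", "run_gibbs", "sample_inv_wishart"]

_STRUCT_TOL = 1e-10


@dataclass
class Term:
    """One random term: record->level map plus optional A-inverse structure."""

    name: str
    levels: np.ndarray
    n_levels: int
    ainv: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.min() < 0 or self.levels.max() >= self.n_levels:
            raise ValueError(f"term {self.name}: level index out of range")
        if self.ainv is not None:
            self.ainv = np.asarray(self.ainv, dtype=float)
            if self.ainv.shape != (self.n_levels, self.n_levels):
                raise ValueError(f"term {self.name}: A-inverse shape mismatch")


@dataclass
class GibbsResult:
    mu: np.ndarray                      # (n_draws, k)
    cov: dict[str, np.ndarray]          # component name -> (n_draws, k, k)
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    n_iter: int = 0
    burnin: int = 0
    thin: int = 1
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


def sample_inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition of W(df, scale^-1)."""
    k = scale.shape[0]
    if df <= k - 1:
        raise ValueError("inverse-Wishart degrees of freedom too small")
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((k, k))
    idx = np.tril_indices(k, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(k)] = np.sqrt(rng.chisquare(df - np.arange(k)))
    LA = L @ A
    W = LA @ LA.T
    return np.linalg.inv(W)


def _greedy_coloring(adj: list[set[int]]) -> list[np.ndarray]:
    """Colour classes of an adjacency list; classes are mutually non-adjacent."""
    n = len(adj)
    order = sorted(range(n), key=lambda j: -len(adj[j]))
    colors = np.full(n, -1, dtype=int)
    for j in order:
        used = {colors[m] for m in adj[j] if colors[m] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[j] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]


def _sample_mvn_stacked(
    P: np.ndarray, h: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw x_l ~ N(P_l^-1 h_l, P_l^-1) for a stack of small precisions."""
    Sigma = np.linalg.inv(P)
    mean = np.einsum("lij,lj->li", Sigma, h)
    L = np.linalg.cholesky(Sigma)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("lij,lj->li", L, z)


def _slice_sample(x0, logf, f0=None, width=0.3, max_steps=40, rng=None):
    """Univariate slice sampler (stepping-out + shrinkage), returns (x1, f1)."""
    if f0 is None:
        f0 = logf(x0)
    y = f0 + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += width
    while True:
        x1 = lo + (hi - lo) * rng.random()
        f1 = logf(x1)
        if f1 > y:
            return x1, f1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _chol_from_params(theta: np.ndarray, k: int) -> np.ndarray:
    """Lower-triangular factor from a flat parameter vector (log diagonal)."""
    L = np.zeros((k, k))
    m = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[m]) if i == j else theta[m]
            m += 1
    return L


def _params_from_chol(L: np.ndarray) -> np.ndarray:
    k = L.shape[0]
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _log_iw(L: np.ndarray, df: float, scale: np.ndarray) -> float:
    """Unnormalized log inverse-Wishart density of LL' (matrix Lebesgue)."""
    k = L.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Linv_scale = np.linalg.solve(L, np.linalg.solve(L, scale).T)  # L^-1 S L^-T
    return -0.5 * (df + k + 1) * logdet - 0.5 * np.trace(Linv_scale)


def _log_iw_chol(L: np.ndarray, df: float, scale: np.ndarray) -> float:
    """log IW density of LL' plus the Jacobian to (log-diag) Cholesky params."""
    k = L.shape[0]
    jac = np.sum((k - np.arange(k) + 1) * np.log(np.diag(L)))
    return _log_iw(L, df, scale) + jac


def _stacked_gaussian_loglik(
    lam: np.ndarray, G: np.ndarray, B: np.ndarray, wt: np.ndarray
) -> float:
    """sum_j log N(wt_j; 0, lam_j G + B), up to the constant.

    Closed-form determinant/adjugate for k <= 3 (the hot path of the marginal
    remix move); generic stacked Cholesky otherwise.  Returns -inf when any
    stacked covariance is not positive definite.
    """
    C = lam[:, None, None] * G + B
    k = G.shape[0]
    if k == 1:
        c = C[:, 0, 0]
        if np.any(c <= 0):
            return -np.inf
        return -0.5 * float(np.sum(np.log(c) + wt[:, 0] ** 2 / c))
    if k == 2:
        a, b, d = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
        det = a * d - b * b
        if np.any(a <= 0) or np.any(det <= 0):
            return -np.inf
        w0, w1 = wt[:, 0], wt[:, 1]
        quad = (w0 * w0 * d - 2 * w0 * w1 * b + w1 * w1 * a) / det
        return -0.5 * float(np.sum(np.log(det) + quad))
    if k == 3:
        a, b, c = C[:, 0, 0], C[:, 0, 1], C[:, 0, 2]
        d, e, f = C[:, 1, 1], C[:, 1, 2], C[:, 2, 2]
        m00 = d * f - e * e
        m01 = b * f - c * e
        m02 = b * e - c * d
        det = a * m00 - b * m01 + c * m02
        det2 = a * d - b * b
        if np.any(a <= 0) or np.any(det2 <= 0) or np.any(det <= 0):
            return -np.inf
        w0, w1, w2 = wt[:, 0], wt[:, 1], wt[:, 2]
        quad = (
            w0 * w0 * m00 + w1 * w1 * (a * f - c * c) + w2 * w2 * det2
            + 2 * (-w0 * w1 * m01 + w0 * w2 * m02 - w1 * w2 * (a * e - b * c))
        ) / det
        return -0.5 * float(np.sum(np.log(det) + quad))
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf
    logdets = 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)), axis=1)
    sol = np.linalg.solve(C, wt[:, :, None])[:, :, 0]
    quad = np.einsum("li,li->l", wt, sol)
    return -0.5 * float(np.sum(logdets + quad))


class _MarginalRemix:
    """Marginal update of a (structured, iid) covariance pair given the sums.

    For a cluster holding breeding values a (prior G (x) A) and plant effects
    b (prior B (x) I) on the same levels, the likelihood depends only on
    w = a + b, so conjugate updates of G and B mix very slowly along the
    allocation ridge.  This move holds w fixed, slice-samples the Cholesky
    parameters of (G, B) under the marginal w ~ N(0, G (x) A + B (x) I) —
    diagonal in the eigenbasis of A — and then redraws the split a | w
    exactly.  It leaves the joint posterior invariant.
    """

    def __init__(self, ainv: np.ndarray, df: float,
                 scale_struct: np.ndarray, scale_iid: np.ndarray, k: int):
        d, Uvec = np.linalg.eigh(ainv)
        self.lam = 1.0 / d            # eigenvalues of A
        self.U = Uvec
        self.df = df
        self.scale_struct = scale_struct
        self.scale_iid = scale_iid
        self.k = k
        # adaptive-Metropolis state (diminishing adaptation)
        npar = k * (k + 1)
        self._mean = np.zeros(npar)
        self._cov = np.eye(npar) * 0.01
        self._count = 0
        self._log_s = np.log(2.38 / np.sqrt(npar))
        self.n_proposals = 15
        self.slice_every = 25
        self._offset = None

    def _logpost(self, theta: np.ndarray, wt: np.ndarray) -> float:
        k = self.k
        nc = k * (k + 1) // 2
        Lg = _chol_from_params(theta[:nc], k)
        Lb = _chol_from_params(theta[nc:], k)
        G = Lg @ Lg.T
        B = Lb @ Lb.T
        if self._offset is not None:
            B = B + self._offset
        ll = _stacked_gaussian_loglik(self.lam, G, B, wt)
        if not np.isfinite(ll):
            return -np.inf
        lp = _log_iw_chol(Lg, self.df, self.scale_struct)
        lp += _log_iw_chol(Lb, self.df, self.scale_iid)
        return ll + lp

    def _logpost_mat(self, G, B, wt) -> float:
        """Target density in matrix coordinates (no chol Jacobian)."""
        try:
            Lg = np.linalg.cholesky(G)
            Lb = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return -np.inf
        Blik = B if self._offset is None else B + self._offset
        ll = _stacked_gaussian_loglik(self.lam, G, Blik, wt)
        if not np.isfinite(ll):
            return -np.inf
        return (
            ll
            + _log_iw(Lg, self.df, self.scale_struct)
            + _log_iw(Lb, self.df, self.scale_iid)
        )

    def update_marginal(self, G, B, wt, rng, offset=None):
        """Slice/adaptive-MH move of (G, B) under the marginal of ``wt``.

        ``offset`` is an optional extra covariance added to B in the
        likelihood only (e.g. the residual of a level mean), not in the
        prior.  Returns the updated (G, B).

        Three kinds of moves, each leaving the target invariant: (1) slice
        scans over log-Cholesky parameters (overall scale and shape), (2)
        element-wise "trade" slices G + dE_ij, B - dE_ij, which run exactly
        along the allocation ridge the likelihood leaves flat, and (3)
        adaptive random-walk Metropolis proposals with a learned covariance
        (diminishing adaptation) that mop up the remaining correlations.
        """
        self._offset = offset
        k = self.k
        self._count += 1

        # (1) shape/scale slice scans, densest early on
        if self._count < 50 or self._count % self.slice_every == 0:
            theta = np.concatenate(
                [_params_from_chol(np.linalg.cholesky(G)),
                 _params_from_chol(np.linalg.cholesky(B))]
            )
            f = self._logpost(theta, wt)
            for m in range(theta.size):
                def logf(x, m=m):
                    th = theta.copy()
                    th[m] = x
                    return self._logpost(th, wt)
                theta[m], f = _slice_sample(
                    theta[m], logf, f0=f,
                    width=max(0.3 * abs(theta[m]), 0.1), rng=rng,
                )
            nc = k * (k + 1) // 2
            Lg = _chol_from_params(theta[:nc], k)
            Lb = _chol_from_params(theta[nc:], k)
            G, B = Lg @ Lg.T, Lb @ Lb.T

        # (2) ridge trades, element by element
        f = self._logpost_mat(G, B, wt)
        for i in range(k):
            for j in range(i + 1):
                E = np.zeros((k, k))
                E[i, j] = E[j, i] = 1.0
                width = 0.3 * np.sqrt(
                    (G[i, i] + B[i, i]) * (G[j, j] + B[j, j])
                )
                def logf_d(delta, E=E):
                    return self._logpost_mat(G + delta * E, B - delta * E, wt)
                delta, f = _slice_sample(0.0, logf_d, f0=f, width=width, rng=rng)
                G = G + delta * E
                B = B - delta * E

        # (3) adaptive Metropolis in log-Cholesky coordinates
        theta = np.concatenate(
            [_params_from_chol(np.linalg.cholesky(G)),
             _params_from_chol(np.linalg.cholesky(B))]
        )
        f = self._logpost(theta, wt)
        L = np.linalg.cholesky(self._cov + 1e-10 * np.eye(theta.size))
        s = np.exp(self._log_s)
        n_acc = 0
        for _ in range(self.n_proposals):
            prop = theta + s * (L @ rng.standard_normal(theta.size))
            fp = self._logpost(prop, wt)
            if np.log(rng.random()) < fp - f:
                theta, f = prop, fp
                n_acc += 1
        gamma = 1.0 / (10.0 + self._count)
        self._log_s += gamma * (n_acc / self.n_proposals - 0.30)
        delta_t = theta - self._mean
        self._mean += gamma * delta_t
        self._cov += gamma * (np.outer(delta_t, delta_t) - self._cov)
        nc = k * (k + 1) // 2
        Lg = _chol_from_params(theta[:nc], k)
        Lb = _chol_from_params(theta[nc:], k)
        return Lg @ Lg.T, Lb @ Lb.T

    def update(self, G, B, Ua, Ub, rng):
        """Returns updated (G, B, Ua, Ub); Ua + Ub is preserved exactly."""
        k = self.k
        w = Ua + Ub
        wt = self.U.T @ w
        G, B = self.update_marginal(G, B, wt, rng)
        # exact re-split: a~ | w~ per eigen-coordinate
        lamG = self.lam[:, None, None] * G
        C = lamG + B
        K = np.linalg.solve(C, lamG)          # C^-1 (lam G)
        mean = np.einsum("lji,lj->li", K, wt)  # (lam G) C^-1 w~
        cov = lamG - np.einsum("lij,ljk->lik", lamG, K)
        cov = 0.5 * (cov + np.swapaxes(cov, 1, 2)) + 1e-12 * np.eye(k)
        Lcv = np.linalg.cholesky(cov)
        at = mean + np.einsum("lij,lj->li", Lcv, rng.standard_normal(mean.shape))
        Ua = self.U @ at
        return G, B, Ua, w - Ua


def _missing_patterns(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group record indices by identical missingness pattern (rows, miss-mask)."""
    rows_with_missing = np.flatnonzero(mask.any(axis=1))
    if rows_with_missing.size == 0:
        return []
    keys = mask[rows_with_missing] @ (1 << np.arange(mask.shape[1]))
    out = []
    for key in np.unique(keys):
        rows = rows_with_missing[keys == key]
        out.append((rows, mask[rows[0]]))
    return out


def run_gibbs(
    Y: np.ndarray,
    terms: Sequence[Term],
    *,
    n_iter: int,
    burnin: int,
    thin: int = 1,
    seed: int = 0,
    prior_df: Optional[float] = None,
    prior_scales: Optional[dict[str, np.ndarray]] = None,
    store_effect_means: Sequence[str] = (),
) -> GibbsResult:
    """Run the sampler and return retained posterior draws.

    Default priors are weakly informative inverse-Wisharts with ``k + 2``
    degrees of freedom and diagonal scale = phenotypic variance divided by
    the number of covariance components (prior mean at an equal split);
    override per component through ``prior_scales`` (keyed by term name or
    ``"residual"``) and ``prior_df``.
    """
    Y = np.array(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (records x traits)")
    n, k = Y.shape
    if n_iter <= burnin:
        raise ValueError("chain length must exceed burn-in")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")
    rng = np.random.default_rng(seed)

    mask = ~np.isfinite(Y)
    if mask.all(axis=0).any():
        raise ValueError("a trait has no observed values")
    patterns = _missing_patterns(mask)

    # Default prior: IW(k+2, diag(phenotypic variance)/n_components), i.e.
    # prior mean at an equal split of the phenotypic variance with about one
    # pseudo-observation of weight.  Near-zero-scale IW(k+1, .) priors spike
    # at zero and push weakly identified variance allocations to corners.
    phen_var = np.nanvar(np.where(mask, np.nan, Y), axis=0, ddof=1)
    phen_var = np.where(np.isfinite(phen_var), phen_var, 0.0)
    df0 = float(prior_df) if prior_df is not None else k + 2.0
    n_comp = len(terms) + 1
    base_scale = (
        max(df0 - k - 1, 0.01) * np.diag(np.maximum(phen_var, 1e-12)) / n_comp
    )

    names = [t.name for t in terms] + ["residual"]
    if len(set(names)) != len(names):
        raise ValueError("duplicate term names")
    scales = {nm: base_scale.copy() for nm in names}
    if prior_scales:
        for nm, sc in prior_scales.items():
            if nm not in scales:
                raise KeyError(f"prior scale for unknown component {nm!r}")
            scales[nm] = np.asarray(sc, dtype=float)

    # Cluster terms sharing an identical record->level partition: their level
    # effects enter the likelihood only through their sum, so they are updated
    # jointly (crucial for mixing when e.g. breeding values and plant effects
    # live on the same individuals).  At most one structured term per cluster.
    clusters: list[list[int]] = []
    for ti, t in enumerate(terms):
        for cl in clusters:
            t0 = terms[cl[0]]
            if t.n_levels == t0.n_levels and np.array_equal(t.levels, t0.levels):
                cl.append(ti)
                break
        else:
            clusters.append([ti])

    cluster_info = []
    for cl in clusters:
        t0 = terms[cl[0]]
        counts = np.bincount(t0.levels, minlength=t0.n_levels).astype(float)
        structured = [ti for ti in cl if terms[ti].ainv is not None]
        if len(structured) > 1:
            raise ValueError("at most one structured term per shared partition")
        if structured:
            ainv = terms[structured[0]].ainv
            off = np.abs(ainv) > _STRUCT_TOL * max(1.0, np.abs(ainv).max())
            np.fill_diagonal(off, False)
            adj = [set(np.flatnonzero(off[j])) for j in range(t0.n_levels)]
            coloring = _greedy_coloring(adj)
            dvec = np.diag(ainv).copy()
        else:
            coloring = [np.arange(t0.n_levels)]
            dvec = None
        cluster_info.append(
            dict(members=cl, counts=counts, coloring=coloring,
                 dvec=dvec, structured=structured[0] if structured else None)
        )

    # marginal remix moves for clusters pairing one structured and one iid
    # term (e.g. breeding values + plant effects): conjugate updates alone
    # cannot traverse the variance-allocation ridge between them.
    remixes: list[tuple[int, int, _MarginalRemix]] = []
    for info in cluster_info:
        if info["structured"] is None or len(info["members"]) != 2:
            continue
        ti_s = info["structured"]
        ti_i = next(ti for ti in info["members"] if ti != ti_s)
        remixes.append(
            (
                ti_s,
                ti_i,
                _MarginalRemix(
                    terms[ti_s].ainv, df0,
                    scales[terms[ti_s].name], scales[terms[ti_i].name], k,
                ),
            )
        )

    # state
    col_mean = np.nanmean(np.where(mask, np.nan, Y), axis=0)
    Yimp = np.where(mask, col_mean, Y)
    mu = col_mean.copy()
    n_comp = len(terms) + 1
    init = np.diag(np.maximum(phen_var, 1e-12)) / n_comp
    V = {t.name: init.copy() for t in terms}
    Q = init.copy()
    U = {t.name: np.zeros((t.n_levels, k)) for t in terms}
    total = np.zeros((n, k))  # sum of term effects per record

    n_draws = (n_iter - burnin) // thin
    out_mu = np.empty((n_draws, k))
    out_cov = {nm: np.empty((n_draws, k, k)) for nm in names}
    term_by_name = {t.name: t for t in terms}
    eff_sums = {
        nm: np.zeros((term_by_name[nm].n_levels, k)) for nm in store_effect_means
    }
    stored = 0

    for it in range(n_iter):
        Qinv = np.linalg.inv(Q)

        # -- impute missing trait values
        if patterns:
            fitted = mu + total
            for rows, miss in patterns:
                obs = ~miss
                resid_obs = Yimp[np.ix_(rows, np.flatnonzero(obs))] - fitted[
                    np.ix_(rows, np.flatnonzero(obs))
                ]
                if obs.any():
                    Qoo = Q[np.ix_(np.flatnonzero(obs), np.flatnonzero(obs))]
                    Qmo = Q[np.ix_(np.flatnonzero(miss), np.flatnonzero(obs))]
                    Wt = np.linalg.solve(Qoo, Qmo.T).T
                    cmean = fitted[np.ix_(rows, np.flatnonzero(miss))] + resid_obs @ Wt.T
                    ccov = Q[np.ix_(np.flatnonzero(miss), np.flatnonzero(miss))] - Wt @ Qmo.T
                else:
                    cmean = fitted[rows][:, miss]
                    ccov = Q[np.ix_(np.flatnonzero(miss), np.flatnonzero(miss))]
                Lc = np.linalg.cholesky(ccov + 1e-14 * np.eye(miss.sum()))
                z = rng.standard_normal(cmean.shape)
                Yimp[np.ix_(rows, np.flatnonzero(miss))] = cmean + z @ Lc.T

        # -- trait means (flat prior)
        resid = Yimp - total
        Lq = np.linalg.cholesky(Q / n)
        mu = resid.mean(axis=0) + Lq @ rng.standard_normal(k)

        # -- level effects, cluster by cluster (terms in a cluster jointly)
        for info in cluster_info:
            members = info["members"]
            t0 = terms[members[0]]
            m = len(members)
            Vinvs = [np.linalg.inv(V[terms[ti].name]) for ti in members]
            excl = np.zeros((n, k))
            for ti in members:
                excl += U[terms[ti].name][terms[ti].levels]
            R = Yimp - mu - (total - excl)
            S = np.empty((t0.n_levels, k))
            for c in range(k):
                S[:, c] = np.bincount(
                    t0.levels, weights=R[:, c], minlength=t0.n_levels
                )
            nl = info["counts"]
            SQ = S @ Qinv
            for cls in info["coloring"]:
                L = len(cls)
                P = np.zeros((L, m * k, m * k))
                h = np.zeros((L, m * k))
                nQ = nl[cls, None, None] * Qinv
                for bi, ti in enumerate(members):
                    sl_i = slice(bi * k, (bi + 1) * k)
                    h[:, sl_i] = SQ[cls]
                    for bj in range(m):
                        sl_j = slice(bj * k, (bj + 1) * k)
                        P[:, sl_i, sl_j] = nQ
                    if ti == info["structured"]:
                        t = terms[ti]
                        d = info["dvec"]
                        W = t.ainv[cls] @ U[t.name]
                        off = W - d[cls, None] * U[t.name][cls]
                        P[:, sl_i, sl_i] += d[cls, None, None] * Vinvs[bi]
                        h[:, sl_i] -= off @ Vinvs[bi]
                    else:
                        P[:, sl_i, sl_i] += Vinvs[bi]
                draw = _sample_mvn_stacked(P, h, rng)
                for bi, ti in enumerate(members):
                    U[terms[ti].name][cls] = draw[:, bi * k:(bi + 1) * k]
            total = np.zeros((n, k))
            for t2 in terms:
                total += U[t2.name][t2.levels]

        # -- covariance components
        for t in terms:
            Ut = U[t.name]
            SS = Ut.T @ (t.ainv @ Ut) if t.ainv is not None else Ut.T @ Ut
            V[t.name] = sample_inv_wishart(
                rng, df0 + t.n_levels, scales[t.name] + SS
            )
        E = Yimp - mu - total
        Q = sample_inv_wishart(rng, df0 + n, scales["residual"] + E.T @ E)

        # -- marginal (G, B) move holding the effect sums fixed
        for ti_s, ti_i, remix in remixes:
            ns, ni = terms[ti_s].name, terms[ti_i].name
            V[ns], V[ni], U[ns], U[ni] = remix.update(
                V[ns], V[ni], U[ns], U[ni], rng
            )

        # -- record
        if it >= burnin and (it - burnin) % thin == 0:
            if not (np.isfinite(mu).all() and np.isfinite(Q).all()):
                raise RuntimeError(f"non-finite draw at iteration {it}")
            out_mu[stored] = mu
            for t in terms:
                if not np.isfinite(V[t.name]).all():
                    raise RuntimeError(f"non-finite draw at iteration {it}")
                out_cov[t.name][stored] = V[t.name]
            out_cov["residual"][stored] = Q
            for nm in eff_sums:
                eff_sums[nm] += U[nm]
            stored += 1

    effects = {nm: s / max(stored, 1) for nm, s in eff_sums.items()}
    return GibbsResult(
        mu=out_mu, cov=out_cov, effects=effects,
        n_iter=n_iter, burnin=burnin, thin=thin, seed=seed,
    )


def run_animal_gibbs(
    Y: np.ndarray,
    plant: np.ndarray,
    date: np.ndarray,
    A: np.ndarray,
    *,
    n_iter: int,
    burnin: int,
    thin: int = 1,
    seed: int = 0,
    prior_df: Optional[float] = None,
    prior_scales: Optional[dict[str, np.ndarray]] = None,
) -> GibbsResult:
    """Collapsed Gibbs sampler for the animal model with plant and date effects.

    Model per record: y = mu + a_j + b_j + d_t + q, with breeding values
    a ~ N(0, G (x) A) over the pedigree, plant effects b ~ N(0, B), date
    effects d ~ N(0, D_date) and residual q ~ N(0, Q).

    Breeding values and plant effects are confounded through the likelihood
    (both are plant-level), so G and B are updated from their *collapsed*
    conditional with (a, b) integrated out: records are padded to a common
    count m per phenotyped plant (all-missing rows, imputed by data
    augmentation, which leaves the observed-data posterior unchanged), after
    which the plant-mean residuals are independent in the eigenbasis of the
    phenotyped block of A,

        r~_j ~ N(0, lam_j G + B + Q/m).

    (G, B) moves under this marginal via slice/adaptive-Metropolis steps, and
    (a, b) are then redrawn exactly from their joint Gaussian conditional, so
    the notorious allocation ridge between additive and permanent-environment
    covariance is traversed without the slow conjugate feedback loop.  mu, d,
    D_date and Q keep standard conjugate updates.
    """
    Y = np.array(Y, dtype=float)
    n0, k = Y.shape
    if n_iter <= burnin:
        raise ValueError("chain length must exceed burn-in")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")
    rng = np.random.default_rng(seed)
    plant = np.asarray(plant, dtype=int)
    date = np.asarray(date, dtype=int)
    n_ind = A.shape[0]

    # pad records so every phenotyped plant has exactly m rows (the extra
    # all-missing rows carry no date effect and no information)
    pheno, counts0 = np.unique(plant, return_counts=True)
    m = int(counts0.max())
    pad_plant, pad_date = [], []
    for p, c in zip(pheno, counts0):
        pad_plant.extend([p] * (m - c))
        pad_date.extend([-1] * (m - c))
    if pad_plant:
        Y = np.vstack([Y, np.full((len(pad_plant), k), np.nan)])
        plant = np.concatenate([plant, pad_plant])
        date = np.concatenate([date, pad_date])
    n = Y.shape[0]
    n_o = len(pheno)
    code_of_plant = {p: i for i, p in enumerate(pheno)}
    code = np.array([code_of_plant[p] for p in plant])

    mask = ~np.isfinite(Y)
    if mask.all(axis=0).any():
        raise ValueError("a trait has no observed values")
    patterns = _missing_patterns(mask)

    # pedigree partition: phenotyped block (o) and the rest (conditioned)
    o = pheno
    rest = np.setdiff1d(np.arange(n_ind), o)
    Aoo = A[np.ix_(o, o)]
    marg = _MarginalRemix.__new__(_MarginalRemix)
    lam_o, U_o = np.linalg.eigh(Aoo)
    if lam_o[0] <= 0:
        raise ValueError("phenotyped block of A is singular")
    if rest.size:
        M_cond = np.linalg.solve(Aoo, A[np.ix_(o, rest)]).T  # A_ro A_oo^-1
        Spp = A[np.ix_(rest, rest)] - M_cond @ A[np.ix_(o, rest)]
        L_spp = np.linalg.cholesky(Spp + 1e-10 * np.eye(rest.size))

    # priors: IW(k+2, diag(phenotypic variance)/4) by default -- prior mean
    # at an equal split across the four components, ~1 pseudo-observation
    obs_var = np.nanvar(np.where(mask, np.nan, Y), axis=0, ddof=1)
    obs_var = np.where(np.isfinite(obs_var), obs_var, 0.0)
    df0 = float(prior_df) if prior_df is not None else k + 2.0
    base_scale = (
        max(df0 - k - 1, 0.01) * np.diag(np.maximum(obs_var, 1e-12)) / 4.0
    )
    names = ["G", "B", "D_date", "residual"]
    scales = {nm: base_scale.copy() for nm in names}
    if prior_scales:
        for nm, sc in prior_scales.items():
            if nm not in scales:
                raise KeyError(f"prior scale for unknown component {nm!r}")
            scales[nm] = np.asarray(sc, dtype=float)

    # marginal updater over the phenotyped eigenbasis
    marg.lam = lam_o
    marg.U = U_o
    marg.df = df0
    marg.scale_struct = scales["G"]
    marg.scale_iid = scales["B"]
    marg.k = k
    npar = k * (k + 1)
    marg._mean = np.zeros(npar)
    marg._cov = np.eye(npar) * 0.01
    marg._count = 0
    marg._log_s = np.log(2.38 / np.sqrt(npar))
    marg.n_proposals = 15
    marg.slice_every = 25
    marg._offset = None

    nd = int(date.max()) + 1
    date_idx = np.where(date >= 0, date, nd)
    real = date >= 0
    nd_counts = np.bincount(date[real], minlength=nd).astype(float)

    # state
    col_mean = np.nanmean(np.where(mask, np.nan, Y), axis=0)
    Yimp = np.where(mask, col_mean, Y)
    mu = col_mean.copy()
    init = np.diag(np.maximum(obs_var, 1e-12)) / 4.0
    G, B, D, Q = init.copy(), init.copy(), init.copy(), init.copy()
    a = np.zeros((n_ind, k))
    b = np.zeros((n_o, k))
    d = np.zeros((nd, k))

    n_draws = (n_iter - burnin) // thin
    out_mu = np.empty((n_draws, k))
    out_cov = {nm: np.empty((n_draws, k, k)) for nm in names}
    stored = 0

    def dpad():
        return np.vstack([d, np.zeros((1, k))])

    for it in range(n_iter):
        Qinv = np.linalg.inv(Q)
        d_at = dpad()[date_idx]
        plant_eff = a[plant] + b[code]

        # impute missing trait values (including the padding rows)
        if patterns:
            fitted = mu + plant_eff + d_at
            for rows, miss in patterns:
                mi = np.flatnonzero(miss)
                oi = np.flatnonzero(~miss)
                if oi.size:
                    Qoo = Q[np.ix_(oi, oi)]
                    Qmo = Q[np.ix_(mi, oi)]
                    Wt = np.linalg.solve(Qoo, Qmo.T).T
                    resid_obs = Yimp[np.ix_(rows, oi)] - fitted[np.ix_(rows, oi)]
                    cmean = fitted[np.ix_(rows, mi)] + resid_obs @ Wt.T
                    ccov = Q[np.ix_(mi, mi)] - Wt @ Qmo.T
                else:
                    cmean = fitted[np.ix_(rows, mi)]
                    ccov = Q[np.ix_(mi, mi)]
                Lc = np.linalg.cholesky(ccov + 1e-14 * np.eye(mi.size))
                Yimp[np.ix_(rows, mi)] = (
                    cmean + rng.standard_normal(cmean.shape) @ Lc.T
                )

        # trait means (flat prior)
        resid = Yimp - plant_eff - d_at
        mu = resid.mean(axis=0) + np.linalg.cholesky(Q / n) @ rng.standard_normal(k)

        # date effects (conjugate, independent given the rest)
        Dinv = np.linalg.inv(D)
        R = Yimp - mu - plant_eff
        Sd = np.empty((nd, k))
        for c in range(k):
            Sd[:, c] = np.bincount(date[real], weights=R[real, c], minlength=nd)
        P = nd_counts[:, None, None] * Qinv + Dinv
        d = _sample_mvn_stacked(P, Sd @ Qinv, rng)
        D = sample_inv_wishart(rng, df0 + nd, scales["D_date"] + d.T @ d)

        # residual covariance
        E = Yimp - mu - plant_eff - dpad()[date_idx]
        Q = sample_inv_wishart(rng, df0 + n, scales["residual"] + E.T @ E)

        # collapsed (G, B) update followed by an exact joint redraw of (a, b)
        r = Yimp - mu - dpad()[date_idx]
        rbar = np.empty((n_o, k))
        for c in range(k):
            rbar[:, c] = np.bincount(code, weights=r[:, c], minlength=n_o) / m
        rt = U_o.T @ rbar
        G, B = marg.update_marginal(G, B, rt, rng, offset=Q / m)

        lamG = lam_o[:, None, None] * G
        C = lamG + B + Q / m
        Ka = np.linalg.solve(C, lamG)
        Kb = np.linalg.solve(C, np.broadcast_to(B, C.shape))
        mean_a = np.einsum("lji,lj->li", Ka, rt)
        mean_b = np.einsum("lji,lj->li", Kb, rt)
        Saa = lamG - np.einsum("lij,ljk->lik", lamG, Ka)
        Sab = -np.einsum("lij,ljk->lik", lamG, Kb)
        Sbb = B - np.einsum("ij,ljk->lik", B, Kb)
        J = np.empty((n_o, 2 * k, 2 * k))
        J[:, :k, :k] = Saa
        J[:, :k, k:] = Sab
        J[:, k:, :k] = np.swapaxes(Sab, 1, 2)
        J[:, k:, k:] = Sbb
        J = 0.5 * (J + np.swapaxes(J, 1, 2)) + 1e-12 * np.eye(2 * k)
        Lj = np.linalg.cholesky(J)
        z = rng.standard_normal((n_o, 2 * k))
        x = np.concatenate([mean_a, mean_b], axis=1) + np.einsum(
            "lij,lj->li", Lj, z
        )
        a_o = U_o @ x[:, :k]
        b = U_o @ x[:, k:]
        a[o] = a_o
        if rest.size:
            a[rest] = M_cond @ a_o + L_spp @ rng.standard_normal(
                (rest.size, k)
            ) @ np.linalg.cholesky(G + 1e-14 * np.eye(k)).T

        if it >= burnin and (it - burnin) % thin == 0:
            for nm, M in (("G", G), ("B", B), ("D_date", D), ("residual", Q)):
                if not np.isfinite(M).all():
                    raise RuntimeError(f"non-finite draw at iteration {it}")
                out_cov[nm][stored] = M
            out_mu[stored] = mu
            stored += 1

    return GibbsResult(
        mu=out_mu, cov=out_cov,
        n_iter=n_iter, burnin=burnin, thin=thin, seed=seed,
    )
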