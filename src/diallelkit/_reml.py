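"""Restricted maximum likelihood for Gaussian variance-component models.

The model is ``y = X beta + sum_c u_c + eps`` with ``u_c ~ N(0, sigma_c^2
Z_c Z_c')`` and ``eps ~ N(0, sigma_e^2 I)``, i.e. marginally ``y ~ N(X beta,
V)`` with ``V = sum_c sigma_c^2 K_c + sigma_e^2 I``, ``K_c = Z_c Z_c'``.

Two exact reductions keep the 7500-vial diallel fit fast:

* **Replicate collapse.**  When rows fall into groups (replicate vials of
  the same cross) within which every fixed and random design row is
  constant and the groups are balanced (equal size ``r``), the restricted
  likelihood factorizes into (i) a within-group part depending only on the
  residual variance through the pooled within sum of squares and (ii) the
  likelihood of the group means, whose covariance is
  ``M = sum_c sigma_c^2 Zc Zc' + tau^2 I`` on the collapsed designs.

* **Term folding.**  A random term whose collapsed incidence matrix is a
  permutation (one private level per group — e.g. the ordered-pair
  interaction in a replicated diallel) contributes ``sigma_c^2 I`` to
  ``M`` and is folded into the effective mean residual
  ``tau^2 = sigma_e^2 / r + sum_folded sigma_c^2``.

With ``Z`` the stacked non-folded collapsed incidence matrix (C x q),
``M^{-1}`` and ``log|M|`` come from the Woodbury identity through the
Cholesky factor of the q x q matrix ``W = tau^2 I + G^{1/2} Z'Z G^{1/2}``.
Analytic gradients use the standard identities
``d(-2l)/d theta = tr(P dV) - y'P (dV) P y``.

Components are constrained non-negative by box bounds; the optimizer is
L-BFGS-B on the variance scale (phenotype standardized internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = ["RandomTerm", "REMLOptions", "REMLResult", "REMLError",
           "REMLConvergenceError", "reml_core"]


class REMLError(RuntimeError):
    pass


class REMLConvergenceError(REMLError):
    """Optimizer failed; ``trajectory`` carries the visited -2*loglik values."""

    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class RandomTerm:
    """One random effect: a name and its n_obs x q incidence matrix."""

    name: str
    Z: sp.csr_matrix

    def __post_init__(self) -> None:
        self.Z = sp.csr_matrix(self.Z)


@dataclass
class REMLOptions:
    max_iter: int = 500
    gtol: float = 1e-6        # projected-gradient tolerance (scaled units)
    ftol: float = 1e-13
    min_variance: float = 1e-12


@dataclass
class REMLResult:
    variances: dict
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list
    converged: bool
    n_iter: int
    grad_norm: float
    trajectory: list = field(default_factory=list)
    n_obs: int = 0

    @property
    def residual(self) -> float:
        return self.variances["residual"]


def _collapse(y, X, terms, groups):
    """Group rows, verify within-group constancy, return collapsed pieces."""
    codes, _ = _factorize(groups)
    C = codes.max() + 1
    sizes = np.bincount(codes, minlength=C)
    first = np.full(C, -1, dtype=int)
    last = np.zeros(C, dtype=int)
    for idx in range(len(codes) - 1, -1, -1):
        first[codes[idx]] = idx
    for idx in range(len(codes)):
        last[codes[idx]] = idx

    balanced = sizes.min() == sizes.max()
    constant = np.allclose(X[first], X[last])
    for t in terms:
        if constant and (t.Z[first] - t.Z[last]).nnz > 0:
            constant = False
    if not (balanced and constant):
        # no reduction possible: treat every row as its own group
        n = len(y)
        return (np.arange(n), 1, y.copy(), X.copy(),
                [t.Z.copy() for t in terms], 0.0, n)

    r = int(sizes[0])
    ybar = np.bincount(codes, weights=y, minlength=C) / r
    ssw = float(np.sum(y * y) - r * np.sum(ybar * ybar))
    return codes, r, ybar, X[first], [t.Z[first] for t in terms], ssw, C


def _factorize(groups):
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq


def _is_permutation(Z: sp.csr_matrix) -> bool:
    """True when Z selects one private all-ones level per row."""
    C, q = Z.shape
    if q != C or Z.nnz != C:
        return False
    if not np.all(Z.data == 1.0):
        return False
    rows = np.diff(Z.indptr)
    if not np.all(rows == 1):
        return False
    cols = np.bincount(Z.indices, minlength=q)
    return bool(np.all(cols == 1))


def reml_core(y: np.ndarray, X: np.ndarray, terms: Sequence[RandomTerm],
              groups: Optional[np.ndarray] = None,
              start: Optional[dict] = None,
              options: Optional[REMLOptions] = None,
              fixed_names: Optional[list] = None,
              _return_objective: bool = False) -> REMLResult:
    """Fit the variance-component model by REML.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effect design (n, p).
    terms
        Random terms; each incidence matrix has n rows.
    groups
        Replicate-group labels (one per row).  Rows sharing a label must
        have identical fixed and random design rows; when group sizes
        are balanced the collapsed fast path is used, otherwise the
        full-data path.  ``None`` disables the reduction.
    start
        Optional initial variances keyed by term name plus ``residual``.
    """
    opts = options or REMLOptions()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X are not conformable")
    if np.linalg.matrix_rank(X) < p:
        raise REMLError("fixed-effect design is singular")
    for t in terms:
        if t.Z.shape[0] != n:
            raise ValueError(f"term {t.name!r} has {t.Z.shape[0]} rows, "
                             f"expected {n}")
        if t.Z.shape[1] < 2:
            raise REMLError(f"term {t.name!r} needs at least 2 levels")

    if float(np.var(y)) == 0.0:
        # degenerate: no variation to partition
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        variances = {t.name: 0.0 for t in terms}
        variances["residual"] = 0.0
        return REMLResult(
            variances=variances, loglik=math.inf, beta=beta,
            beta_cov=np.zeros((p, p)),
            fixed_names=list(fixed_names) if fixed_names is not None
            else [f"x{i}" for i in range(p)],
            converged=True, n_iter=0, grad_norm=0.0, n_obs=n)

    if groups is None:
        groups = np.arange(n)
    codes, r, ybar, Xc, Zc_list, ssw, C = _collapse(y, X, terms, groups)

    folded = [i for i, Zc in enumerate(Zc_list) if _is_permutation(Zc)]
    if folded and n == C:
        names = ", ".join(terms[i].name for i in folded)
        raise REMLError(
            f"term(s) {names} are confounded with the residual: every "
            "level has a single observation (no replication)")
    free = [i for i in range(len(terms)) if i not in folded]

    # standardize the phenotype so tolerances are scale-free
    sd2 = float(np.var(y))
    if sd2 <= 0.0:
        sd2 = 1.0
    sd = math.sqrt(sd2)
    ys = ybar / sd
    ssw_s = ssw / sd2

    if free:
        Z = sp.hstack([Zc_list[i] for i in free], format="csr")
        q = Z.shape[1]
        blocks, off = [], 0
        for i in free:
            qi = Zc_list[i].shape[1]
            blocks.append(slice(off, off + qi))
            off += qi
        S = np.asarray((Z.T @ Z).todense())
        S_diag = np.diag(S).copy()
    else:
        Z, q, blocks, S, S_diag = None, 0, [], None, None

    k = len(terms)
    names = [t.name for t in terms]
    col_term = np.concatenate(
        [np.full(Zc_list[i].shape[1], i) for i in free]
    ) if free else np.zeros(0, dtype=int)

    I_q = np.eye(q) if q else None

    def unpack(theta):
        comp = theta[:k]
        sige2 = theta[k]
        tau2 = sige2 / r + sum(comp[i] for i in folded)
        return comp, sige2, max(tau2, opts.min_variance)

    def objective(theta):
        comp, sige2, tau2 = unpack(theta)
        sige2 = max(sige2, opts.min_variance)
        if q:
            g = np.maximum(comp[col_term], 0.0)
            sg = np.sqrt(g)
            W = (sg[:, None] * S) * sg[None, :]
            W[np.diag_indices_from(W)] += tau2
            L = cholesky(W, lower=True)
            logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))
            logdetM = (C - q) * math.log(tau2) + logdetW

            def Minv(V):
                if V.ndim == 1:
                    return Minv(V[:, None])[:, 0]
                HtV = sg[:, None] * (Z.T @ V)
                t_ = cho_solve((L, True), HtV)
                return (V - Z @ (sg[:, None] * t_)) / tau2
        else:
            sg = L = None
            logdetM = C * math.log(tau2)

            def Minv(V):
                return V / tau2

        B = Minv(Xc)  # C x p
        a = Minv(ys)
        XtMinvX = Xc.T @ B
        XtMinvX = 0.5 * (XtMinvX + XtMinvX.T)
        try:
            cp = cho_factor(XtMinvX, lower=True)
        except np.linalg.LinAlgError as exc:
            raise REMLError("X'V^-1 X is singular") from exc
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cp[0]))))
        Xta = Xc.T @ a
        bhat = cho_solve(cp, Xta)
        Py = a - B @ bhat
        quad = float(ys @ Py)

        F = ((n - C) * math.log(sige2) + ssw_s / sige2 + C * math.log(r)
             + logdetM + logdet_x + quad)

        # ---- gradient ------------------------------------------------
        grad = np.zeros(k + 1)
        Lp = cp[0]
        if q:
            St = sg[:, None] * S                      # G^{1/2} S
            U = solve_triangular(L, St, lower=True)   # L^{-1} G^{1/2} S
            R = np.asarray(Z.T @ B)                   # Z' M^{-1} X
            ZtPy = np.asarray(Z.T @ Py)
            Linv = solve_triangular(L, I_q, lower=True)
            trWinv = float(np.sum(Linv * Linv))
        else:
            trWinv = 0.0

        # identity-direction pieces (folded terms, residual)
        tr_Minv = (C - q + tau2 * trWinv) / tau2
        BtB = B.T @ B
        tr_corr_I = float(np.trace(cho_solve(cp, BtB)))
        tr_P = tr_Minv - tr_corr_I
        quad_I = float(Py @ Py)
        dF_dtau2 = tr_P - quad_I

        for j, i in enumerate(free):
            sl = blocks[j]
            tr_MinvK = (float(np.sum(S_diag[sl]))
                        - float(np.sum(U[:, sl] * U[:, sl]))) / tau2
            Rc = R[sl]                                # q_c x p
            T = solve_triangular(Lp, Rc.T, lower=True)
            tr_PK = tr_MinvK - float(np.sum(T * T))
            grad[i] = tr_PK - float(np.sum(ZtPy[sl] ** 2))
        for i in folded:
            grad[i] = dF_dtau2
        grad[k] = ((n - C) / sige2 - ssw_s / sige2 ** 2 + dF_dtau2 / r)

        aux = (bhat, XtMinvX, cp)
        return F, grad, aux

    def fun(theta):
        F, grad, _ = objective(theta)
        return F, grad

    x0 = np.empty(k + 1)
    vy = float(np.var(ys) * C / max(C - 1, 1)) or 1.0
    for i, name in enumerate(names):
        if start and name in start:
            x0[i] = max(start[name] / sd2, 0.0)
        else:
            x0[i] = 0.5 * vy / max(k, 1)
    if start and "residual" in start:
        x0[k] = max(start["residual"] / sd2, opts.min_variance)
    else:
        x0[k] = 0.5 * vy
    x0 = np.maximum(x0, 1e-6)

    if _return_objective:
        return objective, x0

    trajectory: list = []

    def callback(xk):
        Fk, _, _ = objective(xk)
        trajectory.append(float(Fk))

    bounds = [(0.0, None)] * k + [(opts.min_variance, None)]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   callback=callback,
                   options={"maxiter": opts.max_iter, "ftol": opts.ftol,
                            "gtol": opts.gtol, "maxcor": 25})
    F, grad, (bhat, XtMinvX, cp) = objective(res.x)
    # projected gradient: a component pinned at its bound with an uphill
    # gradient is stationary
    proj = grad.copy()
    at_bound = res.x <= np.array([b[0] for b in bounds]) + 1e-14
    proj[at_bound & (proj > 0)] = 0.0
    stationary = float(np.max(np.abs(proj))) < 1e-2
    if not res.success and "ABNORMAL" in str(res.message).upper():
        # line-search breakdown at machine precision is acceptance-grade
        # convergence provided the projected gradient has vanished
        if not stationary:
            raise REMLConvergenceError(
                f"REML optimizer failed: {res.message}", trajectory)
    elif res.nit >= opts.max_iter:
        raise REMLConvergenceError(
            f"REML did not converge in {opts.max_iter} iterations",
            trajectory)
    theta = res.x * sd2
    variances = {name: float(theta[i]) for i, name in enumerate(names)}
    variances["residual"] = float(theta[k])
    # snap numerically-zero components to exactly zero
    for key, val in variances.items():
        if key != "residual" and val < 1e-8 * sd2:
            variances[key] = 0.0
    loglik = -0.5 * (F + (n - p) * math.log(2.0 * math.pi)
                     + (n - p) * math.log(sd2))
    beta = bhat * sd
    beta_cov = np.linalg.inv(XtMinvX) * sd2
    return REMLResult(
        variances=variances,
        loglik=float(loglik),
        beta=np.asarray(beta, dtype=float),
        beta_cov=np.asarray(beta_cov, dtype=float),
        fixed_names=list(fixed_names) if fixed_names is not None
        else [f"x{i}" for i in range(p)],
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(grad))),
        trajectory=[-0.5 * (f + (n - p) * math.log(2.0 * math.pi)
                            + (n - p) * math.log(sd2)) for f in trajectory],
        n_obs=n,
    )
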