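"""REML variance components and Henderson mixed-model equations.

The core model is the animal model on adjusted phenotypes,

    y' = X b + Z u + e,      u ~ N(0, K * sigma2_a),  e ~ N(0, I * sigma2_e),

with K either the pedigree numerator matrix A (ABLUP) or the VanRaden
genomic matrix G (GBLUP). Narrow-sense heritability is
``h2 = sigma2_a / (sigma2_a + sigma2_e)``.

Two REML engines are provided:

* :func:`reml_fit` — the single-kernel model above, solved in the eigenbasis
  of the training-set kernel so each EM or average-information (AI)
  iteration costs O(n) after one eigendecomposition; and
* :func:`reml_multi` — a dense general engine for several random terms
  (used for the design-adjustment model with random incomplete blocks plus
  an additive genetic term).

EM iterations never decrease the restricted log-likelihood; AI iterations
fall back to an EM step whenever a Newton step would leave the parameter
space or reduce the likelihood. Negative additive variance is constrained
to the zero boundary and flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "VarianceComponents",
    "FitResult",
    "reml_fit",
    "solve_mme",
    "heritability",
    "RandomTerm",
    "MultiFit",
    "reml_multi",
]


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)
    boundary: bool = False
    se_a: float = float("nan")
    se_e: float = float("nan")
    algorithm: str = "em"

    @property
    def h2(self) -> float:
        return heritability(self)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_e), the exact ratio."""
    total = vc.sigma2_a + vc.sigma2_e
    if total <= 0.0:
        raise ValueError("both variance components are zero; h2 undefined")
    return vc.sigma2_a / total


@dataclass
class FitResult:
    vc: VarianceComponents
    intercept: np.ndarray  # fixed-effect estimates (first entry: grand mean)
    ebv: pd.Series  # breeding values for every kernel id
    zero_variance: bool = False


# ---------------------------------------------------------------------------
# Single-kernel REML in the eigenbasis of K


class _EigenWorkspace:
    """Quantities of the restricted likelihood in the eigenbasis of K."""

    def __init__(self, y, K, X, eig=None):
        self.n, self.p = X.shape
        if eig is None:
            d, U = linalg.eigh(K)
        else:
            d, U = eig
        d = np.clip(d, 0.0, None)  # tiny negative eigenvalues are rounding
        self.d, self.U = d, U
        self.yt = U.T @ y
        self.Xt = U.T @ X

    def at(self, s2a: float, s2e: float) -> dict:
        d, yt, Xt = self.d, self.yt, self.Xt
        v = s2a * d + s2e
        w = 1.0 / v
        WX = Xt * w[:, None]
        M = Xt.T @ WX
        Mc = linalg.cho_factor(M)
        beta = linalg.cho_solve(Mc, WX.T @ yt)
        r = yt - Xt @ beta
        py = w * r  # P y in eigen coordinates
        ypy = float(r @ py)
        trP = float(w.sum() - np.trace(linalg.cho_solve(Mc, Xt.T @ (Xt * (w**2)[:, None]))))
        trPK = float(
            (w * d).sum()
            - np.trace(linalg.cho_solve(Mc, Xt.T @ (Xt * (w**2 * d)[:, None])))
        )
        sign, logdetM = np.linalg.slogdet(M)
        ll = -0.5 * (np.log(v).sum() + logdetM + ypy)

        def applyP(t):
            return w * t - (w * (Xt @ linalg.cho_solve(Mc, WX.T @ t)))

        return {
            "beta": beta, "py": py, "ypy": ypy, "trP": trP, "trPK": trPK,
            "ll": float(ll), "applyP": applyP,
            "yPKPy": float(py @ (d * py)), "yPPy": float(py @ py),
        }


def _boundary_fit(y, X) -> tuple[float, np.ndarray, float]:
    """sigma2_a = 0: residual variance is the OLS REML estimate RSS/(n-p)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    s2e = float(resid @ resid) / (n - p)
    return s2e, beta, s2e


def reml_fit(
    y,
    kernel,
    X: np.ndarray | None = None,
    algorithm: str = "em",
    tol: float = 1e-6,
    max_iter: int = 500,
    eig=None,
) -> VarianceComponents:
    """Maximize the restricted likelihood over (sigma2_a, sigma2_e).

    ``kernel`` is the (training-subset) relationship matrix as an ndarray or
    RelationshipMatrix; ``X`` defaults to an intercept column. ``eig`` may
    carry a precomputed ``(eigenvalues, eigenvectors)`` of the kernel, which
    repeated fits on the same individuals (e.g. a cambial-age sweep) reuse.
    """
    K = kernel.values if hasattr(kernel, "values") else np.asarray(kernel, float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    if K.shape != (n, n):
        raise ValueError("kernel dimension does not match phenotype vector")
    if X is None:
        X = np.ones((n, 1))
    if algorithm not in ("em", "ai"):
        raise ValueError("algorithm must be 'em' or 'ai'")

    ws = _EigenWorkspace(y, K, X, eig=eig)
    if ws.d.max() <= 0:
        raise ValueError("kernel is not positive semi-definite; blend it first")
    if np.ptp(ws.d) < 1e-8 * ws.d.max():
        # K proportional to I on the training set (e.g. a pedigree matrix over
        # mutually unrelated founders): sigma2_a and sigma2_e are confounded
        warnings.warn(
            "training kernel is a multiple of the identity; additive and "
            "residual variances are not separately identifiable",
            stacklevel=2,
        )
    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        raise ValueError("phenotypes have zero variance")
    s2a, s2e = vy / 2.0, vy / 2.0
    trace: list[float] = []
    converged = False
    boundary = False
    it = 0
    q = ws.at(s2a, s2e)
    trace.append(q["ll"])
    for it in range(1, max_iter + 1):
        use_em = algorithm == "em" or it <= 2
        new_a = new_e = None
        if not use_em:
            step = _ai_step(ws, q, s2a, s2e)
            if step is not None:
                cand_a, cand_e = step
                qc = ws.at(cand_a, cand_e)
                if qc["ll"] >= q["ll"] - 1e-10:
                    new_a, new_e, qn = cand_a, cand_e, qc
        if new_a is None:  # EM update (monotone in the restricted likelihood)
            new_a = s2a * (1.0 + s2a * (q["yPKPy"] - q["trPK"]) / n)
            new_e = s2e * (1.0 + s2e * (q["yPPy"] - q["trP"]) / n)
            new_a = max(new_a, 0.0)
            new_e = max(new_e, 1e-12 * vy)
            qn = ws.at(new_a, new_e)
            if algorithm == "ai" and 0.0 < new_a < s2a:
                # EM shrinks toward the boundary only geometrically; jump a
                # decade at a time while the likelihood does not decrease
                qd = ws.at(new_a * 0.1, new_e)
                if qd["ll"] >= qn["ll"] - 1e-12:
                    new_a, qn = new_a * 0.1, qd
        delta = max(abs(new_a - s2a), abs(new_e - s2e))
        s2a, s2e, q = new_a, new_e, qn
        trace.append(q["ll"])
        if s2a < 1e-4 * (s2a + s2e):
            # candidate boundary optimum: accept if the profiled likelihood
            # at sigma2_a = 0 is no worse than the current point
            s2e0, _, _ = _boundary_fit(ws.yt, ws.Xt)
            q0 = ws.at(0.0, s2e0)
            if q0["ll"] >= q["ll"] - 1e-8 or s2a < 1e-9 * vy:
                s2a, s2e, q = 0.0, s2e0, q0
                trace.append(q["ll"])
                boundary = True
                converged = True
                break
        if delta < tol * (s2a + s2e):
            converged = True
            break

    se_a = se_e = float("nan")
    if s2a > 0.0:
        AI = _ai_quantities(ws, ws.at(s2a, s2e))
        try:
            cov = np.linalg.inv(AI)
            if cov[0, 0] > 0:
                se_a = float(np.sqrt(cov[0, 0]))
            if cov[1, 1] > 0:
                se_e = float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
    return VarianceComponents(
        sigma2_a=float(s2a), sigma2_e=float(s2e), converged=converged, n_iter=it,
        loglik_trace=trace, boundary=boundary, se_a=se_a, se_e=se_e,
        algorithm=algorithm,
    )


def _ai_quantities(ws: _EigenWorkspace, q) -> np.ndarray:
    """Average-information matrix: AI_ij = y'P Gi P Gj P y / 2, with
    G_a = K (diag(d) in the eigenbasis) and G_e = I."""
    py = q["py"]
    ta = ws.d * py
    te = py
    Pta = q["applyP"](ta)
    Pte = q["applyP"](te)
    return 0.5 * np.array([[ta @ Pta, ta @ Pte], [te @ Pta, te @ Pte]])


def _ai_step(ws: _EigenWorkspace, q, s2a, s2e):
    """One Newton step with the AI matrix; None if it leaves the parameter
    space (caller then falls back to EM)."""
    scores = np.array(
        [-0.5 * (q["trPK"] - q["yPKPy"]), -0.5 * (q["trP"] - q["yPPy"])]
    )
    AI = _ai_quantities(ws, q)
    try:
        delta = np.linalg.solve(AI, scores)
    except np.linalg.LinAlgError:
        return None
    cand = np.array([s2a, s2e]) + delta
    if cand[0] < 0.0 or cand[1] <= 0.0:
        return None
    return float(cand[0]), float(cand[1])


# ---------------------------------------------------------------------------
# Henderson mixed-model equations


def solve_mme(y, kernel, train_ids, vc: VarianceComponents, X=None) -> FitResult:
    """Solve Henderson's MME for fixed effects and breeding values of every
    kernel individual (phenotyped or not).

    ``kernel`` is a RelationshipMatrix over all individuals to predict;
    ``train_ids`` names the phenotyped records in the order of ``y``.
    With ``lambda = sigma2_e / sigma2_a`` the equations are

        [ X'X   X'Z            ] [b]   [X'y]
        [ Z'X   Z'Z + lambda*Kinv ] [u] = [Z'y]
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ids = kernel.ids
    N = len(ids)
    tidx = kernel.indices(train_ids)
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    if vc.sigma2_a <= 0.0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ebv = pd.Series(np.zeros(N), index=list(ids))
        return FitResult(vc=vc, intercept=beta, ebv=ebv, zero_variance=True)

    lam = vc.sigma2_e / vc.sigma2_a
    try:
        Kc = linalg.cho_factor(kernel.values)
        Kinv = linalg.cho_solve(Kc, np.eye(N))
    except linalg.LinAlgError as exc:
        raise ValueError(
            "kernel is singular; blend toward identity or the A matrix first"
        ) from exc

    Z = np.zeros((n, N))
    Z[np.arange(n), tidx] = 1.0
    C = np.zeros((p + N, p + N))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + lam * Kinv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = linalg.solve(C, rhs, assume_a="pos")
    except linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(C, rhs, rcond=None)
    beta = sol[:p]
    u = sol[p:]
    return FitResult(vc=vc, intercept=beta, ebv=pd.Series(u, index=list(ids)))


# ---------------------------------------------------------------------------
# General dense REML for several random terms


@dataclass
class RandomTerm:
    """One random effect: incidence Z (n x q) and optional covariance K (q x q,
    identity when None)."""

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def gamma(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class MultiFit:
    variances: dict
    sigma2_e: float
    beta: np.ndarray
    blups: dict
    converged: bool
    n_iter: int
    loglik_trace: list


def reml_multi(
    y,
    X,
    terms: list[RandomTerm],
    algorithm: str = "ai",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MultiFit:
    """Dense EM/AI REML for ``y = X b + sum_i Z_i u_i + e``.

    Intended for moderate n (trial-level design-adjustment models). Each
    iteration inverts the n x n phenotypic covariance once.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    gammas = [t.gamma() for t in terms]
    qs = [t.q for t in terms]
    vy = float(np.var(y, ddof=1))
    k = len(terms)
    sig = np.full(k + 1, vy / (k + 1))  # last entry: residual
    trace: list[float] = []
    converged = False
    it = 0

    def quantities(sig):
        V = sig[-1] * np.eye(n)
        for s, G in zip(sig[:-1], gammas):
            V = V + s * G
        Vc = linalg.cho_factor(V)
        Vinv = linalg.cho_solve(Vc, np.eye(n))
        B = Vinv @ X
        M = X.T @ B
        Minv = np.linalg.inv(M)
        P = Vinv - B @ Minv @ B.T
        Py = P @ y
        logdetV = 2.0 * np.log(np.diag(Vc[0])).sum()
        sign, logdetM = np.linalg.slogdet(M)
        ll = -0.5 * (logdetV + logdetM + float(y @ Py))
        beta = Minv @ (B.T @ y)
        return P, Py, float(ll), beta

    P, Py, ll, beta = quantities(sig)
    trace.append(ll)
    for it in range(1, max_iter + 1):
        mats = gammas + [np.eye(n)]
        yPGPy = np.array([Py @ (G @ Py) for G in mats])
        trPG = np.array([float(np.sum(P * G)) for G in mats])
        new = None
        if algorithm == "ai" and it > 2:
            scores = -0.5 * (trPG - yPGPy)
            t_vecs = [G @ Py for G in mats]
            AI = 0.5 * np.array([[ti @ (P @ tj) for tj in t_vecs] for ti in t_vecs])
            try:
                delta = np.linalg.solve(AI, scores)
                cand = sig + delta
                if np.all(cand[:-1] >= 0.0) and cand[-1] > 0.0:
                    Pc, Pyc, llc, betac = quantities(cand)
                    if llc >= ll - 1e-10:
                        new = (cand, Pc, Pyc, llc, betac)
            except np.linalg.LinAlgError:
                pass
        if new is None:  # EM step
            denom = np.array(qs + [n], dtype=float)
            cand = sig * (1.0 + sig * (yPGPy - trPG) / denom)
            cand = np.maximum(cand, 0.0)
            cand[-1] = max(cand[-1], 1e-12 * vy)
            new = (cand, *quantities(cand))
        cand, Pn, Pyn, lln, betan = new
        delta = np.max(np.abs(cand - sig))
        sig, P, Py, ll, beta = cand, Pn, Pyn, lln, betan
        trace.append(ll)
        if delta < tol * sig.sum():
            converged = True
            break

    blups = {}
    for t, s in zip(terms, sig[:-1]):
        u = t.Z.T @ Py
        if t.K is not None:
            u = t.K @ u
        blups[t.name] = s * u
    return MultiFit(
        variances={t.name: float(s) for t, s in zip(terms, sig[:-1])},
        sigma2_e=float(sig[-1]),
        beta=beta,
        blups=blups,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
    )
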