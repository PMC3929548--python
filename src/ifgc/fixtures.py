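"""Stationary VAR fixtures with analytic Granger causality.

These fixtures serve as ground-truth oracles for the estimation machinery:
a known stationary VAR(p) has closed-form process covariances (from the
companion-form discrete Lyapunov equation), from which the population
version of every regression the estimator performs -- and hence the exact
GC each estimate converges to -- can be computed without simulation.

The population computations here deliberately use their own dense solver
on exact covariances; they share no code with the sample-covariance
estimation path in :mod:`ifgc.vargc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import linalg as sla


class FixtureError(RuntimeError):
    pass


@dataclass
class VarFixture:
    m: int
    p: int
    coefficients: np.ndarray      # (p, m, m)
    noise_cov: np.ndarray         # (m, m)
    analytic_gc: np.ndarray       # (m, m), [j, i] = F_{j->i} at order p
    seed: Optional[int] = None
    spectral_radius: float = float("nan")


def companion_matrix(A: np.ndarray) -> np.ndarray:
    p, m, _ = A.shape
    Phi = np.zeros((m * p, m * p))
    Phi[:m] = np.concatenate(list(A), axis=1)
    if p > 1:
        Phi[m:, :-m] = np.eye(m * (p - 1))
    return Phi


def population_covariances(A: np.ndarray, Sigma: np.ndarray,
                           max_lag: int) -> np.ndarray:
    """Exact Gamma(k) = E[x_t x_{t-k}^T], k = 0..max_lag, for the
    stationary VAR with coefficient blocks A and noise covariance Sigma."""
    p, m, _ = A.shape
    Phi = companion_matrix(A)
    if np.max(np.abs(np.linalg.eigvals(Phi))) >= 1:
        raise FixtureError("VAR model is not stationary")
    Q = np.zeros((m * p, m * p))
    Q[:m, :m] = Sigma
    S = sla.solve_discrete_lyapunov(Phi, Q)
    G = np.empty((max_lag + 1, m, m))
    for k in range(min(p, max_lag + 1)):
        G[k] = S[:m, k * m:(k + 1) * m]
    for k in range(p, max_lag + 1):
        G[k] = sum(A[u] @ G[k - 1 - u] for u in range(p))
    G[0] = 0.5 * (G[0] + G[0].T)
    return G


def _population_residual_variances(G: np.ndarray, channels, order: int):
    """Diagonal of the noise covariance of the population least-squares
    VAR(order) regression restricted to ``channels``."""
    channels = list(channels)
    sub = np.ix_(channels, channels)
    Gs = np.array([G[k][sub] for k in range(order + 1)])
    m = len(channels)
    R = np.empty((m * order, m * order))
    for u in range(order):
        for v in range(order):
            k = v - u
            R[u * m:(u + 1) * m, v * m:(v + 1) * m] = Gs[k] if k >= 0 else Gs[-k].T
    C = np.concatenate([Gs[v + 1].T for v in range(order)], axis=0)
    sol = np.linalg.solve(R, C)
    A = np.stack([sol[u * m:(u + 1) * m].T for u in range(order)])
    S = Gs[0].copy()
    for u in range(order):
        S -= A[u] @ Gs[u + 1].T
    return np.diag(S).copy()


def analytic_gc_matrix(A: np.ndarray, Sigma: np.ndarray,
                       order: Optional[int] = None) -> np.ndarray:
    """Exact conditional GC matrix of a stationary VAR, computed from its
    population covariances at the given regression order (default: the
    model order).  This is the quantity Yule-Walker estimation converges
    to at that order."""
    p, m, _ = A.shape
    q = p if order is None else int(order)
    G = population_covariances(A, Sigma, q)
    sig_jr = _population_residual_variances(G, range(m), q)
    F = np.zeros((m, m))
    for j in range(m):
        keep = [c for c in range(m) if c != j]
        sig_ar = _population_residual_variances(G, keep, q)
        for pos, i in enumerate(keep):
            F[j, i] = max(np.log(sig_ar[pos] / sig_jr[i]), 0.0)
    return F


def generate_var_fixture(m: int = 2, p: int = 2,
                         coupling_pattern: Union[str, np.ndarray] = "full",
                         seed: int = 0, target_radius: float = 0.85,
                         max_tries: int = 50) -> VarFixture:
    """Random stationary VAR(p) with its analytic GC matrix.

    ``coupling_pattern`` controls which cross terms exist: "full",
    "diagonal", or an m x m 0/1 array in source->target orientation
    (``pattern[j, i] = 1`` allows channel i to load on lagged channel j).
    Coefficients are rescaled so the companion spectral radius is
    ``target_radius`` (< 0.95, comfortably stationary).
    """
    rng = np.random.default_rng(seed)
    if isinstance(coupling_pattern, str):
        if coupling_pattern == "full":
            mask = np.ones((m, m))
        elif coupling_pattern == "diagonal":
            mask = np.eye(m)
        else:
            raise FixtureError(f"unknown pattern {coupling_pattern!r}")
    else:
        mask = np.asarray(coupling_pattern, float) + np.eye(m)
        mask = (mask > 0).astype(float)
    for _ in range(max_tries):
        A = rng.normal(0, 0.35 / np.sqrt(p), size=(p, m, m))
        A *= mask.T  # A[u][i, j] loads x_i on lagged x_j: mask is [j, i]
        rho = np.max(np.abs(np.linalg.eigvals(companion_matrix(A))))
        if rho == 0:
            rho = 1e-12
        scale = target_radius / rho
        A = A * np.array([scale ** (u + 1) for u in range(p)])[:, None, None]
        rho = np.max(np.abs(np.linalg.eigvals(companion_matrix(A))))
        if rho < 0.95:
            break
    else:
        raise FixtureError("could not generate a stationary fixture")
    Sigma = np.diag(rng.uniform(0.5, 1.5, size=m))
    F = analytic_gc_matrix(A, Sigma)
    return VarFixture(m=m, p=p, coefficients=A, noise_cov=Sigma,
                      analytic_gc=F, seed=seed, spectral_radius=float(rho))


def simulate_var(fixture: VarFixture, T: int, seed: int = 0,
                 burnin: int = 1000) -> np.ndarray:
    """Draw one realization of length T (after burn-in) from the fixture."""
    A, Sigma = fixture.coefficients, fixture.noise_cov
    p, m, _ = A.shape
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(Sigma)
    eps = rng.standard_normal((T + burnin + p, m)) @ L.T
    X = np.zeros((T + burnin + p, m))
    for t in range(p, T + burnin + p):
        x = eps[t].copy()
        for u in range(p):
            x += A[u] @ X[t - 1 - u]
        X[t] = x
    return X[p + burnin:]
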