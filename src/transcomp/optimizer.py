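"""Coordinate-ascent maximization of the trans-contact likelihood.

The joint problem is non-convex, but it splits into convex pieces: with the
Rabl coefficients and all other rows fixed, each score row C_i solves a
convex nonnegatively-constrained subproblem (handled by the projected
Newton kernel in :mod:`transcomp._kernels`); with all rows fixed, -L is
convex in (alpha, beta) and a damped Newton step suffices. Iterating
per-chromosome row sweeps and a Rabl update can only increase the
likelihood, so each restart converges to a local maximum; multiple random
restarts are compared by final likelihood.

This module exposes the numerical primitives (per-locus gradient/Hessian,
single-locus solve, Rabl Newton step) plus a functional ``fit`` wrapper
around the :class:`~transcomp.estimator.SubcompartmentModel` estimator,
which owns the outer loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import solve_row
from .genome_io import ContactTable, ExclusionSet
from .model_core import (
    CompartmentModel,
    PairSums,
    eligible_entries,
    group_cross_pairs,
    rabl_term,
)

__all__ = [
    "FitConfig",
    "locus_gradient_hessian",
    "solve_locus",
    "rabl_step",
    "rabl_standard_errors",
    "fit",
]


@dataclass
class FitConfig:
    """Settings for one model fit.

    ``seed`` is mandatory and recorded in run summaries: restarts draw their
    initial score matrices from it, and the best final likelihood wins
    (ties broken by lowest restart index).
    """

    M: int
    seed: int
    n_restarts: int = 5
    max_outer_iters: int = 100
    rel_tol: float = 1e-6
    inner_tol: float = 1e-8
    rabl_enabled: bool = True
    max_inner: int = 80

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")


def _locus_context(i, table, model, exclusions):
    """Neighbors (rows, counts) and linear term w for locus i."""
    binning = table.binning
    ei, ej, N = eligible_entries(table, exclusions)
    sel_i = ei == i
    sel_j = ej == i
    nbr = np.concatenate([ej[sel_i], ei[sel_j]])
    cnt = np.concatenate([N[sel_i], N[sel_j]])
    gp = group_cross_pairs(exclusions, binning)
    C = model.C
    ps = PairSums(C, binning, group_pairs=gp)
    c = int(binning.chrom_ids[i])
    lo = int(binning.chrom_offsets[c])
    W = ps.w_for_chrom(c, model.alpha, model.beta)
    _apply_group_w_correction(
        W, lo, int(binning.chrom_offsets[c + 1]), gp[0], gp[1], C,
        binning.r, model.alpha, model.beta,
    )
    return C[nbr], cnt, W[i - lo]


def _apply_group_w_correction(W, lo, hi, gi, gj, C, r, alpha, beta):
    """Subtract region-group partners from the linear term of a chromosome block."""
    if gi.size == 0:
        return
    for x, y in ((gi, gj), (gj, gi)):
        m = (x >= lo) & (x < hi)
        if not np.any(m):
            continue
        xa, yb = x[m], y[m]
        R = rabl_term(r[xa], r[yb], alpha, beta)
        np.subtract.at(W, xa - lo, R[:, None] * C[yb])


def locus_gradient_hessian(i, table: ContactTable, model: CompartmentModel,
                           exclusions: ExclusionSet | None = None):
    """Gradient and Hessian of the locus-i conditional log-likelihood L_i.

    G_k = sum_j N_ij C_jk / (sum_m C_im C_jm) - sum_j R_ij C_jk and
    H_kl = -sum_j N_ij C_jk C_jl / (sum_m C_im C_jm)^2; -H is positive
    semidefinite, making -L_i convex on C_i >= 0. A pair with N_ij > 0 but
    zero rate signals an infeasible iterate and raises.
    """
    Cj, N, w = _locus_context(i, table, model, exclusions)
    x = model.C[i]
    M = model.M
    if N.size:
        dots = Cj @ x
        if np.any(dots <= 0):
            raise ZeroDivisionError(
                f"locus {i}: observed pair with zero expected rate (infeasible iterate)"
            )
        G = (N / dots) @ Cj - w
        H = -(Cj * (N / dots**2)[:, None]).T @ Cj
    else:
        G = -w
        H = np.zeros((M, M))
    return G, H


def solve_locus(i, table: ContactTable, model: CompartmentModel,
                inner_tol: float = 1e-8, max_inner: int = 80,
                exclusions: ExclusionSet | None = None):
    """Solve the locus-i subproblem to KKT tolerance; returns the new row.

    The returned row never has a lower L_i than the current one.
    """
    Cj, N, w = _locus_context(i, table, model, exclusions)
    x, _res = solve_row(
        np.ascontiguousarray(Cj), N.astype(np.float64), w.astype(np.float64),
        model.C[i].astype(np.float64).copy(), inner_tol, max_inner,
    )
    return x


def _rabl_positive_everywhere(alpha, beta, p_obs, s_obs, r):
    """R > 0 on all observed pairs, and on a grid over the occupied r square."""
    if p_obs.size and np.any(1.0 + alpha * p_obs + beta * s_obs * p_obs <= 0):
        return False
    if r.size == 0:
        return True
    grid = np.linspace(float(np.min(r)), float(np.max(r)), 64)
    gx, gy = np.meshgrid(grid, grid)
    R = 1.0 + alpha * gx * gy + beta * (gx + gy) * gx * gy
    return bool(np.all(R > 0))


def _rabl_newton_core(p, s, N, dots, ps: PairSums, r, alpha, beta,
                      max_halvings=30):
    """One damped Newton update of (alpha, beta) with all C fixed.

    ``p``, ``s`` are r_i*r_j and r_i+r_j over observed eligible pairs;
    ``dots`` the Rabl-free rates sum_k C_ik C_jk. The step is halved until
    the likelihood does not decrease and R stays positive; a numerically
    singular Hessian falls back to a scaled-gradient step. Returns
    (alpha, beta, loglik at the accepted point).
    """

    def loglik(a, b):
        R = 1.0 + a * p + b * s * p
        if np.any(R * dots <= 0):
            return -np.inf
        return float(np.dot(N, np.log(R * dots)) - ps.total_expected(a, b))

    L0 = loglik(alpha, beta)
    R = 1.0 + alpha * p + beta * s * p
    Ga = float(np.dot(N, p / R)) - ps.dF_dalpha()
    Gb = float(np.dot(N, p * s / R)) - ps.dF_dbeta()
    w2 = N / R**2
    nHaa = float(np.dot(w2, p * p))
    nHbb = float(np.dot(w2, (p * s) ** 2))
    nHab = float(np.dot(w2, p * p * s))
    negH = np.array([[nHaa, nHab], [nHab, nHbb]])
    G = np.array([Ga, Gb])
    ridge = 1e-12 * (np.trace(negH) / 2.0 + 1.0)
    try:
        d = np.linalg.solve(negH + ridge * np.eye(2), G)
        if float(G @ d) <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        d = G / (np.trace(negH) / 2.0 + 1.0)  # gradient ascent fallback
    step = 1.0
    for _ in range(max_halvings):
        a, b = alpha + step * d[0], beta + step * d[1]
        if _rabl_positive_everywhere(a, b, p, s, r):
            Lc = loglik(a, b)
            if Lc >= L0:
                return a, b, Lc
        step *= 0.5
    return alpha, beta, L0


def rabl_step(table: ContactTable, model: CompartmentModel,
              exclusions: ExclusionSet | None = None):
    """One damped Newton update of the Rabl coefficients.

    Returns (alpha, beta, loglik) at the accepted point; the likelihood
    never decreases and R_ij stays positive on all eligible pairs.
    """
    binning = table.binning
    i, j, N = eligible_entries(table, exclusions)
    gp = group_cross_pairs(exclusions, binning)
    ps = PairSums(model.C, binning, group_pairs=gp)
    r = binning.r
    p = r[i] * r[j]
    s = r[i] + r[j]
    dots = np.einsum("ek,ek->e", model.C[i], model.C[j])
    return _rabl_newton_core(p, s, N, dots, ps, r, model.alpha, model.beta)


def rabl_standard_errors(table: ContactTable, model: CompartmentModel,
                         exclusions: ExclusionSet | None = None):
    """Asymptotic standard errors of (alpha, beta) from the observed information."""
    binning = table.binning
    i, j, N = eligible_entries(table, exclusions)
    r = binning.r
    p = r[i] * r[j]
    s = r[i] + r[j]
    R = rabl_term(r[i], r[j], model.alpha, model.beta)
    w2 = N / R**2
    negH = np.array(
        [
            [np.dot(w2, p * p), np.dot(w2, p * p * s)],
            [np.dot(w2, p * p * s), np.dot(w2, (p * s) ** 2)],
        ]
    )
    cov = np.linalg.inv(negH)
    return np.sqrt(np.diag(cov))


def fit(table: ContactTable, config: FitConfig,
        exclusions: ExclusionSet | None = None):
    """Fit the model under ``config``; thin wrapper over the estimator.

    Returns (CompartmentModel, info) where info holds the per-restart
    likelihood traces (non-decreasing within each restart), the chosen
    restart, iteration count and AIC.
    """
    from .estimator import SubcompartmentModel

    est = SubcompartmentModel(
        n_compartments=config.M,
        n_restarts=config.n_restarts,
        max_outer_iters=config.max_outer_iters,
        rel_tol=config.rel_tol,
        inner_tol=config.inner_tol,
        rabl=config.rabl_enabled,
        max_inner=config.max_inner,
        random_state=config.seed,
    )
    est.fit(table, exclusions=exclusions)
    model = est.to_model()
    info = {
        "trace": est.trace_,
        "traces": est.traces_,
        "best_restart": est.best_restart_,
        "restart_logliks": est.restart_logliks_,
        "loglik": est.log_likelihood_,
        "aic": est.aic_,
        "n_iter": est.n_iter_,
        "kkt_residual": est.kkt_residual_,
        "seed": config.seed,
    }
    return model, info
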