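"""Numba kernels for the per-locus convex subproblems.

Given all other score rows and the Rabl coefficients fixed, the part of the
log-likelihood involving row C_i is

    L_i(x) = sum_t N_t ln(x . c_t) - x . w        (x = C_i, x >= 0),

where c_t are the neighbor rows with observed counts N_t > 0 and
w_k = sum_j R_ij C_jk collects the closed-form zero-count term. -L_i is
convex, so the nonnegatively-constrained maximum is found by a projected
Newton iteration with backtracking; the contract is the KKT condition
(gradient <= tol at active zeros, |gradient| <= tol at free coordinates,
scaled by 1 + w_k).
"""

import numpy as np
from numba import njit

__all__ = ["solve_row", "sweep_block"]


@njit(cache=True)
def _objective(x, Cj, N, w):
    s = -np.dot(x, w)
    for t in range(N.shape[0]):
        d = np.dot(Cj[t], x)
        if d <= 0.0:
            return -np.inf
        s += N[t] * np.log(d)
    return s


@njit(cache=True)
def _grad_neghess(x, Cj, N, w, g, H):
    """Gradient of L_i and -Hessian (PSD) at x, into g and H."""
    M = x.shape[0]
    for k in range(M):
        g[k] = -w[k]
        for l in range(M):
            H[k, l] = 0.0
    for t in range(N.shape[0]):
        d = np.dot(Cj[t], x)
        a = N[t] / d
        b = a / d
        for k in range(M):
            ck = Cj[t, k]
            g[k] += a * ck
            bk = b * ck
            for l in range(M):
                H[k, l] += bk * Cj[t, l]


@njit(cache=True)
def _kkt_residual(x, g, w):
    res = 0.0
    for k in range(x.shape[0]):
        if x[k] > 0.0:
            rk = abs(g[k])
        else:
            rk = g[k] if g[k] > 0.0 else 0.0
        rk = rk / (1.0 + w[k])
        if rk > res:
            res = rk
    return res


@njit(cache=True)
def solve_row(Cj, N, w, x0, tol, max_inner):
    """Maximize L_i over x >= 0 starting from x0.

    Returns (x, kkt_residual). Never returns an iterate with a lower
    objective than a feasible x0.
    """
    M = w.shape[0]
    T = N.shape[0]
    x = x0.copy()
    if T == 0:
        # no observed reads: L_i = -x.w, maximized at 0 (w >= 0)
        return np.zeros(M), 0.0

    fx = _objective(x, Cj, N, w)
    if fx == -np.inf:
        # infeasible start (zero rate at an observed pair): nudge positive
        scale = 0.0
        for t in range(T):
            for k in range(M):
                if Cj[t, k] > scale:
                    scale = Cj[t, k]
        if scale <= 0.0:
            # a neighbor with reads but an all-zero row: structurally
            # infeasible here; leave x for the next sweep to repair
            return x, np.inf
        for k in range(M):
            if x[k] <= 0.0:
                x[k] = 1e-8 * scale + 1e-300
        fx = _objective(x, Cj, N, w)
        if fx == -np.inf:
            return x, np.inf

    g = np.empty(M)
    H = np.empty((M, M))
    res = np.inf
    for _ in range(max_inner):
        _grad_neghess(x, Cj, N, w, g, H)
        res = _kkt_residual(x, g, w)
        if res <= tol:
            break
        # free set: positive coords plus zeros with ascent direction
        nf = 0
        free = np.empty(M, dtype=np.int64)
        for k in range(M):
            if x[k] > 0.0 or g[k] > 0.0:
                free[nf] = k
                nf += 1
        if nf == 0:
            break
        gf = np.empty(nf)
        Hf = np.empty((nf, nf))
        tr = 0.0
        for a in range(nf):
            gf[a] = g[free[a]]
            for b in range(nf):
                Hf[a, b] = H[free[a], free[b]]
            tr += Hf[a, a]
        ridge = 1e-12 * (tr / nf + 1.0)
        for a in range(nf):
            Hf[a, a] += ridge
        df = np.linalg.solve(Hf, gf)
        if np.dot(gf, df) <= 0.0:
            # numerically bad Newton direction: fall back to scaled gradient
            denom = tr / nf + 1e-300
            for a in range(nf):
                df[a] = gf[a] / denom
        step = 1.0
        accepted = False
        for _ls in range(60):
            xn = x.copy()
            for a in range(nf):
                v = x[free[a]] + step * df[a]
                xn[free[a]] = v if v > 0.0 else 0.0
            fn = _objective(xn, Cj, N, w)
            if fn >= fx and fn > -np.inf:
                moved = False
                for k in range(M):
                    if xn[k] != x[k]:
                        moved = True
                        break
                x = xn
                fx = fn
                accepted = moved
                break
            step *= 0.5
        if not accepted:
            break
    _grad_neghess(x, Cj, N, w, g, H)
    return x, _kkt_residual(x, g, w)


@njit(cache=True)
def sweep_block(C, indptr, indices, data, b0, b1, W, skip, tol, max_inner):
    """Update all score rows of bins [b0, b1) in place.

    Bins on one chromosome share no trans pairs, so given every other
    chromosome fixed their subproblems are independent and the block update
    is exact coordinate ascent. ``W`` holds the per-bin linear coefficients
    (already group-corrected); ``skip`` marks blacklisted bins, which keep
    all-zero rows. Returns the max KKT residual over updated rows.
    """
    M = C.shape[1]
    maxres = 0.0
    for i in range(b0, b1):
        if skip[i]:
            for k in range(M):
                C[i, k] = 0.0
            continue
        lo = indptr[i]
        hi = indptr[i + 1]
        T = hi - lo
        if T == 0:
            for k in range(M):
                C[i, k] = 0.0
            continue
        Cj = np.empty((T, M))
        N = np.empty(T)
        for t in range(T):
            j = indices[lo + t]
            N[t] = data[lo + t]
            for k in range(M):
                Cj[t, k] = C[j, k]
        x, res = solve_row(Cj, N, W[i - b0], C[i].copy(), tol, max_inner)
        for k in range(M):
            C[i, k] = x[k]
        if res > maxres and res != np.inf:
            maxres = res
    return maxres
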