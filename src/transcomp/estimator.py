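"""Scikit-learn-style estimator for sub-compartment score inference.

:class:`SubcompartmentModel` fits the Poisson trans-contact factorization
(see :mod:`transcomp.model_core`) to a :class:`~transcomp.genome_io.ContactTable`
by coordinate ascent with random restarts. It follows the scikit-learn
estimator contract — constructor stores hyperparameters unchanged,
``fit`` returns ``self``, fitted attributes carry a trailing underscore,
``get_params``/``set_params`` come from ``BaseEstimator`` — so it composes
with sklearn model-selection utilities that treat X as an opaque object.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import sweep_block
from .genome_io import ContactTable, ExclusionSet, GenomeBinning
from .model_core import (
    CompartmentModel,
    PairSums,
    decompose,
    eligible_entries,
    group_cross_pairs,
    log_likelihood,
)
from .optimizer import _apply_group_w_correction, _rabl_newton_core

__all__ = ["SubcompartmentModel", "fit_compartment_scores"]


class SubcompartmentModel(BaseEstimator):
    """Maximum-likelihood sub-compartment probabilities from trans Hi-C contacts.

    Parameters
    ----------
    n_compartments : int, default 5
        Number of sub-compartments M.
    n_restarts : int, default 5
        Random restarts; the fit with the highest final likelihood wins,
        ties broken by lowest restart index.
    max_outer_iters : int, default 100
        Outer coordinate-ascent iterations per restart (one iteration =
        per-chromosome row sweeps plus a Rabl update).
    rel_tol : float, default 1e-6
        Stop when the outer-iteration likelihood gain drops below
        ``rel_tol * (|L| + 1)``.
    inner_tol : float, default 1e-8
        KKT tolerance of the per-locus convex subproblems (scaled by
        ``1 + w_k``).
    rabl : bool, default True
        Fit the Rabl coefficients (alpha, beta); when False both stay 0 and
        the model reduces to plain bias factorization.
    max_inner : int, default 80
        Projected-Newton iteration budget per locus subproblem.
    random_state : int, default 0
        Seed for restart initializations; fits are reproducible given the
        seed.
    verbose : int, default 0
        Print per-iteration likelihoods when > 0.

    Attributes
    ----------
    C_ : ndarray (n_bins, M)
        Fitted nonnegative score matrix, C_ik = B_i P_ik.
    alpha_, beta_ : float
        Fitted Rabl coefficients.
    B_, P_ : ndarray
        Bias vector and probability rows (rows of P_ sum to 1 where B_ > 0).
    present_ : ndarray of bool
        False for bins with no trans reads or blacklisted.
    log_likelihood_ : float
        Final log-likelihood of the best restart.
    aic_ : float
        2(nM + 2) - 2L with n the number of non-empty bins.
    trace_ : list of float
        Outer-iteration likelihoods of the best restart (non-decreasing).
    traces_ : list of list of float
        Traces of all restarts.
    n_iter_ : int
        Outer iterations used by the best restart.
    kkt_residual_ : float
        Largest per-locus KKT residual at termination of the best restart.
    """

    def __init__(self, n_compartments=5, n_restarts=5, max_outer_iters=100,
                 rel_tol=1e-6, inner_tol=1e-8, rabl=True, max_inner=80,
                 random_state=0, verbose=0):
        self.n_compartments = n_compartments
        self.n_restarts = n_restarts
        self.max_outer_iters = max_outer_iters
        self.rel_tol = rel_tol
        self.inner_tol = inner_tol
        self.rabl = rabl
        self.max_inner = max_inner
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _validate(self, X: ContactTable):
        if not isinstance(X, ContactTable):
            raise TypeError("X must be a ContactTable")
        if X.n_entries == 0:
            raise ValueError("empty ContactTable: nothing to fit")
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        binning = X.binning
        if binning.r is None:
            if self.rabl:
                raise ValueError(
                    "binning has no relative positions; call "
                    "compute_relative_positions (or fit with rabl=False)"
                )
            binning = GenomeBinning(
                binning.chrom_names, binning.chrom_lengths, binning.bin_size,
                centromere_pos=binning.centromere_pos,
                r=np.zeros(binning.n_total),
            )
        return binning

    def fit(self, X: ContactTable, y=None, exclusions: ExclusionSet | None = None):
        """Fit the factorization to a trans contact table.

        ``exclusions`` removes blacklisted bins (score rows pinned to zero)
        and within-region-group pairs from the likelihood.
        """
        binning = self._validate(X)
        M = int(self.n_compartments)
        n = binning.n_total

        i, j, N = eligible_entries(X, exclusions)
        if i.size == 0:
            raise ValueError("no eligible contacts left after exclusions")
        gp = group_cross_pairs(exclusions, binning)
        skip = (
            exclusions.blacklist_mask(n)
            if exclusions is not None
            else np.zeros(n, dtype=bool)
        )

        # symmetric CSR adjacency over eligible entries
        import scipy.sparse as sp

        a = sp.coo_matrix((N, (i, j)), shape=(n, n))
        adj = (a + a.T).tocsr()
        indptr = adj.indptr.astype(np.int64)
        indices = adj.indices.astype(np.int64)
        data = adj.data.astype(np.float64)

        t_tot = np.asarray(adj.sum(axis=1)).ravel()
        total = float(N.sum())
        self.n_nonempty_ = int(np.sum((t_tot > 0) & ~skip))

        r = binning.r
        p_obs = r[i] * r[j]
        s_obs = r[i] + r[j]

        def loglik(C, alpha, beta, ps=None):
            ps = ps or PairSums(C, binning, group_pairs=gp)
            R = 1.0 + alpha * p_obs + beta * s_obs * p_obs
            rate = R * np.einsum("ek,ek->e", C[i], C[j])
            if np.any(rate <= 0):
                return -np.inf
            return float(np.dot(N, np.log(rate)) - ps.total_expected(alpha, beta))

        seeds = np.random.SeedSequence(self.random_state).spawn(int(self.n_restarts))
        init_scale = t_tot / np.sqrt(2.0 * total * M)

        results = []
        for ridx, child in enumerate(seeds):
            rng = np.random.default_rng(child)
            C = init_scale[:, None] * rng.uniform(0.5, 1.5, size=(n, M))
            C[skip] = 0.0
            alpha, beta = 0.0, 0.0
            trace = []
            L_prev = -np.inf
            kkt = np.inf
            for it in range(int(self.max_outer_iters)):
                kkt = 0.0
                for c in range(binning.n_chroms):
                    lo = int(binning.chrom_offsets[c])
                    hi = int(binning.chrom_offsets[c + 1])
                    ps = PairSums(C, binning, group_pairs=gp)
                    W = ps.w_for_chrom(c, alpha, beta)
                    _apply_group_w_correction(
                        W, lo, hi, gp[0], gp[1], C, r, alpha, beta
                    )
                    res = sweep_block(
                        C, indptr, indices, data, lo, hi,
                        np.ascontiguousarray(W), skip,
                        float(self.inner_tol), int(self.max_inner),
                    )
                    kkt = max(kkt, res)
                ps = PairSums(C, binning, group_pairs=gp)
                if self.rabl:
                    dots = np.einsum("ek,ek->e", C[i], C[j])
                    alpha, beta, L = _rabl_newton_core(
                        p_obs, s_obs, N, dots, ps, r, alpha, beta
                    )
                else:
                    L = loglik(C, alpha, beta, ps=ps)
                trace.append(L)
                if self.verbose:
                    print(f"restart {ridx} iter {it + 1}: L = {L:.6f}")
                if L - L_prev < self.rel_tol * (abs(L) + 1.0):
                    break
                L_prev = L
            results.append(
                {"C": C, "alpha": alpha, "beta": beta, "trace": trace,
                 "loglik": trace[-1], "n_iter": len(trace), "kkt": kkt}
            )

        logliks = np.array([res["loglik"] for res in results])
        best = int(np.argmax(logliks))  # first max: lowest index wins ties
        bres = results[best]

        self.C_ = bres["C"]
        self.alpha_ = float(bres["alpha"])
        self.beta_ = float(bres["beta"])
        self.log_likelihood_ = float(bres["loglik"])
        self.trace_ = bres["trace"]
        self.traces_ = [res["trace"] for res in results]
        self.restart_logliks_ = logliks.tolist()
        self.best_restart_ = best
        self.n_iter_ = int(bres["n_iter"])
        self.kkt_residual_ = float(bres["kkt"])
        self.binning_ = binning
        self.aic_ = 2.0 * (self.n_nonempty_ * M + 2) - 2.0 * self.log_likelihood_
        B, P, present = decompose(self.to_model())
        self.B_, self.P_, self.present_ = B, P, present
        return self

    # ------------------------------------------------------------------

    def to_model(self) -> CompartmentModel:
        """The fitted parameters as a CompartmentModel value object."""
        self._check_fitted()
        return CompartmentModel(
            self.C_, alpha=self.alpha_, beta=self.beta_,
            n_nonempty=self.n_nonempty_,
        )

    def predict(self, X=None):
        """Hard sub-compartment assignment: per-bin argmax of P_.

        Ties break to the lowest compartment index; bins without data get
        label -1. X is accepted for sklearn API compatibility and ignored
        (assignments are a property of the fitted genome).
        """
        self._check_fitted()
        from .evaluation import assign_compartments

        return assign_compartments(self.P_, present=self.present_)

    def score(self, X: ContactTable, y=None,
              exclusions: ExclusionSet | None = None) -> float:
        """Log-likelihood of a contact table under the fitted model."""
        self._check_fitted()
        return log_likelihood(X, self.to_model(), exclusions=exclusions)

    def _check_fitted(self):
        if not hasattr(self, "C_"):
            raise AttributeError("SubcompartmentModel instance is not fitted yet")


def fit_compartment_scores(table, n_compartments, seed, **kwargs):
    """Functional one-call fit; thin wrapper over SubcompartmentModel."""
    exclusions = kwargs.pop("exclusions", None)
    est = SubcompartmentModel(
        n_compartments=n_compartments, random_state=seed, **kwargs
    )
    return est.fit(table, exclusions=exclusions)
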