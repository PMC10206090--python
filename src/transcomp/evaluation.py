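"""Model selection, heterogeneity quantification, and score comparison.

The number of sub-compartments M is a hyperparameter selected by AIC
(2k - 2 ln L with k = nM + 2 parameters: n non-empty bins times M scores
plus the two Rabl coefficients). Population heterogeneity of a bin is
summarized by the information content of its probability row,
IC = sum_k p_k log2(p_k M): 0 when localization is uniform (maximal
heterogeneity), log2(M) when deterministic. Because compartment labels are
arbitrary, inferred and reference score matrices are compared after
matching columns by the permutation maximizing total Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

__all__ = [
    "aic",
    "aic_value",
    "aic_sweep",
    "information_content",
    "assign_compartments",
    "matched_correlation",
]


def aic_value(n_nonempty: int, M: int, loglik: float, n_extra_params: int = 2) -> float:
    """AIC = 2k - 2 ln L with k = n*M + n_extra_params.

    The default 2 extra parameters are the Rabl coefficients, counted
    unconditionally; pass ``n_extra_params=0`` to penalize only the score
    matrix (e.g. for a Rabl-free fit).
    """
    return 2.0 * (n_nonempty * M + n_extra_params) - 2.0 * loglik


def aic(model, final_log_likelihood: float, n_extra_params: int = 2) -> float:
    """AIC of a fitted CompartmentModel (uses its n_nonempty and M)."""
    return aic_value(model.n_nonempty, model.M, final_log_likelihood,
                     n_extra_params=n_extra_params)


def aic_sweep(table, M_list, seed: int, exclusions=None, **fit_kwargs):
    """Fit each M with the same restart budget; tabulate (M, loglik, AIC).

    Returns a DataFrame with columns M, loglik, aic, n_iter and an
    ``attrs['selected_M']`` entry holding the argmin-AIC compartment number.
    Reproducible end-to-end given ``seed``.
    """
    from .estimator import SubcompartmentModel

    rows = []
    for M in M_list:
        est = SubcompartmentModel(
            n_compartments=int(M), random_state=seed, **fit_kwargs
        )
        est.fit(table, exclusions=exclusions)
        rows.append(
            {"M": int(M), "loglik": est.log_likelihood_, "aic": est.aic_,
             "n_iter": est.n_iter_}
        )
    df = pd.DataFrame(rows)
    df.attrs["selected_M"] = int(df.loc[df["aic"].idxmin(), "M"])
    return df


def information_content(P, M: int | None = None):
    """Per-bin localization certainty IC = sum_k p_k log2(p_k * M), in bits.

    Accepts a single probability row or an (n, M) matrix; rows must sum to 1
    within 1e-6 (the baseline 1/M generalizes the 5-compartment 0.2).
    0*log2(0) counts as 0. Zero rows (missing bins) return NaN. Ranges from
    0 (uniform row) to log2(M) (one-hot row).
    """
    P = np.asarray(P, dtype=np.float64)
    one_row = P.ndim == 1
    if one_row:
        P = P[None, :]
    if M is None:
        M = P.shape[1]
    if np.any(P < 0):
        raise ValueError("probabilities must be nonnegative")
    sums = P.sum(axis=1)
    nonzero = sums > 0
    if np.any(np.abs(sums[nonzero] - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(np.clip(P * M, 1e-300, None)), 0.0)
    ic = terms.sum(axis=1)
    ic[~nonzero] = np.nan
    return float(ic[0]) if one_row else ic


def assign_compartments(P, present=None):
    """Per-bin hard label: argmax of each probability row (0-based).

    Ties break to the lowest compartment index; rows that are all zero or
    flagged absent get -1.
    """
    P = np.asarray(P, dtype=np.float64)
    labels = np.argmax(P, axis=1).astype(np.int64)
    missing = P.sum(axis=1) <= 0
    if present is not None:
        missing |= ~np.asarray(present, dtype=bool)
    labels[missing] = -1
    return labels


def matched_correlation(P_inferred, P_truth):
    """Best column matching between two score matrices, plus per-column r.

    Compartment labels are arbitrary, so columns are matched by the
    permutation maximizing the total Pearson correlation (solved as a
    linear assignment). Rows where either matrix is all zero / non-finite
    are dropped pairwise. Returns (perm, r) with
    ``P_inferred[:, perm[k]]`` matched to ``P_truth[:, k]`` and ``r[k]``
    their correlation.
    """
    A = np.asarray(P_inferred, dtype=np.float64)
    B = np.asarray(P_truth, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("score matrices must have equal shapes")
    ok = (
        np.isfinite(A).all(axis=1)
        & np.isfinite(B).all(axis=1)
        & (A.sum(axis=1) > 0)
        & (B.sum(axis=1) > 0)
    )
    A, B = A[ok], B[ok]
    if A.shape[0] < 3:
        raise ValueError("fewer than 3 common bins with data on both sides")
    M = A.shape[1]
    corr = np.empty((M, M))
    for a in range(M):
        for b in range(M):
            if np.std(A[:, a]) == 0 or np.std(B[:, b]) == 0:
                corr[a, b] = 0.0
            else:
                corr[a, b] = pearsonr(A[:, a], B[:, b])[0]
    # maximize sum of r over a perfect matching (truth column b <- inferred a)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(M, dtype=np.int64)
    r = np.empty(M)
    for a, b in zip(rows, cols):
        perm[b] = a
        r[b] = corr[a, b]
    return perm, r
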