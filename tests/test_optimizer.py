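"""Derivatives, per-locus solves, Rabl updates, and full coordinate-ascent fits."""

import numpy as np
import pytest

from transcomp import (
    CompartmentModel,
    ContactTable,
    FitConfig,
    SubcompartmentModel,
    fit,
    locus_gradient_hessian,
    log_likelihood,
    make_synthetic_genome,
    matched_correlation,
    rabl_step,
    rabl_term,
    simulate_contacts,
    solve_locus,
)
from transcomp.model_core import PairSums, decompose, eligible_entries
from transcomp.optimizer import rabl_standard_errors

from conftest import calibrated_spec, random_instance


def _perturbed_loglik(table, model, i, k, h):
    C = model.C.copy()
    C[i, k] += h
    return log_likelihood(table, CompartmentModel(C, model.alpha, model.beta))


class TestLocusDerivatives:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        binning, table, model = random_instance(seed)
        i = int(table.row[0])
        G, H = locus_gradient_hessian(i, table, model)
        h = 1e-5
        for k in range(model.M):
            num = (
                _perturbed_loglik(table, model, i, k, h)
                - _perturbed_loglik(table, model, i, k, -h)
            ) / (2 * h)
            assert G[k] == pytest.approx(num, rel=1e-6, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_hessian_matches_gradient_differences(self, seed):
        binning, table, model = random_instance(seed)
        i = int(table.row[0])
        _, H = locus_gradient_hessian(i, table, model)
        h = 1e-6
        for k in range(model.M):
            Cp, Cm = model.C.copy(), model.C.copy()
            Cp[i, k] += h
            Cm[i, k] -= h
            Gp, _ = locus_gradient_hessian(
                i, table, CompartmentModel(Cp, model.alpha, model.beta))
            Gm, _ = locus_gradient_hessian(
                i, table, CompartmentModel(Cm, model.alpha, model.beta))
            num = (Gp - Gm) / (2 * h)
            assert np.allclose(H[:, k], num, rtol=1e-6, atol=1e-6)

    def test_neg_hessian_psd(self):
        for seed in range(4):
            _, table, model = random_instance(seed)
            i = int(table.row[0])
            _, H = locus_gradient_hessian(i, table, model)
            eig = np.linalg.eigvalsh(-H)
            assert eig.min() >= -1e-10 * max(1.0, eig.max())

    def test_no_reads_gradient_is_minus_w(self):
        binning, table, model = random_instance(5)
        # a locus with no observed trans reads at all
        present = set(table.row.tolist()) | set(table.col.tolist())
        i = next(b for b in range(binning.n_total) if b not in present)
        G, H = locus_gradient_hessian(i, table, model)
        assert np.all(H == 0)
        # brute-force w: sum over eligible partners of R_ij C_j
        w = np.zeros(model.M)
        for j in range(binning.n_total):
            if binning.chrom_ids[j] == binning.chrom_ids[i]:
                continue
            w += rabl_term(binning.r[i], binning.r[j], model.alpha,
                           model.beta) * model.C[j]
        assert np.allclose(G, -w, rtol=1e-10)


class TestSolveLocus:
    def test_no_reads_optimum_is_zero(self):
        binning, table, model = random_instance(6)
        present = set(table.row.tolist()) | set(table.col.tolist())
        i = next(b for b in range(binning.n_total) if b not in present)
        assert np.all(solve_locus(i, table, model) == 0.0)

    def test_single_neighbor_closed_form(self):
        # M = 1, one neighbor with N = 4 and C_j = 2, R = 1: optimum C_i = 2
        from transcomp.genome_io import GenomeBinning, compute_relative_positions

        b = compute_relative_positions(
            GenomeBinning(["a", "b"], np.array([50_000, 50_000]), 100_000)
        )
        t = ContactTable(b, np.array([0]), np.array([1]), np.array([4]))
        model = CompartmentModel(np.array([[1.0], [2.0]]), 0.0, 0.0)
        x = solve_locus(0, t, model)
        assert x[0] == pytest.approx(2.0, rel=1e-8)

    def test_beats_dense_grid(self):
        # 3 loci on 3 chromosomes, M = 2: the solved row must beat every
        # point of a dense grid on the full likelihood (independent oracle)
        binning, table, model = random_instance(
            7, n_chroms=3, bins_per_chrom=1, M=2, n_entries=3
        )
        x = solve_locus(0, table, model)
        C = model.C.copy()
        C[0] = x
        L_solved = log_likelihood(table, CompartmentModel(C, model.alpha, model.beta))
        import warnings

        grid = np.arange(0.0, 3.0, 0.01)
        best = -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for a in grid:
                for bb in grid:
                    C[0] = [a, bb]
                    L = log_likelihood(
                        table, CompartmentModel(C, model.alpha, model.beta))
                    best = max(best, L)
        assert L_solved >= best - 1e-9


class TestRablStep:
    def test_gradients_match_finite_differences(self):
        _, table, model = random_instance(8, n_entries=15)
        i, j, N = eligible_entries(table, None)
        r = table.binning.r
        p, s = r[i] * r[j], r[i] + r[j]
        ps = PairSums(model.C, table.binning)
        R = 1 + model.alpha * p + model.beta * s * p
        Ga = float(N @ (p / R)) - ps.dF_dalpha()
        Gb = float(N @ (p * s / R)) - ps.dF_dbeta()

        h = 1e-6
        def L(a, b):
            return log_likelihood(table, CompartmentModel(model.C, a, b))
        a0, b0 = model.alpha, model.beta
        assert Ga == pytest.approx((L(a0 + h, b0) - L(a0 - h, b0)) / (2 * h),
                                   rel=1e-6)
        assert Gb == pytest.approx((L(a0, b0 + h) - L(a0, b0 - h)) / (2 * h),
                                   rel=1e-6)

    def test_hessian_matches_gradient_differences(self):
        _, table, model = random_instance(9, n_entries=25)
        i, j, N = eligible_entries(table, None)
        r = table.binning.r
        p, s = r[i] * r[j], r[i] + r[j]

        def grads(a, b):
            ps = PairSums(model.C, table.binning)
            R = 1 + a * p + b * s * p
            return (float(N @ (p / R)) - ps.dF_dalpha(),
                    float(N @ (p * s / R)) - ps.dF_dbeta())

        a0, b0 = model.alpha, model.beta
        R = 1 + a0 * p + b0 * s * p
        w2 = N / R**2
        Haa = -float(w2 @ (p * p))
        Hbb = -float(w2 @ ((p * s) ** 2))
        Hab = -float(w2 @ (p * p * s))
        h = 1e-6
        nHaa = (grads(a0 + h, b0)[0] - grads(a0 - h, b0)[0]) / (2 * h)
        nHbb = (grads(a0, b0 + h)[1] - grads(a0, b0 - h)[1]) / (2 * h)
        nHab = (grads(a0, b0 + h)[0] - grads(a0, b0 - h)[0]) / (2 * h)
        assert Haa == pytest.approx(nHaa, rel=1e-6)
        assert Hbb == pytest.approx(nHbb, rel=1e-6)
        assert Hab == pytest.approx(nHab, rel=1e-6)
        # -H is PSD
        eig = np.linalg.eigvalsh(np.array([[-Haa, -Hab], [-Hab, -Hbb]]))
        assert eig.min() >= 0

    def test_step_never_decreases_likelihood(self):
        _, table, model = random_instance(10, n_entries=30)
        L0 = log_likelihood(table, model)
        a, b, L1 = rabl_step(table, model)
        assert L1 >= L0 - 1e-9 * abs(L0)
        assert L1 == pytest.approx(
            log_likelihood(table, CompartmentModel(model.C, a, b)), rel=1e-10
        )

    def test_null_rabl_recovery(self):
        # data generated without a Rabl effect: fitted (alpha, beta) within
        # 3 standard errors of zero
        binning, truth_C = make_synthetic_genome(4, 5_000_000, 100_000, 2, seed=50)
        spec = calibrated_spec(binning, truth_C, 1200, alpha=0.0, beta=0.0, seed=51)
        table = simulate_contacts(spec)
        est = SubcompartmentModel(n_compartments=2, n_restarts=2, random_state=52)
        est.fit(table)
        se = rabl_standard_errors(table, est.to_model())
        assert abs(est.alpha_) < 3 * se[0]
        assert abs(est.beta_) < 3 * se[1]

    def test_score_near_zero_at_generating_parameters(self, small_sim):
        # ML score property: the likelihood gradient at the generating
        # (alpha, beta) vanishes up to sampling noise (scaled by the
        # Fisher information)
        table = small_sim["table"]
        spec = small_sim["spec"]
        C = spec.depth_scale**0.5 * small_sim["truth_C"]
        i, j, N = eligible_entries(table, None)
        r = table.binning.r
        p, s = r[i] * r[j], r[i] + r[j]
        ps = PairSums(C, table.binning)
        R = 1 + spec.alpha * p + spec.beta * s * p
        Ga = float(N @ (p / R)) - ps.dF_dalpha()
        Gb = float(N @ (p * s / R)) - ps.dF_dbeta()
        w2 = N / R**2
        assert abs(Ga) < 4 * np.sqrt(float(w2 @ (p * p)))
        assert abs(Gb) < 4 * np.sqrt(float(w2 @ ((p * s) ** 2)))


class TestFit:
    def test_trace_monotone_and_kkt(self, small_fit):
        for trace in small_fit.traces_:
            t = np.array(trace)
            assert np.all(np.diff(t) >= -1e-8 * np.abs(t[:-1]))
        assert small_fit.kkt_residual_ <= 10 * small_fit.inner_tol

    def test_reported_loglik_is_reproducible(self, small_sim, small_fit):
        L = log_likelihood(small_sim["table"], small_fit.to_model())
        assert L == pytest.approx(small_fit.log_likelihood_, rel=1e-9)

    def test_two_compartment_recovery(self):
        # ~200 bins, 4 chromosomes, ~1e5 reads: scores recover the truth
        binning, truth_C = make_synthetic_genome(4, 5_000_000, 100_000, 2, seed=60)
        spec = calibrated_spec(binning, truth_C, 1000, alpha=0.3, beta=0.1, seed=61)
        table = simulate_contacts(spec)
        assert 5e4 < table.total_trans < 2e5
        est = SubcompartmentModel(n_compartments=2, n_restarts=3, random_state=62)
        est.fit(table)
        _, truth_P, _ = decompose(CompartmentModel(truth_C))
        _, r = matched_correlation(est.P_, truth_P)
        assert r.min() > 0.95

    def test_single_compartment_is_bias_estimation(self):
        binning, truth_C = make_synthetic_genome(4, 3_000_000, 100_000, 1, seed=70)
        spec = calibrated_spec(binning, truth_C, 800, seed=71)
        table = simulate_contacts(spec)
        est = SubcompartmentModel(n_compartments=1, n_restarts=1, rabl=False,
                                  random_state=72)
        est.fit(table)
        truth_B = truth_C.sum(axis=1)
        assert np.corrcoef(est.B_, truth_B)[0, 1] > 0.99

    def test_seed_determinism_and_restart_stability(self, small_sim):
        t = small_sim["table"]
        e1 = SubcompartmentModel(n_compartments=2, n_restarts=2, random_state=5)
        e2 = SubcompartmentModel(n_compartments=2, n_restarts=2, random_state=5)
        e1.fit(t)
        e2.fit(t)
        assert np.array_equal(e1.C_, e2.C_)
        assert e1.log_likelihood_ == e2.log_likelihood_
        # a different seed reaches the same optimum up to restart noise
        e3 = SubcompartmentModel(n_compartments=2, n_restarts=2, random_state=6)
        e3.fit(t)
        assert e3.log_likelihood_ == pytest.approx(e1.log_likelihood_, rel=5e-3)

    def test_blacklisted_rows_stay_zero(self, small_sim):
        from transcomp import ExclusionSet

        excl = ExclusionSet(blacklisted_bins=np.array([0, 10, 25]))
        est = SubcompartmentModel(n_compartments=2, n_restarts=1, random_state=1,
                                  max_outer_iters=5)
        est.fit(small_sim["table"], exclusions=excl)
        assert np.all(est.C_[[0, 10, 25]] == 0)
        assert not est.present_[0]

    def test_functional_wrapper_and_config(self, small_sim):
        cfg = FitConfig(M=2, seed=5, n_restarts=2)
        model, info = fit(small_sim["table"], cfg)
        assert model.M == 2
        assert info["loglik"] == info["trace"][-1]
        assert len(info["traces"]) == 2
        with pytest.raises(ValueError):
            FitConfig(M=0, seed=1)
        with pytest.raises(ValueError):
            FitConfig(M=2, seed=1, n_restarts=0)
        with pytest.raises(ValueError):
            FitConfig(M=2, seed=1, rel_tol=0.0)
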