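"""Solvers: fixed points, cross-consistency, sampling and FBP."""

import numpy as np
import pytest

from multitomo import (
    AcquisitionGeometry, BlockOperator, GradientOperator,
    IdentityOperator, ImageGeometry, IndicatorBox, L1Norm, L2NormSquared,
    LeastSquares, MixedL21Norm, MultiChannelImage, RadonTransform,
    ZeroFunction, allocate, cgls_run, default_pdhg_stepsizes,
    fbp_reconstruct, fista_run, pdhg_run, radon_forward, sampling_pattern,
    sirt_run, spdhg_run, warm_started_channelwise_sirt, write_trace_csv,
)
from conftest import materialize, flatten, rand_fill

IG = ImageGeometry((4, 4), 1.0, 1)


def _soft(b, tau):
    return np.sign(b) * np.maximum(np.abs(b) - tau, 0.0)


class TestFISTA:
    def test_lasso_reaches_soft_threshold(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        st = fista_run(L2NormSquared(b), 0.3 * L1Norm(),
                       allocate(IG, 0.0), max_iter=300)
        assert np.allclose(st.x.values, _soft(b.values, 0.3), atol=1e-6)

    def test_zero_g_reduces_to_gradient_descent(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        st = fista_run(L2NormSquared(b), ZeroFunction(),
                       allocate(IG, 0.0), max_iter=200)
        assert np.allclose(st.x.values, b.values, atol=1e-8)

    def test_objective_decreases_with_iterations(self, rng):
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            b = rand_fill(allocate(IG, 0.0), r)
            f, g = L2NormSquared(b), 0.2 * L1Norm()
            early = fista_run(f, g, allocate(IG, 0.0), max_iter=20)
            late = fista_run(f, g, allocate(IG, 0.0), max_iter=200)
            assert late.objective <= early.objective + 1e-12

    def test_missing_lipschitz_rejected(self, rng):
        with pytest.raises(ValueError):
            fista_run(L1Norm(), ZeroFunction(), allocate(IG, 0.0))


class TestPDHG:
    def test_default_stepsizes_satisfy_strict_inequality(self):
        for norm in (0.5, 1.0, 2.0, 17.3):
            sigma, tau = default_pdhg_stepsizes(norm)
            assert sigma == 1.0
            assert sigma * tau * norm ** 2 < 1.0
        with pytest.raises(ValueError):
            default_pdhg_stepsizes(0.0)

    def test_violating_stepsizes_warn_not_raise(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        K = IdentityOperator(IG)
        with pytest.warns(UserWarning, match="convergence"):
            pdhg_run(K, L2NormSquared(b), ZeroFunction(),
                     allocate(IG, 0.0), sigma=2.0, tau=2.0, max_iter=2)

    def test_lasso_limit(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        st = pdhg_run(IdentityOperator(IG), L2NormSquared(b),
                      0.3 * L1Norm(), allocate(IG, 0.0), max_iter=2000,
                      trace_interval=1000)
        assert np.allclose(st.x.values, _soft(b.values, 0.3), atol=1e-6)

    def test_zero_data_converges_to_zero(self):
        st = pdhg_run(IdentityOperator(IG), L2NormSquared(),
                      0.1 * L1Norm(), allocate(IG, 1.0), max_iter=500,
                      trace_interval=500)
        assert np.allclose(st.x.values, 0.0, atol=1e-8)

    def test_tgv_instance_converges_to_long_run_objective(self, rng):
        from multitomo import tgv_assembly

        ig = ImageGeometry((12, 12), 1.0, 1)
        b = rand_fill(allocate(ig, 0.0), rng)
        mask = np.ones((12, 12), dtype=bool)
        mask[5:7, 3:9] = False
        K, f, g = tgv_assembly(b, mask, 0.4, 0.2)
        x0 = allocate(K.domain, 0.0)
        short = pdhg_run(K, f, g, x0, max_iter=800, trace_interval=800)
        long = pdhg_run(K, f, g, x0, max_iter=8000, trace_interval=8000)
        assert abs(short.objective - long.objective) \
            <= 1e-3 * abs(long.objective)

    def test_trace_reproducible_and_writable(self, rng, tmp_path):
        b = rand_fill(allocate(IG, 0.0), rng)
        runs = [
            pdhg_run(IdentityOperator(IG), L2NormSquared(b), 0.3 * L1Norm(),
                     allocate(IG, 0.0), max_iter=40, trace_interval=10)
            for _ in range(2)
        ]
        assert runs[0].trace == runs[1].trace
        path = tmp_path / "trace.csv"
        write_trace_csv(runs[0], path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "iteration,objective"
        assert len(rows) == 1 + len(runs[0].trace)


class TestSPDHG:
    def test_probabilities_validated(self, rng):
        K = IdentityOperator(IG)
        f = L2NormSquared()
        with pytest.raises(ValueError):
            spdhg_run([K], [f], ZeroFunction(), [0.5],
                      allocate(IG, 0.0), max_iter=1)
        with pytest.raises(ValueError):
            spdhg_run([K], [f, f], ZeroFunction(), [1.0],
                      allocate(IG, 0.0), max_iter=1)

    def test_single_subset_reproduces_pdhg_trajectory(self, rng):
        """With one term and p = (1,), SPDHG's iterates coincide with the
        dual-extrapolated PDHG at matched step sizes."""
        b = rand_fill(allocate(IG, 0.0), rng)
        K = IdentityOperator(IG)
        f, g = L2NormSquared(b), 0.2 * L1Norm()
        spdhg = spdhg_run([K], [f], g, [1.0], allocate(IG, 0.0),
                          max_iter=60, seed=5, trace_interval=10)
        sigma = spdhg.config["sigmas"][0]
        tau = spdhg.config["tau"]
        pdhg = pdhg_run(K, f, g, allocate(IG, 0.0), sigma=sigma, tau=tau,
                        max_iter=60, extrapolation="dual", trace_interval=10)
        assert np.array_equal(spdhg.x.values, pdhg.x.values)
        assert spdhg.trace == pdhg.trace

    def test_seeded_run_is_reproducible(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        ops = [IdentityOperator(IG), GradientOperator(IG)]
        fs = [L2NormSquared(b), 0.2 * MixedL21Norm()]
        runs = [
            spdhg_run(ops, fs, ZeroFunction(), [0.5, 0.5],
                      allocate(IG, 0.0), max_iter=100, seed=9,
                      trace_interval=25)
            for _ in range(2)
        ]
        assert runs[0].trace == runs[1].trace
        assert np.array_equal(runs[0].x.values, runs[1].x.values)

    def test_balanced_sampling_frequency(self):
        """Over 10^4 draws with S = 10 the regularizer is selected at a
        rate within 3 standard errors of 0.5."""
        probs = sampling_pattern("balanced", 10)
        rng = np.random.default_rng(123)
        draws = rng.choice(len(probs), size=10_000, p=probs)
        freq = np.mean(draws == 10)
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(freq - 0.5) <= 3 * se


class TestSamplingPattern:
    def test_balanced_rule(self):
        probs = sampling_pattern("balanced", 10)
        assert probs[-1] == 0.5
        assert probs[:-1] == tuple([0.05] * 10)

    def test_uniform_rule(self):
        probs = sampling_pattern("uniform", 10)
        assert len(probs) == 11
        assert all(p == pytest.approx(1 / 11) for p in probs)

    def test_single_subset_balanced(self):
        assert sampling_pattern("balanced", 1) == (0.5, 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sampling_pattern("balanced", 0)
        with pytest.raises(ValueError):
            sampling_pattern("adaptive", 4)


class TestSIRT:
    def test_identity_fixed_point(self, rng):
        b = rand_fill(allocate(IG, 0.0), rng)
        st = sirt_run(IdentityOperator(IG), b, max_iter=50)
        assert np.allclose(st.x.values, b.values, atol=1e-10)

    def test_box_constraint_projects_solution(self):
        b = allocate(IG, -1.0)
        st = sirt_run(IdentityOperator(IG), b, max_iter=50,
                      box=(0.0, None))
        assert np.allclose(st.x.values, 0.0)

    def test_converges_to_weighted_least_squares(self, rng):
        """SIRT without constraints solves (A^T R A) x = A^T R b."""
        ig = ImageGeometry((4, 4), 1.0, 1)
        ag = AcquisitionGeometry(
            "parallel2D", tuple(np.arange(8) * 22.5), 6, 1.0)
        A = RadonTransform(ig, ag)
        mat = materialize(A)
        assert np.linalg.matrix_rank(mat) == mat.shape[1]  # unique solution
        x_true = rand_fill(allocate(ig, 0.0), rng)
        b = A.direct(x_true)
        # the weighted normal matrix has a near-null direction, so plain
        # SIRT needs many (cheap) iterations on this tiny system
        st = sirt_run(A, b, max_iter=20000, trace_interval=20000)
        row_sums = mat.sum(axis=1)
        R = np.diag(np.where(row_sums > 0, 1.0 / np.maximum(row_sums, 1e-30),
                             0.0))
        lhs = mat.T @ R @ mat
        rhs = mat.T @ R @ flatten(b)
        x_wls = np.linalg.solve(lhs, rhs)
        assert np.allclose(flatten(st.x), x_wls, atol=1e-4)

    def test_warm_start_accelerates_identical_channels(self, rng):
        """With identical channels, warm-started channels start at the
        previous solution and keep a smaller residual than a cold start."""
        ig1 = ImageGeometry((6, 6), 1.0, 1)
        ag1 = AcquisitionGeometry(
            "parallel2D", tuple(np.arange(8) * 22.5), 8, 1.0)
        A1 = RadonTransform(ig1, ag1)
        x = allocate(ig1, 0.0)
        x.values[0, 2:4, 2:4] = 1.0
        b1 = A1.direct(x)
        b_multi = allocate(
            AcquisitionGeometry("parallel2D", tuple(np.arange(8) * 22.5),
                                8, 1.0, num_channels=3), 0.0)
        for c in range(3):
            b_multi.values[c] = b1.values[0]
        iters = 15
        recon = warm_started_channelwise_sirt(A1, b_multi,
                                              iters_per_channel=iters)

        def residual(channel):
            img = MultiChannelImage(ig1, recon.values[channel:channel + 1])
            return (A1.direct(img) - b1).norm()

        assert residual(1) < residual(0)
        assert residual(2) <= residual(1) + 1e-12

    def test_zero_operator_rejected(self):
        from multitomo import ZeroOperator

        b = allocate(IG, 0.0)
        with pytest.raises(ValueError):
            sirt_run(ZeroOperator(IG, IG), b)


class TestCGLS:
    def test_exact_solve_of_materialized_system(self, rng):
        ig = ImageGeometry((2, 2), 1.0, 1)
        ag = AcquisitionGeometry("parallel2D", (0., 90.), 2, 1.0)
        A = RadonTransform(ig, ag)
        x_true = rand_fill(allocate(ig, 0.0), rng)
        b = A.direct(x_true)
        st = cgls_run(A, b, max_iter=20, tol=1e-12)
        mat = materialize(A)
        x_dense, *_ = np.linalg.lstsq(mat, flatten(b), rcond=None)
        assert np.allclose(flatten(st.x), x_dense, atol=1e-8)

    def test_zero_data_returns_zero_immediately(self):
        st = cgls_run(IdentityOperator(IG), allocate(IG, 0.0), max_iter=10)
        assert st.iterations == 0
        assert np.all(st.x.values == 0.0)

    def test_normal_residual_non_increasing(self, rng):
        ig = ImageGeometry((6, 6), 1.0, 1)
        ag = AcquisitionGeometry(
            "parallel2D", tuple(np.arange(10) * 18.0), 8, 1.0)
        A = RadonTransform(ig, ag)
        b = A.direct(rand_fill(allocate(ig, 0.0), rng))
        st = cgls_run(A, b, max_iter=40, tol=0.0, trace_interval=1)
        objectives = [obj for _, obj in st.trace]
        assert all(b2 <= a2 + 1e-10 for a2, b2 in zip(objectives,
                                                      objectives[1:]))


class TestFBP:
    def _disc(self, size=64):
        ig = ImageGeometry((size, size), 1.0, 1)
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        disc = ((yy - c) ** 2 + (xx - c) ** 2
                <= (0.35 * size) ** 2).astype(float)
        return ig, MultiChannelImage(ig, disc[None]), disc

    def test_zero_sinogram_gives_zero_image(self):
        ag = AcquisitionGeometry("parallel2D", tuple(np.arange(8) * 22.5),
                                 16, 1.0)
        out = fbp_reconstruct(allocate(ag, 0.0))
        assert np.all(out.values == 0.0)

    def test_linearity(self, rng):
        ag = AcquisitionGeometry("parallel2D", tuple(np.arange(12) * 15.0),
                                 16, 1.0, num_channels=2)
        s1 = rand_fill(allocate(ag, 0.0), rng)
        s2 = rand_fill(allocate(ag, 0.0), rng)
        combo = fbp_reconstruct(s1 * 1.7 + s2)
        parts = fbp_reconstruct(s1) * 1.7 + fbp_reconstruct(s2)
        assert np.allclose(combo.values, parts.values, atol=1e-10)

    def test_disc_reconstruction_fidelity(self):
        """Noiseless 180-view FBP of a disc: > 25 dB inside the support."""
        ig, img, disc = self._disc()
        ag = AcquisitionGeometry("parallel2D", tuple(np.arange(180) * 1.0),
                                 64, 1.0)
        rec = fbp_reconstruct(radon_forward(img, ag), ig)
        size = 64
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        support = (yy - c) ** 2 + (xx - c) ** 2 <= (0.45 * size) ** 2
        err = rec.values[0][support] - disc[support]
        psnr_db = 20 * np.log10(1.0 / np.sqrt(np.mean(err ** 2)))
        assert psnr_db > 25.0

    def test_fan_geometry_refused(self):
        ag = AcquisitionGeometry("fan2D", (0.0,), 8, 1.0, 20.0, 40.0)
        with pytest.raises(ValueError, match="parallel2D"):
            fbp_reconstruct(allocate(ag, 0.0))


class TestCrossSolverConsistency:
    """FISTA, PDHG and SPDHG must agree on the minimum of shared problems."""

    def test_denoising_instance(self, rng):
        # (1/2)||u - b||^2 + alpha VTV(u) on a 16x16 RGB image
        from multitomo import TotalVariation

        ig = ImageGeometry((16, 16), 1.0, 3)
        b = rand_fill(allocate(ig, 0.0), rng)
        alpha = 0.3
        tv = TotalVariation(alpha, inner_iter=2000, warm_start=False)
        x_fgp = tv.prox(b, 1.0)
        D = GradientOperator(ig)
        pd = pdhg_run(D, alpha * MixedL21Norm(), L2NormSquared(b),
                      allocate(ig, 0.0), max_iter=4000, trace_interval=4000)
        sp = spdhg_run([IdentityOperator(ig), D],
                       [L2NormSquared(b), alpha * MixedL21Norm()],
                       ZeroFunction(), [0.5, 0.5], allocate(ig, 0.0),
                       max_iter=8000, seed=3, trace_interval=8000)
        obj = lambda v: 0.5 * (v - b).squared_norm() + tv(v)  # noqa: E731
        ref = obj(pd.x)
        assert abs(obj(x_fgp) - ref) <= 1e-3 * abs(ref)
        assert abs(obj(sp.x) - ref) <= 1e-3 * abs(ref)

    def test_sparse_view_tv_instance(self, rng):
        # (1/2)||Au - b||^2 + alpha TV(u), u >= 0 on a 16x16 grid
        ig = ImageGeometry((16, 16), 1.0, 1)
        ag = AcquisitionGeometry("parallel2D", tuple(np.arange(8) * 22.5),
                                 16, 1.0)
        A = RadonTransform(ig, ag)
        x_true = allocate(ig, 0.0)
        x_true.values[0, 5:11, 5:11] = 1.0
        b = A.direct(x_true)
        alpha = 0.2
        D = GradientOperator(ig)
        K = BlockOperator([[A], [D]])
        from multitomo import BlockFunction

        f = BlockFunction(L2NormSquared(b), alpha * MixedL21Norm())
        g = IndicatorBox(0.0)
        pd = pdhg_run(K, f, g, allocate(ig, 0.0), max_iter=4000,
                      trace_interval=4000)
        sp = spdhg_run([A, D], [L2NormSquared(b), alpha * MixedL21Norm()],
                       g, [0.5, 0.5], allocate(ig, 0.0), max_iter=8000,
                       seed=4, trace_interval=8000)
        from multitomo import TotalVariation

        tv_fn = TotalVariation(alpha, inner_iter=100, nonneg=True)
        fi = fista_run(LeastSquares(A, b), tv_fn, allocate(ig, 0.0),
                       max_iter=400)

        def obj(v):
            return 0.5 * (A.direct(v) - b).squared_norm() \
                + alpha * MixedL21Norm()(D.direct(v)) + g(v)

        ref = obj(pd.x)
        assert abs(obj(sp.x) - ref) <= 1e-3 * max(abs(ref), 1e-3)
        assert abs(obj(fi.x) - ref) <= 1e-3 * max(abs(ref), 1e-3)
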