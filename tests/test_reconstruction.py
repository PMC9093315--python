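import numpy as np
import pytest
import scipy.sparse as sp

from headeit import forward as F
from headeit import mesh as M
from headeit import reconstruction as R


class TestSmoothnessPrior:
    def test_constant_field_in_null_space(self, head3k):
        prior = R.smoothness_prior(head3k)
        assert np.allclose(prior @ np.ones(head3k.n_elements), 0.0)

    def test_two_element_mesh(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1]])
        elements = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        mesh = M.HeadMesh(nodes, elements, np.zeros(2, dtype=np.int8))
        prior = R.smoothness_prior(mesh).toarray()
        assert prior.shape == (1, 2)
        assert sorted(prior[0]) == [-1.0, 1.0]

    def test_row_count_equals_interior_faces(self, tiny_head):
        prior = R.smoothness_prior(tiny_head)
        # independent count: faces seen by exactly two elements
        from collections import Counter
        count = Counter()
        for tet in tiny_head.elements:
            for drop in range(4):
                face = tuple(sorted(v for i, v in enumerate(tet)
                                    if i != drop))
                count[face] += 1
        assert prior.shape[0] == sum(1 for c in count.values() if c == 2)


class TestNewtonKrylovStep:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.A = rng.normal(size=(80, 50))
        self.M = self.A.T @ self.A + 1e-3 * np.eye(50)
        self.b = rng.normal(size=50)

    def test_full_subspace_matches_dense(self):
        x, _ = R.newton_krylov_step(lambda v: self.M @ v, self.b, m=50)
        xd = np.linalg.solve(self.M, self.b)
        assert np.linalg.norm(x - xd) / np.linalg.norm(xd) < 1e-8

    def test_zero_rhs_zero_step(self):
        x, _ = R.newton_krylov_step(lambda v: self.M @ v, np.zeros(50), m=10)
        assert np.all(x == 0)

    def test_residual_non_increasing_in_subspace_dimension(self):
        _, info = R.newton_krylov_step(lambda v: self.M @ v, self.b, m=50)
        r = info["residual_norms"]
        assert all(r[i + 1] <= r[i] + 1e-12 for i in range(len(r) - 1))

    def test_breakdown_flagged_and_solution_returned(self):
        # rhs is an eigenvector: the Krylov space is 1-D and Arnoldi breaks
        # down after one step with the exact solution in hand
        D = np.diag([2.0, 3.0, 4.0])
        b = np.array([1.0, 0, 0])
        x, info = R.newton_krylov_step(lambda v: D @ v, b, m=3)
        assert info["flag"] == "arnoldi_breakdown"
        assert np.allclose(x, [0.5, 0, 0], atol=1e-12)


class TestIterativeTikhonov:
    def test_matches_dense_recurrence(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5))
        b = rng.normal(size=5)
        prior = sp.eye(5).tocsr()
        lam = 0.1
        x = np.zeros(5)
        xd = np.zeros(5)
        for _ in range(2):
            x = R.iterative_tikhonov_update(x, A, b, lam, prior, m=5)
            xd = xd + np.linalg.solve(A.T @ A + lam * np.eye(5),
                                      A.T @ (b - A @ xd))
        assert np.linalg.norm(x - xd) / np.linalg.norm(xd) < 1e-10

    def test_small_lambda_converges_to_exact_solution(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        xstar = rng.normal(size=6)
        b = A @ xstar
        x = np.zeros(6)
        for _ in range(60):
            x = R.iterative_tikhonov_update(x, A, b, 1e-10, sp.eye(6).tocsr(),
                                            m=6)
        assert np.allclose(x, xstar, rtol=1e-6)

    def test_huge_lambda_freezes_iterate(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4))
        b = rng.normal(size=4)
        x0 = np.zeros(4)
        x1 = R.iterative_tikhonov_update(x0, A, b, 1e12, sp.eye(4).tocsr(),
                                         m=4)
        assert np.linalg.norm(x1 - x0) < 1e-9


class TestStepLength:
    def test_descending_step_accepted_at_full_scale(self):
        scale, flag = R.step_length(1.0, np.array([0.1]),
                                    lambda s: 0.5)
        assert scale == 1.0 and flag is None

    def test_overshooting_quadratic_halved(self):
        # f(x) = (x - 1)^2 from x=0 with step 3: full step raises the
        # residual, half step lands at 0.5 exactly
        def ev(step):
            return abs(0.0 + step[0] - 1.0)
        scale, flag = R.step_length(abs(0 - 1.0), np.array([3.0]), ev)
        assert scale == 0.5 and flag is None

    def test_exhaustion_flags_floor(self):
        scale, flag = R.step_length(1.0, np.array([1.0]), lambda s: 2.0)
        assert scale == R.ReconOptions().step_scales[-1]
        assert flag == "step_floor"


class TestTraditionalDifference:
    def test_zero_dv_gives_zero_image(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        J = F.jacobian(tiny_head, sigma, proto509)
        res = R.traditional_difference(np.zeros(len(proto509)), sigma, J,
                                       tiny_head)
        assert np.all(res.dsigma == 0)

    def test_matches_dense_direct_solve(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        J = F.jacobian(tiny_head, sigma, proto509)
        rng = np.random.default_rng(0)
        dv = 1e-5 * rng.normal(size=len(proto509))
        opts = R.ReconOptions(lam=1e-7, krylov=tiny_head.n_elements)
        res = R.traditional_difference(dv, sigma, J, tiny_head, opts)
        mask = ~tiny_head.tissue_mask("skull")
        Jm = J[:, mask]
        Rm = R.smoothness_prior(tiny_head)[:, mask].toarray()
        dense = np.linalg.solve(Jm.T @ Jm + 1e-7 * Rm.T @ Rm, Jm.T @ dv)
        assert np.linalg.norm(res.dsigma[mask] - dense) \
            / np.linalg.norm(dense) < 1e-8
        assert np.all(res.dsigma[~mask] == 0)

    def test_image_norm_non_increasing_in_lambda(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        J = F.jacobian(tiny_head, sigma, proto509)
        rng = np.random.default_rng(4)
        dv = 1e-5 * rng.normal(size=len(proto509))
        norms = []
        for lam in np.logspace(-9, 0, 10):
            opts = R.ReconOptions(lam=lam, krylov=tiny_head.n_elements)
            res = R.traditional_difference(dv, sigma, J, tiny_head, opts)
            norms.append(np.linalg.norm(res.dsigma))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(norms, norms[1:]))


class TestNonlinearDifference:
    def test_zero_dv_returns_nominal(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        res = R.nonlinear_difference(np.zeros(len(proto509)), sigma,
                                     tiny_head, proto509,
                                     R.ReconOptions(iterations=2))
        assert np.linalg.norm(res.dsigma) / np.linalg.norm(sigma) < 1e-6

    def test_matched_mesh_closed_loop_localizes(self, proto509):
        from headeit.imaging import (center_of_gravity, localization_error,
                                     remove_scalp, voxelize)
        mesh = M.place_electrodes(
            M.build_layered_head(target_elements=5000, seed=23))
        truth = M.assign_conductivities(mesh, M.simulation_tissue_table())
        center = (0.0, 0.035, 0.030)
        incl = M.embed_sphere(truth, mesh, center, 0.020, 0.65)
        dv = (F.solve_frame(mesh, incl, proto509).values
              - F.solve_frame(mesh, truth, proto509).values)
        sigma_n = M.assign_conductivities(mesh, M.DEFAULT_TISSUE_TABLE)
        res = R.nonlinear_difference(dv, sigma_n, mesh, proto509,
                                     R.ReconOptions(iterations=6))
        img = voxelize(mesh, remove_scalp(res.dsigma, mesh), 0.003)
        cog = center_of_gravity(img)
        assert localization_error(cog, center) < 30.0
        # conductive inclusion: the strongest reconstructed change is a rise
        brain = mesh.tissue_mask("grey") | mesh.tissue_mask("white")
        assert res.dsigma[brain].max() > -res.dsigma[brain].min()

    def test_skull_held_fixed(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        rng = np.random.default_rng(5)
        dv = 1e-6 * rng.normal(size=len(proto509))
        res = R.nonlinear_difference(dv, sigma, tiny_head, proto509,
                                     R.ReconOptions(iterations=2))
        assert np.all(res.dsigma[tiny_head.tissue_mask("skull")] == 0)
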