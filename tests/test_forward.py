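import numpy as np
import pytest

from headeit import forward as F
from headeit import mesh as M
from headeit import protocol as P


def _unit_tet_mesh(z=1e30):
    """Two unit tets sharing a face, with two token electrode patches.

    Enormous contact impedance makes the electrode surface terms negligible
    so the node block can be compared with the hand-assembled stiffness.
    """
    nodes = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                      [0.0, 0.0, 1.0], [1.0, 1.0, 1.0]])
    elements = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    tissue = np.array([0, 0], dtype=np.int8)
    patches = (np.array([[0, 1, 2]]), np.array([[1, 2, 4]]))
    return M.HeadMesh(nodes, elements, tissue, patches, np.array([z, z]))


def _hand_stiffness(nodes, tet, sigma):
    """P1 stiffness via the cross-product formula (independent route)."""
    x = nodes[tet]
    vol = abs(np.linalg.det(x[1:] - x[0])) / 6.0
    K = np.zeros((4, 4))
    grads = []
    for i in range(4):
        rest = [j for j in range(4) if j != i]
        n = np.cross(x[rest[1]] - x[rest[0]], x[rest[2]] - x[rest[0]])
        n = n / (n @ (x[i] - x[rest[0]]))   # affine function = 1 at node i
        grads.append(n)
    for i in range(4):
        for j in range(4):
            K[i, j] = sigma * vol * grads[i] @ grads[j]
    return K


class TestAssembly:
    def test_matrix_exactly_symmetric(self, head3k, sigma3k):
        K = F.assemble(head3k, sigma3k).matrix
        assert abs(K - K.T).max() == 0.0

    def test_assembly_linear_in_sigma(self, head3k, sigma3k):
        K1 = F.assemble(head3k, sigma3k).matrix
        K2 = F.assemble(head3k, 2 * sigma3k).matrix
        K3 = F.assemble(head3k, 3 * sigma3k).matrix
        d21 = (K2 - K1).toarray()
        d32 = (K3 - K2).toarray()
        assert np.allclose(d21, d32, rtol=1e-12, atol=1e-14)

    def test_two_element_mesh_matches_hand_assembly(self):
        mesh = _unit_tet_mesh()
        sigma = np.array([1.3, 0.7])
        K = F.assemble(mesh, sigma).matrix.toarray()[:5, :5]
        expect = np.zeros((5, 5))
        for e, s in enumerate(sigma):
            tet = mesh.elements[e]
            Ke = _hand_stiffness(mesh.nodes, tet, s)
            for a in range(4):
                for b in range(4):
                    expect[tet[a], tet[b]] += Ke[a, b]
        assert np.allclose(K, expect, rtol=1e-9, atol=1e-12)

    def test_nonpositive_sigma_rejected(self, head3k, sigma3k):
        bad = sigma3k.copy()
        bad[0] = 0.0
        with pytest.raises(ValueError):
            F.assemble(head3k, bad)


class TestSolveFrame:
    def test_reciprocity_all_combinations(self, head3k, sigma3k, proto509):
        # drive->measure equals measure->drive for every pattern/pair combo
        system = F.assemble(head3k, sigma3k)
        n = head3k.n_nodes
        pots = {}

        def potentials(a, b):
            if (a, b) not in pots:
                rhs = F._pattern_rhs(system, a, b, 1.0)
                pots[(a, b)] = system.solve(rhs)[n:]
            return pots[(a, b)]

        worst = 0.0
        for p_idx, (lo, hi) in proto509.measurements:
            pat = proto509.patterns[p_idx]
            fwd = potentials(pat.source, pat.sink)
            rev = potentials(lo, hi)
            v1 = fwd[lo - 1] - fwd[hi - 1]
            v2 = rev[pat.source - 1] - rev[pat.sink - 1]
            worst = max(worst, abs(v1 - v2) / max(abs(v1), 1e-300))
        assert worst < 1e-8

    def test_joint_scaling_of_sigma_and_contact_admittance(self, head3k,
                                                           sigma3k, proto509):
        # U(a*sigma, z/a) = U(sigma, z)/a -- exact CEM homogeneity
        from dataclasses import replace
        v1 = F.solve_frame(head3k, sigma3k, proto509).values
        scaled = replace(head3k,
                         contact_impedance=head3k.contact_impedance / 3.0)
        v3 = F.solve_frame(scaled, 3 * sigma3k, proto509).values
        assert np.allclose(v3, v1 / 3.0, rtol=1e-10)

    def test_grounding_choice_does_not_move_differences(self, head3k,
                                                        sigma3k, proto509):
        sys_a = F.assemble(head3k, sigma3k)
        sys_b = F.assemble(head3k, sigma3k)
        sys_b.ground_node = head3k.n_nodes // 2
        pat = proto509.patterns[0]
        rhs = F._pattern_rhs(sys_a, pat.source, pat.sink, 1.0)
        ua = sys_a.solve(rhs)[head3k.n_nodes:]
        ub = sys_b.solve(rhs)[head3k.n_nodes:]
        assert np.allclose(np.diff(ua), np.diff(ub), rtol=1e-8, atol=1e-14)

    def test_mesh_refinement_converges(self, proto509):
        # frames converge monotonically under refinement; the discretization
        # error at desk scale is dominated by the few-face electrode patches
        # and shrinks roughly linearly with mesh spacing
        uniform = {t: 0.3 for t in M.TISSUES}

        def frame(n):
            m = M.place_electrodes(
                M.build_layered_head(target_elements=n, seed=2))
            return F.solve_frame(
                m, M.assign_conductivities(m, uniform), proto509)

        ref = frame(16000)
        re_coarse = F.relative_error(ref, frame(3000))
        re_fine = F.relative_error(ref, frame(6000))
        assert re_fine < re_coarse < 0.5


class TestJacobian:
    def test_shape(self, head3k, sigma3k, proto546):
        J = F.jacobian(head3k, sigma3k, proto546)
        assert J.shape == (546, head3k.n_elements)
        assert np.all(np.isfinite(J))

    def test_matches_central_finite_differences(self, tiny_head, proto509):
        sigma = M.assign_conductivities(tiny_head, M.DEFAULT_TISSUE_TABLE)
        J = F.jacobian(tiny_head, sigma, proto509)
        rng = np.random.default_rng(0)
        for e in rng.choice(tiny_head.n_elements, 6, replace=False):
            h = 1e-6 * sigma[e]
            sp, sm = sigma.copy(), sigma.copy()
            sp[e] += h
            sm[e] -= h
            fd = (F.solve_frame(tiny_head, sp, proto509).values
                  - F.solve_frame(tiny_head, sm, proto509).values) / (2 * h)
            assert np.linalg.norm(fd - J[:, e]) / np.linalg.norm(fd) < 1e-3

    def test_cem_euler_identity(self, head3k, sigma3k, proto509):
        # degree -1 homogeneity of the complete electrode model:
        # J sigma + J_kappa kappa = -U
        J, u = F.jacobian(head3k, sigma3k, proto509, return_frame=True)
        Jz = F.contact_jacobian(head3k, sigma3k, proto509)
        kappa = 1.0 / head3k.contact_impedance
        resid = J @ sigma3k + Jz @ kappa + u.values
        assert np.linalg.norm(resid) / np.linalg.norm(u.values) < 1e-6

    def test_element_identity_holds_in_shunt_limit(self, head3k, sigma3k,
                                                   proto509):
        # with near-ideal electrodes the contact share of the sensitivity
        # vanishes and J sigma = -U on its own
        from dataclasses import replace
        shunt = replace(head3k,
                        contact_impedance=np.full(32, 1e-9))
        J, u = F.jacobian(shunt, sigma3k, proto509, return_frame=True)
        assert np.linalg.norm(J @ sigma3k + u.values) \
            / np.linalg.norm(u.values) < 1e-3


class TestRelativeError:
    def test_hand_examples(self):
        assert F.relative_error(np.array([3.0, 4.0]),
                                np.array([0.0, 0.0])) == 1.0
        assert F.relative_error(np.array([3.0, 4.0]),
                                np.array([3.0, 0.0])) == pytest.approx(0.8)

    def test_identity_and_scale_invariance(self):
        v = np.array([1.0, -2.0, 3.0])
        u = np.array([1.1, -1.9, 2.9])
        assert F.relative_error(v, v) == 0.0
        assert F.relative_error(5 * v, 5 * u) \
            == pytest.approx(F.relative_error(v, u))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            F.relative_error(np.zeros(3), np.ones(3))


class TestGroupJacobian:
    def test_partition_sums_to_row_sums(self, head3k, sigma3k, proto509):
        J = F.jacobian(head3k, sigma3k, proto509)
        G = F.group_jacobian(J, head3k, list(M.TISSUES))
        assert np.allclose(G.sum(axis=1), J.sum(axis=1), rtol=1e-12)

    def test_unknown_tissue_rejected(self, head3k, sigma3k, proto509):
        J = F.jacobian(head3k, sigma3k, proto509)
        with pytest.raises(KeyError):
            F.group_jacobian(J, head3k, ["bone"])

    def test_outer_layers_dominate_on_resolved_shells(self, proto509):
        # per-volume average sensitivity of scalp and skull far exceeds the
        # brain's once the shells are thick enough for the mesh to resolve
        mesh = M.place_electrodes(M.build_layered_head(
            (0.040, 0.052, 0.062, 0.071, 0.080), 16000, seed=0))
        sigma = M.assign_conductivities(mesh, M.DEFAULT_TISSUE_TABLE)
        J = F.jacobian(mesh, sigma, proto509)
        vol = mesh.element_volumes()
        per_vol = {}
        for t in M.TISSUES:
            mask = mesh.tissue_mask(t)
            per_vol[t] = np.abs(J[:, mask]).sum() / vol[mask].sum()
        brain = max(per_vol["grey"], per_vol["white"])
        assert per_vol["scalp"] > 5 * brain
        assert per_vol["skull"] > 5 * brain
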