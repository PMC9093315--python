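"""Complete-electrode-model (CEM) finite-element forward solver.

Potentials use linear (P1) tetrahedral elements with piecewise-constant
conductivity; electrodes are boundary patches with finite contact impedance.
The coupled system for nodal potentials u and electrode potentials U is

    [ A_sigma + A_z   A_v ] [u]   [0]
    [ A_v^T           A_d ] [U] = [I],

where A_sigma is the conductivity stiffness matrix and the A_z / A_v / A_d
blocks carry the contact-impedance surface integrals.  The system is grounded
by pinning one interior node to zero; measured voltage *differences* are
invariant to that choice.  One sparse LU factorization per conductivity field
is reused across all injection and adjoint solves of a frame.

Voltages are reported as rms values of the sinusoidal drive: a pattern quoted
at ``amplitude`` amperes peak-to-peak is solved at amplitude / (2*sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import HeadMesh
from .protocol import MeasurementProtocol, VoltageFrame


@dataclass
class ForwardSystem:
    """Assembled CEM system: symmetric sparse matrix over nodal + electrode
    unknowns, grounded by pinning ``ground_node``."""

    matrix: sp.csr_matrix
    n_nodes: int
    n_electrodes: int
    ground_node: int = 0

    def __post_init__(self):
        self._lu = None

    def _factor(self):
        if self._lu is None:
            n = self.matrix.shape[0]
            keep = np.ones(n, dtype=bool)
            keep[self.ground_node] = False
            self._keep = np.where(keep)[0]
            K = self.matrix[self._keep][:, self._keep].tocsc()
            self._lu = splu(K)
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve the grounded system; the pinned node's potential is zero."""
        lu = self._factor()
        x = np.zeros(self.matrix.shape[0])
        x[self._keep] = lu.solve(rhs[self._keep])
        if not np.all(np.isfinite(x)):
            raise RuntimeError("forward solve produced non-finite values: "
                               "system is singular after grounding")
        return x

    def electrode_potentials(self, rhs: np.ndarray) -> np.ndarray:
        return self.solve(rhs)[self.n_nodes:]


def _face_geometry(mesh: HeadMesh, faces: np.ndarray) -> np.ndarray:
    e1 = mesh.nodes[faces[:, 1]] - mesh.nodes[faces[:, 0]]
    e2 = mesh.nodes[faces[:, 2]] - mesh.nodes[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def assemble(mesh: HeadMesh, sigma: np.ndarray) -> ForwardSystem:
    """Assemble the CEM system matrix for a conductivity field (S/m)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError("conductivity field length must equal element count")
    if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
        raise ValueError("conductivities must be positive and finite")
    if mesh.electrode_count == 0:
        raise ValueError("mesh has no electrodes; run place_electrodes first")

    grads, vol = mesh.element_gradients()
    n, L = mesh.n_nodes, mesh.electrode_count

    # volume (stiffness) block: sigma_e * vol_e * g_i . g_j
    local = np.einsum("eic,ejc->eij", grads, grads)          # (m, 4, 4)
    local *= (sigma * vol)[:, None, None]
    rows = np.repeat(mesh.elements, 4, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 4)).ravel()
    data = [local.ravel()]
    ii = [rows]
    jj = [cols]

    # electrode surface terms
    tri_mass = (np.ones((3, 3)) + np.eye(3)) / 12.0
    for l in range(L):
        faces = mesh.electrode_faces[l]
        z = mesh.contact_impedance[l]
        areas = _face_geometry(mesh, faces)
        m_local = tri_mass[None, :, :] * (areas / z)[:, None, None]
        ii.append(np.repeat(faces, 3, axis=1).ravel())
        jj.append(np.tile(faces, (1, 3)).ravel())
        data.append(m_local.ravel())
        # coupling u -- U_l and the electrode diagonal
        w = np.repeat(areas / (3.0 * z), 3)
        fn = faces.ravel()
        col_l = np.full(len(fn), n + l)
        ii.extend([fn, col_l])
        jj.extend([col_l, fn])
        data.extend([-w, -w])
        ii.append([n + l])
        jj.append([n + l])
        data.append([areas.sum() / z])

    K = sp.coo_matrix(
        (np.concatenate([np.asarray(d, dtype=float).ravel() for d in data]),
         (np.concatenate([np.asarray(a).ravel() for a in ii]),
          np.concatenate([np.asarray(a).ravel() for a in jj]))),
        shape=(n + L, n + L)).tocsr()
    K = (K + K.T) * 0.5          # enforce exact symmetry of the assembly
    return ForwardSystem(K, n, L)


def _pattern_rhs(system: ForwardSystem, source: int, sink: int,
                 current: float) -> np.ndarray:
    rhs = np.zeros(system.matrix.shape[0])
    rhs[system.n_nodes + source - 1] = current
    rhs[system.n_nodes + sink - 1] = -current
    return rhs


def _frame_fields(mesh: HeadMesh, sigma: np.ndarray,
                  protocol: MeasurementProtocol):
    """Shared solve machinery: nodal fields per pattern and electrode
    potentials, using one factorization."""
    system = assemble(mesh, sigma)
    solutions = {}
    for p_idx, pat in enumerate(protocol.patterns):
        rhs = _pattern_rhs(system, pat.source, pat.sink, pat.rms_current)
        solutions[p_idx] = system.solve(rhs)
    return system, solutions


def solve_frame(mesh: HeadMesh, sigma: np.ndarray,
                protocol: MeasurementProtocol, index: int = 0) -> VoltageFrame:
    """Predict the frame of measured voltages U(sigma) for a protocol."""
    _, solutions = _frame_fields(mesh, sigma, protocol)
    n = mesh.n_nodes
    v = np.empty(len(protocol))
    for m_idx, (p_idx, (lo, hi)) in enumerate(protocol.measurements):
        pot = solutions[p_idx]
        v[m_idx] = pot[n + lo - 1] - pot[n + hi - 1]
    return VoltageFrame(v, index=index)


def jacobian(mesh: HeadMesh, sigma: np.ndarray,
             protocol: MeasurementProtocol,
             return_frame: bool = False):
    """Adjoint-field sensitivity matrix J (measurements x elements).

    J[m, e] = -integral over element e of grad(u_drive) . grad(u_meas),
    where u_meas is the field for a unit current injected through the
    measurement pair.  One solve per pattern plus one per distinct pair.
    """
    system, solutions = _frame_fields(mesh, sigma, protocol)
    grads, vol = mesh.element_gradients()
    n = mesh.n_nodes

    def element_grad(x):
        return np.einsum("eic,ei->ec", grads, x[mesh.elements])

    gdrive = {p: element_grad(x[:n]) for p, x in solutions.items()}
    pairs = sorted({pair for _, pair in protocol.measurements})
    gmeas_stack = np.empty((len(pairs), mesh.n_elements, 3))
    pair_index = {}
    for q, (lo, hi) in enumerate(pairs):
        rhs = _pattern_rhs(system, lo, hi, 1.0)
        gmeas_stack[q] = element_grad(system.solve(rhs)[:n])
        pair_index[(lo, hi)] = q

    J = np.empty((len(protocol), mesh.n_elements))
    by_pattern: dict[int, list[int]] = {}
    for m_idx, (p_idx, pair) in enumerate(protocol.measurements):
        by_pattern.setdefault(p_idx, []).append(m_idx)
    for p_idx, rows in by_pattern.items():
        qs = [pair_index[protocol.measurements[r][1]] for r in rows]
        J[rows] = -vol * np.einsum("qec,ec->qe", gmeas_stack[qs],
                                   gdrive[p_idx])
    if return_frame:
        v = np.empty(len(protocol))
        for m_idx, (p_idx, (lo, hi)) in enumerate(protocol.measurements):
            pot = solutions[p_idx]
            v[m_idx] = pot[n + lo - 1] - pot[n + hi - 1]
        return J, VoltageFrame(v)
    return J


def contact_jacobian(mesh: HeadMesh, sigma: np.ndarray,
                     protocol: MeasurementProtocol) -> np.ndarray:
    """Sensitivity of the measurements to the electrode contact admittances
    kappa_l = 1 / z_l (measurements x electrodes).

    dV_m/dkappa_l = -integral over patch l of (u_drive - U_drive,l)
    (u_meas - U_meas,l) dS.  Together with the element Jacobian this closes
    the degree minus-one homogeneity of the complete electrode model:
    J sigma + J_kappa kappa = -U(sigma); scaling the tissue conductivities
    alone does not scale the measurements because the contact admittances
    stay fixed.
    """
    system, solutions = _frame_fields(mesh, sigma, protocol)
    n = mesh.n_nodes
    pairs = sorted({pair for _, pair in protocol.measurements})
    sol_meas = {}
    for lo, hi in pairs:
        rhs = _pattern_rhs(system, lo, hi, 1.0)
        sol_meas[(lo, hi)] = system.solve(rhs)

    tri_mass = (np.ones((3, 3)) + np.eye(3)) / 12.0
    Jz = np.empty((len(protocol), mesh.electrode_count))
    for m_idx, (p_idx, pair) in enumerate(protocol.measurements):
        xd, xm = solutions[p_idx], sol_meas[pair]
        for l in range(mesh.electrode_count):
            faces = mesh.electrode_faces[l]
            areas = _face_geometry(mesh, faces)
            fd = xd[faces] - xd[n + l]
            fm = xm[faces] - xm[n + l]
            Jz[m_idx, l] = -np.sum(areas * np.einsum(
                "fi,ij,fj->f", fd, tri_mass, fm))
    return Jz


def relative_error(V: VoltageFrame | np.ndarray,
                   U: VoltageFrame | np.ndarray) -> float:
    """Model-data misfit ||V - U|| / ||V|| (Euclidean norms)."""
    v = V.values if isinstance(V, VoltageFrame) else np.asarray(V, float)
    u = U.values if isinstance(U, VoltageFrame) else np.asarray(U, float)
    if v.shape != u.shape:
        raise ValueError("frames must have the same length")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("reference frame has zero norm")
    return float(np.linalg.norm(v - u) / nv)


def group_jacobian(J: np.ndarray, mesh: HeadMesh,
                   tissues: list[str]) -> np.ndarray:
    """Sum Jacobian columns over each listed tissue (one column per tissue)."""
    cols = []
    for t in tissues:
        mask = mesh.tissue_mask(t)
        cols.append(J[:, mask].sum(axis=1))
    return np.stack(cols, axis=1)
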