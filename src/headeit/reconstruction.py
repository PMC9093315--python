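"""Difference imaging of conductivity change.

Two reconstruction routes are provided:

* the traditional linearized method: a single Tikhonov-regularised
  Gauss-Newton step ``dsigma = (J'J + lam R'R)^-1 J' dV`` with the Jacobian
  linearized at the nominal conductivity; and

* the nonlinear difference method: the measured change dV is added to the
  model prediction at the nominal conductivity, ``V~ = U(sigma_N) + dV``, and
  an absolute-style nonlinear inverse problem is solved for sigma~ by outer
  regularised Gauss-Newton iterations; the image is dsigma = sigma~ - sigma_N.
  Because the nominal prediction enters both the target and the model side,
  the (large, unknowable) modelling error of the head model largely cancels,
  which is what lets the method survive forward/inverse mesh mismatch.

Each Gauss-Newton step is solved by a Newton-Krylov GMRES (Arnoldi) solver
applied to the regularised normal equations in operator form -- J'J is never
materialized.  Skull elements are excluded from the update by default (their
conductivity is held at the nominal value).  Convergence is declared by
iteration count, not tolerance; a backtracking step-length rule guards
against divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_triangular

from .forward import jacobian, solve_frame
from .mesh import HeadMesh
from .protocol import MeasurementProtocol, VoltageFrame


@dataclass
class ReconOptions:
    """Solver configuration.

    lam
        Tikhonov regularisation weight (default 1e-7).  With
        ``lambda_scaling="relative"`` the effective weight is
        lam * tr(J'J) / tr(R'R), making lam a dimensionless ratio between
        the data and smoothness terms; ``"absolute"`` uses lam as-is against
        the unnormalized face-difference prior.
    iterations
        Outer Gauss-Newton iterations (default 15).
    krylov
        Krylov subspace dimension (default 200, capped at the unknown count).
    """

    lam: float = 1e-7
    iterations: int = 15
    krylov: int = 200
    lambda_scaling: str = "absolute"
    step_scales: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125)
    sigma_floor: float = 1e-4
    fixed_tissues: tuple[str, ...] = ("skull",)
    refresh_jacobian: bool = True
    krylov_tol: float = 1e-12

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.iterations < 1 or self.krylov < 1:
            raise ValueError("iterations and krylov dimension must be >= 1")


@dataclass
class ReconResult:
    """Reconstructed conductivity change plus iteration diagnostics."""

    dsigma: np.ndarray
    sigma: np.ndarray
    residual_norms: list[float] = field(default_factory=list)
    step_lengths: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def smoothness_prior(mesh: HeadMesh) -> sp.csr_matrix:
    """First-difference smoothness operator over the element adjacency graph.

    One row per interior face with +1 / -1 on the two sharing elements;
    constant fields lie in its null space.
    """
    m = mesh.n_elements
    faces = np.concatenate([
        mesh.elements[:, [0, 1, 2]], mesh.elements[:, [0, 1, 3]],
        mesh.elements[:, [0, 2, 3]], mesh.elements[:, [1, 2, 3]],
    ])
    owner = np.tile(np.arange(m), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    key, owner = key[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    a, b = owner[:-1][same], owner[1:][same]
    nrows = len(a)
    rows = np.repeat(np.arange(nrows), 2)
    cols = np.stack([a, b], axis=1).ravel()
    vals = np.tile([1.0, -1.0], nrows)
    return sp.csr_matrix((vals, (rows, cols)), shape=(nrows, m))


def newton_krylov_step(apply_A, rhs: np.ndarray, m: int,
                       x0: np.ndarray | None = None,
                       tol: float = 1e-12):
    """GMRES with Arnoldi on an m-dimensional Krylov subspace.

    ``apply_A`` is the (symmetric positive semi-definite, regularised)
    operator, applied as a callable; the matrix is never formed.  Returns
    ``(x, info)`` where info["flag"] marks Arnoldi breakdown (the current
    best iterate is returned) and info["residual_norms"] traces the
    projected residual per Krylov iteration.
    """
    rhs = np.asarray(rhs, dtype=float)
    n = len(rhs)
    m = min(m, n)
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    r0 = rhs - apply_A(x0)
    beta = np.linalg.norm(r0)
    info = {"flag": None, "residual_norms": [float(beta)]}
    if beta == 0:
        return x0.copy(), info
    V = np.empty((m + 1, n))
    H = np.zeros((m + 1, m))
    V[0] = r0 / beta
    # Givens-rotation bookkeeping for the Hessenberg least-squares problem
    cs = np.empty(m)
    sn = np.empty(m)
    g = np.zeros(m + 1)
    g[0] = beta
    k = 0
    for j in range(m):
        w = apply_A(V[j])
        # classical Gram-Schmidt with one reorthogonalization pass
        h = V[:j + 1] @ w
        w -= V[:j + 1].T @ h
        h2 = V[:j + 1] @ w
        w -= V[:j + 1].T @ h2
        h += h2
        H[:j + 1, j] = h
        hlast = np.linalg.norm(w)
        H[j + 1, j] = hlast
        k = j + 1
        # apply previous rotations to the new column, then a new one
        col = H[:j + 2, j]
        for i in range(j):
            t = cs[i] * col[i] + sn[i] * col[i + 1]
            col[i + 1] = -sn[i] * col[i] + cs[i] * col[i + 1]
            col[i] = t
        r = np.hypot(col[j], col[j + 1])
        if r == 0:
            info["flag"] = "arnoldi_breakdown"
            break
        cs[j], sn[j] = col[j] / r, col[j + 1] / r
        col[j], col[j + 1] = r, 0.0
        g[j + 1] = -sn[j] * g[j]
        g[j] = cs[j] * g[j]
        info["residual_norms"].append(float(abs(g[j + 1])))
        if hlast <= tol * beta:
            info["flag"] = "arnoldi_breakdown"
            break
        V[j + 1] = w / hlast
    if k == 0:
        return x0.copy(), info
    y = solve_triangular(H[:k, :k], g[:k], lower=False)
    return x0 + V[:k].T @ y, info


def _regularized_operator(J: np.ndarray, R, lam: float, scaling: str):
    """Operator v -> J'Jv + lam_eff R'Rv and the effective weight."""
    if scaling == "relative":
        trJJ = float(np.einsum("ij,ij->", J, J))
        RtR = (R.multiply(R)).sum() if sp.issparse(R) else float(np.sum(R * R))
        lam_eff = lam * trJJ / RtR if RtR > 0 else lam
    elif scaling == "absolute":
        lam_eff = lam
    else:
        raise ValueError(f"unknown lambda_scaling {scaling!r}")

    def apply_A(v):
        return J.T @ (J @ v) + lam_eff * (R.T @ (R @ v))

    return apply_A, lam_eff


def iterative_tikhonov_update(x_i: np.ndarray, A, b: np.ndarray, lam: float,
                              R, m: int = 200) -> np.ndarray:
    """One second-order iterative Tikhonov step,

        x_{i+1} = x_i + (A'A + lam R'R)^-1 A' (b - A x_i),

    with the inner system solved by :func:`newton_krylov_step`.
    """
    A = np.asarray(A, dtype=float)
    apply_op, _ = _regularized_operator(A, R, lam, "absolute")
    rhs = A.T @ (b - A @ x_i)
    dx, _ = newton_krylov_step(apply_op, rhs, m)
    return x_i + dx


def step_length(current_residual: float, step: np.ndarray, evaluate,
                scales: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125,
                                             0.0625, 0.03125)):
    """Backtracking rule: accept the first scale whose residual does not
    increase; at the floor, accept the floor step and flag it."""
    for s in scales:
        if evaluate(s * step) <= current_residual:
            return s, None
    return scales[-1], "step_floor"


def _update_mask(mesh: HeadMesh, opts: ReconOptions) -> np.ndarray:
    mask = np.ones(mesh.n_elements, dtype=bool)
    for t in opts.fixed_tissues:
        mask &= ~mesh.tissue_mask(t)
    return mask


def traditional_difference(dV: VoltageFrame | np.ndarray,
                           sigma_N: np.ndarray,
                           J: np.ndarray,
                           mesh: HeadMesh,
                           opts: ReconOptions | None = None) -> ReconResult:
    """One-step linearized difference image at the nominal conductivity."""
    opts = opts or ReconOptions()
    dv = dV.values if isinstance(dV, VoltageFrame) else np.asarray(dV, float)
    mask = _update_mask(mesh, opts)
    Jm = J[:, mask]
    R = smoothness_prior(mesh)[:, mask]
    apply_A, _ = _regularized_operator(Jm, R, opts.lam, opts.lambda_scaling)
    rhs = Jm.T @ dv
    x, info = newton_krylov_step(apply_A, rhs, min(opts.krylov, Jm.shape[1]),
                                 tol=opts.krylov_tol)
    dsigma = np.zeros(mesh.n_elements)
    dsigma[mask] = x
    flags = [info["flag"]] if info["flag"] else []
    return ReconResult(dsigma, sigma_N + dsigma,
                       residual_norms=[float(np.linalg.norm(dv - J @ dsigma))],
                       step_lengths=[1.0], flags=flags)


def nonlinear_difference(dV: VoltageFrame | np.ndarray,
                         sigma_N: np.ndarray,
                         mesh: HeadMesh,
                         protocol: MeasurementProtocol,
                         opts: ReconOptions | None = None) -> ReconResult:
    """Nonlinear difference image.

    Forms the target V~ = U(sigma_N) + dV and runs ``opts.iterations``
    regularised Gauss-Newton steps from sigma = sigma_N, with the Jacobian
    refreshed at each iterate (or frozen at sigma_N if
    ``opts.refresh_jacobian`` is off) and each step solved in the Krylov
    subspace.  Returns dsigma = sigma~ - sigma_N.
    """
    opts = opts or ReconOptions()
    dv = dV.values if isinstance(dV, VoltageFrame) else np.asarray(dV, float)
    u_n = solve_frame(mesh, sigma_N, protocol).values
    target = u_n + dv
    mask = _update_mask(mesh, opts)
    R = smoothness_prior(mesh)[:, mask]

    sigma = np.array(sigma_N, dtype=float, copy=True)
    result = ReconResult(np.zeros(mesh.n_elements), sigma)
    J_frozen = None
    u = u_n.copy()
    residual = float(np.linalg.norm(target - u))
    result.residual_norms.append(residual)
    for it in range(opts.iterations):
        if opts.refresh_jacobian or J_frozen is None:
            J = jacobian(mesh, sigma, protocol)
            if not opts.refresh_jacobian:
                J_frozen = J
        else:
            J = J_frozen
        Jm = J[:, mask]
        apply_A, _ = _regularized_operator(Jm, R, opts.lam,
                                           opts.lambda_scaling)
        rhs = Jm.T @ (target - u)
        dx, info = newton_krylov_step(apply_A, rhs,
                                      min(opts.krylov, Jm.shape[1]),
                                      tol=opts.krylov_tol)
        if info["flag"]:
            result.flags.append(f"iter{it}:{info['flag']}")
        step = np.zeros(mesh.n_elements)
        step[mask] = dx

        def eval_residual(s):
            trial = np.maximum(sigma + s, opts.sigma_floor)
            return float(np.linalg.norm(
                target - solve_frame(mesh, trial, protocol).values))

        scale, flag = step_length(residual, step, eval_residual,
                                  opts.step_scales)
        if flag:
            result.flags.append(f"iter{it}:{flag}")
        sigma = np.maximum(sigma + scale * step, opts.sigma_floor)
        u = solve_frame(mesh, sigma, protocol).values
        residual = float(np.linalg.norm(target - u))
        result.residual_norms.append(residual)
        result.step_lengths.append(scale)
    result.sigma = sigma
    result.dsigma = sigma - sigma_N
    return result


def l_curve(J: np.ndarray, R, dv: np.ndarray, lambdas: np.ndarray,
            krylov: int = 200, scaling: str = "relative"):
    """Residual / solution norms over a lambda sweep (single linear step).

    Returns (residual_norms, solution_norms, corner_lambda), the corner
    picked by maximum curvature in log-log coordinates.
    """
    res, sol = [], []
    for lam in lambdas:
        apply_A, _ = _regularized_operator(J, R, lam, scaling)
        x, _ = newton_krylov_step(apply_A, J.T @ dv, min(krylov, J.shape[1]))
        res.append(float(np.linalg.norm(dv - J @ x)))
        sol.append(float(np.linalg.norm(x)))
    res, sol = np.array(res), np.array(sol)
    lr, ls = np.log(res), np.log(sol)
    if len(lambdas) >= 3:
        curv = np.gradient(lr) * np.gradient(np.gradient(ls)) \
            - np.gradient(ls) * np.gradient(np.gradient(lr))
        corner = float(np.asarray(lambdas)[int(np.argmax(curv))])
    else:
        corner = float(np.asarray(lambdas)[0])
    return res, sol, corner
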