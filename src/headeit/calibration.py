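"""Nominal tissue-conductivity estimation from an averaged voltage frame.

The boundary measurements are orders of magnitude more sensitive to scalp and
skull conductivity than to CSF and brain, so only the grouped scalp and skull
values are estimated; CSF, grey and white matter are held at literature
values.  The estimator is a regularised Gauss-Newton iteration on the grouped
(per-tissue column-summed) Jacobian, evaluated by the Relative Error
||V - U(sigma)|| / ||V||.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import group_jacobian, jacobian, relative_error, solve_frame
from .mesh import DEFAULT_TISSUE_TABLE, TISSUES, HeadMesh, assign_conductivities
from .protocol import MeasurementProtocol, VoltageFrame


@dataclass
class GroupEstimate:
    """Per-tissue conductivity estimates with the RE convergence trace."""

    estimates: dict[str, float]
    re_trace: list[float] = field(default_factory=list)
    iterations: int = 0


class CalibrationDivergence(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def estimate_group_conductivities(V: VoltageFrame,
                                  mesh: HeadMesh,
                                  protocol: MeasurementProtocol,
                                  free: tuple[str, ...] = ("scalp", "skull"),
                                  fixed: dict[str, float] | None = None,
                                  lam: float = 1e-10,
                                  iters: int = 15,
                                  initial: dict[str, float] | None = None
                                  ) -> GroupEstimate:
    """Estimate grouped conductivities of the ``free`` tissues.

    ``lam`` is an identity-prior Tikhonov weight relative to tr(J'J) for the
    small grouped system; the default is effectively unregularised.  Stops
    after ``iters`` Gauss-Newton iterations; raises
    :class:`CalibrationDivergence` (with the RE trace attached) if the
    Relative Error grows for three consecutive iterations.
    """
    fixed = dict(DEFAULT_TISSUE_TABLE if fixed is None else fixed)
    unknown = set(free) - set(TISSUES)
    if unknown:
        raise ValueError(f"unknown free tissues {sorted(unknown)}")
    table = dict(fixed)
    if initial:
        table.update(initial)
    missing = [t for t in TISSUES if t not in table]
    if missing:
        raise KeyError(f"no value for tissue(s) {missing}")

    theta = np.array([table[t] for t in free], dtype=float)
    trace: list[float] = []
    grow = 0
    for it in range(iters):
        for t, v in zip(free, theta):
            table[t] = float(v)
        sigma = assign_conductivities(mesh, table)
        J, u = jacobian(mesh, sigma, protocol, return_frame=True)
        re = relative_error(V, u)
        if trace and re > max(trace[-1] * 1.01, 1e-12):
            grow += 1
            if grow >= 3:
                raise CalibrationDivergence(
                    "calibration diverged: RE increased for 3 consecutive "
                    "iterations", trace + [re])
        else:
            grow = 0
        trace.append(re)
        Jg = group_jacobian(J, mesh, list(free))
        A = Jg.T @ Jg
        A_reg = A + lam * np.trace(A) * np.eye(len(free))
        update = np.linalg.solve(A_reg, Jg.T @ (V.values - u.values))
        new = theta + update
        neg = new <= 0
        new[neg] = theta[neg] / 2.0     # positivity projection
        theta = new
    for t, v in zip(free, theta):
        table[t] = float(v)
    sigma = assign_conductivities(mesh, table)
    trace.append(relative_error(V, solve_frame(mesh, sigma, protocol)))
    return GroupEstimate({t: float(v) for t, v in zip(free, theta)},
                         re_trace=trace, iterations=iters)
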