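"""Adaptive semi-implicit time integration shared by both dynamics models.

The conserved (model-B) updates use a linearly stabilized IMEX scheme:
the true variable-mobility flux div(D phi grad mu) is taken explicitly,
and a constant-coefficient stabilization operator

    K = Mbar * (-S * L + kappa * L @ L)

is applied implicitly to the increment,

    (I + dt K) phi_new = phi_old + dt * div(D phi grad mu)|_old
                         + dt * K phi_old.

Because every term of K annihilates constants and has zero column sums,
the update conserves the total amount of the species exactly (to direct-
solver round-off) for any dt, while the implicit treatment removes the
explicit stability limits of the fourth-order kappa term and of the
uphill (spinodal) part of the bulk free energy.  S is chosen to dominate
the concave part of the bulk density and Mbar tracks the current maximum
mobility.

An adaptive controller wraps each step: a step is rejected (and dt
halved) when it produces non-finite values, fractions outside [0, 1],
a per-cell change above ``delta_max``, or -- for the free-energy-driven
formation model -- an increase of the total free energy.  Accepted steps
let dt climb back up a binary ladder toward ``dt_max`` (see
:class:`StepControls`).  Integration ends at steady state (max |dphi|/dt
below ``steady_tol``), at ``t_max``, or at the step cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .free_energy import CompositionError
from .grid import DiskMesh

PHI_TOL = 1e-9          # tolerance band around [0, 1] for produced fractions
DT_MIN = 1e-8           # abort threshold for the adaptive step size


class StepRejected(Exception):
    """Raised by a stepper when a trial step is invalid."""


class StepSizeUnderflow(RuntimeError):
    """The adaptive controller halved dt below DT_MIN."""


@dataclass(frozen=True)
class StepControls:
    """Adaptive-stepping knobs (times in simulation units).

    Step sizes live on the binary ladder dt = dt_max * 2**(-k): a
    rejected step halves dt (k += 1), and after ``grow_every``
    consecutive accepted steps dt doubles (k -= 1, floor 0).  Keeping dt
    on a small discrete set lets the implicit solvers reuse their LU
    factorizations instead of refactoring at every step.  ``dt0`` is the
    upper bound on the initial step; the starting rung is the largest
    ladder value <= dt0.
    """

    dt0: float = 0.2
    dt_max: float = 0.5
    grow_every: int = 4
    delta_max: float = 0.01
    steady_tol: float = 1e-7
    n_steps: int = 2000
    t_max: float = 400.0
    snapshot_stride: int = 50

    def initial_rung(self) -> int:
        return max(0, int(np.ceil(np.log2(self.dt_max / self.dt0) - 1e-12)))


class _LRU(dict):
    """Small insertion-ordered cache; evicts the oldest entry past maxsize."""

    def __init__(self, maxsize: int = 8):
        super().__init__()
        self.maxsize = maxsize

    def put(self, key, value):
        if len(self) >= self.maxsize:
            del self[next(iter(self))]
        self[key] = value


class ImplicitSolverCache:
    """LU factorizations of (I + dt K) keyed by (dt, Mbar).

    Mbar is rounded up to one significant digit before keying so that the
    cache stays small while still tracking the growing mobility of a
    condensing protein field.  With the controller's binary dt ladder the
    key set stays bounded; an LRU bound caps memory regardless.
    """

    def __init__(self, mesh: DiskMesh, S: float, kappa: float):
        self.mesh = mesh
        self.S = float(S)
        self.kappa = float(kappa)
        L = mesh.laplacian_matrix
        self._K_unit = (-self.S) * L
        if self.kappa > 0:
            self._K_unit = self._K_unit + self.kappa * (L @ L)
        self._K_unit = self._K_unit.tocsr()
        self._lu = _LRU()

    @staticmethod
    def _round_sig(x: float) -> float:
        if x <= 0:
            return 0.0
        mag = 10.0 ** np.floor(np.log10(x))
        return float(np.ceil(x / mag) * mag)

    def stabilized_step(self, phi: np.ndarray, explicit_rhs: np.ndarray,
                        dt: float, mobility_scale: float) -> np.ndarray:
        """Solve (I + dt Mbar K) phi_new = phi + dt*rhs + dt Mbar K phi."""
        mbar = self._round_sig(mobility_scale)
        if mbar == 0.0 or self.S == 0.0 and self.kappa == 0.0:
            return phi + dt * explicit_rhs
        key = (round(float(dt), 12), mbar)
        lu = self._lu.get(key)
        if lu is None:
            n = self.mesh.n_cells
            A = sp.eye(n, format="csr") + (dt * mbar) * self._K_unit
            lu = splu(A.tocsc())
            self._lu.put(key, lu)
        b = phi + dt * explicit_rhs + (dt * mbar) * self._K_unit.dot(phi)
        return lu.solve(b)


class DiffusionSolverCache:
    """LU factorizations of (I + dt*kd - dt*D*L) for Fickian species."""

    def __init__(self, mesh: DiskMesh, D: float, kd: float):
        self.mesh = mesh
        self.D = float(D)
        self.kd = float(kd)
        self._lu = _LRU()

    def step(self, phi: np.ndarray, production: np.ndarray,
             dt: float) -> np.ndarray:
        """Implicit diffusion + implicit decay, explicit production.

        The system matrix is an M-matrix, so non-negative inputs yield a
        non-negative result for any dt.
        """
        key = round(float(dt), 12)
        lu = self._lu.get(key)
        if lu is None:
            n = self.mesh.n_cells
            A = ((1.0 + dt * self.kd) * sp.eye(n, format="csr")
                 - (dt * self.D) * self.mesh.laplacian_matrix)
            lu = splu(A.tocsc())
            self._lu.put(key, lu)
        return lu.solve(phi + dt * production)


def check_fractions(fields: dict) -> None:
    """Reject fields that left the physical range or went non-finite."""
    for name, phi in fields.items():
        if not np.all(np.isfinite(phi)):
            raise StepRejected(f"{name} non-finite")
        if phi.min() < -PHI_TOL or phi.max() > 1.0 + PHI_TOL:
            raise StepRejected(
                f"{name} outside [0,1]: min={phi.min():.3e}, "
                f"max={phi.max():.3e}")


@dataclass
class AdaptiveResult:
    termination: str
    n_accepted: int
    n_rejected: int


def run_adaptive(fields: dict,
                 stepper: Callable[[dict, float], dict],
                 controls: StepControls,
                 on_accept: Callable[[float, float, dict], None],
                 energy: Callable[[dict], float] | None = None,
                 ) -> tuple[dict, AdaptiveResult]:
    """Drive ``stepper`` with the adaptive accept/reject controller.

    ``on_accept(t, dt, fields)`` is invoked after every accepted step;
    ``energy`` (when given) supplies the Lyapunov function whose increase
    triggers rejection.
    """
    t = 0.0
    rung = controls.initial_rung()
    max_rung = int(np.ceil(np.log2(controls.dt_max / DT_MIN)))
    consec = 0
    n_acc = n_rej = 0
    F = energy(fields) if energy is not None else None
    termination = "step_cap"
    while n_acc < controls.n_steps:
        if t >= controls.t_max * (1.0 - 1e-12):
            termination = "t_max"
            break
        dt = min(controls.dt_max * 2.0 ** (-rung), controls.t_max - t)
        try:
            new_fields = stepper(fields, dt)
            check_fractions(new_fields)
            max_delta = max(np.max(np.abs(new_fields[k] - fields[k]))
                            for k in fields)
            if max_delta > controls.delta_max:
                raise StepRejected(f"delta {max_delta:.3e} > delta_max")
            if energy is not None:
                F_new = energy(new_fields)
                if F_new > F + 1e-8 * max(1.0, abs(F)):
                    raise StepRejected(
                        f"free energy increased: {F:.6g} -> {F_new:.6g}")
        except (StepRejected, CompositionError):
            n_rej += 1
            rung += 1
            consec = 0
            if rung > max_rung:
                raise StepSizeUnderflow(
                    f"dt underflow at t={t:.4g} after {n_acc} accepted / "
                    f"{n_rej} rejected steps")
            continue
        fields = new_fields
        if energy is not None:
            F = F_new
        t += dt
        n_acc += 1
        consec += 1
        on_accept(t, dt, fields)
        if max_delta / dt < controls.steady_tol:
            termination = "steady"
            break
        if consec >= controls.grow_every and rung > 0:
            rung -= 1
            consec = 0
    else:
        termination = "step_cap"
    return fields, AdaptiveResult(termination=termination,
                                  n_accepted=n_acc, n_rejected=n_rej)
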