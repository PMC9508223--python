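"""Linear ODE model of whole-body cell trafficking.

For a generic organ *o* the vascular and interstitial concentrations obey

    V_o  dC_o/dt  = B_o (C_h - C_o)
    V~_o dC~_o/dt = e_o B_o (C_o - mu_o C~_o)

with the blood pool closing the mass balance.  Organs with special wiring
modify the template:

* portal organs send their venous outflow ``(1 - e) B C`` to the liver;
* the liver is perfused by its arterial flow plus all portal flows, the
  *effective* flow ``B' = B_art + sum(B_portal)``;
* the pulmonary circuit carries the full cardiac output (``B' = B_tot``);
* the lymph node's interstitium receives the lymphatic efflux of every
  routed organ and discharges a matching efferent flow to the heart.

The system is linear and time invariant: ``dx/dt = A x`` with ``x`` the
concentration state ``[C_h, C_o..., C~_o...]``.  The flux form of ``A``
conserves cells exactly (volume-weighted columns sum to zero), so total
cell number is an invariant of every trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .kinetics import KineticParameters
from .physiology import CirculatorySystem

__all__ = [
    "StateVector",
    "Trajectory",
    "SolverError",
    "DegenerateSystemError",
    "effective_flows",
    "flux_matrix",
    "rate_matrix",
    "ode_rhs",
    "initial_state",
    "simulate",
    "steady_state",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


class SolverError(RuntimeError):
    """ODE integration failed."""


class DegenerateSystemError(RuntimeError):
    """Rate matrix has extra null directions beyond the conserved mode."""


@dataclass(frozen=True)
class StateVector:
    """Concentrations at a single time: blood pool, vascular, interstitial."""

    t: float
    C_h: float
    C_vasc: np.ndarray
    C_int: np.ndarray

    @classmethod
    def from_flat(cls, t: float, x: np.ndarray, n_organs: int) -> "StateVector":
        return cls(t, float(x[0]), x[1 : 1 + n_organs], x[1 + n_organs :])

    def to_flat(self) -> np.ndarray:
        return np.concatenate(([self.C_h], self.C_vasc, self.C_int))

    def contents(self, system: CirculatorySystem) -> np.ndarray:
        """Cell numbers per compartment, ``V * C``."""
        return system.compartment_volumes * self.to_flat()


@dataclass(frozen=True)
class Trajectory:
    """Solution of the trafficking ODEs on a strictly increasing time grid.

    ``states`` has shape ``(len(times), n_states)`` in the flat state
    ordering ``[C_h, C_o..., C~_o...]``.
    """

    system: CirculatorySystem
    times: np.ndarray
    states: np.ndarray
    solver_info: dict

    def state_at(self, i: int) -> StateVector:
        return StateVector.from_flat(
            float(self.times[i]), self.states[i], self.system.n_organs
        )

    def total_cells(self) -> np.ndarray:
        """Total cell number at each output time (conserved quantity)."""
        return self.states @ self.system.compartment_volumes


# ---------------------------------------------------------------------------
# Flows and the rate matrix


def _perfusion_flows(system: CirculatorySystem) -> np.ndarray:
    """Blood flow actually perfusing each organ's vasculature.

    Equal to the arterial flow except for the liver, which is perfused by
    its arterial flow plus the venous flows of all portal organs.
    """
    B = system.arterial_flows.copy()
    liver = system.liver_index
    if liver is not None:
        for m in system.portal_indices:
            B[liver] += system.arterial_flows[m]
    return B


def effective_flows(
    system: CirculatorySystem, params: KineticParameters
) -> np.ndarray:
    """Effective blood flow B' per organ, used by the timescale analysis.

    Generic organs: ``B' = B``.  Liver: arterial plus portal flows.
    Pulmonary circuit: cardiac output.  Lymph node: its blood flow plus the
    total afferent lymph flow ``sum(e_o mu_o B_o)`` over routed organs.
    """
    B_eff = _perfusion_flows(system)
    ln = system.lymph_node_index
    if ln is not None:
        routed = system.routed_via_lymph_node()
        afferent = float(
            np.sum(params.e[routed] * params.mu[routed] * B_eff[routed])
        )
        B_eff[ln] += afferent
    return B_eff


def flux_matrix(system: CirculatorySystem, params: KineticParameters) -> np.ndarray:
    """Cell flux matrix F: ``F[i, j]`` is the volumetric rate (mL/h) carrying
    concentration ``j`` into compartment ``i``; columns sum to zero."""
    if not params.matches_system(system):
        raise ValueError("parameter organ order does not match system")
    n = system.n_organs
    e, mu = params.e, params.mu
    B_art = system.arterial_flows
    B_perf = _perfusion_flows(system)
    liver = system.liver_index
    ln = system.lymph_node_index
    routed = system.routed_via_lymph_node()

    HEART = 0
    vasc = 1 + np.arange(n)
    inter = 1 + n + np.arange(n)

    F = np.zeros((system.n_states, system.n_states))
    # arterial supply from the heart
    F[vasc, HEART] = B_art
    F[HEART, HEART] = -B_art.sum()
    # vascular outflow: extravasation + venous return (portal organs drain
    # into the liver instead of the heart)
    F[inter, vasc] = e * B_perf
    venous_dest = np.zeros(n, dtype=int)
    if liver is not None:
        venous_dest[list(system.portal_indices)] = vasc[liver]
    np.add.at(F, (venous_dest, vasc), (1.0 - e) * B_perf)
    F[vasc, vasc] -= B_perf
    # lymphatic efflux from the interstitium
    g = e * mu * B_perf
    lymph_dest = np.where(routed, inter[ln] if ln is not None else HEART, HEART)
    np.add.at(F, (lymph_dest, inter), g)
    F[inter, inter] -= g
    if ln is not None:
        # afferent lymph passes through the node and leaves as efferent flow
        afferent = float(g[routed].sum())
        F[HEART, inter[ln]] += afferent
        F[inter[ln], inter[ln]] -= afferent

    return F


def rate_matrix(system: CirculatorySystem, params: KineticParameters) -> np.ndarray:
    """Concentration rate matrix A with ``dx/dt = A x``."""
    F = flux_matrix(system, params)
    return F / system.compartment_volumes[:, None]


def ode_rhs(
    system: CirculatorySystem,
    params: KineticParameters,
    state: np.ndarray,
    t: float = 0.0,
) -> np.ndarray:
    """Time derivative of the flat concentration state."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite values in state")
    return rate_matrix(system, params) @ state


def initial_state(system: CirculatorySystem, dose: float = 1.0) -> np.ndarray:
    """All cells in the blood pool: ``C_h(0) = dose / V_h``, organs empty."""
    x0 = np.zeros(system.n_states)
    x0[0] = dose / system.blood_pool_volume
    return x0


# ---------------------------------------------------------------------------
# Simulation


def _propagate_expm(
    A: np.ndarray,
    x0: np.ndarray,
    times: np.ndarray,
    conserved: np.ndarray | None = None,
) -> np.ndarray:
    """Exact propagation of the LTI system ``x(t) = e^{At} x(0)``.

    Diagonalises A once and evaluates every output time in one shot; when
    A is close to defective the eigenbasis loses accuracy, which is
    detected through the conservation invariant (``conserved`` is a left
    null vector of A, the compartment volumes, so total content must stay
    constant) and triggers a fallback to incremental matrix exponentials.
    """
    try:
        lam, P = np.linalg.eig(A)
        c = np.linalg.solve(P, x0.astype(complex))
        phased = np.exp(np.outer(times, lam)) * c  # (T, n)
        states = np.ascontiguousarray(
            phased.real @ P.T.real - phased.imag @ P.T.imag
        )
        states[times == 0.0] = x0  # exact initial condition, no round-off
        if conserved is None:
            return states
        total = states @ conserved
        ref = float(x0 @ conserved)
        if np.all(np.abs(total - ref) <= 1e-8 * max(abs(ref), 1e-30)):
            return states
    except np.linalg.LinAlgError:
        pass
    states = np.empty((len(times), len(x0)))
    x = x0.copy()
    t_prev = 0.0
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt > 0:
            x = scipy.linalg.expm(A * dt) @ x
            t_prev = t
        states[k] = x
    return states


def simulate(
    system: CirculatorySystem,
    params: KineticParameters,
    times,
    x0: np.ndarray | None = None,
    dose: float = 1.0,
    method: str = "lsoda",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Solve the trafficking ODEs at the requested output times.

    Parameters
    ----------
    times
        Strictly increasing output times in hours; ``times[0] = 0`` allowed.
    x0
        Flat initial concentration state; defaults to all cells in blood.
    method
        ``"lsoda"``, ``"bdf"`` or ``"radau"`` select a stiff-capable
        adaptive integrator; ``"expm"`` propagates exactly through matrix
        exponentials (the model is linear and time invariant) and is the
        fast path used by fitting and MCMC loops.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be >= 0")
    if x0 is None:
        x0 = initial_state(system, dose)
    x0 = np.asarray(x0, dtype=float)

    A = rate_matrix(system, params)
    info: dict = {"method": method}

    if len(times) == 1 and times[0] == 0.0:
        states = x0[None, :].copy()
    elif method == "expm":
        states = _propagate_expm(A, x0, times, system.compartment_volumes)
    elif method in {"lsoda", "bdf", "radau"}:
        scipy_method = {"lsoda": "LSODA", "bdf": "BDF", "radau": "Radau"}[method]
        t_eval = times
        prepend_zero = times[0] > 0
        if prepend_zero:
            t_eval = np.concatenate(([0.0], times))
        sol = solve_ivp(
            lambda t, x: A @ x,
            (0.0, float(times[-1])),
            x0,
            method=scipy_method,
            t_eval=t_eval,
            jac=lambda t, x: A,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed at t = {sol.t[-1] if len(sol.t) else 0.0}: "
                f"{sol.message}"
            )
        states = sol.y.T
        if prepend_zero:
            states = states[1:]
        info.update(rtol=rtol, atol=atol, nfev=int(sol.nfev), njev=int(sol.njev))
    else:
        raise ValueError(f"unknown method {method!r}")

    return Trajectory(system, times, states, info)


def steady_state(
    system: CirculatorySystem, params: KineticParameters, dose: float = 1.0
) -> StateVector:
    """Long-time equilibrium, from the null space of the rate matrix.

    The closed system conserves cells, so A has a one-dimensional null
    space; the equilibrium is the null vector scaled to hold ``dose``
    cells.  At equilibrium every organ with its own lymph drainage
    satisfies ``C~ = C / mu``.  Requires all ``e > 0`` (otherwise the
    interstitium decouples and the null space is degenerate).
    """
    A = rate_matrix(system, params)
    ns = scipy.linalg.null_space(A, rcond=1e-10)
    if ns.shape[1] != 1:
        raise DegenerateSystemError(
            f"rate matrix null space has dimension {ns.shape[1]}, expected 1 "
            "(is some e_o = 0?)"
        )
    x = ns[:, 0]
    total = float(system.compartment_volumes @ x)
    if abs(total) < 1e-300:
        raise DegenerateSystemError("null vector carries no cell content")
    x = x * (dose / total)
    return StateVector.from_flat(np.inf, x, system.n_organs)
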