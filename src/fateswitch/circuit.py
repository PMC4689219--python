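"""Three-variable mutual-repression circuit with a pulsed exogenous GATA drive.

Dynamics (concentrations in arbitrary units, time in hours):

    dN/dt   = alpha_N * f_N(s) / (1 + ((G + G_X)/K_GN)^h_N)  -  gamma_N * N
    dG/dt   = alpha_G * f_G(s) / (1 + (N/K_NG)^h_G)          -  gamma_G * G
    dG_X/dt = D * u(t)  -  gamma_X * G_X

where ``u(t) = 1`` on the half-open pulse interval ``[t_start, t_end)`` and 0
otherwise, and ``f_N``, ``f_G`` are the signaling transfer functions of
:class:`~fateswitch.params.ModelParameters`.  Exogenous GATA (the inducible
GATA4-mCherry transgene) represses NANOG through the same Hill term as
endogenous GATA — the two act as a summed total-GATA input — but the
endogenous circuit does not feed back on G_X, so G_X follows the closed-form
pulse solution exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import CellState, ModelParameters, PulseProtocol, Trace

__all__ = [
    "derivatives",
    "rate_field",
    "jacobian_autonomous",
    "simulate_cell",
    "autonomous_steady_nanog",
    "preculture_state",
    "pulse_solution_gx",
    "IntegrationError",
]

#: Default integrator tolerances (adaptive, stiff-capable LSODA).
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


def _rhs(t: float, y: np.ndarray, p: ModelParameters, dose: float,
         pulse_on: bool) -> np.ndarray:
    N, G, G_X = y
    # Negative excursions from roundoff are clipped inside the Hill terms
    # so fractional exponents stay defined.
    total_gata = max(G, 0.0) + max(G_X, 0.0)
    dN = (p.alpha_N * p.signaling_factor_nanog()
          / (1.0 + (total_gata / p.K_GN) ** p.h_N) - p.gamma_N * N)
    dG = (p.alpha_G * p.signaling_factor_gata()
          / (1.0 + (max(N, 0.0) / p.K_NG) ** p.h_G) - p.gamma_G * G)
    dGX = (dose if pulse_on else 0.0) - p.gamma_X * G_X
    return np.array([dN, dG, dGX])


def derivatives(state: CellState | Sequence[float], t: float,
                params: ModelParameters, dose: float = 0.0,
                protocol: PulseProtocol | None = None) -> np.ndarray:
    """Time derivatives (dN/dt, dG/dt, dG_X/dt) at ``state`` and time ``t``.

    With ``protocol=None`` the exogenous drive is off (autonomous system plus
    G_X decay).
    """
    y = state.as_array() if isinstance(state, CellState) else \
        np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    pulse_on = protocol.pulse_active(t) if protocol is not None else False
    return _rhs(t, y, params, dose, pulse_on)


def rate_field(N, G, params: ModelParameters):
    """Vectorised autonomous rates (dN/dt, dG/dt) at G_X = 0.

    Accepts scalars or broadcastable arrays; used by the phase-plane module.
    """
    N = np.asarray(N, dtype=float)
    G = np.asarray(G, dtype=float)
    dN = (params.alpha_N * params.signaling_factor_nanog()
          / (1.0 + (G / params.K_GN) ** params.h_N) - params.gamma_N * N)
    dG = (params.alpha_G * params.signaling_factor_gata()
          / (1.0 + (N / params.K_NG) ** params.h_G) - params.gamma_G * G)
    return dN, dG


def jacobian_autonomous(N: float, G: float,
                        params: ModelParameters) -> np.ndarray:
    """Analytic 2x2 Jacobian of the autonomous (G_X = 0) system at (N, G)."""
    p = params
    aN = p.alpha_N * p.signaling_factor_nanog()
    aG = p.alpha_G * p.signaling_factor_gata()
    # d/dG [ aN / (1 + (G/K)^h) ] = -aN * h * (G/K)^(h-1) / (K * (1+(G/K)^h)^2)
    uG = (G / p.K_GN) ** p.h_N if G > 0 else 0.0
    uN = (N / p.K_NG) ** p.h_G if N > 0 else 0.0
    dfN_dG = 0.0
    if G > 0:
        dfN_dG = -aN * p.h_N * uG / (G * (1.0 + uG) ** 2)
    elif p.h_N == 1:
        dfN_dG = -aN / p.K_GN
    dfG_dN = 0.0
    if N > 0:
        dfG_dN = -aG * p.h_G * uN / (N * (1.0 + uN) ** 2)
    elif p.h_G == 1:
        dfG_dN = -aG / p.K_NG
    return np.array([[-p.gamma_N, dfN_dG],
                     [dfG_dN, -p.gamma_G]])


def autonomous_steady_nanog(params: ModelParameters) -> float:
    """NANOG level of the G = G_X = 0 production/degradation balance,
    ``alpha_N * f_N(s) / gamma_N``."""
    return params.alpha_N * params.signaling_factor_nanog() / params.gamma_N


def preculture_state(params: ModelParameters) -> CellState:
    """Default initial condition: high NANOG, no GATA.

    Cells are pre-cultured with MAPK signaling inhibited (MEK inhibitor), so
    the starting NANOG level is the signaling-free steady state
    ``alpha_N / gamma_N`` — above the steady state reached once signaling is
    restored, which produces the initial NANOG relaxation seen in simulated
    and measured traces.
    """
    return CellState(N=autonomous_steady_nanog(params.with_signaling(0.0)),
                     G=0.0, G_X=0.0)


def pulse_solution_gx(t, dose: float, params: ModelParameters,
                      protocol: PulseProtocol):
    """Closed-form exogenous GATA profile G_X(t) for G_X(t_start) = 0.

    Rises as ``(D/gamma_X)(1 - exp(-gamma_X (t - t_start)))`` during the
    pulse and decays exponentially after it.
    """
    t = np.asarray(t, dtype=float)
    g = params.gamma_X
    rise = (dose / g) * (1.0 - np.exp(-g * np.clip(t - protocol.t_start,
                                                   0.0, None)))
    peak = (dose / g) * (1.0 - np.exp(-g * (protocol.t_end -
                                            protocol.t_start)))
    decay = peak * np.exp(-g * (t - protocol.t_end))
    return np.where(t < protocol.t_end, np.where(t < protocol.t_start,
                                                 0.0, rise), decay)


def _integrate_segments(params, dose, protocol, times, y0,
                        rtol=RTOL, atol=ATOL):
    """Integrate splitting at the pulse edges so the drive discontinuity
    never falls inside an adaptive step."""
    times = np.asarray(times, dtype=float)
    t0, t1 = times[0], times[-1]
    edges = [t0]
    for edge in (protocol.t_start, protocol.t_end):
        if t0 < edge < t1:
            edges.append(edge)
    edges.append(t1)

    out = np.empty((times.size, 3))
    filled = np.zeros(times.size, dtype=bool)
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        pulse_on = protocol.pulse_active(0.5 * (a + b)) and dose > 0
        mask = (times >= a) & (times <= b) & ~filled
        t_eval = times[mask]
        sol = solve_ivp(
            _rhs, (a, b), y, t_eval=t_eval if t_eval.size else None,
            args=(params, dose, pulse_on), method="LSODA",
            dense_output=True, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{a}, {b}] at dose {dose}: "
                f"{sol.message}")
        if t_eval.size:
            out[mask] = sol.y.T
            filled[mask] = True
        # always restart the next segment from the state at its left edge
        y = np.asarray(sol.sol(b) if sol.sol is not None else
                       (sol.y[:, -1] if sol.y.size else y), dtype=float)
    return out, y


def simulate_cell(params: ModelParameters, dose: float,
                  protocol: PulseProtocol, times=None,
                  initial: CellState | None = None,
                  rtol: float = RTOL, atol: float = ATOL) -> Trace:
    """Integrate one cell through the pulse-chase protocol.

    Parameters
    ----------
    params, dose, protocol
        Circuit parameters, the cell's maximum exogenous production rate D,
        and the pulse timing.
    times
        Strictly increasing sample grid within ``[t_start or earlier,
        t_final]``; defaults to 0.25 h frames over the whole protocol.
    initial
        Starting state; defaults to :func:`preculture_state` (high NANOG,
        no GATA).

    Returns
    -------
    Trace
        Deterministic trajectory sampled on the grid (clipped at 0 to within
        solver tolerance).
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if times is None:
        times = np.arange(0.0, protocol.t_final + 1e-9, 0.25)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if times[-1] > protocol.t_final + 1e-9:
        raise ValueError("time grid extends past t_final")
    if initial is None:
        initial = preculture_state(params)
    states, _ = _integrate_segments(params, dose, protocol, times,
                                    initial.as_array(), rtol=rtol, atol=atol)
    return Trace(times=times, states=np.clip(states, -atol * 10, None),
                 dose=dose)
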