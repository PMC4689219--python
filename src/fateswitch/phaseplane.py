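"""Phase-plane analysis of the autonomous (G_X = 0) two-variable circuit.

Characterises the NANOG/GATA toggle switch: nullclines, equilibria with
stability classification, the separatrix (stable manifold of the saddle),
basin-of-attraction geometry, and a path-integral quasi-potential landscape
whose minima are the attractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .circuit import jacobian_autonomous, rate_field
from .params import ModelParameters

__all__ = [
    "Equilibrium",
    "PhasePortrait",
    "PotentialGrid",
    "BasinResult",
    "default_bounds",
    "nullclines",
    "find_equilibria",
    "separatrix",
    "basin_fraction",
    "quasi_potential",
    "phase_portrait",
    "PhasePlaneError",
]

Bounds = Tuple[Tuple[float, float], Tuple[float, float]]

#: residual below which a refined root is accepted
ROOT_TOL = 1e-10
#: eigenvalue real parts closer to zero than this are "marginal"
MARGINAL_TOL = 1e-9


class PhasePlaneError(RuntimeError):
    """Raised when the phase-plane structure violates model assumptions
    (no equilibria, missing/multiple saddles, marginal eigenvalues)."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the autonomous system."""

    location: Tuple[float, float]
    eigenvalues: Tuple[complex, complex]
    stability: str  # "stable" | "saddle" | "unstable"

    @property
    def N(self) -> float:
        return self.location[0]

    @property
    def G(self) -> float:
        return self.location[1]

    @property
    def is_gata_high(self) -> bool:
        return self.G > self.N


@dataclass
class PhasePortrait:
    """Nullclines, equilibria and separatrix of the autonomous system."""

    nullcline_N: np.ndarray  # (n, 2) polyline in (N, G)
    nullcline_G: np.ndarray
    equilibria: List[Equilibrium]
    separatrix: np.ndarray | None
    grid_bounds: Bounds

    @property
    def stable(self) -> List[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]

    @property
    def saddle(self) -> Equilibrium | None:
        saddles = [e for e in self.equilibria if e.stability == "saddle"]
        return saddles[0] if saddles else None


@dataclass
class PotentialGrid:
    """Path-integral quasi-potential on a rectangular (N, G) lattice.

    ``U`` is NaN on cells never visited by any launched trajectory; the
    global minimum of the defined cells is shifted to 0.
    """

    N_axis: np.ndarray
    G_axis: np.ndarray
    U: np.ndarray  # shape (len(N_axis), len(G_axis)); NaN = undefined
    basin: np.ndarray | None = None  # 1 = GATA-high basin, 0 = NANOG-high

    def value_at(self, N: float, G: float) -> float:
        i = int(np.argmin(np.abs(self.N_axis - N)))
        j = int(np.argmin(np.abs(self.G_axis - G)))
        return float(self.U[i, j])


@dataclass
class BasinResult:
    """Outcome of gridding state space by attractor reached."""

    fraction: float          # fraction of resolved points in GATA-high basin
    n_unresolved: int
    labels: np.ndarray       # (res, res); 1 GATA-high, 0 NANOG-high, -1 n/a
    N_axis: np.ndarray
    G_axis: np.ndarray

    def __float__(self) -> float:
        return self.fraction


def default_bounds(params: ModelParameters) -> Bounds:
    """Rectangle [0, 1.5 alpha_N/gamma_N] x [0, 1.5 alpha_G/gamma_G];
    a silenced node's axis is floored at its repression threshold so the
    rectangle never degenerates."""
    return ((0.0, max(1.5 * params.alpha_N / params.gamma_N, params.K_NG)),
            (0.0, max(1.5 * params.alpha_G / params.gamma_G, params.K_GN)))


def _check_bounds(bounds: Bounds) -> Bounds:
    (n0, n1), (g0, g1) = bounds
    if not (n1 > n0 and g1 > g0):
        raise ValueError("empty bounds rectangle")
    return bounds


# -- nullclines -----------------------------------------------------------

def _n_null_curve(G, params: ModelParameters):
    """N on the NANOG nullcline as an explicit function of G."""
    aN = params.alpha_N * params.signaling_factor_nanog()
    return aN / (params.gamma_N * (1.0 + (np.asarray(G, float) /
                                          params.K_GN) ** params.h_N))


def _g_null_curve(N, params: ModelParameters):
    """G on the GATA nullcline as an explicit function of N."""
    aG = params.alpha_G * params.signaling_factor_gata()
    return aG / (params.gamma_G * (1.0 + (np.asarray(N, float) /
                                          params.K_NG) ** params.h_G))


def nullclines(params: ModelParameters, bounds: Bounds | None = None,
               resolution: int = 200) -> Tuple[np.ndarray, np.ndarray]:
    """Zero-rate curves of dN/dt and dG/dt at G_X = 0.

    Both nullclines of the Hill-repression circuit are graphs of explicit
    functions (N of G, and G of N respectively), so each is returned as an
    exact polyline of ``resolution`` points: arrays of shape (resolution, 2)
    in (N, G) coordinates.
    """
    if bounds is None:
        bounds = default_bounds(params)
    (n0, n1), (g0, g1) = _check_bounds(bounds)
    G = np.linspace(g0, g1, resolution)
    ncl_N = np.column_stack([_n_null_curve(G, params), G])
    N = np.linspace(n0, n1, resolution)
    ncl_G = np.column_stack([N, _g_null_curve(N, params)])
    return ncl_N, ncl_G


# -- equilibria -----------------------------------------------------------

def _classify(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) < MARGINAL_TOL):
        raise PhasePlaneError(
            f"marginal equilibrium (eigenvalue real parts {re}); the model "
            "appears to sit at a bifurcation")
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_equilibria(params: ModelParameters,
                    bounds: Bounds | None = None) -> List[Equilibrium]:
    """All fixed points of the autonomous system inside ``bounds``.

    Equilibria lie on both nullclines; since each nullcline is an explicit
    graph, roots are seeds of the scalar equation
    ``N = N_null(G_null(N))`` located by dense sign-change scanning and
    polished by bisection, then refined in 2-D by damped Newton iteration
    with the analytic Jacobian.  Results are classified by Jacobian
    eigenvalues and sorted by N descending.
    """
    if bounds is None:
        bounds = default_bounds(params)
    (n0, n1), (g0, g1) = _check_bounds(bounds)

    def mismatch(N):
        return N - _n_null_curve(_g_null_curve(N, params), params)

    # dense scan for sign changes (the composite map is smooth)
    Ns = np.linspace(max(n0, 0.0), n1, 4001)
    vals = mismatch(Ns)
    seeds = []
    for a, b, fa, fb in zip(Ns[:-1], Ns[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            seeds.append(a)
        elif fa * fb < 0:
            seeds.append(brentq(mismatch, a, b, xtol=1e-14))
    if vals[-1] == 0.0:
        seeds.append(Ns[-1])

    equilibria: List[Equilibrium] = []
    for Nseed in seeds:
        x = np.array([Nseed, float(_g_null_curve(Nseed, params))])
        converged = False
        for _ in range(60):
            f = np.array(rate_field(x[0], x[1], params))
            if np.linalg.norm(f) < ROOT_TOL:
                converged = True
                break
            J = jacobian_autonomous(x[0], x[1], params)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                break
            # damping: halve until the residual decreases
            lam = 1.0
            for _ in range(30):
                xn = x + lam * step
                fn = np.array(rate_field(max(xn[0], 0.0), max(xn[1], 0.0),
                                         params))
                if np.linalg.norm(fn) < np.linalg.norm(f):
                    x = np.clip(xn, 0.0, None)
                    break
                lam *= 0.5
            else:
                break
        else:  # pragma: no cover - loop exhausted without break
            converged = np.linalg.norm(
                rate_field(x[0], x[1], params)) < ROOT_TOL
        if not converged:
            import warnings
            warnings.warn(f"equilibrium seed near N={Nseed:.4g} did not "
                          "converge; discarded")
            continue
        if not (n0 - 1e-9 <= x[0] <= n1 + 1e-9 and
                g0 - 1e-9 <= x[1] <= g1 + 1e-9):
            continue
        if any(np.hypot(x[0] - e.N, x[1] - e.G) < 1e-6 for e in equilibria):
            continue
        eigs = np.linalg.eigvals(jacobian_autonomous(x[0], x[1], params))
        equilibria.append(Equilibrium(location=(float(x[0]), float(x[1])),
                                      eigenvalues=tuple(eigs),
                                      stability=_classify(eigs)))
    if not equilibria:
        raise PhasePlaneError("no equilibria found inside bounds; the model "
                              "is misconfigured")
    return sorted(equilibria, key=lambda e: -e.N)


# -- separatrix and basins ------------------------------------------------

def _autonomous_rhs(t, y, params):
    return np.array(rate_field(max(y[0], 0.0), max(y[1], 0.0), params))


def _reversed_rhs(t, y, params):
    return -_autonomous_rhs(t, y, params)


def separatrix(params: ModelParameters, bounds: Bounds | None = None,
               eps: float = 1e-6, t_max: float = 400.0) -> np.ndarray:
    """The saddle's stable manifold as an (n, 2) polyline.

    Computed by integrating the time-reversed flow from two seeds offset
    ``±eps`` along the saddle's stable eigenvector, truncated at ``bounds``.
    """
    if bounds is None:
        bounds = default_bounds(params)
    (n0, n1), (g0, g1) = _check_bounds(bounds)
    eqs = find_equilibria(params, bounds)
    saddles = [e for e in eqs if e.stability == "saddle"]
    if len(saddles) == 0:
        raise PhasePlaneError("no saddle inside bounds; system not bistable")
    if len(saddles) > 1:
        raise PhasePlaneError("multiple saddles found; outside model scope")
    saddle = saddles[0]

    J = jacobian_autonomous(saddle.N, saddle.G, params)
    eigvals, eigvecs = np.linalg.eig(J)
    stable_idx = int(np.argmin(np.real(eigvals)))
    v = np.real(eigvecs[:, stable_idx])
    v = v / np.linalg.norm(v)

    margin = 1e-9

    def leaves(t, y, params):
        return min(y[0] - (n0 - margin), (n1 + margin) - y[0],
                   y[1] - (g0 - margin), (g1 + margin) - y[1])
    leaves.terminal = True
    leaves.direction = -1

    x0 = np.array([saddle.N, saddle.G])
    branches = []
    for sign in (+1.0, -1.0):
        sol = solve_ivp(_reversed_rhs, (0.0, t_max), x0 + sign * eps * v,
                        args=(params,), method="LSODA", events=leaves,
                        rtol=1e-10, atol=1e-12, max_step=0.25, dense_output=True)
        ts = np.linspace(0.0, sol.t[-1], 400)
        branches.append(sol.sol(ts).T)
    # branch 1 reversed, then the saddle, then branch 2 outward
    return np.vstack([branches[0][::-1], x0[None, :], branches[1]])


def _settle_to_attractor(y0, params, stable_eqs, t_chunk=60.0,
                         t_max=400.0, tol=1e-6):
    """Forward-integrate until the rate norm drops below ``tol``; return the
    index of the reached stable equilibrium, or None if unresolved."""

    def converged(t, y, params):
        return np.linalg.norm(_autonomous_rhs(t, y, params)) - tol
    converged.terminal = True
    converged.direction = -1

    def near_stable(y):
        return min(np.hypot(y[0] - e.N, y[1] - e.G)
                   for e in stable_eqs) < 1e-3

    y = np.asarray(y0, dtype=float)
    t = 0.0
    use_events = True
    while True:
        # the rate norm is also tiny near the saddle, so require proximity
        # to a stable equilibrium before declaring convergence
        if np.linalg.norm(_autonomous_rhs(t, y, params)) < tol \
                and near_stable(y):
            break
        if t >= t_max:
            return None, y
        sol = solve_ivp(_autonomous_rhs, (t, min(t + t_chunk, t_max)), y,
                        args=(params,), method="LSODA",
                        events=converged if use_events else None,
                        rtol=1e-8, atol=1e-10)
        y = sol.y[:, -1]
        t = sol.t[-1]
        if sol.status == 1:
            if near_stable(y):  # event hit at an attractor
                break
            # slow passage near the saddle: restart without events (the
            # event function is exactly zero here, which would break the
            # solver's root bracketing) and push through the next chunk
            use_events = False
        else:
            use_events = True
    if np.linalg.norm(_autonomous_rhs(t, y, params)) > tol * 10:
        return None, y
    dists = [np.hypot(y[0] - e.N, y[1] - e.G) for e in stable_eqs]
    return int(np.argmin(dists)), y


def basin_fraction(params: ModelParameters, bounds: Bounds | None = None,
                   resolution: int = 24) -> BasinResult:
    """Fraction of a uniform state-space lattice attracted to the GATA-high
    state under the autonomous flow.

    Points failing to converge within the time budget are counted as
    unresolved and excluded from the fraction.
    """
    if bounds is None:
        bounds = default_bounds(params)
    (n0, n1), (g0, g1) = _check_bounds(bounds)
    eqs = find_equilibria(params, bounds)
    stable = [e for e in eqs if e.stability == "stable"]
    if not any(e.is_gata_high for e in stable):
        # monostable NANOG regime: nothing converges to a GATA-high state
        labels = np.zeros((resolution, resolution), dtype=int)
        return BasinResult(0.0, 0, labels,
                           np.linspace(n0, n1, resolution),
                           np.linspace(g0, g1, resolution))
    N_axis = np.linspace(n0, n1, resolution)
    G_axis = np.linspace(g0, g1, resolution)
    labels = np.full((resolution, resolution), -1, dtype=int)
    n_gata = n_total = unresolved = 0
    for i, N in enumerate(N_axis):
        for j, G in enumerate(G_axis):
            idx, _ = _settle_to_attractor((N, G), params, stable)
            if idx is None:
                unresolved += 1
                continue
            lab = int(stable[idx].is_gata_high)
            labels[i, j] = lab
            n_gata += lab
            n_total += 1
    if n_total == 0:
        raise PhasePlaneError("no grid point resolved to an attractor")
    return BasinResult(n_gata / n_total, unresolved, labels, N_axis, G_axis)


# -- quasi-potential ------------------------------------------------------

def quasi_potential(params: ModelParameters, bounds: Bounds | None = None,
                    resolution: int = 100, n_traj: int = 400,
                    seed: int = 0, dt: float = 0.01,
                    t_max: float = 200.0) -> PotentialGrid:
    """Path-integral quasi-potential landscape of the autonomous system.

    Trajectories are launched from a jittered uniform lattice of ``n_traj``
    initial points.  Along each trajectory the potential decreases by
    ``dU = -|v|^2 dt`` (v = local rate vector), anchored so the trajectory
    reaches its attractor at relative potential 0; visited grid cells keep
    the per-cell minimum.  The two basins are aligned by matching values in
    the neighbourhood of the saddle (through which both basins' boundary
    trajectories pass), and the global minimum is shifted to 0.  Cells never
    visited hold NaN.
    """
    if n_traj < 100:
        raise ValueError("n_traj must be >= 100")
    if bounds is None:
        bounds = default_bounds(params)
    (n0, n1), (g0, g1) = _check_bounds(bounds)
    eqs = find_equilibria(params, bounds)
    stable = [e for e in eqs if e.stability == "stable"]
    saddles = [e for e in eqs if e.stability == "saddle"]
    if len(stable) != 2 or len(saddles) != 1:
        raise PhasePlaneError("quasi-potential requires a bistable regime "
                              "(two stable states and one saddle)")
    saddle = saddles[0]

    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_traj)))
    NN, GG = np.meshgrid(np.linspace(n0, n1, side),
                         np.linspace(g0, g1, side))
    starts = np.column_stack([NN.ravel(), GG.ravel()])[:n_traj]
    starts += rng.uniform(-0.5, 0.5, starts.shape) * \
        np.array([(n1 - n0) / side, (g1 - g0) / side])
    starts = np.clip(starts, [n0, g0], [n1, g1])

    N_axis = np.linspace(n0, n1, resolution)
    G_axis = np.linspace(g0, g1, resolution)
    dN = N_axis[1] - N_axis[0]
    dG = G_axis[1] - G_axis[0]

    # one potential surface per basin, aligned afterwards
    U_basin = [np.full((resolution, resolution), np.inf),
               np.full((resolution, resolution), np.inf)]

    def reached_attractor(t, y, params):
        # distance-based: the rate norm is also tiny near the saddle, which
        # must not count as arrival
        return min(np.hypot(y[0] - e.N, y[1] - e.G) for e in stable) - 1e-3
    reached_attractor.terminal = True
    reached_attractor.direction = -1

    def run_trajectory(y0):
        """Integrate to an attractor; return sampled path, its relative
        potential (0 on arrival) and the basin index reached, or None if
        the trajectory stalled (e.g. on the separatrix)."""
        sol = solve_ivp(_autonomous_rhs, (0.0, t_max), y0, args=(params,),
                        method="LSODA", dense_output=True,
                        events=reached_attractor, rtol=1e-6, atol=1e-9)
        if sol.status != 1:
            return None
        t_end = sol.t[-1]
        ts = np.arange(0.0, t_end + dt, dt)
        ys = sol.sol(ts)
        vN, vG = rate_field(np.clip(ys[0], 0.0, None),
                            np.clip(ys[1], 0.0, None), params)
        speed2 = vN ** 2 + vG ** 2
        # trapezoidal accumulation of dU = -|v|^2 dt, anchored at 0 on
        # arrival so every trajectory in a basin shares the attractor level
        incr = -0.5 * (speed2[:-1] + speed2[1:]) * np.diff(ts)
        U_traj = np.concatenate([[0.0], np.cumsum(incr)])
        U_traj -= U_traj[-1]
        yf = ys[:, -1]
        b = int(min(range(len(stable)),
                    key=lambda k: np.hypot(yf[0] - stable[k].N,
                                           yf[1] - stable[k].G)))
        return ys, U_traj, b

    def deposit(ys, U_traj, b):
        ii = np.clip(np.round((ys[0] - n0) / dN).astype(int), 0,
                     resolution - 1)
        jj = np.clip(np.round((ys[1] - g0) / dG).astype(int), 0,
                     resolution - 1)
        np.minimum.at(U_basin[b], (ii, jj), U_traj)

    for y0 in starts:
        result = run_trajectory(y0)
        if result is not None:
            deposit(*result)

    # Basin alignment: launch one trajectory down each side of the saddle's
    # unstable manifold (the downhill path from the ridge into each basin).
    # Its start value is that basin's depth below the saddle, so requiring
    # both sides to assign the saddle the same potential fixes the offset.
    J = jacobian_autonomous(saddle.N, saddle.G, params)
    eigvals_s, eigvecs_s = np.linalg.eig(J)
    v_unstable = np.real(eigvecs_s[:, int(np.argmax(np.real(eigvals_s)))])
    v_unstable /= np.linalg.norm(v_unstable)
    ref = [np.nan, np.nan]
    x_saddle = np.array([saddle.N, saddle.G])
    for sign in (+1.0, -1.0):
        y0 = np.clip(x_saddle + sign * 1e-4 * v_unstable, 0.0, None)
        result = run_trajectory(y0)
        if result is None:
            continue
        ys, U_traj, b = result
        deposit(ys, U_traj, b)
        ref[b] = U_traj[0]
    if np.isnan(ref[0]) or np.isnan(ref[1]):
        raise PhasePlaneError("basin alignment failed: the saddle's "
                              "unstable manifold did not reach both "
                              "attractors")
    U_basin[1] += ref[0] - ref[1]

    for b in (0, 1):
        U_basin[b][np.isinf(U_basin[b])] = np.nan

    U = np.where(np.isnan(U_basin[0]), U_basin[1],
                 np.where(np.isnan(U_basin[1]), U_basin[0],
                          np.minimum(U_basin[0], U_basin[1])))
    # basin label: which surface supplied each cell's value
    take_second = (np.isnan(U_basin[0]) |
                   (~np.isnan(U_basin[1]) & (U_basin[1] < U_basin[0])))
    is_gata = np.array([stable[0].is_gata_high, stable[1].is_gata_high],
                       dtype=int)
    basin = np.where(np.isnan(U), -1, is_gata[take_second.astype(int)])

    U -= np.nanmin(U)
    return PotentialGrid(N_axis=N_axis, G_axis=G_axis, U=U, basin=basin)


def phase_portrait(params: ModelParameters, bounds: Bounds | None = None,
                   resolution: int = 200) -> PhasePortrait:
    """Convenience bundle: nullclines + equilibria + separatrix (when the
    system is bistable)."""
    if bounds is None:
        bounds = default_bounds(params)
    ncl_N, ncl_G = nullclines(params, bounds, resolution)
    eqs = find_equilibria(params, bounds)
    sep = None
    if any(e.stability == "saddle" for e in eqs):
        sep = separatrix(params, bounds)
    return PhasePortrait(nullcline_N=ncl_N, nullcline_G=ncl_G,
                         equilibria=eqs, separatrix=sep,
                         grid_bounds=bounds)
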