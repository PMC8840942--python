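"""Kinetic transport solver for the velocity-jump migration model.

The mesoscopic cell distribution ``p(t, x, v, vhat)`` evolves by

``dp/dt + v vhat . grad p = mu (rho T psi - p)``

i.e. free transport plus a run-and-tumble turning operator relaxing the
velocity distribution toward the post-tumble equilibrium ``rho T psi`` at
frequency ``mu``.  The solver uses Strang splitting:

* transport: first-order upwind finite volumes per (direction, speed) node,
  with specular-reflecting walls (outgoing flux re-enters in the mirrored
  direction node), which conserves mass exactly and preserves positivity
  under the CFL bound;
* turning: the exact solution of the linear relaxation ODE over the substep
  with the density frozen, which is unconditionally positive.

State is stored on the tensor grid (x, y, theta, v).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import (ConfigurationError, DegenerateStateError,
                         InvalidParameterError)
from .fields import DirectionGrid, Domain2D, SpeedDistribution
from .sensing import TransitionKernel

__all__ = [
    "KineticState",
    "SolverConfig",
    "Snapshot",
    "Trajectory",
    "initialize_gaussian",
    "turning_substep",
    "transport_substep",
    "run",
    "moments",
    "mean_speed_pi_half",
    "center_of_mass",
]


@dataclass
class KineticState:
    """Distribution values ``p[i, j, m, l]`` on the (x, y, theta, v) grid."""

    domain: Domain2D
    dirs: DirectionGrid
    psi: SpeedDistribution
    T: TransitionKernel
    p: np.ndarray
    t: float = 0.0
    n_v: int = 4

    def __post_init__(self):
        self.v_nodes, self.w_v, self.psi_vals = self.psi.discretize(self.n_v)

    def copy(self) -> "KineticState":
        new = KineticState(self.domain, self.dirs, self.psi, self.T,
                           self.p.copy(), self.t, self.n_v)
        return new

    @property
    def cell_area(self) -> float:
        return self.domain.dx * self.domain.dy

    def density(self) -> np.ndarray:
        """Macroscopic density ``rho(x) = int p dv dvhat``."""
        return np.einsum("ijml,l->ij", self.p, self.w_v) * self.dirs.weight

    def total_mass(self) -> float:
        return float(np.sum(self.density()) * self.cell_area)

    def equilibrium(self, rho: np.ndarray | None = None) -> np.ndarray:
        """Post-tumble equilibrium ``rho T psi`` for the current density."""
        if rho is None:
            rho = self.density()
        return (rho[:, :, None, None] * self.T.values[:, :, :, None]
                * self.psi_vals[None, None, None, :])


@dataclass
class SolverConfig:
    """Time-integration parameters.

    ``mu`` is the turning frequency (1/time); ``cfl`` bounds
    ``dt * v_max / min(dx, dy)``; snapshots are emitted every
    ``snapshot_every`` time units (0 keeps only first/last).
    """

    mu: float = 1.0
    t_end: float = 10.0
    cfl: float = 0.45
    snapshot_every: float = 1.0
    dt: float | None = None
    seed: int | None = None
    scheme: str = "upwind"  # "upwind" | "minmod"

    def __post_init__(self):
        if self.mu <= 0 or self.t_end <= 0:
            raise ConfigurationError("mu and t_end must be positive")
        if not (0 < self.cfl <= 1):
            raise ConfigurationError("cfl must be in (0, 1]")


def initialize_gaussian(domain: Domain2D, dirs: DirectionGrid,
                        psi: SpeedDistribution, T: TransitionKernel,
                        r0: float, center, var0: float,
                        mode: str = "rest", n_v: int = 4,
                        rng: np.random.Generator | None = None) -> KineticState:
    """Gaussian initial cell density

    ``rho_0(x, y) = r0 exp(-|x - c|^2 / (2 var0))``

    with velocity structure per ``mode``: ``"rest"`` places all mass at the
    lowest speed node with orientations uniformly distributed (vanishing
    initial momentum); ``"equilibrium"`` starts at the post-tumble
    equilibrium ``rho_0 T psi``.  An optional ``rng`` perturbs the uniform
    orientations of the rest mode by a small random factor (reproducible
    randomized initial polarization).
    """
    if var0 <= 0:
        raise InvalidParameterError("var0 must be positive")
    cx, cy = float(center[0]), float(center[1])
    if not domain.contains(cx, cy):
        raise InvalidParameterError(f"initial center ({cx}, {cy}) outside the domain")
    X, Y = domain.mesh()
    rho0 = r0 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * var0))
    n_theta = dirs.n_theta
    state = KineticState(domain, dirs, psi, T,
                         np.zeros((domain.nx, domain.ny, n_theta, len(
                             psi.discretize(n_v)[0]))), 0.0, n_v)
    if mode == "rest":
        ang = np.full(n_theta, 1.0 / (2.0 * np.pi))
        if rng is not None:
            ang = ang * (1.0 + 0.01 * rng.standard_normal(n_theta))
            ang = np.abs(ang)
            ang /= np.sum(ang) * dirs.weight
        # all mass on the lowest (positive) speed node
        state.p[:, :, :, 0] = rho0[:, :, None] * ang[None, None, :] / state.w_v[0]
    elif mode == "equilibrium":
        state.p[:] = state.equilibrium(rho0)
    else:
        raise InvalidParameterError(f"unknown initial mode {mode!r}")
    return state


def turning_substep(state: KineticState, dt: float, mu: float) -> None:
    """Exact relaxation update of the turning operator (in place).

    ``p <- E + exp(-mu dt) (p - E)`` with ``E = rho T psi`` and the density
    frozen over the substep; mass-neutral and positivity-preserving.
    """
    E = state.equilibrium()
    decay = np.exp(-mu * dt)
    state.p *= decay
    state.p += (1.0 - decay) * E


def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def _advect_axis(p: np.ndarray, speeds: np.ndarray, refl: np.ndarray,
                 dt: float, dx: float, axis: int,
                 scheme: str = "upwind") -> np.ndarray:
    """Conservative upwind sweep along one spatial axis with specular walls.

    ``speeds[m, l]`` is the signed advection speed of node (theta_m, v_l);
    ``refl`` maps each direction index to its wall-mirrored partner.  The
    wall influx of a direction equals the wall outflux of its partner, so
    total mass is conserved to round-off.  ``scheme='minmod'`` adds a
    limited second-order (MUSCL) correction on interior faces; wall faces
    stay first-order so the reflection pairing is unchanged.
    """
    if axis == 1:
        p = np.swapaxes(p, 0, 1)
    a = speeds[None, :, :]  # broadcast over the transverse spatial axis
    ap = np.maximum(a, 0.0)
    am = np.minimum(a, 0.0)
    # interior faces: F[i] is the flux across the face between cells i and i+1
    F = ap * p[:-1] + am * p[1:]
    if scheme == "minmod":
        slope = np.zeros_like(p)  # limited cell slopes (zero at walls)
        slope[1:-1] = _minmod(p[1:-1] - p[:-2], p[2:] - p[1:-1])
        nu = np.abs(a) * dt / dx
        F = F + 0.5 * (1.0 - nu) * (ap * slope[:-1] + am * slope[1:])
    # wall faces (specular reflection: influx from the mirrored direction)
    F_lo = ap * p[0][:, refl, :] + am * p[0]
    F_hi = ap * p[-1] + am * p[-1][:, refl, :]
    out = p.copy()
    r = dt / dx
    out[0] -= r * (F[0] - F_lo)
    if p.shape[0] > 2:
        out[1:-1] -= r * (F[1:] - F[:-1])
    out[-1] -= r * (F_hi - F[-1])
    if axis == 1:
        out = np.swapaxes(out, 0, 1)
    return out


def transport_substep(state: KineticState, dt: float,
                      scheme: str = "upwind") -> None:
    """Free-transport update ``dp/dt + v vhat . grad p = 0`` (in place).

    Dimensionally split (x then y sweep) finite volumes with
    specular-reflecting walls; first-order upwind by default (robust,
    positivity-preserving) or limited second-order (``scheme='minmod'``)
    for convergence studies.  Raises if the CFL bound is violated.
    """
    d, g = state.domain, state.dirs
    vmax = float(np.max(state.v_nodes))
    if dt * vmax > min(d.dx, d.dy) + 1e-15:
        raise ConfigurationError(
            f"CFL violation: dt={dt:g}, vmax={vmax:g}, h={min(d.dx, d.dy):g}")
    ax = state.v_nodes[None, :] * g.vx[:, None]  # (n_theta, n_v)
    ay = state.v_nodes[None, :] * g.vy[:, None]
    state.p = _advect_axis(state.p, ax, g.reflect_x(), dt, d.dx, axis=0, scheme=scheme)
    state.p = _advect_axis(state.p, ay, g.reflect_y(), dt, d.dy, axis=1, scheme=scheme)


# --------------------------------------------------------------------------
# moments and diagnostics
# --------------------------------------------------------------------------

def moments(state: KineticState):
    """Macroscopic moments: density, momentum and diffusion tensor fields.

    Returns ``(rho, rho_U, Dtens)`` with shapes (nx, ny), (nx, ny, 2),
    (nx, ny, 2, 2).  Where ``rho`` vanishes the mean velocity is reported
    as zero rather than NaN.
    """
    w_th = state.dirs.weight
    wv = state.w_v
    vx = state.dirs.vx[:, None] * state.v_nodes[None, :]  # (n_theta, n_v)
    vy = state.dirs.vy[:, None] * state.v_nodes[None, :]
    rho = np.einsum("ijml,l->ij", state.p, wv) * w_th
    mx = np.einsum("ijml,ml,l->ij", state.p, state.dirs.vx[:, None]
                   * np.ones_like(state.v_nodes), wv * state.v_nodes) * w_th
    my = np.einsum("ijml,ml,l->ij", state.p, state.dirs.vy[:, None]
                   * np.ones_like(state.v_nodes), wv * state.v_nodes) * w_th
    rho_U = np.stack([mx, my], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = np.where(rho[:, :, None] > 0, rho_U / rho[:, :, None], 0.0)
    # second central moment: int (v - U)(x)(v - U) p
    M2 = np.empty((state.domain.nx, state.domain.ny, 2, 2))
    M2[..., 0, 0] = np.einsum("ijml,ml,l->ij", state.p, vx * vx, wv) * w_th
    M2[..., 0, 1] = np.einsum("ijml,ml,l->ij", state.p, vx * vy, wv) * w_th
    M2[..., 1, 0] = M2[..., 0, 1]
    M2[..., 1, 1] = np.einsum("ijml,ml,l->ij", state.p, vy * vy, wv) * w_th
    Dtens = (M2 - rho_U[..., :, None] * U[..., None, :]
             - U[..., :, None] * rho_U[..., None, :]
             + rho[..., None, None] * U[..., :, None] * U[..., None, :])
    return rho, rho_U, Dtens


def mean_speed_pi_half(state: KineticState) -> float:
    """Population mean speed along the upward direction (theta = pi/2):

    the domain-averaged L1 norm of ``int v p(t, x, v, pi/2) dv``.
    """
    j = state.dirs.index_of(np.pi / 2.0)
    g = np.einsum("ijl,l->ij", state.p[:, :, j, :], state.w_v * state.v_nodes)
    return float(np.sum(np.abs(g)) * state.cell_area / state.domain.area)


def center_of_mass(rho: np.ndarray, domain: Domain2D) -> np.ndarray:
    """Mass-weighted mean position of a density field."""
    tot = float(np.sum(rho))
    if tot <= 0:
        raise DegenerateStateError("zero total mass: center of mass undefined")
    X, Y = domain.mesh()
    return np.array([float(np.sum(rho * X)) / tot, float(np.sum(rho * Y)) / tot])


# --------------------------------------------------------------------------
# time integration
# --------------------------------------------------------------------------

@dataclass
class Snapshot:
    t: float
    rho: np.ndarray
    momentum: np.ndarray


@dataclass
class Trajectory:
    """Output of a kinetic run: snapshots plus scalar diagnostics series."""

    snapshots: list = dc_field(default_factory=list)
    times: list = dc_field(default_factory=list)
    mass: list = dc_field(default_factory=list)
    com: list = dc_field(default_factory=list)
    vbar: list = dc_field(default_factory=list)

    def diagnostics(self):
        """Diagnostics as a pandas DataFrame (time, mass, com, vbar)."""
        import pandas as pd
        com = np.asarray(self.com)
        return pd.DataFrame({"time": self.times, "mass": self.mass,
                             "com_x": com[:, 0], "com_y": com[:, 1],
                             "vbar": self.vbar})


def run(state: KineticState, config: SolverConfig,
        store_snapshots: bool = True,
        callback=None) -> Trajectory:
    """Integrate the transport equation by Strang splitting.

    Per step: transport(dt/2) - turning(dt) - transport(dt/2).  Snapshots
    (density, momentum) and scalar diagnostics (mass, center of mass, mean
    upward speed) are recorded at the requested cadence.  ``callback(state)``
    may return True to stop early (e.g. event detection).
    """
    d = state.domain
    vmax = float(np.max(state.v_nodes))
    dt = config.dt if config.dt is not None else config.cfl * min(d.dx, d.dy) / vmax
    if dt * vmax > min(d.dx, d.dy) * (1 + 1e-12):
        raise ConfigurationError("configured dt violates the CFL bound")
    n_steps = int(np.ceil(config.t_end / dt))
    every = max(1, int(round(config.snapshot_every / dt))) \
        if config.snapshot_every > 0 else n_steps
    traj = Trajectory()

    def record():
        rho, rho_U, _ = moments(state)
        if store_snapshots:
            traj.snapshots.append(Snapshot(state.t, rho, rho_U))
        traj.times.append(state.t)
        traj.mass.append(float(np.sum(rho) * state.cell_area))
        traj.com.append(center_of_mass(rho, d))
        traj.vbar.append(mean_speed_pi_half(state))

    record()
    for step in range(n_steps):
        transport_substep(state, dt / 2.0, config.scheme)
        turning_substep(state, dt, config.mu)
        transport_substep(state, dt / 2.0, config.scheme)
        state.t += dt
        if np.any(~np.isfinite(state.p)) or np.any(state.p < -1e-12):
            raise DegenerateStateError(
                f"NaN or negative density detected at t = {state.t:g}")
        if (step + 1) % every == 0 or step == n_steps - 1:
            record()
            if callback is not None and callback(state):
                break
        elif callback is not None and callback(state):
            record()
            break
    return traj
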