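"""Non-local sensing of the guidance cues and transition probabilities.

A cell at position ``x`` extends protrusions of maximal length ``R`` (the
sensing radius) in every direction ``vhat`` and weighs the cues it measures
along the ray ``x + lambda vhat`` with a sensing kernel ``gamma(lambda)``
supported in ``[0, R]``.  Two strategies are modelled:

* *independent sensing*: fibers and chemoattractant are averaged separately
  with kernels ``gamma_q`` and ``gamma_S``, and the transition probability
  is the normalized product of the two averages;
* *dependent sensing*: one simultaneous average of the product
  ``S(x + lambda vhat) q(x + lambda vhat, vhat)`` with a single kernel.

Rays are truncated at the domain boundary (only in-domain points are
sensed); no per-ray renormalization is applied, the global normalization
``c(x)`` alone restores unit probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateKernelError, InvalidParameterError
from .fields import (DirectionGrid, Domain2D, FiberField, ScalarCueField,
                     SpeedDistribution)

__all__ = [
    "SensingKernel",
    "KernelMoments",
    "TransitionKernel",
    "kernel_moments",
    "ray_average_S",
    "ray_average_q",
    "transition_independent",
    "transition_dependent",
    "transition_mean_velocity",
    "transition_covariance",
]

#: default number of midpoint quadrature nodes along a ray
N_LAMBDA = 16


@dataclass(frozen=True)
class SensingKernel:
    """Weight profile ``gamma(lambda) >= 0`` over the sensed distance.

    Kinds: ``dirac_at_R`` (membrane-tip sensing), ``heaviside`` (uniform
    averaging along the protrusion), ``dirac_at_0`` (local sensing), or
    ``custom`` with a tabulated profile on ``[0, R]``.
    """

    kind: str
    R: float
    table: np.ndarray | None = None  # gamma sampled uniformly on [0, R]

    def __post_init__(self):
        if self.kind not in ("dirac_at_R", "heaviside", "dirac_at_0", "custom"):
            raise InvalidParameterError(f"unknown kernel kind {self.kind!r}")
        if self.R <= 0:
            raise InvalidParameterError("sensing radius R must be positive")
        if self.kind == "custom":
            if self.table is None:
                raise InvalidParameterError("custom kernel needs a table")
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 1 or tab.size < 2:
                raise InvalidParameterError("kernel table must be 1-D with >= 2 values")
            if np.any(tab < 0):
                raise InvalidParameterError("sensing kernel must be non-negative")
            object.__setattr__(self, "table", tab)

    def gamma(self, lam):
        """Kernel value at distances ``lam`` (custom/heaviside kinds only)."""
        lam = np.asarray(lam, dtype=float)
        if self.kind == "heaviside":
            return np.where(lam <= self.R, 1.0, 0.0)
        if self.kind == "custom":
            grid = np.linspace(0.0, self.R, self.table.size)
            return np.interp(lam, grid, self.table, left=0.0, right=0.0)
        raise InvalidParameterError("Dirac kernels have no pointwise density")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "R": self.R}
        if self.table is not None:
            d["table"] = np.asarray(self.table).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensingKernel":
        table = np.asarray(d["table"], dtype=float) if d.get("table") is not None else None
        return cls(kind=d["kind"], R=float(d["R"]), table=table)


@dataclass(frozen=True)
class KernelMoments:
    """Moments ``Gamma_i = int lambda^i gamma(lambda) dlambda`` and their
    ratio ``Gamma = Gamma_1 / Gamma_0`` (the mean sensed distance)."""

    Gamma0: float
    Gamma1: float

    @property
    def Gamma(self) -> float:
        return self.Gamma1 / self.Gamma0


def kernel_moments(kernel: SensingKernel) -> KernelMoments:
    """Closed-form moments for the named kernels, quadrature for custom."""
    R = kernel.R
    if kernel.kind == "dirac_at_R":
        return KernelMoments(1.0, R)
    if kernel.kind == "dirac_at_0":
        return KernelMoments(1.0, 0.0)
    if kernel.kind == "heaviside":
        return KernelMoments(R, R**2 / 2.0)
    lam = np.linspace(0.0, R, kernel.table.size)
    g0 = float(np.trapezoid(kernel.table, lam))
    g1 = float(np.trapezoid(lam * kernel.table, lam))
    if g0 <= 0:
        raise InvalidParameterError("custom kernel has zero mass")
    return KernelMoments(g0, g1)


# --------------------------------------------------------------------------
# ray geometry
# --------------------------------------------------------------------------

def _boundary_distance(domain: Domain2D, x, y, cx: float, cy: float):
    """Distance from points to the domain boundary along direction (cx, cy)."""
    with np.errstate(divide="ignore"):
        if cx > 1e-14:
            tx = (domain.x_max - np.asarray(x, dtype=float)) / cx
        elif cx < -1e-14:
            tx = (domain.x_min - np.asarray(x, dtype=float)) / cx
        else:
            tx = np.full(np.shape(x), np.inf)
        if cy > 1e-14:
            ty = (domain.y_max - np.asarray(y, dtype=float)) / cy
        elif cy < -1e-14:
            ty = (domain.y_min - np.asarray(y, dtype=float)) / cy
        else:
            ty = np.full(np.shape(y), np.inf)
    return np.minimum(tx, ty)


def _ray_integral(eval_along, domain, x, y, cx, cy, kernel, n_lambda):
    """Quadrature of ``gamma(lambda) f(x + lambda vhat)`` with boundary
    truncation.  ``eval_along(px, py)`` evaluates the integrand factor f.

    Dirac kernels are evaluated by direct point lookup (mass outside the
    domain is annihilated); distributed kernels use a midpoint rule with
    ``n_lambda`` nodes on the truncated support, which preserves positivity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kernel.kind == "dirac_at_0":
        return eval_along(x, y)
    t_b = _boundary_distance(domain, x, y, cx, cy)
    if kernel.kind == "dirac_at_R":
        inside = kernel.R <= t_b
        px = x + kernel.R * cx
        py = y + kernel.R * cy
        vals = eval_along(np.where(inside, px, x), np.where(inside, py, y))
        return np.where(inside, vals, 0.0)
    lam_max = np.minimum(kernel.R, t_b)
    frac = (np.arange(n_lambda) + 0.5) / n_lambda
    lam = lam_max[..., None] * frac  # (..., n_lambda)
    px = x[..., None] + lam * cx
    py = y[..., None] + lam * cy
    vals = eval_along(px, py)
    if kernel.kind == "custom":
        vals = vals * kernel.gamma(lam)
    dl = lam_max / n_lambda
    return np.sum(vals, axis=-1) * dl


def ray_average_S(S: ScalarCueField, x, y, cx, cy, kernel: SensingKernel,
                  n_lambda: int = N_LAMBDA):
    """Non-local average ``int gamma_S(lambda) S(x + lambda vhat) dlambda``
    along the direction ``vhat = (cx, cy)`` (boundary-truncated)."""
    return _ray_integral(lambda px, py: S(px, py), S.domain, x, y,
                         float(cx), float(cy), kernel, n_lambda)


def ray_average_q(fibers: FiberField, x, y, cx, cy, kernel: SensingKernel,
                  n_lambda: int = N_LAMBDA):
    """Non-local average ``int gamma_q(lambda) q(x + lambda vhat, vhat)
    dlambda``: the fiber density is sampled at the displaced point but always
    evaluated at the sensing direction ``vhat`` itself (radial fibers)."""
    vhat = np.array([cx, cy], dtype=float)
    return _ray_integral(lambda px, py: fibers.q_at(px, py, vhat),
                         fibers.domain, x, y, float(cx), float(cy), kernel, n_lambda)


def _grid_averages(field_eval, domain: Domain2D, dirs: DirectionGrid,
                   kernel: SensingKernel, n_lambda: int) -> np.ndarray:
    """Ray averages on the full (x, y, theta) tensor grid."""
    X, Y = domain.mesh()
    out = np.empty((domain.nx, domain.ny, dirs.n_theta))
    for j in range(dirs.n_theta):
        cx, cy = float(dirs.vx[j]), float(dirs.vy[j])
        out[:, :, j] = _ray_integral(
            lambda px, py: field_eval(px, py, cx, cy),
            domain, X, Y, cx, cy, kernel, n_lambda)
    return out


def ray_average_S_grid(S: ScalarCueField, dirs: DirectionGrid,
                       kernel: SensingKernel, n_lambda: int = N_LAMBDA) -> np.ndarray:
    return _grid_averages(lambda px, py, cx, cy: S(px, py),
                          S.domain, dirs, kernel, n_lambda)


def ray_average_q_grid(fibers: FiberField, dirs: DirectionGrid,
                       kernel: SensingKernel, n_lambda: int = N_LAMBDA) -> np.ndarray:
    def ev(px, py, cx, cy):
        return fibers.q_at(px, py, np.array([cx, cy]))
    return _grid_averages(ev, fibers.domain, dirs, kernel, n_lambda)


# --------------------------------------------------------------------------
# transition kernels
# --------------------------------------------------------------------------

@dataclass
class TransitionKernel:
    """Angular factor of the post-tumble transition probability.

    ``values[i, j, m]`` is ``T(x_ij, theta_m)``; the speed factor ``psi(v)``
    is attached at solver level, so the direction quadrature of ``values``
    is 1 at every node.  ``c`` is the normalization map ``c(x)``.
    """

    domain: Domain2D
    dirs: DirectionGrid
    values: np.ndarray
    c: np.ndarray
    provenance: str = "independent"
    kernels: dict = field(default_factory=dict)

    def direction_mass(self) -> np.ndarray:
        """Direction-space quadrature of T at every node (should be 1)."""
        return np.sum(self.values, axis=2) * self.dirs.weight


def _normalize(weights: np.ndarray, domain: Domain2D, dirs: DirectionGrid,
               provenance: str, kernels: dict) -> TransitionKernel:
    tot = np.sum(weights, axis=2) * dirs.weight
    bad = np.argwhere(tot <= 0.0)
    if bad.size:
        i, j = bad[0]
        raise DegenerateKernelError(
            f"all sensing rays annihilated at grid node ({i}, {j}) "
            f"(x = {domain.x_nodes[i]:.4f}, y = {domain.y_nodes[j]:.4f})")
    c = 1.0 / tot
    return TransitionKernel(domain=domain, dirs=dirs,
                            values=weights * c[:, :, None], c=c,
                            provenance=provenance, kernels=kernels)


def transition_independent(fibers: FiberField, S: ScalarCueField,
                           gamma_q: SensingKernel, gamma_S: SensingKernel,
                           dirs: DirectionGrid | None = None,
                           n_lambda: int = N_LAMBDA) -> TransitionKernel:
    """Transition probability for independent sensing: the product of the
    two separately averaged cues, normalized per node."""
    dirs = dirs or DirectionGrid()
    if fibers.domain != S.domain:
        raise InvalidParameterError("cue fields must share a domain")
    Aq = ray_average_q_grid(fibers, dirs, gamma_q, n_lambda)
    AS = ray_average_S_grid(S, dirs, gamma_S, n_lambda)
    prov = "local-q" if gamma_q.kind == "dirac_at_0" else "independent"
    return _normalize(Aq * AS, fibers.domain, dirs, prov,
                      {"gamma_q": gamma_q.to_dict(), "gamma_S": gamma_S.to_dict()})


def transition_dependent(fibers: FiberField, S: ScalarCueField,
                         gamma: SensingKernel,
                         dirs: DirectionGrid | None = None,
                         n_lambda: int = N_LAMBDA) -> TransitionKernel:
    """Transition probability for dependent sensing: one simultaneous
    average of ``S(x + lambda vhat) q(x + lambda vhat, vhat)``."""
    dirs = dirs or DirectionGrid()
    if fibers.domain != S.domain:
        raise InvalidParameterError("cue fields must share a domain")
    domain = fibers.domain
    X, Y = domain.mesh()
    W = np.empty((domain.nx, domain.ny, dirs.n_theta))
    for j in range(dirs.n_theta):
        cx, cy = float(dirs.vx[j]), float(dirs.vy[j])
        vhat = np.array([cx, cy])
        W[:, :, j] = _ray_integral(
            lambda px, py: S(px, py) * fibers.q_at(px, py, vhat),
            domain, X, Y, cx, cy, gamma, n_lambda)
    return _normalize(W, domain, dirs, "dependent", {"gamma": gamma.to_dict()})


def transition_mean_velocity(T: TransitionKernel,
                             psi: SpeedDistribution) -> np.ndarray:
    """Mean post-tumble velocity field ``U_T(x)``; shape (nx, ny, 2).

    The speed factor contributes the mean speed ``Ubar``; the angular
    quadrature of ``T vhat`` carries the directional bias.
    """
    w = T.dirs.weight
    ux = np.sum(T.values * T.dirs.vx, axis=2) * w
    uy = np.sum(T.values * T.dirs.vy, axis=2) * w
    return psi.Ubar * np.stack([ux, uy], axis=-1)


def transition_covariance(T: TransitionKernel,
                          psi: SpeedDistribution) -> np.ndarray:
    """Post-tumble variance-covariance tensor field ``D_T(x)``.

    With the separable speed factor the integral reduces to
    ``D_T = D M2 - U_T (x) U_T`` where ``M2`` is the second angular moment
    of T and ``D`` the speed energy; shape (nx, ny, 2, 2).
    """
    w = T.dirs.weight
    U = transition_mean_velocity(T, psi)
    M2 = np.empty((T.domain.nx, T.domain.ny, 2, 2))
    M2[..., 0, 0] = np.sum(T.values * T.dirs.vx**2, axis=2) * w
    M2[..., 0, 1] = np.sum(T.values * T.dirs.vx * T.dirs.vy, axis=2) * w
    M2[..., 1, 0] = M2[..., 0, 1]
    M2[..., 1, 1] = np.sum(T.values * T.dirs.vy**2, axis=2) * w
    return psi.D * M2 - U[..., :, None] * U[..., None, :]
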