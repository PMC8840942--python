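"""Guidance-cue fields and regime analysis.

Two external cues drive cell polarization in the model:

* a chemoattractant ``S(x) > 0`` (mono-directional cue, chemotaxis), and
* a non-polarized fiber network described by a direction distribution
  ``q(x, vhat)`` (bi-directional cue, contact guidance), modelled with the
  bimodal von Mises density with concentration ``k(x)`` and axis angle
  ``theta_q(x)``.

This module constructs the parametric fields used throughout, evaluates the
fiber statistics (mean direction ``E_q``, variance-covariance tensor ``D_q``,
circular variance), and computes the characteristic lengths of variation
``l_S`` and ``l_q`` whose ratios to the sensing radius ``R`` select the
macroscopic regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import ive

from .exceptions import InvalidParameterError, InvariantViolationError

__all__ = [
    "Domain2D",
    "DirectionGrid",
    "SpeedDistribution",
    "ScalarCueField",
    "FiberField",
    "RegimeReport",
    "gaussian_chemoattractant",
    "linear_chemoattractant",
    "constant_chemoattractant",
    "bimodal_von_mises",
    "gaussian_alignment_map",
    "stripe_alignment_map",
    "fiber_mean_direction",
    "fiber_diffusion_tensor",
    "circular_variance",
    "char_length_S",
    "char_length_q",
    "regime_classify",
]


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Domain2D:
    """Rectangular spatial domain with a cell-centered grid.

    Nodes sit at cell centers: ``x_i = x_min + (i + 1/2) dx``.
    """

    x_min: float = 0.0
    x_max: float = 5.0
    y_min: float = 0.0
    y_max: float = 5.0
    nx: int = 128
    ny: int = 128

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidParameterError("domain extents must be positive")
        if self.nx < 4 or self.ny < 4:
            raise InvalidParameterError("need at least 4 grid nodes per axis")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def dy(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def x_nodes(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_nodes(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.dy

    def mesh(self):
        """Node coordinate arrays ``X, Y`` of shape ``(nx, ny)``."""
        return np.meshgrid(self.x_nodes, self.y_nodes, indexing="ij")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x <= self.x_max) and (self.y_min <= y <= self.y_max)


@dataclass(frozen=True)
class DirectionGrid:
    """Uniform discretization of the unit circle.

    ``n_theta`` uniform angles on ``[0, 2pi)``.  An even count keeps antipodal
    pairs on-grid, which makes the symmetry ``q(vhat) = q(-vhat)`` exact in
    the discretization; a count divisible by 4 additionally keeps specular
    wall reflections (``theta -> pi - theta`` and ``theta -> -theta``) on-grid.
    """

    n_theta: int = 32

    def __post_init__(self):
        if self.n_theta < 4 or self.n_theta % 2 != 0:
            raise InvalidParameterError("n_theta must be even and >= 4")

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_theta) / self.n_theta

    @property
    def vx(self) -> np.ndarray:
        return np.cos(self.theta)

    @property
    def vy(self) -> np.ndarray:
        return np.sin(self.theta)

    @property
    def weight(self) -> float:
        """Quadrature weight of the rectangle rule (exact for trig polys)."""
        return 2.0 * np.pi / self.n_theta

    @property
    def antipode(self) -> np.ndarray:
        """Index map ``theta -> theta + pi``."""
        return (np.arange(self.n_theta) + self.n_theta // 2) % self.n_theta

    def reflect_x(self) -> np.ndarray:
        """Index map of specular reflection across a wall with normal ex
        (``theta -> pi - theta``); requires ``n_theta`` divisible by 4 only
        for the ``theta -> -theta`` companion, this one is always on-grid."""
        n = self.n_theta
        return (n // 2 - np.arange(n)) % n

    def reflect_y(self) -> np.ndarray:
        """Index map of specular reflection across a wall with normal ey
        (``theta -> -theta``)."""
        n = self.n_theta
        return (n - np.arange(n)) % n

    def index_of(self, angle: float) -> int:
        """Index of an on-grid angle; raises if the angle is off-grid."""
        pos = (angle % (2 * np.pi)) / (2 * np.pi) * self.n_theta
        idx = int(round(pos)) % self.n_theta
        if not np.isclose(pos % self.n_theta, round(pos) % self.n_theta, atol=1e-9):
            raise InvalidParameterError(f"angle {angle} is not on the direction grid")
        return idx


# --------------------------------------------------------------------------
# speed distribution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedDistribution:
    """Probability density ``psi(v)`` of cell speeds on ``[0, V]``.

    Carries the moments that enter every macroscopic coefficient: the mean
    speed ``Ubar``, the energy ``D = <v^2>`` and the variance
    ``sigma_psi^2 = (D - Ubar^2)/2``.
    """

    V: float
    Ubar: float
    D: float
    kind: str = "uniform"

    def __post_init__(self):
        if self.V <= 0:
            raise InvalidParameterError("maximal speed V must be positive")
        if not (0 < self.Ubar <= self.V):
            raise InvalidParameterError("mean speed must lie in (0, V]")
        if self.D < self.Ubar**2 - 1e-12:
            raise InvalidParameterError("energy must dominate squared mean speed")

    @property
    def sigma2(self) -> float:
        return 0.5 * (self.D - self.Ubar**2)

    @classmethod
    def uniform(cls, V: float = 1.0) -> "SpeedDistribution":
        """Uniform speed density on [0, V] (the default used in simulations)."""
        return cls(V=V, Ubar=V / 2.0, D=V**2 / 3.0, kind="uniform")

    @classmethod
    def from_pdf(cls, pdf, V: float, n: int = 4096) -> "SpeedDistribution":
        """Build from a density callable by midpoint quadrature on [0, V]."""
        v = (np.arange(n) + 0.5) * V / n
        w = V / n
        psi = np.asarray(pdf(v), dtype=float)
        if np.any(psi < 0):
            raise InvalidParameterError("speed density must be non-negative")
        mass = np.sum(psi) * w
        if not np.isclose(mass, 1.0, atol=1e-6):
            raise InvalidParameterError(f"speed density mass {mass:.6f} != 1")
        return cls(V=V, Ubar=float(np.sum(v * psi) * w),
                   D=float(np.sum(v**2 * psi) * w), kind="custom")

    def discretize(self, n_v: int):
        """Midpoint speed nodes, weights and density values for the solver.

        Returns ``(v_nodes, w_v, psi_vals)`` with ``sum(w_v * psi_vals) = 1``.
        Only the uniform family is discretized (custom densities are used for
        their moments in macroscopic formulas).
        """
        if self.kind != "uniform":
            raise InvalidParameterError("only uniform psi can be discretized")
        v = (np.arange(n_v) + 0.5) * self.V / n_v
        w = np.full(n_v, self.V / n_v)
        psi = np.full(n_v, 1.0 / self.V)
        return v, w, psi


# --------------------------------------------------------------------------
# chemoattractant
# --------------------------------------------------------------------------

class ScalarCueField:
    """Chemoattractant ``S(x) > 0`` with (optionally analytic) gradient."""

    def __init__(self, domain: Domain2D, kind: str, params: dict,
                 value_fn=None, grad_fn=None, values=None):
        self.domain = domain
        self.kind = kind
        self.params = dict(params)
        self._value_fn = value_fn
        self._grad_fn = grad_fn
        self.analytic = value_fn is not None
        if values is not None:
            self.values = np.asarray(values, dtype=float)
        else:
            X, Y = domain.mesh()
            self.values = value_fn(X, Y)
        if np.any(self.values <= 0):
            raise InvariantViolationError("chemoattractant must be strictly positive")
        self._interp = RegularGridInterpolator(
            (domain.x_nodes, domain.y_nodes), self.values,
            method="linear", bounds_error=False, fill_value=None)

    # -- evaluation --------------------------------------------------------

    def __call__(self, x, y):
        """S at arbitrary points; analytic when parametric, else bilinear
        interpolation with clamping at the node hull."""
        if self.analytic:
            return self._value_fn(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return self._interp_clamped(x, y)

    def _interp_clamped(self, x, y):
        d = self.domain
        xc = np.clip(x, d.x_nodes[0], d.x_nodes[-1])
        yc = np.clip(y, d.y_nodes[0], d.y_nodes[-1])
        pts = np.stack([np.ravel(xc), np.ravel(yc)], axis=-1)
        out = self._interp(pts)
        return out.reshape(np.shape(xc))

    def gradient(self, x, y):
        """Gradient ``(S_x, S_y)`` at points; analytic when available."""
        if self._grad_fn is not None:
            return self._grad_fn(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        gx, gy = self.gradient_grid()
        ix = RegularGridInterpolator((self.domain.x_nodes, self.domain.y_nodes), gx,
                                     bounds_error=False, fill_value=None)
        iy = RegularGridInterpolator((self.domain.x_nodes, self.domain.y_nodes), gy,
                                     bounds_error=False, fill_value=None)
        pts = np.stack([np.ravel(x), np.ravel(y)], axis=-1)
        return ix(pts).reshape(np.shape(x)), iy(pts).reshape(np.shape(x))

    def gradient_grid(self):
        """Gradient on the grid (analytic or centered differences)."""
        if self._grad_fn is not None:
            X, Y = self.domain.mesh()
            return self._grad_fn(X, Y)
        gx = np.gradient(self.values, self.domain.dx, axis=0)
        gy = np.gradient(self.values, self.domain.dy, axis=1)
        return gx, gy


def gaussian_chemoattractant(domain: Domain2D, m_S: float, var_S: float,
                             center) -> ScalarCueField:
    """Gaussian chemoattractant profile

    ``S(x, y) = m_S / sqrt(2 pi var_S) * exp(-|x - c|^2 / (2 var_S))``.
    """
    if var_S <= 0 or m_S <= 0:
        raise InvalidParameterError("m_S and var_S must be positive")
    cx, cy = float(center[0]), float(center[1])
    amp = m_S / np.sqrt(2.0 * np.pi * var_S)

    def value(x, y):
        return amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * var_S))

    def grad(x, y):
        s = value(x, y)
        return -(x - cx) / var_S * s, -(y - cy) / var_S * s

    return ScalarCueField(domain, "gaussian",
                          {"m_S": m_S, "sigma_S2": var_S, "x_S": cx, "y_S": cy},
                          value_fn=value, grad_fn=grad)


def linear_chemoattractant(domain: Domain2D, m_S: float,
                           floor: float | None = None) -> ScalarCueField:
    """Linear chemoattractant ``S(x, y) = m_S * y + floor``.

    The profile vanishes at ``y = 0``, while the model requires a strictly
    positive field (normalizations divide by ``S``); a small configurable
    floor (default ``0.01 * m_S``) regularizes it.
    """
    if m_S <= 0:
        raise InvalidParameterError("m_S must be positive")
    if floor is None:
        floor = 0.01 * m_S
    if floor < 0:
        raise InvalidParameterError("floor must be non-negative")

    def value(x, y):
        return m_S * y + floor + 0.0 * x

    def grad(x, y):
        z = np.zeros(np.broadcast(x, y).shape)
        return z, z + m_S

    return ScalarCueField(domain, "linear", {"m_S": m_S, "floor": floor},
                          value_fn=value, grad_fn=grad)


def constant_chemoattractant(domain: Domain2D, s0: float = 1.0) -> ScalarCueField:
    """Homogeneous chemoattractant (no chemotactic bias)."""
    if s0 <= 0:
        raise InvalidParameterError("s0 must be positive")

    def value(x, y):
        return np.full(np.broadcast(x, y).shape, float(s0))

    def grad(x, y):
        z = np.zeros(np.broadcast(x, y).shape)
        return z, z.copy()

    return ScalarCueField(domain, "constant", {"s0": s0}, value_fn=value, grad_fn=grad)


# --------------------------------------------------------------------------
# fiber orientation distribution
# --------------------------------------------------------------------------

def bimodal_von_mises(k, u, vhat):
    """Bimodal von Mises direction density on the unit circle.

    ``q(vhat) = (exp(k u.vhat) + exp(-k u.vhat)) / (4 pi I0(k))``

    evaluated in the log domain with exponentially scaled Bessel functions,
    so arbitrarily large concentrations (``k = 700`` in the fiber stripes)
    do not overflow.  ``u`` is the fiber axis (the density is antipodally
    symmetric: +u and -u are equivalent).

    Parameters broadcast: ``k`` scalar or array, ``u`` shape ``(..., 2)``,
    ``vhat`` shape ``(..., 2)``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise InvalidParameterError("concentration k must be non-negative")
    u = np.asarray(u, dtype=float)
    vhat = np.asarray(vhat, dtype=float)
    c = u[..., 0] * vhat[..., 0] + u[..., 1] * vhat[..., 1]
    kc = np.abs(k * c)
    # log cosh(kc) = kc + log1p(exp(-2 kc)) - log 2 ; log I0(k) = log ive(0,k) + k
    log_q = kc + np.log1p(np.exp(-2.0 * kc)) - np.log(2.0) \
        - np.log(2.0 * np.pi) - (np.log(ive(0, k)) + k)
    return np.exp(log_q)


def _axis_vectors(theta_q):
    theta_q = np.asarray(theta_q, dtype=float)
    return np.stack([np.cos(theta_q), np.sin(theta_q)], axis=-1)


class FiberField:
    """Spatial field of fiber concentration ``k(x)`` and axis ``theta_q(x)``.

    The direction distribution at each point is the bimodal von Mises
    density.  Off-grid evaluation interpolates the *parameters* (k and the
    fiber axis, the latter through the angle-doubled axial vector so that
    theta and theta + pi are identified) and re-evaluates the density, which
    preserves its unit direction-space mass exactly.
    """

    def __init__(self, domain: Domain2D, k_values, theta_q, kind: str = "custom",
                 params: dict | None = None, k_grad_fn=None):
        self.domain = domain
        self.kind = kind
        self.params = dict(params or {})
        self.k_values = np.broadcast_to(np.asarray(k_values, dtype=float),
                                        (domain.nx, domain.ny)).copy()
        if np.any(self.k_values < 0):
            raise InvalidParameterError("fiber concentration k must be >= 0")
        self.theta_q = np.broadcast_to(np.asarray(theta_q, dtype=float),
                                       (domain.nx, domain.ny)).copy()
        self._k_grad_fn = k_grad_fn  # analytic grad of k when parametric
        # axial (angle-doubled) representation for interpolation
        a1 = self.k_values * np.cos(2.0 * self.theta_q)
        a2 = self.k_values * np.sin(2.0 * self.theta_q)
        nodes = (domain.x_nodes, domain.y_nodes)
        self._ia1 = RegularGridInterpolator(nodes, a1, bounds_error=False, fill_value=None)
        self._ia2 = RegularGridInterpolator(nodes, a2, bounds_error=False, fill_value=None)
        self._ik = RegularGridInterpolator(nodes, self.k_values,
                                           bounds_error=False, fill_value=None)

    # -- parameter interpolation -------------------------------------------

    def k_theta_at(self, x, y):
        """Interpolated ``(k, theta_q)`` at arbitrary points (clamped)."""
        d = self.domain
        xc = np.clip(x, d.x_nodes[0], d.x_nodes[-1])
        yc = np.clip(y, d.y_nodes[0], d.y_nodes[-1])
        pts = np.stack([np.ravel(xc), np.ravel(yc)], axis=-1)
        a1 = self._ia1(pts)
        a2 = self._ia2(pts)
        k = np.hypot(a1, a2)
        theta = 0.5 * np.arctan2(a2, a1)
        return k.reshape(np.shape(xc)), theta.reshape(np.shape(xc))

    def q_at(self, x, y, vhat):
        """Direction density ``q(x, vhat)`` at arbitrary points.

        ``vhat`` has shape ``(..., 2)`` broadcastable against ``x, y``.
        """
        k, theta = self.k_theta_at(x, y)
        u = _axis_vectors(theta)
        return bimodal_von_mises(k, u, np.asarray(vhat, dtype=float))

    def q_grid(self, dirs: DirectionGrid) -> np.ndarray:
        """Density on the (x, y, theta) tensor grid; shape (nx, ny, n_theta)."""
        u = _axis_vectors(self.theta_q)[:, :, None, :]
        vhat = np.stack([dirs.vx, dirs.vy], axis=-1)[None, None, :, :]
        return bimodal_von_mises(self.k_values[:, :, None], u, vhat)

    def k_gradient_grid(self):
        """Gradient of the concentration map (analytic when parametric)."""
        if self._k_grad_fn is not None:
            X, Y = self.domain.mesh()
            return self._k_grad_fn(X, Y)
        gx = np.gradient(self.k_values, self.domain.dx, axis=0)
        gy = np.gradient(self.k_values, self.domain.dy, axis=1)
        return gx, gy

    @property
    def homogeneous(self) -> bool:
        return bool(np.ptp(self.k_values) == 0.0 and
                    (np.ptp(self.theta_q) == 0.0 or np.all(self.k_values == 0.0)))


def gaussian_alignment_map(domain: Domain2D, m_k: float, var_k: float, center,
                           theta_q: float) -> FiberField:
    """Fiber field whose concentration is a Gaussian bump

    ``k(x, y) = m_k * exp(-|x - c|^2 / (2 var_k))``

    with a constant alignment axis: fibers are strongly aligned near the
    bump center and uniformly distributed far from it.
    """
    if m_k < 0 or var_k <= 0:
        raise InvalidParameterError("m_k must be >= 0 and var_k > 0")
    cx, cy = float(center[0]), float(center[1])
    X, Y = domain.mesh()
    k = m_k * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * var_k))

    def k_grad(x, y):
        kv = m_k * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * var_k))
        return -(x - cx) / var_k * kv, -(y - cy) / var_k * kv

    return FiberField(domain, k, theta_q, kind="gaussian",
                      params={"m_k": m_k, "sigma_k2": var_k, "x_k": cx, "y_k": cy,
                              "theta_q": float(theta_q)},
                      k_grad_fn=k_grad)


def stripe_alignment_map(domain: Domain2D, x1: float, x2: float, k_in: float,
                         theta_q: float) -> FiberField:
    """Vertical stripe ``x1 <= x <= x2`` of aligned fibers (concentration
    ``k_in``, axis ``theta_q``); uniformly distributed fibers outside."""
    if not x2 > x1:
        raise InvalidParameterError("stripe requires x2 > x1")
    if k_in < 0:
        raise InvalidParameterError("k_in must be >= 0")
    X, _ = domain.mesh()
    k = np.where((X >= x1) & (X <= x2), float(k_in), 0.0)
    return FiberField(domain, k, theta_q, kind="stripe",
                      params={"x1": x1, "x2": x2, "k": k_in, "theta_q": float(theta_q)})


def uniform_fibers(domain: Domain2D, k: float = 0.0, theta_q: float = 0.0) -> FiberField:
    """Spatially homogeneous fiber field (isotropic when ``k = 0``)."""
    return FiberField(domain, np.full((domain.nx, domain.ny), float(k)), theta_q,
                      kind="constant", params={"k": k, "theta_q": float(theta_q)})


# --------------------------------------------------------------------------
# fiber statistics
# --------------------------------------------------------------------------

def fiber_mean_direction(fibers: FiberField, x, y,
                         dirs: DirectionGrid | None = None) -> np.ndarray:
    """Mean fiber direction ``E_q = \\int q vhat dvhat`` by quadrature.

    Vanishes (to quadrature accuracy) for every non-polarized network; for
    the antipodally symmetric density on an even direction grid the
    cancellation is exact up to round-off.
    """
    dirs = dirs or DirectionGrid(128)
    vhat = np.stack([dirs.vx, dirs.vy], axis=-1)
    q = fibers.q_at(np.asarray(x)[..., None], np.asarray(y)[..., None], vhat)
    ex = np.sum(q * dirs.vx, axis=-1) * dirs.weight
    ey = np.sum(q * dirs.vy, axis=-1) * dirs.weight
    return np.stack([ex, ey], axis=-1)


def fiber_diffusion_tensor(fibers: FiberField, x, y, method: str = "closed_form",
                           dirs: DirectionGrid | None = None) -> np.ndarray:
    """Variance-covariance tensor of the fiber distribution.

    Closed form for the bimodal von Mises density:

    ``D_q = 1/2 (1 - I2(k)/I0(k)) Id + I2(k)/I0(k) u (x) u``

    (Bessel ratios through scaled functions).  ``method='quadrature'``
    integrates ``q vhat (x) vhat`` on the direction grid instead; the two
    agree to quadrature accuracy.
    """
    k, theta = fibers.k_theta_at(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    if method == "closed_form":
        return dq_closed_form(k, theta)
    dirs = dirs or DirectionGrid(128)
    vhat = np.stack([dirs.vx, dirs.vy], axis=-1)
    u = _axis_vectors(theta)
    q = bimodal_von_mises(k[..., None], u[..., None, :], vhat)
    w = dirs.weight
    out = np.empty(np.shape(k) + (2, 2))
    out[..., 0, 0] = np.sum(q * dirs.vx * dirs.vx, axis=-1) * w
    out[..., 0, 1] = np.sum(q * dirs.vx * dirs.vy, axis=-1) * w
    out[..., 1, 0] = out[..., 0, 1]
    out[..., 1, 1] = np.sum(q * dirs.vy * dirs.vy, axis=-1) * w
    return out


def dq_closed_form(k, theta_q) -> np.ndarray:
    """Closed-form ``D_q`` from concentration and axis angle arrays."""
    k = np.asarray(k, dtype=float)
    r2 = ive(2, k) / ive(0, k)
    u = _axis_vectors(theta_q)
    out = np.zeros(np.shape(k) + (2, 2))
    iso = 0.5 * (1.0 - r2)
    out[..., 0, 0] = iso + r2 * u[..., 0] * u[..., 0]
    out[..., 0, 1] = r2 * u[..., 0] * u[..., 1]
    out[..., 1, 0] = out[..., 0, 1]
    out[..., 1, 1] = iso + r2 * u[..., 1] * u[..., 1]
    return out


def circular_variance(k) -> np.ndarray:
    """Degree of orientational spread ``1 - I1(k)/I0(k)``.

    Equals 1 for randomly disposed fibers (k = 0) and tends to 0 for
    perfectly aligned ones; evaluated with scaled Bessel functions.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise InvalidParameterError("concentration k must be non-negative")
    return 1.0 - ive(1, k) / ive(0, k)


# --------------------------------------------------------------------------
# characteristic lengths and regimes
# --------------------------------------------------------------------------

def char_length_S(S: ScalarCueField) -> float:
    """Characteristic variation length ``l_S = 1 / max |grad S| / S``.

    The supremum over the domain is approximated by a scan over grid nodes;
    the analytic gradient is used when the field is parametric.  Returns
    ``+inf`` for a homogeneous field.
    """
    if np.any(S.values <= 0):
        raise InvariantViolationError("S must be positive on the grid")
    gx, gy = S.gradient_grid()
    rel = np.hypot(gx, gy) / S.values
    m = float(np.max(rel))
    return np.inf if m == 0.0 else 1.0 / m


def char_length_q(fibers: FiberField, dirs: DirectionGrid | None = None,
                  method: str = "finite_difference") -> float:
    """Characteristic variation length of the fiber distribution

    ``l_q = 1 / max_x max_vhat |grad q . vhat| / q``.

    The default path evaluates ``q`` per direction node and takes centered
    differences in space; ``method='chain_rule'`` uses the parametric
    derivative ``dq/dk grad k`` (valid for a constant-axis field with an
    analytic concentration map).  Returns ``+inf`` for homogeneous fields.
    """
    dirs = dirs or DirectionGrid(64)
    if method == "chain_rule":
        if fibers._k_grad_fn is None or np.ptp(fibers.theta_q) != 0.0:
            raise InvalidParameterError(
                "chain_rule path needs an analytic k-map and constant axis")
        # d log q / dk = c tanh(k c) - I1(k)/I0(k), c = u . vhat
        k = fibers.k_values[:, :, None]
        theta0 = float(fibers.theta_q.flat[0])
        c = np.cos(dirs.theta - theta0)[None, None, :]
        r1 = (ive(1, k) / ive(0, k))
        dlogq_dk = c * np.tanh(k * c) - r1
        gkx, gky = fibers.k_gradient_grid()
        gk_dot_v = gkx[:, :, None] * dirs.vx + gky[:, :, None] * dirs.vy
        rel = np.abs(dlogq_dk * gk_dot_v)
    else:
        q = fibers.q_grid(dirs)
        gqx = np.gradient(q, fibers.domain.dx, axis=0)
        gqy = np.gradient(q, fibers.domain.dy, axis=1)
        rel = np.abs(gqx * dirs.vx + gqy * dirs.vy) / q
    m = float(np.max(rel))
    return np.inf if m == 0.0 else 1.0 / m


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of the regime analysis selecting the macroscopic limit.

    ``eta_S = R / l_S`` and ``eta_q = R / l_q`` compare the sensing radius
    with the cue variation lengths; ``eta = l_S / l_q`` is cell-independent
    and separates fiber-dominated (``eta > 1``) from chemotaxis-dominated
    (``eta < 1``) dynamics.  Case labels: (i) both fast, (ii) both slow,
    (iii) fast fibers / slow chemoattractant, (iv) the converse.
    """

    l_S: float
    l_q: float
    R: float
    eta_S: float
    eta_q: float
    eta: float
    case: str

    def to_dict(self) -> dict:
        return {"l_S": self.l_S, "l_q": self.l_q, "R": self.R,
                "eta_S": self.eta_S, "eta_q": self.eta_q, "eta": self.eta,
                "case": self.case}


def regime_classify(l_S: float, l_q: float, R: float) -> RegimeReport:
    """Classify the macroscopic regime from ``(l_S, l_q, R)``.

    Ties (``eta_i == 1``) are deterministically assigned to the fast branch.
    Infinite lengths (homogeneous cues) give ``eta_i = 0`` (slow).
    """
    if not (l_S > 0 and l_q > 0 and R > 0):
        raise InvalidParameterError("l_S, l_q and R must be positive")
    eta_S = 0.0 if np.isinf(l_S) else R / l_S
    eta_q = 0.0 if np.isinf(l_q) else R / l_q
    if np.isinf(l_q):
        eta = 0.0 if not np.isinf(l_S) else 1.0
    elif np.isinf(l_S):
        eta = np.inf
    else:
        eta = l_S / l_q
    fast_S = eta_S >= 1.0
    fast_q = eta_q >= 1.0
    if fast_S and fast_q:
        case = "i"
    elif not fast_S and not fast_q:
        case = "ii"
    elif fast_q:
        case = "iii"
    else:
        case = "iv"
    return RegimeReport(l_S=float(l_S), l_q=float(l_q), R=float(R),
                        eta_S=eta_S, eta_q=eta_q, eta=eta, case=case)
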