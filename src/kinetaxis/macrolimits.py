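"""Closed-form macroscopic limits of the kinetic model.

Depending on how the sensing radius ``R`` compares with the characteristic
variation lengths of the cues, the hydrodynamic limit of the transport
equation is either

* a pure advection equation ``d rho / dt + div(rho U_T) = 0`` (drift
  dominated; regimes i, iii, iv, where at least one cue varies fast on the
  sensing scale), or
* a drift-diffusion equation (regime ii, both cues slow)

  ``d rho / dt + div(U1 rho) = div( (1/mu) div(D Dq rho) )``

  of Keller-Segel type with logarithmic chemotactic sensitivity: the drift
  responds to ``grad S / S``, so rescaling ``S -> 2 S`` leaves it unchanged.

Note the diffusion term is a *double divergence* of the tensor ``D Dq rho``
(both derivatives hit the tensor), not the Fickian form ``div(D Dq grad
rho)``; the two differ wherever the fiber distribution varies in space.

This module evaluates the coefficient fields for both sensing models and
integrates the limit PDEs with conservative finite volumes, for cross-scale
validation against the kinetic solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import (ConfigurationError, DegenerateNormalizationError,
                         InvalidParameterError, InvariantViolationError)
from .fields import (DirectionGrid, Domain2D, FiberField, ScalarCueField,
                     SpeedDistribution, dq_closed_form)
from .sensing import (N_LAMBDA, SensingKernel, kernel_moments,
                      ray_average_q_grid, ray_average_S_grid)

__all__ = [
    "MacroCoefficients",
    "MacroState",
    "caseii_coeffs",
    "casei_drift",
    "caseiii_drift",
    "caseiv_drift",
    "drift_diffusion_solve",
    "advection_solve",
]

_DEGEN_TOL = 1e-13


@dataclass
class MacroCoefficients:
    """Coefficient fields of a macroscopic limit equation.

    ``drift`` (nx, ny, 2) is present for every case; ``diffusion``
    (nx, ny, 2, 2) and the sensitivities only for the drift-diffusion
    regime (case ii).
    """

    case: str
    model: str
    domain: Domain2D
    drift: np.ndarray
    diffusion: np.ndarray | None = None
    chi_S: np.ndarray | None = None
    chi_q: float | None = None
    mu: float = 1.0


@dataclass
class MacroState:
    """Macroscopic density on the grid at a given time."""

    domain: Domain2D
    rho: np.ndarray
    t: float = 0.0

    def total_mass(self) -> float:
        return float(np.sum(self.rho) * self.domain.dx * self.domain.dy)


# --------------------------------------------------------------------------
# tensor calculus helpers
# --------------------------------------------------------------------------

def _grad(f: np.ndarray, domain: Domain2D):
    """Centered differences, one-sided at walls (np.gradient convention)."""
    return (np.gradient(f, domain.dx, axis=0), np.gradient(f, domain.dy, axis=1))


def tensor_divergence(Dfield: np.ndarray, domain: Domain2D) -> np.ndarray:
    """Row-wise divergence of a (nx, ny, 2, 2) tensor field."""
    out = np.empty(Dfield.shape[:2] + (2,))
    for i in range(2):
        gx, _ = _grad(Dfield[..., i, 0], domain)
        _, gy = _grad(Dfield[..., i, 1], domain)
        out[..., i] = gx + gy
    return out


def _dq_field(fibers: FiberField) -> np.ndarray:
    return dq_closed_form(fibers.k_values, fibers.theta_q)


def _q_gradient_grid(fibers: FiberField, dirs: DirectionGrid):
    """Spatial gradient of the evaluated direction density per direction."""
    q = fibers.q_grid(dirs)
    gx = np.gradient(q, fibers.domain.dx, axis=0)
    gy = np.gradient(q, fibers.domain.dy, axis=1)
    return q, gx, gy


def _check_S(S: ScalarCueField):
    if np.any(S.values <= 0):
        raise InvariantViolationError("S must be strictly positive")


# --------------------------------------------------------------------------
# case (ii): drift-diffusion coefficients
# --------------------------------------------------------------------------

def caseii_coeffs(model: str, fibers: FiberField, S: ScalarCueField,
                  kernels, psi: SpeedDistribution,
                  mu: float = 1.0) -> MacroCoefficients:
    """Drift-diffusion coefficients for slow variation of both cues.

    Diffusion tensor ``D_T0 = D Dq``; first-order drift

    * independent: ``U1 = Ubar [ Gq div(Dq) + GS Dq grad(S)/S ]`` with
      ``Gq, GS`` the moment ratios of the two kernels;
    * dependent: ``U1 = Ubar G [ div(Dq) + Dq grad(S)/S ]``.

    ``kernels`` is ``(gamma_q, gamma_S)`` for the independent model or a
    single kernel for the dependent one.
    """
    _check_S(S)
    Dq = _dq_field(fibers)
    divDq = tensor_divergence(Dq, fibers.domain)
    gx, gy = S.gradient_grid()
    gradS_over_S = np.stack([gx, gy], axis=-1) / S.values[..., None]
    proj = np.einsum("...ij,...j->...i", Dq, gradS_over_S)
    if model == "independent":
        gamma_q, gamma_S = kernels
        Gq = kernel_moments(gamma_q).Gamma
        GS = kernel_moments(gamma_S).Gamma
    elif model == "dependent":
        gamma = kernels if isinstance(kernels, SensingKernel) else kernels[0]
        Gq = GS = kernel_moments(gamma).Gamma
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    drift = psi.Ubar * (Gq * divDq + GS * proj)
    return MacroCoefficients(
        case="ii", model=model, domain=fibers.domain, drift=drift,
        diffusion=psi.D * Dq,
        chi_S=psi.Ubar * GS / S.values, chi_q=psi.Ubar * Gq, mu=mu)


# --------------------------------------------------------------------------
# drift-dominated cases
# --------------------------------------------------------------------------

def casei_drift(model: str, fibers: FiberField, S: ScalarCueField,
                kernels, psi: SpeedDistribution,
                dirs: DirectionGrid | None = None,
                n_lambda: int = N_LAMBDA) -> MacroCoefficients:
    """Equilibrium drift for fast variation of both cues.

    The transition probability admits no expansion, so the drift is the
    full non-local mean post-tumble velocity: the normalized first angular
    moment of the (independent or dependent) sensing product.
    """
    _check_S(S)
    dirs = dirs or DirectionGrid()
    w = dirs.weight
    if model == "independent":
        gamma_q, gamma_S = kernels
        Aq = ray_average_q_grid(fibers, dirs, gamma_q, n_lambda)
        AS = ray_average_S_grid(S, dirs, gamma_S, n_lambda)
        W = Aq * AS
    elif model == "dependent":
        gamma = kernels if isinstance(kernels, SensingKernel) else kernels[0]
        from .sensing import transition_dependent
        W = transition_dependent(fibers, S, gamma, dirs, n_lambda).values
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    norm = np.sum(W, axis=2) * w
    ux = np.sum(W * dirs.vx, axis=2) * w / norm
    uy = np.sum(W * dirs.vy, axis=2) * w / norm
    drift = psi.Ubar * np.stack([ux, uy], axis=-1)
    return MacroCoefficients(case="i", model=model, domain=fibers.domain, drift=drift)


def _two_term_drift(case, model, domain, psi, num0, num1, den0, den1):
    """Assemble ``U = Ubar (num0 / den0 + num1 / den1)`` with the degenerate
    rule: a vanishing denominator with a vanishing numerator contributes
    zero (the corresponding expansion term is absent); a vanishing
    denominator under a finite numerator is an error."""
    drift = np.zeros(num0.shape)
    for num, den, tag in ((num0, den0, "c0"), (num1, den1, "c1")):
        scale = np.max(np.abs(num)) + np.max(np.abs(den)) + 1.0
        small_den = np.abs(den) < _DEGEN_TOL * scale
        small_num = np.linalg.norm(num, axis=-1) < _DEGEN_TOL * scale
        bad = small_den & ~small_num
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise DegenerateNormalizationError(
                f"normalization {tag} vanishes at node ({i}, {j}) while its "
                "numerator does not")
        safe_den = np.where(small_den, 1.0, den)
        drift += np.where(small_den[..., None], 0.0, num / safe_den[..., None])
    return MacroCoefficients(case=case, model=model, domain=domain,
                             drift=psi.Ubar * drift)


def caseiii_drift(model: str, fibers: FiberField, S: ScalarCueField,
                  kernels, psi: SpeedDistribution,
                  dirs: DirectionGrid | None = None,
                  n_lambda: int = N_LAMBDA) -> MacroCoefficients:
    """Leading-order drift for fast fiber and slow chemoattractant variation.

    Two-term assembly: a non-locally averaged mean fiber direction weighted
    by the local chemoattractant, plus the non-local fiber diffusion tensor
    contracted with ``grad S``, each with its own normalization.

    When the non-locally averaged fiber distribution ``q~`` is itself
    antipodally symmetric (homogeneous fibers, or local fiber sensing), the
    hyperbolic expansion degenerates (its second normalization vanishes
    identically) and the appropriate limit is parabolic: the returned
    coefficients then carry the drift ``Ubar G^S D_q~ grad(S)/S`` together
    with the diffusion tensor ``D D_q~``.
    """
    _check_S(S)
    dirs = dirs or DirectionGrid()
    w = dirs.weight
    domain = fibers.domain
    gsx, gsy = S.gradient_grid()
    gradS = np.stack([gsx, gsy], axis=-1)
    if model == "independent":
        gamma_q, gamma_S = kernels
        mS = kernel_moments(gamma_S)
        G0S, G1S = mS.Gamma0, mS.Gamma1
        GS = mS.Gamma
        G0q = kernel_moments(gamma_q).Gamma0
        Aq = ray_average_q_grid(fibers, dirs, gamma_q, n_lambda)  # int gamma_q q
        Bq = Aq  # same lambda-average enters both terms
        w0, w1 = G0S, G1S
    elif model == "dependent":
        gamma = kernels if isinstance(kernels, SensingKernel) else kernels[0]
        GS = kernel_moments(gamma).Gamma
        G0q = kernel_moments(gamma).Gamma0
        Aq = ray_average_q_grid(fibers, dirs, gamma, n_lambda)  # int gamma q
        Bq = _lambda_weighted_q(fibers, dirs, gamma, n_lambda)  # int lambda gamma q
        w0, w1 = 1.0, 1.0
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    # symmetric q~: hyperbolic expansion degenerate -> parabolic remark form
    qt = Aq / G0q
    Eqt = np.stack([np.sum(qt * dirs.vx, axis=2),
                    np.sum(qt * dirs.vy, axis=2)], axis=-1) * w
    if float(np.max(np.linalg.norm(Eqt, axis=-1))) < 1e-9:
        Dqt = np.empty((domain.nx, domain.ny, 2, 2))
        Dqt[..., 0, 0] = np.sum(qt * dirs.vx**2, axis=2) * w
        Dqt[..., 0, 1] = np.sum(qt * dirs.vx * dirs.vy, axis=2) * w
        Dqt[..., 1, 0] = Dqt[..., 0, 1]
        Dqt[..., 1, 1] = np.sum(qt * dirs.vy**2, axis=2) * w
        drift = psi.Ubar * GS * np.einsum(
            "...ij,...j->...i", Dqt, gradS) / S.values[..., None]
        return MacroCoefficients(case="iii", model=model, domain=domain,
                                 drift=drift, diffusion=psi.D * Dqt,
                                 chi_S=psi.Ubar * GS / S.values)
    # first term: S(x) * int vhat Aq dvhat / c0, c0 = 2 w0 S int Aq
    E1 = np.stack([np.sum(Aq * dirs.vx, axis=2), np.sum(Aq * dirs.vy, axis=2)],
                  axis=-1) * w
    num0 = w0 * S.values[..., None] * E1
    den0 = 2.0 * w0 * S.values * np.sum(Aq, axis=2) * w
    # second term: (int vhat (x) vhat Bq dvhat) gradS / c1,
    # c1 = 2 w1 int (gradS . vhat) Bq
    M2 = np.empty((domain.nx, domain.ny, 2, 2))
    M2[..., 0, 0] = np.sum(Bq * dirs.vx**2, axis=2) * w
    M2[..., 0, 1] = np.sum(Bq * dirs.vx * dirs.vy, axis=2) * w
    M2[..., 1, 0] = M2[..., 0, 1]
    M2[..., 1, 1] = np.sum(Bq * dirs.vy**2, axis=2) * w
    num1 = w1 * np.einsum("...ij,...j->...i", M2, gradS)
    gdotv = gradS[..., None, 0] * dirs.vx + gradS[..., None, 1] * dirs.vy
    den1 = 2.0 * w1 * np.sum(gdotv * Bq, axis=2) * w
    return _two_term_drift("iii", model, domain, psi, num0, num1, den0, den1)


def caseiv_drift(model: str, fibers: FiberField, S: ScalarCueField,
                 kernels, psi: SpeedDistribution,
                 dirs: DirectionGrid | None = None,
                 n_lambda: int = N_LAMBDA) -> MacroCoefficients:
    """Leading-order drift for fast chemoattractant and slow fiber variation.

    Two-term assembly: the local fiber density weighted by the non-local
    chemoattractant average, plus the direction dyads contracted with the
    spatial gradient of the fiber density, weighted by the (for the
    dependent model, distance-weighted) chemoattractant average.
    """
    _check_S(S)
    dirs = dirs or DirectionGrid()
    w = dirs.weight
    domain = fibers.domain
    q, gqx, gqy = _q_gradient_grid(fibers, dirs)
    gq_dot_v = gqx * dirs.vx + gqy * dirs.vy  # (nx, ny, n_theta)
    if model == "independent":
        gamma_q, gamma_S = kernels
        mq = kernel_moments(gamma_q)
        G0q, G1q = mq.Gamma0, mq.Gamma1
        AS = ray_average_S_grid(S, dirs, gamma_S, n_lambda)  # int gamma_S S
        BS = AS
        w0, w1 = G0q, G1q
    elif model == "dependent":
        gamma = kernels if isinstance(kernels, SensingKernel) else kernels[0]
        AS = ray_average_S_grid(S, dirs, gamma, n_lambda)
        BS = _lambda_weighted_S(S, dirs, gamma, n_lambda)  # int lambda gamma S
        w0, w1 = 1.0, 1.0
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    qa = q * AS
    num0 = w0 * np.stack([np.sum(qa * dirs.vx, axis=2),
                          np.sum(qa * dirs.vy, axis=2)], axis=-1) * w
    den0 = 2.0 * w0 * np.sum(qa, axis=2) * w
    gb = gq_dot_v * BS
    num1 = w1 * np.stack([np.sum(gb * dirs.vx, axis=2),
                          np.sum(gb * dirs.vy, axis=2)], axis=-1) * w
    den1 = 2.0 * w1 * np.sum(gb, axis=2) * w
    return _two_term_drift("iv", model, domain, psi, num0, num1, den0, den1)


def _lambda_weighted_q(fibers, dirs, kernel, n_lambda):
    """``int lambda gamma(lambda) q(x + lambda vhat, vhat) dlambda`` grid."""
    if kernel.kind == "dirac_at_R":
        return kernel.R * ray_average_q_grid(fibers, dirs, kernel, n_lambda)
    return ray_average_q_grid(fibers, dirs, _lambda_weight_kernel(kernel), n_lambda)


def _lambda_weighted_S(S, dirs, kernel, n_lambda):
    if kernel.kind == "dirac_at_R":
        return kernel.R * ray_average_S_grid(S, dirs, kernel, n_lambda)
    return ray_average_S_grid(S, dirs, _lambda_weight_kernel(kernel), n_lambda)


def _lambda_weight_kernel(kernel: SensingKernel) -> SensingKernel:
    """Kernel with density ``lambda * gamma(lambda)``."""
    if kernel.kind == "dirac_at_0":
        raise InvalidParameterError("lambda-weighted local kernel vanishes")
    n = 257
    lam = np.linspace(0.0, kernel.R, n)
    base = np.ones(n) if kernel.kind == "heaviside" else kernel.gamma(lam)
    return SensingKernel(kind="custom", R=kernel.R, table=lam * base)


# --------------------------------------------------------------------------
# finite-volume solvers for the limit equations
# --------------------------------------------------------------------------

def _advective_fluxes(rho: np.ndarray, drift: np.ndarray, domain: Domain2D,
                      periodic: bool = False):
    """Upwind advective fluxes on x- and y-faces; wall-normal drift is
    zeroed at the boundary (no-flux) unless periodic."""
    if periodic:
        ux_f = 0.5 * (drift[..., 0] + np.roll(drift[..., 0], -1, axis=0))
        Fx = np.maximum(ux_f, 0) * rho + np.minimum(ux_f, 0) * np.roll(rho, -1, axis=0)
        uy_f = 0.5 * (drift[..., 1] + np.roll(drift[..., 1], -1, axis=1))
        Fy = np.maximum(uy_f, 0) * rho + np.minimum(uy_f, 0) * np.roll(rho, -1, axis=1)
        return Fx, Fy
    ux_f = 0.5 * (drift[:-1, :, 0] + drift[1:, :, 0])  # interior x-faces
    Fx = np.maximum(ux_f, 0) * rho[:-1] + np.minimum(ux_f, 0) * rho[1:]
    uy_f = 0.5 * (drift[:, :-1, 1] + drift[:, 1:, 1])
    Fy = np.maximum(uy_f, 0) * rho[:, :-1] + np.minimum(uy_f, 0) * rho[:, 1:]
    return Fx, Fy


def _apply_divergence(rho, Fx, Fy, domain, dt, periodic=False):
    if periodic:
        rho -= dt / domain.dx * (Fx - np.roll(Fx, 1, axis=0))
        rho -= dt / domain.dy * (Fy - np.roll(Fy, 1, axis=1))
        return
    # cell update rho_i -= dt/dx (F_{i+1/2} - F_{i-1/2}); wall faces carry 0
    divx = np.zeros_like(rho)
    divx[:-1] -= Fx
    divx[1:] += Fx
    rho += dt / domain.dx * divx
    divy = np.zeros_like(rho)
    divy[:, :-1] -= Fy
    divy[:, 1:] += Fy
    rho += dt / domain.dy * divy


def advection_solve(coeffs: MacroCoefficients, rho0: np.ndarray, dt: float,
                    t_end: float, periodic: bool = False,
                    snapshot_every: float = 0.0) -> list[MacroState]:
    """Integrate the drift-dominated limit ``d rho/dt + div(rho U) = 0``.

    Upwind finite volumes; wall faces carry zero flux, honoring the no-flux
    boundary condition ``U . n = 0``.  A periodic mode exists for
    convergence sanity checks against analytic translates.
    """
    domain = coeffs.domain
    umax = float(np.max(np.abs(coeffs.drift))) + 1e-300
    if dt * umax > min(domain.dx, domain.dy):
        raise ConfigurationError("advective CFL violation")
    rho = np.array(rho0, dtype=float)
    n_steps = int(np.ceil(t_end / dt))
    out = [MacroState(domain, rho.copy(), 0.0)]
    every = max(1, int(round(snapshot_every / dt))) if snapshot_every > 0 else n_steps
    for s in range(n_steps):
        Fx, Fy = _advective_fluxes(rho, coeffs.drift, domain, periodic)
        _apply_divergence(rho, Fx, Fy, domain, dt, periodic)
        if (s + 1) % every == 0 or s == n_steps - 1:
            out.append(MacroState(domain, rho.copy(), (s + 1) * dt))
    return out


def drift_diffusion_solve(coeffs: MacroCoefficients, rho0: np.ndarray,
                          dt: float, t_end: float,
                          snapshot_every: float = 0.0) -> list[MacroState]:
    """Integrate the case-(ii) drift-diffusion limit.

    The diffusive term is the double divergence ``div((1/mu) div(D Dq rho))``
    with the tensor inside both derivatives; discretized in conservative
    flux form (the diffusive face flux is the face-interpolated divergence of
    the tensor field ``G = D Dq rho``), so total mass is conserved exactly
    and the no-flux condition is imposed by zeroing wall fluxes.
    """
    if coeffs.diffusion is None:
        raise ConfigurationError("drift_diffusion_solve needs case-ii coefficients")
    domain = coeffs.domain
    mu = coeffs.mu
    dmax = float(np.max(np.abs(coeffs.diffusion))) / mu
    if dt * dmax / min(domain.dx, domain.dy) ** 2 > 0.25:
        raise ConfigurationError("diffusive CFL violation: reduce dt")
    umax = float(np.max(np.abs(coeffs.drift)))
    if umax > 0 and dt * umax > min(domain.dx, domain.dy):
        raise ConfigurationError("advective CFL violation: reduce dt")
    rho = np.array(rho0, dtype=float)
    n_steps = int(np.ceil(t_end / dt))
    out = [MacroState(domain, rho.copy(), 0.0)]
    every = max(1, int(round(snapshot_every / dt))) if snapshot_every > 0 else n_steps
    dx, dy = domain.dx, domain.dy
    Dten = coeffs.diffusion / mu  # (nx, ny, 2, 2)
    for s in range(n_steps):
        G = Dten * rho[..., None, None]
        # F = div G (vector field), evaluated on faces component-wise:
        # x-face flux of the conservation law is F_x = dGxx/dx + dGxy/dy
        dGxx = (G[1:, :, 0, 0] - G[:-1, :, 0, 0]) / dx  # on x-faces
        Gxy_y = np.gradient(G[..., 0, 1], dy, axis=1)  # centered at cells
        Fx_diff = dGxx + 0.5 * (Gxy_y[1:, :] + Gxy_y[:-1, :])
        dGyy = (G[:, 1:, 1, 1] - G[:, :-1, 1, 1]) / dy
        Gyx_x = np.gradient(G[..., 1, 0], dx, axis=0)
        Fy_diff = dGyy + 0.5 * (Gyx_x[:, 1:] + Gyx_x[:, :-1])
        Fx_adv, Fy_adv = _advective_fluxes(rho, coeffs.drift, domain)
        Fx = Fx_adv - Fx_diff
        Fy = Fy_adv - Fy_diff
        _apply_divergence(rho, Fx, Fy, domain, dt)
        if (s + 1) % every == 0 or s == n_steps - 1:
            out.append(MacroState(domain, rho.copy(), (s + 1) * dt))
    return out
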