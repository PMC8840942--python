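"""Canonical experiment configurations and reproduction drivers.

Each experiment is a fully serializable :class:`ExperimentSpec` bundling the
cue fields, sensing strategy, solver settings and initial condition.  The
builders encode the four canonical study scenarios:

* ``build_test1`` — local fiber sensing on a vertical high-alignment stripe
  plus non-local chemotaxis toward a Gaussian source;
* ``build_test2`` — four sensing-strategy variants (local/Dirac/Heaviside,
  independent vs dependent) crossing a stripe toward the source;
* ``build_test3`` — the five regime rows (combinations of cue variation
  lengths and sensing radius spanning macroscopic cases i-iv) on a Gaussian
  alignment bump with diagonal fibers;
* ``build_application`` — electrospun-fiber scaffold under a linear
  chemoattractant gradient, with fibers parallel or perpendicular to it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError, NotConvergedError
from .fields import (DirectionGrid, Domain2D, FiberField, RegimeReport,
                     ScalarCueField, SpeedDistribution, char_length_q,
                     char_length_S, gaussian_alignment_map,
                     gaussian_chemoattractant, linear_chemoattractant,
                     regime_classify, stripe_alignment_map, uniform_fibers)
from .kinetic import SolverConfig, Trajectory, initialize_gaussian, run
from .sensing import (SensingKernel, TransitionKernel, transition_dependent,
                      transition_independent)

__all__ = [
    "ExperimentSpec",
    "DiagnosticsSeries",
    "build_test1",
    "build_test2",
    "build_test3",
    "build_application",
    "estimate_relaxation_time",
    "run_experiment",
]

#: default reproduction resolution (space x directions x speeds)
DEFAULT_RESOLUTION = {"nx": 128, "ny": 128, "n_theta": 32, "n_v": 4}
#: reduced single-speed resolution for quick runs
FAST_RESOLUTION = {"nx": 64, "ny": 64, "n_theta": 16, "n_v": 1}


@dataclass
class ExperimentSpec:
    """Serializable description of one simulation experiment."""

    name: str
    domain: dict = dc_field(default_factory=lambda: dict(
        x_min=0.0, x_max=5.0, y_min=0.0, y_max=5.0, nx=128, ny=128))
    fibers: dict = dc_field(default_factory=dict)
    chemo: dict = dc_field(default_factory=dict)
    model: str = "independent"  # independent | dependent
    kernels: dict = dc_field(default_factory=dict)
    solver: dict = dc_field(default_factory=lambda: dict(
        mu=1.0, V=1.0, n_theta=32, n_v=4, cfl=0.45, t_end=10.0,
        snapshot_every=1.0))
    initial: dict = dc_field(default_factory=lambda: dict(
        r0=0.1, center=(2.5, 2.5), sigma02=0.1, mode="rest"))
    diagnostics: list = dc_field(default_factory=lambda: ["mass", "com", "vbar"])
    seed: int = 0
    reference_lengths: dict = dc_field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def build_domain(self) -> Domain2D:
        return Domain2D(**self.domain)

    def build_fibers(self) -> FiberField:
        d = self.build_domain()
        f = dict(self.fibers)
        kind = f.pop("type")
        if kind == "stripe":
            return stripe_alignment_map(d, f["x1"], f["x2"], f["k"], f["theta_q"])
        if kind == "gaussian":
            return gaussian_alignment_map(d, f["m_k"], f["sigma_k2"],
                                          (f["x_k"], f["y_k"]), f["theta_q"])
        if kind == "constant":
            return uniform_fibers(d, f["k"], f["theta_q"])
        raise ConfigurationError(f"unknown fiber field type {kind!r}")

    def build_chemo(self) -> ScalarCueField:
        d = self.build_domain()
        c = dict(self.chemo)
        kind = c.pop("type")
        if kind == "gaussian":
            return gaussian_chemoattractant(d, c["m_S"], c["sigma_S2"],
                                            (c["x_S"], c["y_S"]))
        if kind == "linear":
            return linear_chemoattractant(d, c["m_S"], c.get("floor"))
        raise ConfigurationError(f"unknown chemoattractant type {kind!r}")

    def build_kernels(self):
        if self.model == "independent":
            return (SensingKernel.from_dict(self.kernels["gamma_q"]),
                    SensingKernel.from_dict(self.kernels["gamma_S"]))
        return SensingKernel.from_dict(self.kernels["gamma"])

    def build_speed(self) -> SpeedDistribution:
        return SpeedDistribution.uniform(self.solver.get("V", 1.0))

    def build_transition(self, dirs: DirectionGrid | None = None) -> TransitionKernel:
        dirs = dirs or DirectionGrid(self.solver["n_theta"])
        fib, chem = self.build_fibers(), self.build_chemo()
        if self.model == "independent":
            gq, gS = self.build_kernels()
            return transition_independent(fib, chem, gq, gS, dirs)
        return transition_dependent(fib, chem, self.build_kernels(), dirs)

    def regime_report(self, recompute: bool = False) -> RegimeReport:
        """Regime classification; uses the spec's reference variation
        lengths when present, else computes them from the fields."""
        R = self.sensing_radius
        if self.reference_lengths and not recompute:
            return regime_classify(self.reference_lengths["l_S"],
                                   self.reference_lengths["l_q"], R)
        return regime_classify(char_length_S(self.build_chemo()),
                               char_length_q(self.build_fibers()), R)

    @property
    def sensing_radius(self) -> float:
        ks = self.kernels
        key = "gamma" if self.model == "dependent" else "gamma_S"
        return float(ks[key]["R"])

    def with_resolution(self, nx=None, ny=None, n_theta=None, n_v=None,
                        fast: bool = False) -> "ExperimentSpec":
        """Copy with a different grid resolution (``fast`` selects the
        reduced single-speed preset)."""
        res = dict(FAST_RESOLUTION) if fast else {}
        for key, val in zip(("nx", "ny", "n_theta", "n_v"), (nx, ny, n_theta, n_v)):
            if val is not None:
                res[key] = val
        new = dataclasses.replace(
            self,
            domain={**self.domain, **{k: res[k] for k in ("nx", "ny") if k in res}},
            solver={**self.solver,
                    **{k: res[k] for k in ("n_theta", "n_v") if k in res}})
        return new

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["initial"] = dict(d["initial"])
        d["initial"]["center"] = list(d["initial"]["center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        init = dict(d.get("initial", {}))
        if "center" in init:
            init["center"] = tuple(init["center"])
        d["initial"] = init
        return cls(**d)


# --------------------------------------------------------------------------
# builders for the canonical configurations
# --------------------------------------------------------------------------

def build_test1(sigma_S2: float = 0.05, gamma_S_kind: str = "dirac_at_R",
                t_end: float = 30.0) -> ExperimentSpec:
    """Local fiber sensing + non-local chemotaxis on a k = 700 stripe.

    Fibers occupy the vertical stripe 1.8 <= x <= 3.2 with axis pi/2; the
    chemoattractant is a Gaussian of mass parameter 10 at (4, 4).  The
    default chemoattractant variance is 0.05; ``gamma_S_kind`` switches the
    chemoattractant kernel between membrane-tip (Dirac at R) and uniform
    (Heaviside) sensing for relaxation-time comparisons.
    """
    return ExperimentSpec(
        name="test1",
        fibers=dict(type="stripe", x1=1.8, x2=3.2, k=700.0, theta_q=np.pi / 2),
        chemo=dict(type="gaussian", m_S=10.0, sigma_S2=sigma_S2, x_S=4.0, y_S=4.0),
        model="independent",
        kernels=dict(gamma_q=dict(kind="dirac_at_0", R=0.5),
                     gamma_S=dict(kind=gamma_S_kind, R=0.5)),
        solver=dict(mu=1.0, V=1.0, n_theta=32, n_v=4, cfl=0.45, t_end=t_end,
                    snapshot_every=1.0),
        initial=dict(r0=0.1, center=(2.5, 2.5), sigma02=0.1, mode="rest"),
    )


def build_test2(setting: int) -> ExperimentSpec:
    """Four sensing strategies on a k = 100 stripe (2.1 <= x <= 2.9).

    1. local fibers, membrane-tip chemoattractant (Dirac at R);
    2. membrane-tip sensing of both cues (independent = dependent);
    3. independent sensing, Heaviside kernels for both cues;
    4. dependent sensing with one Heaviside kernel.
    """
    if setting not in (1, 2, 3, 4):
        raise InvalidParameterError("setting must be in 1..4")
    R = 0.5
    base = dict(
        name=f"test2_setting{setting}",
        fibers=dict(type="stripe", x1=2.1, x2=2.9, k=100.0, theta_q=np.pi / 2),
        chemo=dict(type="gaussian", m_S=10.0, sigma_S2=0.05, x_S=4.0, y_S=4.0),
        solver=dict(mu=1.0, V=1.0, n_theta=32, n_v=4, cfl=0.45, t_end=20.0,
                    snapshot_every=1.0),
        initial=dict(r0=0.1, center=(1.0, 0.5), sigma02=0.1, mode="rest"),
    )
    if setting == 1:
        base.update(model="independent",
                    kernels=dict(gamma_q=dict(kind="dirac_at_0", R=R),
                                 gamma_S=dict(kind="dirac_at_R", R=R)))
    elif setting == 2:
        base.update(model="independent",
                    kernels=dict(gamma_q=dict(kind="dirac_at_R", R=R),
                                 gamma_S=dict(kind="dirac_at_R", R=R)))
    elif setting == 3:
        base.update(model="independent",
                    kernels=dict(gamma_q=dict(kind="heaviside", R=R),
                                 gamma_S=dict(kind="heaviside", R=R)))
    else:
        base.update(model="dependent",
                    kernels=dict(gamma=dict(kind="heaviside", R=R)))
    return ExperimentSpec(**base)


#: Test-3 rows: (sigma_S2, printed l_S, m_k, printed l_q, R, expected case)
TEST3_ROWS = {
    1: dict(sigma_S2=0.05, l_S=0.002, m_k=100.0, l_q=0.0031, R=0.7, case="i"),
    2: dict(sigma_S2=1.8, l_S=0.25, m_k=100.0, l_q=0.0031, R=0.7, case="i"),
    3: dict(sigma_S2=0.25, l_S=0.055, m_k=10.0, l_q=0.031, R=0.02, case="ii"),
    4: dict(sigma_S2=1.8, l_S=0.25, m_k=100.0, l_q=0.0031, R=0.2, case="iii"),
    5: dict(sigma_S2=0.05, l_S=0.002, m_k=10.0, l_q=0.031, R=0.02, case="iv"),
}


def build_test3(row: int) -> ExperimentSpec:
    """Regime-comparison rows on a Gaussian alignment bump.

    Fibers have axis 3pi/4 with a Gaussian concentration bump at (2.5, 2.5)
    of variance 0.15; the chemoattractant sits at (4.5, 4.5).  Each row
    picks (chemoattractant variance, fiber strength, sensing radius) to land
    in one macroscopic regime; independent Heaviside sensing throughout.
    """
    if row not in TEST3_ROWS:
        raise InvalidParameterError("row must be in 1..5")
    r = TEST3_ROWS[row]
    return ExperimentSpec(
        name=f"test3_row{row}",
        fibers=dict(type="gaussian", m_k=r["m_k"], sigma_k2=0.15,
                    x_k=2.5, y_k=2.5, theta_q=3 * np.pi / 4),
        chemo=dict(type="gaussian", m_S=10.0, sigma_S2=r["sigma_S2"],
                   x_S=4.5, y_S=4.5),
        model="independent",
        kernels=dict(gamma_q=dict(kind="heaviside", R=r["R"]),
                     gamma_S=dict(kind="heaviside", R=r["R"])),
        solver=dict(mu=1.0, V=1.0, n_theta=32, n_v=4, cfl=0.45, t_end=15.0,
                    snapshot_every=2.5),
        initial=dict(r0=0.1, center=(1.5, 1.5), sigma02=0.1, mode="rest"),
        reference_lengths=dict(l_S=r["l_S"], l_q=r["l_q"]),
    )


def build_application(orientation: str, t_end: float = 3.0) -> ExperimentSpec:
    """Electrospun-fiber scaffold under a linear chemoattractant gradient.

    Homogeneous strongly aligned fibers (k = 100) with axis pi/2 when
    parallel to the gradient (pointing up) or pi when perpendicular; linear
    chemoattractant of slope 10 in y; the mean upward speed is the key
    diagnostic (cooperation vs competition of the cues).
    """
    if orientation not in ("parallel", "perpendicular"):
        raise InvalidParameterError("orientation must be parallel|perpendicular")
    theta_q = np.pi / 2 if orientation == "parallel" else np.pi
    return ExperimentSpec(
        name=f"application_{orientation}",
        fibers=dict(type="constant", k=100.0, theta_q=float(theta_q)),
        chemo=dict(type="linear", m_S=10.0, floor=None),
        model="independent",
        kernels=dict(gamma_q=dict(kind="heaviside", R=0.7),
                     gamma_S=dict(kind="heaviside", R=0.7)),
        solver=dict(mu=1.0, V=1.0, n_theta=32, n_v=4, cfl=0.45, t_end=t_end,
                    snapshot_every=0.25),
        initial=dict(r0=0.1, center=(2.5, 0.5), sigma02=0.05, mode="rest"),
    )


# --------------------------------------------------------------------------
# running and diagnostics
# --------------------------------------------------------------------------

def run_experiment(spec: ExperimentSpec, store_snapshots: bool = True,
                   callback=None) -> Trajectory:
    """Build all objects of a spec and integrate the kinetic equation."""
    dirs = DirectionGrid(spec.solver["n_theta"])
    psi = spec.build_speed()
    T = spec.build_transition(dirs)
    rng = np.random.default_rng(spec.seed) if spec.initial.get("randomize") else None
    state = initialize_gaussian(
        spec.build_domain(), dirs, psi, T,
        r0=spec.initial["r0"], center=spec.initial["center"],
        var0=spec.initial["sigma02"], mode=spec.initial.get("mode", "rest"),
        n_v=spec.solver["n_v"], rng=rng)
    cfg = SolverConfig(mu=spec.solver["mu"], t_end=spec.solver["t_end"],
                       cfl=spec.solver["cfl"],
                       snapshot_every=spec.solver.get("snapshot_every", 1.0),
                       seed=spec.seed)
    return run(state, cfg, store_snapshots=store_snapshots, callback=callback)


class DiagnosticsSeries:
    """Scalar time series of a run: mass, center of mass, mean upward speed."""

    def __init__(self, times, mass, com, vbar=None):
        self.times = np.asarray(times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("time stamps must be strictly increasing")
        self.mass = np.asarray(mass, dtype=float)
        self.com = np.asarray(com, dtype=float)
        self.vbar = None if vbar is None else np.asarray(vbar, dtype=float)

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "DiagnosticsSeries":
        return cls(traj.times, traj.mass, traj.com, traj.vbar)

    def to_frame(self):
        import pandas as pd
        d = {"time": self.times, "mass": self.mass,
             "com_x": self.com[:, 0], "com_y": self.com[:, 1]}
        if self.vbar is not None:
            d["vbar"] = self.vbar
        return pd.DataFrame(d)


def estimate_relaxation_time(series: DiagnosticsSeries, target=None,
                             tol: float = 0.05) -> float:
    """First time the center of mass stays within ``tol`` of ``target``
    (default: its final value) for the remainder of the series.

    Raises :class:`NotConvergedError` (carrying the closest approach) when
    the criterion is never met before the final sample.
    """
    com = series.com
    if target is None:
        target = com[-1]
    target = np.asarray(target, dtype=float)
    dist = np.linalg.norm(com - target, axis=1)
    # suffix maxima: the plateau condition must hold for all later samples
    suffix = np.maximum.accumulate(dist[::-1])[::-1]
    ok = np.flatnonzero(suffix <= tol)
    if ok.size == 0 or (ok[0] == len(dist) - 1 and len(dist) > 1
                        and dist[-2] > tol):
        closest = float(np.min(dist[:-1])) if len(dist) > 1 else float(dist[0])
        raise NotConvergedError(
            f"center of mass never settled within {tol} of the target "
            f"(closest approach {closest:.4f})", closest_approach=closest)
    return float(series.times[ok[0]])
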