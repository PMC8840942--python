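"""Configuration files and gridded output containers.

Experiment specs serialize to YAML or JSON (type-tagged field constructors
with the model's parameter names); gridded fields and trajectories are
written to HDF5 with axis coordinates and parameter attributes, scalar
diagnostics to CSV, regime reports and run metadata to JSON.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import h5py
import numpy as np
import yaml

from .exceptions import ConfigurationError
from .experiments import DiagnosticsSeries, ExperimentSpec
from .kinetic import Trajectory

__all__ = [
    "load_spec",
    "save_spec",
    "save_fields_h5",
    "save_trajectory",
    "file_checksum",
]


def load_spec(path) -> ExperimentSpec:
    """Read an experiment spec from a YAML or JSON config file."""
    path = pathlib.Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict) or "name" not in data:
        raise ConfigurationError(f"config {path} must be a mapping with a 'name'")
    try:
        return ExperimentSpec.from_dict(data)
    except TypeError as exc:
        raise ConfigurationError(f"invalid config key in {path}: {exc}") from exc


def save_spec(spec: ExperimentSpec, path) -> None:
    path = pathlib.Path(path)
    data = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def save_fields_h5(path, spec: ExperimentSpec) -> None:
    """Export the gridded cue fields of a spec with coordinates and params."""
    domain = spec.build_domain()
    fibers = spec.build_fibers()
    chemo = spec.build_chemo()
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=domain.x_nodes)
        f.create_dataset("y", data=domain.y_nodes)
        f.create_dataset("S", data=chemo.values)
        f.create_dataset("k", data=fibers.k_values)
        f.create_dataset("theta_q", data=fibers.theta_q)
        f.attrs["name"] = spec.name
        for group, params in (("chemo", spec.chemo), ("fibers", spec.fibers)):
            for key, val in params.items():
                if val is not None:
                    f.attrs[f"{group}_{key}"] = val


def save_trajectory(outdir, traj: Trajectory, spec: ExperimentSpec,
                    regime=None) -> None:
    """Write a run: HDF5 density snapshots, CSV diagnostics, JSON metadata."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    domain = spec.build_domain()
    with h5py.File(outdir / "trajectory.h5", "w") as f:
        f.create_dataset("x", data=domain.x_nodes)
        f.create_dataset("y", data=domain.y_nodes)
        f.create_dataset("times", data=np.array([s.t for s in traj.snapshots]))
        f.create_dataset("rho", data=np.stack([s.rho for s in traj.snapshots]))
        f.create_dataset("momentum",
                         data=np.stack([s.momentum for s in traj.snapshots]))
        f.attrs["name"] = spec.name
    DiagnosticsSeries.from_trajectory(traj).to_frame().to_csv(
        outdir / "diagnostics.csv", index=False)
    meta = {"spec": spec.to_dict(), "seed": spec.seed}
    if regime is not None:
        meta["regime"] = regime.to_dict()
        (outdir / "regime.json").write_text(json.dumps(regime.to_dict(), indent=2))
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, default=float))


def file_checksum(path) -> str:
    """SHA-256 of a file (used to verify fixture reproducibility)."""
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()
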