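"""Configuration, trajectory and checkpoint I/O.

Configs are TOML files with two sections: ``[parameters]`` (any field of
:class:`~lamelliflow.params.Parameters`) and ``[scenario]`` (fields of
:class:`~lamelliflow.protocols.ScenarioConfig`).  Missing keys fall back
to the reference defaults; unknown keys are rejected with the offending
key named.

Frames are written as a CSV bead table plus an XYZ snapshot for external
viewers; checkpoints are HDF5 files containing every array of the network
state plus the RNG state, so a restarted run reproduces an uninterrupted
one bit for bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np

from .params import Parameters, ParameterError
from .protocols import ScenarioConfig
from .state import NetworkState, FocalAdhesionRegion, CL_TYPE_NAMES

CHECKPOINT_VERSION = 1


class ConfigError(ValueError):
    """Malformed configuration file."""


def read_config(path) -> Tuple[Parameters, ScenarioConfig]:
    """Parse a TOML config into (Parameters, ScenarioConfig)."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    unknown_sections = set(raw) - {"parameters", "scenario"}
    if unknown_sections:
        raise ConfigError(
            f"unknown section(s): {', '.join(sorted(unknown_sections))}")
    try:
        params = Parameters.from_dict(raw.get("parameters", {}))
    except (ParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    scen_raw = dict(raw.get("scenario", {}))
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    bad = set(scen_raw) - known
    if bad:
        raise ConfigError(f"unknown scenario key(s): "
                          f"{', '.join(sorted(bad))}")
    try:
        scenario = ScenarioConfig(**scen_raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return params, scenario


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        return ("{" + ", ".join(f"{k} = {_toml_value(x)}"
                                for k, x in v.items()) + "}")
    return repr(v)


def config_toml(params: Parameters,
                scenario: Optional[ScenarioConfig] = None) -> str:
    """Fully-resolved configuration as a TOML string."""
    lines = ["[parameters]"]
    for k, v in params.to_dict().items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    if scenario is not None:
        lines.append("")
        lines.append("[scenario]")
        for f in dataclasses.fields(ScenarioConfig):
            v = getattr(scenario, f.name)
            if v is None:
                continue
            if isinstance(v, tuple):
                v = list(v)
            lines.append(f"{f.name} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def write_config(path, params: Parameters,
                 scenario: Optional[ScenarioConfig] = None) -> None:
    """Echo a fully-resolved configuration back to TOML."""
    Path(path).write_text(config_toml(params, scenario))


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def write_frame_csv(state: NetworkState, path) -> None:
    """Bead table: id, filament, index, x, y, z, unwrapped x, bound flag,
    birth time."""
    import pandas as pd
    rows = []
    fil_of = {}
    idx_of = {}
    for f, beads in enumerate(state.filaments):
        for m, b in enumerate(beads):
            fil_of[int(b)] = state.fil_ids[f]
            idx_of[int(b)] = m
    ux = state.unwrapped_x()
    for b in range(state.n_beads):
        rows.append(dict(uid=int(state.uid[b]), filament=fil_of.get(b, -1),
                         index=idx_of.get(b, -1),
                         x=state.pos[b, 0], y=state.pos[b, 1],
                         z=state.pos[b, 2], x_unwrapped=ux[b],
                         fa_bound=bool(state.fa_bound[b]),
                         birth=state.birth[b]))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_frame_xyz(state: NetworkState, path, append: bool = False) -> None:
    """XYZ snapshot; the species column encodes FA binding (AB = bound,
    AC = crosslinked, AA otherwise)."""
    crosslinked = np.zeros(state.n_beads, dtype=bool)
    if state.n_crosslinks:
        crosslinked[state.cl_i] = True
        crosslinked[state.cl_j] = True
    lines = [str(state.n_beads), f"t={state.t:.6f}"]
    for b in range(state.n_beads):
        if state.fa_bound[b]:
            species = "AB"
        elif crosslinked[b]:
            species = "AC"
        else:
            species = "AA"
        lines.append(f"{species} {state.pos[b, 0]:.6f} "
                     f"{state.pos[b, 1]:.6f} {state.pos[b, 2]:.6f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _state_checksum(state: NetworkState) -> str:
    h = hashlib.sha256()
    h.update(state.pos.tobytes())
    h.update(state.uid.tobytes())
    h.update(np.float64(state.t).tobytes())
    for beads in state.filaments:
        h.update(beads.tobytes())
    h.update(state.cl_i.tobytes())
    h.update(state.cl_j.tobytes())
    return h.hexdigest()


def save_checkpoint(state: NetworkState, path) -> None:
    """Write a complete, restartable snapshot to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CHECKPOINT_VERSION
        f.attrs["params"] = json.dumps(state.params.to_dict())
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        f.attrs["t"] = state.t
        f.attrs["spawn_residue"] = state.spawn_residue
        f.attrs["next_refresh_time"] = state.next_refresh_time
        f.attrs["spawn_count"] = state.spawn_count
        f.attrs["next_uid"] = state._next_uid
        f.attrs["next_fil_id"] = state._next_fil_id
        f.attrs["checksum"] = _state_checksum(state)
        fa = state.fa
        f.attrs["fa"] = json.dumps(dict(
            p0=list(fa.p0), p1=list(fa.p1), width=fa.width,
            height=fa.height, kappa_FA=fa.kappa_FA, k_bind=fa.k_bind,
            k_unbind=fa.k_unbind))
        for name in ("pos", "uid", "birth", "fa_bound", "x_wraps",
                     "cl_i", "cl_j", "cl_k", "cl_rest", "cl_tau", "cl_type",
                     "br_i", "br_j", "br_k"):
            f.create_dataset(name, data=getattr(state, name))
        lengths = np.array([b.size for b in state.filaments], dtype=np.int64)
        f.create_dataset("fil_lengths", data=lengths)
        f.create_dataset("fil_ids", data=np.array(state.fil_ids,
                                                  dtype=np.int64))
        cat = (lambda lst, d: np.concatenate(lst) if lst else
               np.zeros(0, dtype=d))
        f.create_dataset("fil_beads",
                         data=cat(state.filaments, np.int64))
        f.create_dataset("fil_bond_tau",
                         data=cat(state.fil_bond_tau, np.float64))
        f.create_dataset("fil_bond_rest",
                         data=cat(state.fil_bond_rest, np.float64))


def restore_checkpoint(path) -> NetworkState:
    """Load a checkpoint; the restored run continues bit-identically."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != CHECKPOINT_VERSION:
            raise IOError(f"checkpoint version {version} not supported")
        params = Parameters.from_dict(json.loads(f.attrs["params"]))
        fa_d = json.loads(f.attrs["fa"])
        fa = FocalAdhesionRegion(
            p0=np.array(fa_d["p0"]), p1=np.array(fa_d["p1"]),
            width=fa_d["width"], height=fa_d["height"],
            kappa_FA=fa_d["kappa_FA"], k_bind=fa_d["k_bind"],
            k_unbind=fa_d["k_unbind"])
        state = NetworkState(params, fa=fa)
        for name in ("pos", "uid", "birth", "fa_bound", "x_wraps",
                     "cl_i", "cl_j", "cl_k", "cl_rest", "cl_tau", "cl_type",
                     "br_i", "br_j", "br_k"):
            setattr(state, name, f[name][...])
        state.fa_bound = state.fa_bound.astype(bool)
        lengths = f["fil_lengths"][...]
        beads = f["fil_beads"][...]
        taus = f["fil_bond_tau"][...]
        rests = f["fil_bond_rest"][...]
        bp = 0
        tp = 0
        state.filaments, state.fil_bond_tau, state.fil_bond_rest = [], [], []
        for ln in lengths:
            state.filaments.append(beads[bp:bp + ln])
            state.fil_bond_tau.append(taus[tp:tp + ln - 1])
            state.fil_bond_rest.append(rests[tp:tp + ln - 1])
            bp += ln
            tp += ln - 1
        state.fil_ids = [int(x) for x in f["fil_ids"][...]]
        state.t = float(f.attrs["t"])
        state.spawn_residue = float(f.attrs["spawn_residue"])
        state.next_refresh_time = float(f.attrs["next_refresh_time"])
        state.spawn_count = int(f.attrs["spawn_count"])
        state._next_uid = int(f.attrs["next_uid"])
        state._next_fil_id = int(f.attrs["next_fil_id"])
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        state.rng = rng
        expected = f.attrs["checksum"]
    actual = _state_checksum(state)
    if actual != expected:
        raise IOError("checkpoint checksum mismatch")
    state.invalidate()
    return state


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(path, *, seed: int, params: Parameters,
                   scenario: Optional[ScenarioConfig], t_start: float,
                   t_end: float, files: dict) -> None:
    """JSON manifest with config echo, seed, time range and file
    checksums, sufficient to reproduce the run."""
    from . import __version__
    inventory = {}
    for name, fpath in files.items():
        fpath = Path(fpath)
        if fpath.exists():
            inventory[name] = dict(
                path=str(fpath),
                sha256=hashlib.sha256(fpath.read_bytes()).hexdigest())
    doc = dict(code_version=__version__, seed=seed,
               params=params.to_dict(),
               scenario=(dataclasses.asdict(scenario)
                         if scenario is not None else None),
               t_start=t_start, t_end=t_end, files=inventory)
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
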