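"""Plain-text I/O: trajectories, jump paths, grid fields, model configs."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import BeadSpringModel, build_chain
from .fields import FieldOnGrid
from .simulate import JumpTrajectory, Trajectory

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_jump_trajectory",
    "write_field",
    "read_model_config",
]


def write_trajectory(traj: Trajectory, path, sep: str = "\t") -> None:
    """Write a trajectory as delimited text: header then t, x1, ..., xn."""
    n = traj.n_dim
    cols = ["t"] + [f"x{i + 1}" for i in range(n)]
    df = pd.DataFrame(np.column_stack([traj.times, traj.positions]),
                      columns=cols)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_trajectory(path, sep: str = "\t") -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    df = pd.read_csv(path, sep=sep)
    t = df["t"].to_numpy()
    dts = np.diff(t)
    if len(dts) < 1 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trajectory file must have uniform time spacing")
    x = df.drop(columns="t").to_numpy(dtype=float)
    return Trajectory(dt=float(dts[0]), positions=x, t0=float(t[0]))


def write_jump_trajectory(jt: JumpTrajectory, path, sep: str = "\t") -> None:
    """Write a jump path: rows time, site_index (+ coordinates if known)."""
    times = np.concatenate([[0.0], jt.times])
    cols = {"time": times, "site_index": jt.sites}
    if jt.lattice is not None:
        pos = jt.lattice.site_positions()[jt.sites]
        for i in range(pos.shape[1]):
            cols[f"x{i + 1}"] = pos[:, i]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_field(fld: FieldOnGrid, path, sep: str = "\t") -> None:
    """Export a grid field as bin centres + values (long format)."""
    pos = fld.grid.site_positions()
    cols = {f"x{i + 1}": pos[:, i] for i in range(fld.grid.n_dim)}
    if fld.is_vector:
        flat = fld.values.reshape(-1, fld.values.shape[-1])
        for i in range(flat.shape[1]):
            cols[f"{fld.kind}_{i + 1}"] = flat[:, i]
    else:
        cols[fld.kind] = fld.values.reshape(-1)
    if fld.estimated is not None:
        cols["estimated"] = fld.estimated.reshape(-1).astype(int)
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.8g")


def read_model_config(path) -> BeadSpringModel:
    """Build a chain from a flat TOML (or JSON) key-value config.

    Keys: n_beads, k, gamma, and either temps = [..] or t_cold/t_hot.
    """
    path = Path(path)
    text = path.read_bytes()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("TOML configs require Python >= 3.11")
        cfg = tomllib.loads(text.decode())
    kwargs = dict(n_beads=cfg["n_beads"], k=cfg["k"], gamma=cfg["gamma"])
    if "temps" in cfg:
        kwargs["temps"] = cfg["temps"]
    else:
        kwargs["endpoints"] = (cfg["t_cold"], cfg["t_hot"])
    return build_chain(**kwargs)
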