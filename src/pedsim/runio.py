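"""Run outputs: HDF5 snapshots, iteration/contact CSV logs, manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone

import h5py
import numpy as np
import pandas as pd


def _manifest(seed=None, config: dict | None = None) -> dict:
    import pedsim

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package_version": getattr(pedsim, "__version__", "unknown"),
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": -1 if seed is None else int(seed),
        "config_sha1": hashlib.sha1(cfg_json.encode()).hexdigest(),
        "config_json": cfg_json,
    }


def save_stance_result(path, result, seed=None, config: dict | None = None):
    """Write a :class:`~pedsim.protocols.StanceResult` to HDF5."""
    with h5py.File(path, "w") as h5:
        for k, v in _manifest(seed, config).items():
            h5.attrs[k] = v
        h5["time"] = result.time
        h5["grf"] = result.grf
        h5["cop"] = result.cop
        h5["pa_tension"] = result.pa_tension
        h5["pa_total"] = result.pa_total
        h5["cone_margin"] = result.cone_margin
        h5["min_tissue_tension"] = result.min_tissue_tension
        h5["column_fn"] = result.column_fn
        h5["column_pos"] = result.column_pos
        h5["audits"] = result.audits
        g = h5.create_group("joint_angles")
        for joint, series in result.joint_angles.items():
            g[joint.replace("/", "_")] = series
        g = h5.create_group("bone_positions")
        for bone, series in result.bone_positions.items():
            g[bone] = series


def save_standing_result(path, result, seed=None, config: dict | None = None):
    """Write a :class:`~pedsim.protocols.StandingResult` to HDF5."""
    with h5py.File(path, "w") as h5:
        for k, v in _manifest(seed, config).items():
            h5.attrs[k] = v
        h5["grf"] = result.grf
        h5["stage1_grf"] = result.stage1_grf
        h5["cop"] = result.cop
        h5["pressure"] = result.pressure.pressure
        h5["pressure_origin"] = result.pressure.origin
        h5.attrs["pressure_cell_size"] = result.pressure.cell_size
        h5.attrs["settled_stage1"] = bool(result.settled[0])
        h5.attrs["settled_stage2"] = bool(result.settled[1])


def save_axial_result(path, result, seed=None, config: dict | None = None):
    """Write an :class:`~pedsim.protocols.AxialLoadingResult` to HDF5."""
    with h5py.File(path, "w") as h5:
        for k, v in _manifest(seed, config).items():
            h5.attrs[k] = v
        h5["loads"] = result.loads
        gt = h5.create_group("translations")
        gr = h5.create_group("rotations")
        for bone in result.translations:
            gt[bone] = result.translations[bone]
            gr[bone] = result.rotations[bone]
        h5["settled"] = np.asarray(result.settled, dtype=bool)


def write_contact_log(path, result):
    """Per-frame, per-column contact log CSV (position, Fn, |Ft| proxy)."""
    rows = []
    for k, t in enumerate(result.time):
        for j in range(result.column_fn.shape[1]):
            x, y, z = result.column_pos[k, j]
            rows.append((t, j, x, y, z, result.column_fn[k, j]))
    df = pd.DataFrame(rows, columns=["t_ms", "column", "x_mm", "y_mm",
                                     "z_mm", "fn_N"])
    df.to_csv(path, index=False)


def write_joint_angle_csv(path, result):
    """Stance-% against y-x-z joint angles for every reported joint."""
    frac = result.stance_fraction * 100.0
    data = {"stance_pct": frac}
    for joint, series in result.joint_angles.items():
        for i, comp in enumerate(("y_plantarflexion", "x_inversion",
                                  "z_internal_rotation")):
            data[f"{joint}_{comp}_deg"] = series[:, i]
    pd.DataFrame(data).to_csv(path, index=False)
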