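"""Joint kinematics and plantar-pressure post-processing.

Bone motion is reported with y-x-z Euler angles, ``R = Ry(ty) Rx(tx)
Rz(tz)``, the standard foot-biomechanics sequence in which the three
angles map onto plantarflexion--dorsiflexion (about y),
inversion--eversion (about x) and internal--external rotation, also
called adduction--abduction, (about z).  Sign conventions throughout
the package: x anterior, y medial, z superior; positive rotations are
plantarflexion, inversion and internal rotation.

Plantar pressure is accumulated on a regular grid from the discrete
contact normal forces, conserving total force exactly, with optional
block-averaging down to a tactile-sensor-like resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerYXZ",
    "PressureMap",
    "euler_yxz",
    "compose_yxz",
    "joint_angles",
    "pressure_map",
    "center_of_pressure",
    "mae_sd",
    "lowpass_markers",
]


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class EulerYXZ:
    """y-x-z Euler angle triple, degrees.

    ``about_y``: plantarflexion(+)/dorsiflexion(-);
    ``about_x``: inversion(+)/eversion(-);
    ``about_z``: internal(+)/external(-) rotation (adduction/abduction).
    ``gimbal_proximity`` flags |about_x| > 89 deg where the
    decomposition degenerates.
    """

    about_y: float
    about_x: float
    about_z: float
    gimbal_proximity: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.about_y, self.about_x, self.about_z])


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise KinematicsError(f"expected 3x3 rotation, got shape {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise KinematicsError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise KinematicsError("matrix is a reflection, not a rotation")
    return R


def euler_yxz(rotation) -> EulerYXZ:
    """Decompose a rotation as ``Ry(ty) Rx(tx) Rz(tz)``, angles in degrees."""
    if isinstance(rotation, Rotation):
        rot = rotation
    else:
        rot = Rotation.from_matrix(_check_rotation(rotation))
    ty, tx, tz = rot.as_euler("YXZ", degrees=True)
    return EulerYXZ(
        about_y=float(ty),
        about_x=float(tx),
        about_z=float(tz),
        gimbal_proximity=abs(tx) > 89.0,
    )


def compose_yxz(about_y: float, about_x: float, about_z: float) -> np.ndarray:
    """Rotation matrix ``Ry(ty) Rx(tx) Rz(tz)`` from angles in degrees."""
    return Rotation.from_euler("YXZ", [about_y, about_x, about_z],
                               degrees=True).as_matrix()


def joint_angles(
    proximal_rotation,
    distal_rotation,
    proximal_reference=None,
    distal_reference=None,
) -> EulerYXZ:
    """Joint angles of the distal bone relative to the proximal bone.

    The relative rotation ``R_prox^T R_dist`` is expressed against the
    same quantity in the reference (build/neutral) posture, then
    decomposed y-x-z.  Both reference poses must be given together; a
    missing reference is a configuration error (identity references can
    be passed explicitly).
    """
    if proximal_reference is None or distal_reference is None:
        raise KinematicsError(
            "joint_angles requires reference poses for both bones"
        )
    Rp = _as_matrix(proximal_rotation)
    Rd = _as_matrix(distal_rotation)
    Rp0 = _as_matrix(proximal_reference)
    Rd0 = _as_matrix(distal_reference)
    rel = Rp.T @ Rd
    rel0 = Rp0.T @ Rd0
    return euler_yxz(rel0.T @ rel)


def _as_matrix(rotation) -> np.ndarray:
    if isinstance(rotation, Rotation):
        return rotation.as_matrix()
    return _check_rotation(rotation)


@dataclass
class PressureMap:
    """Plantar pressure on a regular x-y grid.

    ``pressure[i, j]`` is the mean normal pressure (MPa) in the cell
    whose lower corner is ``origin + (i, j) * cell_size``.  ``cop`` is
    the vertical-force-weighted centre of pressure in mm, or None when
    no cell is loaded.
    """

    origin: np.ndarray          # (2,) mm
    cell_size: float            # mm
    pressure: np.ndarray        # (nx, ny) MPa
    cop: np.ndarray | None      # (2,) mm or None

    @property
    def total_force(self) -> float:
        """Integral of pressure over the map, N."""
        return float(self.pressure.sum() * self.cell_size**2)

    def downsample(self, block: int) -> "PressureMap":
        """Block-average to a coarser, sensor-like resolution."""
        nx, ny = self.pressure.shape
        px = -(-nx // block) * block
        py = -(-ny // block) * block
        padded = np.zeros((px, py))
        padded[:nx, :ny] = self.pressure
        coarse = padded.reshape(px // block, block, py // block, block).mean(
            axis=(1, 3)
        )
        return PressureMap(
            origin=self.origin.copy(),
            cell_size=self.cell_size * block,
            pressure=coarse,
            cop=None if self.cop is None else self.cop.copy(),
        )


def pressure_map(
    positions,
    normal_forces,
    origin,
    cell_size: float,
    shape: tuple[int, int],
) -> PressureMap:
    """Bin contact normal forces into a pressure grid.

    Parameters
    ----------
    positions : (n, 2) or (n, 3) array
        Contact point locations, mm (z ignored if present).
    normal_forces : (n,) array
        Vertical/normal force magnitude per point, N (>= 0).
    origin, cell_size, shape
        Grid specification; every loaded point must fall inside.

    Total force is conserved: ``sum(pressure) * cell_size**2`` equals
    ``sum(normal_forces)`` to machine precision.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))[:, :2]
    f = np.asarray(normal_forces, dtype=float)
    if pos.shape[0] != f.shape[0]:
        raise KinematicsError("positions and forces length mismatch")
    origin = np.asarray(origin, dtype=float)
    nx, ny = shape
    grid = np.zeros((nx, ny))
    loaded = f > 0
    if loaded.any():
        ij = np.floor((pos[loaded] - origin) / cell_size).astype(int)
        if (ij < 0).any() or (ij[:, 0] >= nx).any() or (ij[:, 1] >= ny).any():
            raise KinematicsError("grid does not cover a loaded contact point")
        np.add.at(grid, (ij[:, 0], ij[:, 1]), f[loaded])
    grid /= cell_size**2
    cop = None
    if loaded.any():
        cop = (pos[loaded] * f[loaded, None]).sum(axis=0) / f[loaded].sum()
    return PressureMap(origin=origin, cell_size=cell_size, pressure=grid, cop=cop)


def center_of_pressure(positions, vertical_forces) -> np.ndarray:
    """Vertical-force-weighted mean contact position (mm).

    Raises if the total vertical force is not positive (COP undefined).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    f = np.asarray(vertical_forces, dtype=float)
    total = f.sum()
    if total <= 0:
        raise KinematicsError("COP undefined: total vertical force <= 0")
    return (pos * f[:, None]).sum(axis=0) / total


def mae_sd(series_a, series_b) -> tuple[float, float]:
    """Mean absolute difference and its sample SD between two series.

    The SD is the (n-1)-denominator standard deviation of the absolute
    differences.  Symmetric in its arguments and invariant to a common
    offset.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise KinematicsError(f"series shapes differ: {a.shape} vs {b.shape}")
    d = np.abs(a - b).ravel()
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def lowpass_markers(
    trajectories,
    sample_rate: float,
    cutoff: float = 20.0,
    order: int = 4,
):
    """Zero-phase Butterworth low-pass along the first (time) axis.

    A forward--backward 4th-order Butterworth at the given cutoff; DC
    gain is exactly 1 and the filter is delay-free.  ``sample_rate`` and
    ``cutoff`` in Hz; the sample rate must exceed twice the cutoff.
    """
    x = np.asarray(trajectories, dtype=float)
    if sample_rate <= 2 * cutoff:
        raise KinematicsError(
            f"sample rate {sample_rate} Hz must exceed twice the "
            f"{cutoff} Hz cutoff"
        )
    b, a = butter(order, cutoff / (sample_rate / 2.0))
    return filtfilt(b, a, x, axis=0)
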