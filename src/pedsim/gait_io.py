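"""Motion/force file I/O and the synthetic stance-phase gait generator.

Marker trajectories are exchanged as TRC (the plain-text motion-capture
format), force-plate and muscle-force series as CSV.  Because no
deposited recordings accompany the model, :func:`synthesize_gait`
produces a seeded, deterministic stand-in for one stance phase of
walking with the canonical waveform structure:

* vertical GRF: double-peaked, ~1.1 BW peaks near 25% and 75% stance
  with a ~0.75 BW mid-stance valley,
* anteroposterior GRF: braking (posterior) in early stance, propulsion
  (anterior) in late stance, zero net impulse,
* a small mediolateral component,
* tibial landmark trajectories (medial/lateral malleolus, tibial
  tuberosity) following an inverted-pendulum-like shank progression
  consistent with the GRF timing: heel-down ankle descent, a foot-flat
  plateau, then forward/upward ankle travel during heel rise.

All internal units are mm / N / ms; files in metres or seconds are
converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .units import GRAVITY

__all__ = [
    "GaitRecord",
    "SyntheticGaitParams",
    "read_trc",
    "write_trc",
    "read_grf_csv",
    "read_muscle_csv",
    "write_grf_csv",
    "write_muscle_csv",
    "synthesize_gait",
    "MARKER_NAMES",
]

MARKER_NAMES = ("medial_malleolus", "lateral_malleolus", "tibial_tuberosity")

#: default local positions (mm) of the tibial landmarks relative to the
#: ankle-joint centre, matching the default foot build.
DEFAULT_MARKER_LAYOUT: dict[str, np.ndarray] = {
    "medial_malleolus": np.array([-5.0, 30.0, 10.0]),
    "lateral_malleolus": np.array([-8.0, -30.0, 5.0]),
    "tibial_tuberosity": np.array([25.0, 12.0, 330.0]),
}


class GaitDataError(ValueError):
    """Malformed or inconsistent gait input data."""


@dataclass
class GaitRecord:
    """Time-aligned markers, GRF and muscle forces for one stance phase.

    ``time`` is a uniform grid in ms covering the stance window.
    ``markers`` maps landmark name to an (n, 3) trajectory in mm;
    ``grf`` is (n, 3) in N in the model frame (x anterior, y medial,
    z superior — vertical component non-negative inside stance);
    ``muscles`` maps muscle name to an (n,) force series in N.
    """

    time: np.ndarray
    markers: dict[str, np.ndarray]
    grf: np.ndarray
    muscles: dict[str, np.ndarray] = field(default_factory=dict)
    stance_window: tuple[float, float] | None = None
    body_mass: float = 72.0  # kg

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n > 1:
            steps = np.diff(self.time)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise GaitDataError("time grid must be uniform")
            if steps[0] <= 0:
                raise GaitDataError("time must be strictly increasing")
        for name, traj in self.markers.items():
            traj = np.asarray(traj, dtype=float)
            if traj.shape != (n, 3):
                raise GaitDataError(f"marker {name!r} has shape {traj.shape}")
            self.markers[name] = traj
        self.grf = np.asarray(self.grf, dtype=float)
        if self.grf.shape != (n, 3):
            raise GaitDataError(f"GRF has shape {self.grf.shape}, expected ({n}, 3)")
        if self.stance_window is None:
            self.stance_window = (float(self.time[0]), float(self.time[-1]))
        t0, t1 = self.stance_window
        if not (self.time[0] - 1e-9 <= t0 < t1 <= self.time[-1] + 1e-9):
            raise GaitDataError("stance window must lie inside the record")
        inside = (self.time >= t0) & (self.time <= t1)
        if np.any(self.grf[inside, 2] < -1e-9):
            raise GaitDataError("vertical GRF must be non-negative inside stance")

    @property
    def sample_rate(self) -> float:
        """Hz."""
        return 1000.0 / float(self.time[1] - self.time[0])

    @property
    def stance_fraction(self) -> np.ndarray:
        """Normalized stance time in [0, 1] for each sample."""
        t0, t1 = self.stance_window
        return (self.time - t0) / (t1 - t0)

    def marker_array(self, names=MARKER_NAMES) -> np.ndarray:
        """(n, len(names), 3) stacked marker trajectories."""
        return np.stack([self.markers[n] for n in names], axis=1)


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(markers: Mapping[str, np.ndarray], time_ms, path, units: str = "mm"):
    """Write marker trajectories to a TRC file (tab-separated, mm)."""
    time_ms = np.asarray(time_ms, dtype=float)
    names = list(markers)
    n = time_ms.size
    rate = 1000.0 / (time_ms[1] - time_ms[0]) if n > 1 else 100.0
    scale = 1.0 if units == "mm" else 1e-3
    lines = [
        "PathFileType\t4\t(X/Y/Z)\t" + str(path),
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:.6f}\t{rate:.6f}\t{n}\t{len(names)}\t{units}\t{rate:.6f}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))
        ),
        "",
    ]
    for k in range(n):
        row = [str(k + 1), f"{time_ms[k] / 1000.0:.6f}"]
        for name in names:
            xyz = np.asarray(markers[name])[k] * scale
            row.extend(f"{v:.6f}" for v in xyz)
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trc(path) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read a TRC file; returns ``(markers, time_ms)`` with positions in mm."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if len(raw) < 6:
        raise GaitDataError("TRC file too short to contain a header")
    meta_names = raw[1].split("\t")
    meta_vals = raw[2].split("\t")
    meta = dict(zip(meta_names, meta_vals))
    try:
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"]
    except (KeyError, ValueError) as exc:
        raise GaitDataError(f"malformed TRC header (line 3): {exc}") from exc
    if units not in ("mm", "m"):
        raise GaitDataError(f"unsupported TRC units {units!r}")
    scale = 1.0 if units == "mm" else 1e3
    header = raw[3].split("\t")
    names = [h for h in header[2:] if h.strip()]
    if len(names) != n_markers:
        raise GaitDataError(
            f"TRC header (line 4) names {len(names)} markers, "
            f"header says {n_markers}"
        )
    data_lines = [ln for ln in raw[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise GaitDataError(
            f"TRC truncated: header promises {n_frames} frames, "
            f"found {len(data_lines)}"
        )
    time_ms = np.empty(n_frames)
    arr = np.empty((n_frames, n_markers, 3))
    for k, ln in enumerate(data_lines):
        parts = ln.split("\t")
        if len(parts) < 2 + 3 * n_markers:
            raise GaitDataError(
                f"TRC line {k + 6}: expected {2 + 3 * n_markers} columns, "
                f"got {len(parts)}"
            )
        time_ms[k] = float(parts[1]) * 1000.0
        vals = np.array(parts[2:2 + 3 * n_markers], dtype=float)
        arr[k] = vals.reshape(n_markers, 3) * scale
    markers = {name: arr[:, i, :] for i, name in enumerate(names)}
    return markers, time_ms


# ---------------------------------------------------------------------------
# CSV force / muscle files
# ---------------------------------------------------------------------------

def _read_timeseries_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GaitDataError(f"{path}: missing required column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise GaitDataError(
                f"{path}: time column not strictly increasing at row {bad + 1}"
            )
    # optional integrity footer written by our writers
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# nrows="):
        declared = int(first.split("=", 1)[1])
        if declared != len(df):
            raise GaitDataError(
                f"{path}: truncated — declares {declared} rows, found {len(df)}"
            )
    return df


def read_grf_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a force-plate CSV with columns ``t`` (ms), ``Fx, Fy, Fz`` (N)."""
    df = _read_timeseries_csv(path, ("t", "Fx", "Fy", "Fz"))
    return (
        df["t"].to_numpy(dtype=float),
        df[["Fx", "Fy", "Fz"]].to_numpy(dtype=float),
    )


def read_muscle_csv(path, muscles=("TS", "TA", "EDL", "EHL")):
    """Read a muscle-force CSV with columns ``t`` and one column per muscle.

    ``t`` may be ms or stance-%; it is returned as-is together with a
    name -> force-array mapping.
    """
    df = _read_timeseries_csv(path, ("t",) + tuple(muscles))
    t = df["t"].to_numpy(dtype=float)
    return t, {m: df[m].to_numpy(dtype=float) for m in muscles}


def _write_with_count(df: pd.DataFrame, path):
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(f"# nrows={len(df)}\n")
        fh.write(buf.getvalue())


def write_grf_csv(time_ms, grf, path):
    df = pd.DataFrame(
        {"t": np.asarray(time_ms, float),
         "Fx": grf[:, 0], "Fy": grf[:, 1], "Fz": grf[:, 2]}
    )
    _write_with_count(df, path)


def write_muscle_csv(time_ms, muscles: Mapping[str, np.ndarray], path):
    df = pd.DataFrame({"t": np.asarray(time_ms, float), **dict(muscles)})
    _write_with_count(df, path)


def resample_to(t_src, values, t_dst) -> np.ndarray:
    """Linear resampling onto a new grid, clamped at the ends."""
    t_src = np.asarray(t_src, float)
    values = np.asarray(values, float)
    t_dst = np.clip(np.asarray(t_dst, float), t_src[0], t_src[-1])
    if values.ndim == 1:
        return np.interp(t_dst, t_src, values)
    return np.stack(
        [np.interp(t_dst, t_src, values[:, j]) for j in range(values.shape[1])],
        axis=1,
    )


# ---------------------------------------------------------------------------
# Synthetic gait
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGaitParams:
    """Study conditions of the synthetic stance phase.

    Defaults describe a 72 kg adult walking at a self-selected speed:
    ~0.6 s of stance sampled at 200 Hz, vertical GRF peaks of 1.1 BW
    and an anteroposterior amplitude of 0.17 BW.  Noise amplitudes
    default to zero (clean waveforms); a seed makes any added noise
    reproducible.
    """

    body_mass: float = 72.0          # kg
    stance_duration: float = 600.0   # ms
    speed_scale: float = 1.0         # scales ankle travel
    sample_rate: float = 200.0       # Hz
    seed: int = 0
    marker_noise: float = 0.0        # mm, SD per axis
    grf_noise: float = 0.0           # N, SD per component
    vertical_peak_bw: float = 1.1
    ap_amplitude_bw: float = 0.17
    ml_amplitude_bw: float = 0.05
    #: heel-rise (forefoot rocker) kinematics of late stance
    heel_rise_angle: float = 25.0       # deg at toe-off
    heel_off_fraction: float = 0.64
    #: sagittal offset (x, z) mm of the ankle from the met-head pivot
    ankle_pivot_offset: tuple = (-135.0, 30.0)

    def __post_init__(self) -> None:
        for name in ("body_mass", "stance_duration", "speed_scale", "sample_rate"):
            if getattr(self, name) <= 0:
                raise GaitDataError(f"{name} must be positive")
        if self.sample_rate < 100.0:
            raise GaitDataError("sampling rate must be at least 100 Hz")


def _smooth_ramp(u):
    """C1 smoothstep on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def synthesize_gait(
    params: SyntheticGaitParams | None = None,
    ankle_origin=(60.0, -1.0, 45.0),
    marker_layout: Mapping[str, np.ndarray] | None = None,
) -> GaitRecord:
    """Generate one deterministic synthetic stance phase.

    ``ankle_origin`` is the ankle-joint centre (mm) of the foot model in
    its build pose; ``marker_layout`` gives the tibial landmarks
    relative to that point (defaults match the default foot build).
    """
    p = params or SyntheticGaitParams()
    layout = {k: np.asarray(v, float)
              for k, v in (marker_layout or DEFAULT_MARKER_LAYOUT).items()}
    rng = np.random.default_rng(p.seed)
    dt = 1000.0 / p.sample_rate
    n = int(round(p.stance_duration / dt)) + 1
    time = np.arange(n) * dt
    tau = time / time[-1]

    bw = p.body_mass * GRAVITY * 1000.0  # N

    # vertical: two Gaussian bumps shaped for a ~0.75/1.1 valley/peak ratio,
    # tapered to zero at heel contact and toe-off
    s = 0.1704
    bump = (np.exp(-((tau - 0.25) ** 2) / (2 * s * s))
            + np.exp(-((tau - 0.75) ** 2) / (2 * s * s)))
    taper = _smooth_ramp(tau / 0.12) * _smooth_ramp((1.0 - tau) / 0.12)
    fz = bump * taper
    fz = fz / fz.max() * p.vertical_peak_bw * bw

    # anteroposterior: braking (posterior, -x) then propulsion (+x);
    # antisymmetric about mid-stance so the net impulse vanishes
    fx = -p.ap_amplitude_bw * bw * np.sin(2 * np.pi * tau) * taper
    # mediolateral: small medial bump
    fy = p.ml_amplitude_bw * bw * np.sin(np.pi * tau) * taper

    grf = np.stack([fx, fy, fz], axis=1)
    if p.grf_noise > 0:
        grf = grf + rng.normal(0.0, p.grf_noise, grf.shape)
        grf[:, 2] = np.maximum(grf[:, 2], 0.0)
        grf[0] = 0.0
        grf[-1] = 0.0

    # shank trajectory: ankle path + pitch about the medial (y) axis.
    # Two consistency rules shape it: (i) the ankle dips ~5 mm below its
    # unloaded height through mid-stance — the plantar-pad compression
    # under body weight, which is what loads the foot when the shank is
    # position-driven; (ii) after heel-off the ankle follows the
    # forefoot rocker, i.e. it rotates about the metatarsal heads, so
    # the prescribed path neither drags nor crowds the planted forefoot.
    knots = np.array([0.0, 0.10, 0.30, 0.50, 0.65, 0.85, 1.0])
    # late-stance base height stays depressed: during heel rise the whole
    # load rides on the compressed forefoot pad; the ankle lift itself
    # comes from the rocker term below
    dz = PchipInterpolator(knots, [8.0, -2.0, -4.5, -4.5, -4.5, -5.0, -5.5])(tau)
    # the ankle advances only while the heel rocker lowers the foot;
    # during foot-flat it is the stationary pivot of the shank
    dx = PchipInterpolator(
        knots, np.array([-15.0, -6.0, -1.0, 0.0, 0.0, 0.0, 0.0]) * p.speed_scale
    )(tau)
    pitch = np.deg2rad(
        PchipInterpolator(knots, [-12.0, -8.0, -4.0, 0.0, 6.0, 18.0, 28.0])(tau)
    )
    # forefoot-rocker heel rise: rotate the ankle about the met-head
    # pivot by a smooth angle ramp after the heel-off fraction
    s = np.clip((tau - p.heel_off_fraction) / (1.0 - p.heel_off_fraction),
                0.0, 1.0)
    phi = np.deg2rad(p.heel_rise_angle) * s * s * (3.0 - 2.0 * s)
    ax, az = p.ankle_pivot_offset      # ankle minus pivot, sagittal (x, z)
    dx = dx + (ax * (np.cos(phi) - 1.0) + az * np.sin(phi))
    dz = dz + (-ax * np.sin(phi) + az * (np.cos(phi) - 1.0))

    ankle0 = np.asarray(ankle_origin, float)
    ankle = ankle0 + np.stack([dx, np.zeros_like(dx), dz], axis=1)
    c, sn = np.cos(pitch), np.sin(pitch)
    markers: dict[str, np.ndarray] = {}
    for name, local in layout.items():
        # rotation about +y: x' = c*x + s*z ; z' = -s*x + c*z
        rx = c * local[0] + sn * local[2]
        rz = -sn * local[0] + c * local[2]
        traj = ankle + np.stack([rx, np.full_like(rx, local[1]), rz], axis=1)
        if p.marker_noise > 0:
            traj = traj + rng.normal(0.0, p.marker_noise, traj.shape)
        markers[name] = traj

    muscles = _synthetic_muscle_forces(tau, bw)
    return GaitRecord(
        time=time,
        markers=markers,
        grf=grf,
        muscles=muscles,
        stance_window=(0.0, float(time[-1])),
        body_mass=p.body_mass,
    )


#: synthetic default muscle-force profiles, N at a 72 kg body mass,
#: sampled on stance-%.  Shapes are physiologic (triceps surae ramps to a
#: late-stance peak, tibialis anterior peaks just after heel contact,
#: long toe extensors small and early/mid stance); magnitudes are
#: representative, not subject-specific.
SYNTHETIC_MUSCLE_PROFILE = {
    "pct": np.array([0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0,
                     80.0, 90.0, 100.0]),
    "TS": np.array([0.0, 20.0, 40.0, 90.0, 180.0, 330.0, 560.0, 900.0,
                    1300.0, 1500.0, 700.0, 0.0]),
    "TA": np.array([120.0, 260.0, 300.0, 180.0, 80.0, 30.0, 10.0, 5.0,
                    5.0, 10.0, 30.0, 60.0]),
    "EDL": np.array([40.0, 80.0, 90.0, 60.0, 30.0, 15.0, 10.0, 10.0,
                     15.0, 25.0, 35.0, 30.0]),
    "EHL": np.array([20.0, 40.0, 50.0, 40.0, 25.0, 15.0, 15.0, 20.0,
                     30.0, 45.0, 40.0, 20.0]),
}


def _synthetic_muscle_forces(tau: np.ndarray, bw: float) -> dict[str, np.ndarray]:
    prof = SYNTHETIC_MUSCLE_PROFILE
    scale = bw / (72.0 * GRAVITY * 1000.0)  # scale with body weight
    pct = tau * 100.0
    return {
        m: np.interp(pct, prof["pct"], prof[m]) * scale
        for m in ("TS", "TA", "EDL", "EHL")
    }
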