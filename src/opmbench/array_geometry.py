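"""Synthetic triaxial OPM helmet array geometry.

Sensors are placed quasi-uniformly on a spherical cap (a Fibonacci lattice
restricted to polar angles <= ``cap_angle``) at radius ``head_radius +
standoff``, emulating a rigid helmet that covers the scalp but leaves the
face and neck free.  Each sensor measures the magnetic field along three
orthonormal sensitive axes: two tangential, the third radial, giving
``3 * n_sensors`` independent channels (192 for the default 64-sensor
build).

Coordinate convention: right-handed head frame, origin at the conductor
sphere centre, +z through the vertex, units metres.  Fields are tesla
internally everywhere in this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sensor",
    "SensorArray",
    "build_helmet_array",
    "orientation_matrix",
    "array_to_csv",
    "array_from_csv",
]

#: default polar-angle extent of the helmet cap, radians (~upper 65 % of
#: the sphere, typical rigid-helmet coverage; no face/neck sensors)
DEFAULT_CAP_ANGLE = np.deg2rad(105.0)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class InvalidGeometryError(ValueError):
    """Raised for non-physical array geometry requests."""


@dataclass(frozen=True)
class Sensor:
    """One triaxial OPM.

    Parameters
    ----------
    id : int
        Stable sensor index (0-based).
    position : (3,) ndarray
        Vapour-cell centre in the head frame, metres.
    axes : (3, 3) ndarray
        Rows are the unit sensitive directions (x, y tangential, z radial).
    """

    id: int
    position: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.position.shape != (3,) or self.axes.shape != (3, 3):
            raise InvalidGeometryError("sensor needs a 3-vector position and 3x3 axes")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-10):
            raise InvalidGeometryError(f"sensor {self.id}: axes not orthonormal")


@dataclass(frozen=True)
class SensorArray:
    """Ordered collection of sensors plus the flattened channel table.

    Channel ordering is sensor-major with axes x, y, z within each sensor,
    so channel ``3*s + a`` is axis ``a`` of sensor ``s``.  This ordering is
    relied on throughout the package and by the raw-container format.
    """

    sensors: tuple[Sensor, ...]
    head_radius: float
    standoff: float = 0.0
    seed: int = 0

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def n_channels(self) -> int:
        return 3 * len(self.sensors)

    @property
    def positions(self) -> np.ndarray:
        """(n_sensors, 3) cell positions, metres."""
        return np.array([s.position for s in self.sensors])

    @property
    def axes(self) -> np.ndarray:
        """(n_sensors, 3, 3) stack of sensitive-axis triads."""
        return np.array([s.axes for s in self.sensors])

    def channel_table(self) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
        """Flattened (sensor id, axis index, unit vector, position) rows."""
        rows = []
        for s in self.sensors:
            for a in range(3):
                rows.append((s.id, a, s.axes[a].copy(), s.position.copy()))
        return rows

    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) position of each channel's cell, metres."""
        return np.repeat(self.positions, 3, axis=0)

    def channel_names(self) -> list[str]:
        return [f"S{s.id:02d}-{ax}" for s in self.sensors for ax in "xyz"]


def _fibonacci_cap(n: int, cap_angle: float, phase: float) -> np.ndarray:
    """Quasi-uniform unit vectors on the polar cap theta <= cap_angle.

    Uniform in cos(theta) with golden-angle azimuths; ``phase`` rotates the
    whole lattice about z (this is where the seed enters, keeping builds
    deterministic but decorrelated between seeds).
    """
    i = np.arange(n)
    cmin = np.cos(cap_angle)
    cos_t = 1.0 - (1.0 - cmin) * (i + 0.5) / n
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = i * _GOLDEN_ANGLE + phase
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _tangent_frame(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangents completing a right-handed triad with ``radial``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(radial @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    return t1, t2


def build_helmet_array(
    n_sensors: int = 64,
    head_radius: float = 0.09,
    standoff: float = 0.0065,
    seed: int = 0,
    cap_angle: float = DEFAULT_CAP_ANGLE,
) -> SensorArray:
    """Build the synthetic helmet array.

    Parameters
    ----------
    n_sensors : int
        Number of triaxial sensors (default 64 -> 192 channels).
    head_radius : float
        Conductor sphere radius, metres.
    standoff : float
        Scalp-to-cell distance, metres (helmet wall + sensor housing).
    seed : int
        Rotates the lattice azimuthally; identical seeds give bitwise
        identical geometry.
    cap_angle : float
        Polar extent of helmet coverage, radians.

    Raises
    ------
    InvalidGeometryError
        For fewer than 4 sensors or non-positive radii.
    """
    if n_sensors < 4:
        raise InvalidGeometryError("need at least 4 sensors")
    if head_radius <= 0:
        raise InvalidGeometryError("head radius must be positive")
    if standoff < 0:
        raise InvalidGeometryError("standoff must be non-negative")

    phase = 2.0 * np.pi * (np.uint64(seed) * np.uint64(2654435761) % np.uint64(2**32)) / 2**32
    radii = head_radius + standoff
    units = _fibonacci_cap(n_sensors, cap_angle, float(phase))

    sensors = []
    for k in range(n_sensors):
        radial = units[k]
        t1, t2 = _tangent_frame(radial)
        sensors.append(Sensor(id=k, position=radii * radial, axes=np.array([t1, t2, radial])))
    return SensorArray(sensors=tuple(sensors), head_radius=head_radius, standoff=standoff, seed=seed)


def orientation_matrix(array: SensorArray) -> np.ndarray:
    """(n_channels, 3) matrix whose row i is channel i's unit sensitive axis.

    This is the ``N`` matrix consumed by homogeneous field correction: a
    spatially uniform field ``v`` produces channel data ``N @ v``.
    """
    return array.axes.reshape(array.n_channels, 3).copy()


# -- CSV export/import --------------------------------------------------------

_CSV_HEADER = (
    "sensor_id,x,y,z,"
    "ax0_x,ax0_y,ax0_z,ax1_x,ax1_y,ax1_z,ax2_x,ax2_y,ax2_z"
)


def array_to_csv(array: SensorArray, path) -> None:
    """Write the geometry as CSV (positions in metres, unit axis vectors)."""
    with open(path, "w") as fh:
        fh.write(f"# head_radius={array.head_radius!r} standoff={array.standoff!r} seed={array.seed}\n")
        fh.write(_CSV_HEADER + "\n")
        for s in array.sensors:
            vals = np.concatenate([s.position, s.axes.ravel()])
            fh.write(f"{s.id}," + ",".join(f"{v:.17g}" for v in vals) + "\n")


def array_from_csv(path) -> SensorArray:
    """Read geometry written by :func:`array_to_csv` (exact round trip)."""
    with open(path) as fh:
        meta_line = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in meta_line)
        text = fh.read()
    raw = np.loadtxt(io.StringIO(text), delimiter=",", skiprows=1, ndmin=2)
    sensors = tuple(
        Sensor(id=int(row[0]), position=row[1:4], axes=row[4:13].reshape(3, 3))
        for row in raw
    )
    return SensorArray(
        sensors=sensors,
        head_radius=float(meta["head_radius"]),
        standoff=float(meta["standoff"]),
        seed=int(meta["seed"]),
    )
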