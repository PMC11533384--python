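"""Forward models: current dipoles in a conducting sphere, the triangular
phantom coil, homogeneous background fields, and lead fields.

The neural forward model is the closed-form field of a current dipole in a
homogeneous conducting sphere (Sarvas' formula).  Two properties of that
solution are load-bearing for everything downstream and are asserted by the
test suite: the external field is independent of the sphere's conductivity
profile, and a radially oriented dipole produces *no* external field, so
lead fields have a rank-2 (tangential) column space.

The phantom is a single-turn triangular coil in air (dry phantom): its field
is the exact Biot-Savart solution of three finite straight segments with no
volume-current term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dipole",
    "TriangleCoil",
    "SourceGrid",
    "LeadField",
    "dipole_field_sphere",
    "triangle_coil_field",
    "homogeneous_field",
    "compute_leadfield",
    "make_triangle_coil",
    "default_phantom_coil",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A


class ForwardDomainError(ValueError):
    """Evaluation point or source violates the model's domain."""


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m) and moment (A·m), head frame."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))


@dataclass(frozen=True)
class TriangleCoil:
    """Single-turn triangular coil; vertices (3, 3) in metres.

    The default phantom geometry is an isosceles triangle with a 5 mm base
    and 45 mm height, mimicking a current dipole of strength
    ``I * base`` concentrated at the base.
    """

    vertices: np.ndarray
    n_turns: int = 1

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 3):
            raise ForwardDomainError("triangle coil needs 3 vertices")
        if np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0])) < 1e-12:
            raise ForwardDomainError("triangle vertices are collinear")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        v = self.vertices
        return 0.5 * float(np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0])))

    @property
    def normal(self) -> np.ndarray:
        v = self.vertices
        n = np.cross(v[1] - v[0], v[2] - v[0])
        return n / np.linalg.norm(n)

    @property
    def extent(self) -> float:
        """Largest vertex-to-vertex distance, metres."""
        v = self.vertices
        return float(max(np.linalg.norm(v[i] - v[j]) for i in range(3) for j in range(i)))


@dataclass(frozen=True)
class SourceGrid:
    """Regular lattice of candidate source points inside the conductor."""

    points: np.ndarray  # (n_points, 3), metres
    spacing: float = 0.004

    @property
    def n_points(self) -> int:
        return len(self.points)

    @classmethod
    def sphere_interior(
        cls,
        radius: float,
        spacing: float = 0.004,
        origin: np.ndarray | None = None,
    ) -> "SourceGrid":
        """All lattice points with ``|p - origin| < radius``.

        The lattice passes through the origin; 4 mm spacing by default.
        """
        if radius <= 0:
            raise ForwardDomainError("grid radius must be positive")
        origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
        n = int(np.floor(radius / spacing))
        ax = np.arange(-n, n + 1) * spacing
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) < radius] + origin
        return cls(points=pts, spacing=spacing)


@dataclass(frozen=True)
class LeadField:
    """Per-point (n_channels, 3) gain matrices, tesla per A·m.

    Column j of ``matrices[i]`` is the channel response to a unit dipole
    moment along head axis j at grid point i.  For the spherical conductor
    the radial moment direction lies in the null space of every matrix.
    """

    grid: SourceGrid
    matrices: np.ndarray  # (n_points, n_channels, 3)
    sphere_origin: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


def dipole_field_sphere(
    dipole: Dipole,
    points: np.ndarray,
    sphere_origin: np.ndarray | None = None,
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Magnetic field of a current dipole inside a homogeneous conducting
    sphere, evaluated at external points (Sarvas closed form).

    Parameters
    ----------
    dipole : Dipole
        Source; must lie inside the conductor.
    points : (n, 3) ndarray
        External evaluation points, metres.
    sphere_origin : (3,) ndarray, optional
        Conductor centre (defaults to the head-frame origin).
    sphere_radius : float, optional
        If given, used to validate the source-inside / points-outside
        domain; the field itself does not depend on the radius.

    Returns
    -------
    (n, 3) ndarray
        Field in tesla.  Exactly zero for radial moments; a dipole at the
        sphere centre is externally silent for any moment (documented
        degenerate case, not an error).
    """
    origin = np.zeros(3) if sphere_origin is None else np.asarray(sphere_origin, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r0 = dipole.position - origin
    q = dipole.moment

    if sphere_radius is not None:
        if np.linalg.norm(r0) >= sphere_radius:
            raise ForwardDomainError("dipole lies outside the conductor sphere")
        if np.any(np.linalg.norm(pts - origin, axis=1) <= sphere_radius):
            raise ForwardDomainError("evaluation point inside the conductor sphere")

    r = pts - origin
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rr = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ForwardDomainError("evaluation point coincides with the dipole")

    f = a * (rr * a + rr**2 - r @ r0)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    grad_f = (
        (a**2 / rr + adotr / a + 2.0 * a + 2.0 * rr)[:, None] * r
        - (a + 2.0 * rr + adotr / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    if np.linalg.norm(qxr0) == 0.0:
        # radial moment (or dipole at the centre): externally silent
        return np.zeros_like(pts)
    b = MU0 / (4.0 * np.pi * f**2)[:, None] * (f[:, None] * qxr0 - (r @ qxr0)[:, None] * grad_f)
    return b


def _segment_field(p1: np.ndarray, p2: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Biot-Savart field per ampere of a finite straight segment p1->p2.

    Closed form in terms of the endpoint vectors (Hanson-Hirshman):
    ``B = (mu0 I / 4 pi) (ri x rf)(ri + rf) / (ri rf (ri rf + ri.rf))``.
    """
    ri = points - p1
    rf = points - p2
    ni = np.linalg.norm(ri, axis=1)
    nf = np.linalg.norm(rf, axis=1)
    denom = ni * nf * (ni * nf + np.einsum("ij,ij->i", ri, rf))
    if np.any(denom < 1e-30):
        raise ForwardDomainError("evaluation point lies on a wire segment")
    scale = MU0 / (4.0 * np.pi) * (ni + nf) / denom
    return scale[:, None] * np.cross(ri, rf)


def triangle_coil_field(coil: TriangleCoil, points: np.ndarray, current: float) -> np.ndarray:
    """Field of the closed triangular loop at ``points`` for ``current`` amperes.

    Linear in current; zero current returns exactly zero.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if current == 0.0:
        return np.zeros_like(pts)
    v = coil.vertices
    b = np.zeros_like(pts)
    for i in range(3):
        b += _segment_field(v[i], v[(i + 1) % 3], pts)
    return coil.n_turns * current * b


def homogeneous_field(vector: np.ndarray, array) -> np.ndarray:
    """Per-channel reading of a spatially uniform field ``vector`` (tesla).

    Channel i reads ``vector . orientation_i``; all sensors see the same
    vector, which is exactly what homogeneous field correction removes.
    """
    from .array_geometry import orientation_matrix

    return orientation_matrix(array) @ np.asarray(vector, dtype=float)


def compute_leadfield(
    grid: SourceGrid,
    array,
    sphere_origin: np.ndarray | None = None,
) -> LeadField:
    """Lead field of every grid point seen by every channel.

    Vectorised Sarvas evaluation over (points x channels); the result maps
    unit moments along the head axes to channel outputs in T/(A·m).
    """
    if grid.n_points == 0:
        raise ForwardDomainError("empty source grid")
    origin = np.zeros(3) if sphere_origin is None else np.asarray(sphere_origin, dtype=float)

    sens = array.channel_positions() - origin  # (n_ch, 3)
    orient = array.axes.reshape(array.n_channels, 3)  # (n_ch, 3)
    src = grid.points - origin  # (n_pts, 3)

    # Broadcast geometry: index p = grid point, c = channel
    r = sens[None, :, :]  # (1, n_ch, 3)
    r0 = src[:, None, :]  # (n_pts, 1, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=2)  # (n_pts, n_ch)
    rr = np.linalg.norm(sens, axis=1)[None, :]  # (1, n_ch)
    rdotr0 = src @ sens.T  # (n_pts, n_ch)
    adotr = np.einsum("pcj,cj->pc", a_vec, sens)

    f = a * (rr * a + rr**2 - rdotr0)
    c1 = a**2 / rr + adotr / a + 2.0 * a + 2.0 * rr
    c2 = a + 2.0 * rr + adotr / a
    grad_f = c1[..., None] * r - c2[..., None] * r0  # (n_pts, n_ch, 3)

    # B = mu0/(4 pi F^2) [F (q x r0) - ((q x r0).r) grad F]; build the
    # 3 unit-moment columns at once via the cross-product matrix of r0.
    eye = np.eye(3)
    qxr0 = np.cross(eye[None, :, :], src[:, None, :])  # (n_pts, 3(moment), 3)
    inv_f2 = MU0 / (4.0 * np.pi) / f**2  # (n_pts, n_ch)
    term1 = np.einsum("pc,pmj->pcmj", f, qxr0)
    rdotqxr0 = np.einsum("cj,pmj->pcm", sens, qxr0)
    term2 = np.einsum("pcm,pcj->pcmj", rdotqxr0, grad_f)
    b = inv_f2[..., None, None] * (term1 - term2)  # (n_pts, n_ch, moment, 3)
    gains = np.einsum("pcmj,cj->pcm", b, orient)  # (n_pts, n_ch, 3)
    return LeadField(grid=grid, matrices=gains, sphere_origin=origin)


def make_triangle_coil(
    base: float = 0.005,
    height: float = 0.045,
    apex_position: np.ndarray = (0.0, 0.0, 0.0),
    base_direction: np.ndarray = (1.0, 0.0, 0.0),
    height_direction: np.ndarray = (0.0, 0.0, 1.0),
) -> TriangleCoil:
    """Isosceles triangular coil (default 5 mm base, 45 mm height).

    The base is centred ``height`` away from the apex along
    ``height_direction``; the twisted feed wires of the physical phantom
    carry no net field and are not modelled.
    """
    apex = np.asarray(apex_position, dtype=float)
    bdir = np.asarray(base_direction, dtype=float)
    bdir = bdir / np.linalg.norm(bdir)
    hdir = np.asarray(height_direction, dtype=float)
    hdir = hdir - (hdir @ bdir) * bdir
    hdir /= np.linalg.norm(hdir)
    centre = apex + height * hdir
    return TriangleCoil(
        vertices=np.array([apex, centre - 0.5 * base * bdir, centre + 0.5 * base * bdir])
    )


def default_phantom_coil(helmet_radius: float = 0.0965) -> TriangleCoil:
    """Phantom coil pose used by the simulated experiments.

    The coil hangs inside the helmet like a dipole ~2.5 cm under the crown,
    base (current-dipole edge) oriented tangentially, so that the strongest
    channel at 1 mA drive sees a field of order 10^2 pT.  The pose is a
    configuration default, not a claim about the physical phantom.
    """
    apex = np.array([0.0, 0.0, helmet_radius - 0.070])
    return make_triangle_coil(
        apex_position=apex,
        base_direction=(0.0, 1.0, 0.0),
        height_direction=(0.0, 0.0, 1.0),
    )
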