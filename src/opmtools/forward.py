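"""Array geometry and the spherical-conductor dipole forward model.

The head is modelled as a homogeneous conducting sphere.  For a current
dipole inside a sphere the external magnetic field has a closed form
(Sarvas, 1987) in which volume currents contribute no radial field and any
dipole-moment component parallel to the source's radius vector is
externally silent.  Those two algebraic facts are what the interference
pipelines rely on, so a sphere preserves everything the package exercises
while avoiding an MRI-based surface model.

Sensors are laid out on a Fibonacci lattice over the upper hemisphere,
about 1 cm off a 9 cm scalp sphere -- the stand-off of wearable sensors in
a scanner-cast.  Each sensor carries a radial sensitive axis plus one
(dual-axis) or two (triaxial) tangential axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChannelInfo

__all__ = [
    "SphereModel",
    "LeadField",
    "ArrayGeometry",
    "build_array_geometry",
    "default_reference_channels",
    "sarvas_leadfield",
    "dual_source_leadfield",
    "AUDITORY_SOURCES",
    "SENSORIMOTOR_SOURCE",
]

MU0_OVER_4PI = 1e-7  # T·m/A

# Conventional bilateral "auditory" source positions in the sphere frame
# (metres): canonical-atlas auditory-cortex coordinates read as sphere-frame
# millimetres, scaled to sit well inside the default sphere.  A convention,
# not anatomy.
AUDITORY_SOURCES = (np.array([-0.054, -0.022, 0.004]), np.array([0.054, -0.022, 0.004]))
# Left "sensorimotor" position for the finger-tapping preset.
SENSORIMOTOR_SOURCE = np.array([-0.040, -0.010, 0.055])


@dataclass(frozen=True)
class SphereModel:
    centre: np.ndarray = None
    radius: float = 0.09

    def __post_init__(self):
        centre = np.zeros(3) if self.centre is None else np.asarray(self.centre, float)
        object.__setattr__(self, "centre", centre)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class LeadField:
    """(n_channels x 3) map from dipole moment (A·m) to channel fields (T)."""

    source_position: np.ndarray
    matrix: np.ndarray


@dataclass
class ArrayGeometry:
    """Ordered scalp-sensor channel list."""

    channels: list[ChannelInfo]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([c.position for c in self.channels])

    @property
    def orientations(self) -> np.ndarray:
        return np.stack([c.orientation for c in self.channels])


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n unit vectors spread evenly around the head: a Fibonacci lattice
    over the spherical cap z > -0.25 (whole-head coverage reaching below
    the equator, as a scanner-cast does, but leaving out the face/neck)."""
    i = np.arange(n)
    z = -0.25 + 1.2 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def build_array_geometry(
    n_sensors: int,
    axes: str = "dual",
    head_radius: float = 0.09,
    scalp_offset: float = 0.01,
) -> ArrayGeometry:
    """Evenly spread ``n_sensors`` over the upper hemisphere.

    ``axes='dual'`` gives a radial plus one tangential channel per sensor
    (names ``S##-RAD``, ``S##-TAN``); ``'triaxial'`` adds ``S##-TAN2``.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if axes not in ("dual", "triaxial"):
        raise ValueError("axes must be 'dual' or 'triaxial'")
    radial = _fibonacci_hemisphere(n_sensors)
    r = head_radius + scalp_offset
    channels: list[ChannelInfo] = []
    zhat = np.array([0.0, 0.0, 1.0])
    for k in range(n_sensors):
        u = radial[k]
        pos = r * u
        t1 = np.cross(zhat, u)
        if np.linalg.norm(t1) < 1e-6:  # sensor at the pole
            t1 = np.array([1.0, 0.0, 0.0])
        t1 = t1 / np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        name = f"S{k:02d}"
        channels.append(ChannelInfo(f"{name}-RAD", "scalp", "RAD", pos, u))
        channels.append(ChannelInfo(f"{name}-TAN", "scalp", "TAN", pos, t1))
        if axes == "triaxial":
            channels.append(ChannelInfo(f"{name}-TAN2", "scalp", "TAN2", pos, t2))
    return ArrayGeometry(channels)


def default_reference_channels() -> list[ChannelInfo]:
    """Four reference channels: two dual-axis sensors mounted statically,
    away from the head (named after the study's N0/N4 references)."""
    out = []
    # axes chosen so the four sensitive directions condition all three
    # field components well (horizontal pair on N0, vertical-leaning pair
    # on N4), as reference sensors are mounted in practice
    for name, pos in (("N0", np.array([0.45, 0.35, 0.20])), ("N4", np.array([-0.45, 0.35, 0.20]))):
        u = pos / np.linalg.norm(pos)
        t_h = np.cross([0.0, 0.0, 1.0], u)
        t_h = t_h / np.linalg.norm(t_h)
        t_v = np.cross(u, t_h)  # tangential, strong vertical component
        out.append(ChannelInfo(f"{name}-RAD", "reference", "RAD", pos, u))
        if name == "N0":
            out.append(ChannelInfo(f"{name}-TAN", "reference", "TAN", pos, t_h))
        else:
            out.append(ChannelInfo(f"{name}-TAN", "reference", "TAN", pos, t_v))
    return out


def sarvas_leadfield(
    geom: ArrayGeometry, sphere: SphereModel, source: np.ndarray
) -> LeadField:
    """Lead field of a current dipole in a homogeneous conducting sphere.

    Returns the (n_channels x 3) matrix mapping the dipole moment to the
    field projected on each channel's sensitive axis.  Linear in the
    moment; silent for radial moments.
    """
    source = np.asarray(source, dtype=float)
    r0 = source - sphere.centre
    if np.linalg.norm(r0) >= sphere.radius:
        raise ValueError("source must lie strictly inside the sphere")
    if np.linalg.norm(r0) < 1e-9:
        raise ValueError("source at the sphere centre is degenerate")

    pos = geom.positions - sphere.centre  # (n, 3)
    if np.any(np.linalg.norm(pos, axis=1) <= sphere.radius):
        raise ValueError("sensors must lie outside the sphere")
    ori = geom.orientations

    n = pos.shape[0]
    L = np.empty((n, 3))
    for col, q in enumerate(np.eye(3)):
        qxr0 = np.cross(q, r0)  # (3,)
        a_vec = pos - r0
        a = np.linalg.norm(a_vec, axis=1)
        r = np.linalg.norm(pos, axis=1)
        a_dot_r = np.einsum("ij,ij->i", a_vec, pos)
        F = a * (r * a + r**2 - pos @ r0)
        gF = (
            (a**2 / r + a_dot_r / a + 2.0 * a + 2.0 * r)[:, None] * pos
            - (a + 2.0 * r + a_dot_r / a)[:, None] * r0[None, :]
        )
        B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0[None, :] - (pos @ qxr0)[:, None] * gF)
        L[:, col] = np.einsum("ij,ij->i", B, ori)
    return LeadField(source_position=source, matrix=L)


def dual_source_leadfield(
    geom: ArrayGeometry, sphere: SphereModel, sources: list[np.ndarray]
) -> np.ndarray:
    """Column-wise concatenation of per-source lead fields.

    Column order: source-1 x,y,z then source-2 x,y,z (and so on -- any
    number of sources is accepted, two being the evoked-field use case).
    """
    mats = [sarvas_leadfield(geom, sphere, s).matrix for s in sources]
    return np.hstack(mats)


def free_space_dipole_field(
    positions: np.ndarray, source: np.ndarray, moment: np.ndarray
) -> np.ndarray:
    """Biot-Savart field of the primary current element alone (no volume
    currents); the independent check for the radial field component."""
    rv = positions - source
    r = np.linalg.norm(rv, axis=1)
    return MU0_OVER_4PI * np.cross(moment, rv) / r[:, None] ** 3
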