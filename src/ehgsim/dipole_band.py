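"""Moving dipole-band model of uterine electrical activity.

The depolarization front travelling over the myometrium is abstracted as a
narrow annular band of electric dipoles on the wall of an inverted cone
(the pregnant uterus).  The band starts at the fundus, travels to the
cervix at constant speed ``c`` and returns, producing a transient potential
at every observation coordinate on the cone axis.

Geometry and units
------------------
All lengths are millimetres and times seconds.  The cone apex sits at the
origin of the band's axial coordinate; a band whose slant distance from the
apex is ``R`` lies at axial position ``R*cos(theta)`` with ring radius
``R*sin(theta)``, where ``theta`` is the cone half-angle.  The band's
potential is evaluated in uncalibrated model units: the dipole moment is
expressed in C*mm and the medium constant ``eps0`` is the dimensionless
value used by the source expression, so only ratios and timings of the
resulting waveforms are physically meaningful.

Round trip
----------
The axial band position follows a triangular trajectory
``-Ros -> +Ros -> -Ros``.  Past the apex the slant radius is folded
(``R = |z_band|/cos(theta)``) and the band is mirrored to the opposite
half-axis, so the cone re-expands symmetrically on the far leg and the
round-trip waveform is an exact palindrome about the turnaround instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, SingularityError

__all__ = [
    "DipoleBandParams",
    "SourceWaveform",
    "band_displacement",
    "band_axial_position",
    "band_radius",
    "band_density",
    "source_potential",
    "simulate_round_trip",
]

#: Denominators of the source potential smaller than this (relative to the
#: band scale) are treated as singular configurations.
_SINGULARITY_RTOL = 1e-12


@dataclass(frozen=True)
class DipoleBandParams:
    """Parameters of the travelling dipole band.

    Attributes
    ----------
    c:
        Band propagation speed along the uterine axis, mm/s.
    Ros:
        Initial axial position of the band (fundus half-span), mm.
    theta_deg:
        Cone half-angle of the uterus wall, degrees.
    delta:
        Width of the dipole band measured along the wall, mm.
    p0:
        Total dipole moment carried by the band, C*mm.
    eps0:
        Medium constant in the source-potential denominator
        (dimensionless model units).
    """

    c: float = 30.0
    Ros: float = 400.0
    theta_deg: float = 10.0
    delta: float = 6.0
    p0: float = 2.2e-13
    eps0: float = 0.36

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise DomainError(f"band speed c must be positive, got {self.c}")
        if not self.Ros > 0:
            raise DomainError(f"initial position Ros must be positive, got {self.Ros}")
        if not 0.0 < self.theta_deg < 90.0:
            raise DomainError(
                f"cone half-angle must lie strictly between 0 and 90 deg, got {self.theta_deg}"
            )
        if not self.delta > 0:
            raise DomainError(f"band width delta must be positive, got {self.delta}")
        if not self.p0 > 0:
            raise DomainError(f"band moment p0 must be positive, got {self.p0}")
        if not self.eps0 > 0:
            raise DomainError(f"medium constant eps0 must be positive, got {self.eps0}")

    @property
    def theta(self) -> float:
        """Cone half-angle in radians."""
        return float(np.deg2rad(self.theta_deg))

    @property
    def one_way_time(self) -> float:
        """Time for the band to travel from -Ros to +Ros, s."""
        return 2.0 * self.Ros / self.c

    @property
    def round_trip_time(self) -> float:
        """Duration of the full fundus -> cervix -> fundus trip, s."""
        return 4.0 * self.Ros / self.c


@dataclass(frozen=True)
class SourceWaveform:
    """A sampled source-potential waveform at a fixed axial coordinate."""

    times: np.ndarray
    band_z: np.ndarray
    values: np.ndarray
    zeta: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        band_z = np.asarray(self.band_z, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if not (len(times) == len(band_z) == len(values)):
            raise DomainError("times, band_z and values must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "band_z", band_z)
        object.__setattr__(self, "values", values)


def band_displacement(params: DipoleBandParams, t):
    """Displacement ``c*t`` of the band since the start of the trip, mm.

    ``t`` may be a scalar or array of times in seconds; negative times are
    outside the model's domain.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    out = params.c * t
    return float(out) if out.ndim == 0 else out


def band_axial_position(params: DipoleBandParams, t):
    """Signed axial band position for the round trip, mm.

    Triangular trajectory: ``-Ros`` at ``t=0``, ``+Ros`` at the turnaround
    (cervix) and back to ``-Ros`` at ``t = 4*Ros/c``.  Times beyond one
    round trip are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if np.any(t > params.round_trip_time * (1 + 1e-12)):
        raise DomainError(
            f"time beyond one round trip ({params.round_trip_time:g} s); "
            "the model covers a single fundus-cervix-fundus excursion"
        )
    t_turn = params.one_way_time
    out = np.where(
        t <= t_turn,
        -params.Ros + params.c * t,
        params.Ros - params.c * (t - t_turn),
    )
    return float(out) if out.ndim == 0 else out


def band_radius(params: DipoleBandParams, t):
    """Slant position of the band on the cone wall, ``(Ros - c*t)/cos(theta)``, mm.

    This is the one-way expression exactly as the model defines it; it goes
    negative once the band passes the apex, which the round-trip driver
    handles by folding (see :func:`source_potential`).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    out = (params.Ros - params.c * t) / np.cos(params.theta)
    return float(out) if out.ndim == 0 else out


def _band_area(params: DipoleBandParams, R):
    """Annular area of the band on the cone wall at slant radius ``R``, mm^2."""
    return np.pi * np.sin(params.theta) * ((R + params.delta) ** 2 - R**2)


def band_density(params: DipoleBandParams, R):
    """Dipole density of the band at slant radius ``R``, C*mm per mm^2.

    The total moment ``p0`` is spread over the annular band area, so the
    density decreases strictly with ``R``.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("slant radius R must be non-negative")
    out = params.p0 / _band_area(params, R)
    return float(out) if out.ndim == 0 else out


def _potential_from_band_position(params: DipoleBandParams, zeta, z_band):
    """Source potential at axial coordinate ``zeta`` for a band at ``z_band``.

    Implements the two-term axial expression: each term is the derivative
    of the distance from the observation point to one edge circle of the
    band, weighted by the band's dipole density.  When the band sits on the
    negative half-axis it is mirrored (``zeta -> -zeta``), which keeps the
    round trip exactly symmetric.
    """
    zeta = np.asarray(zeta, dtype=float)
    z_band = np.asarray(z_band, dtype=float)
    sign = np.where(z_band >= 0, 1.0, -1.0)
    u = sign * zeta
    cos_t = np.cos(params.theta)
    R = np.abs(z_band) / cos_t
    edges = (R, R + params.delta)

    dist = []
    for name, a in zip(("inner", "outer"), edges):
        d2 = u**2 - 2.0 * a * u * cos_t + a**2
        d = np.sqrt(np.maximum(d2, 0.0))
        scale = np.maximum(np.abs(u), a) + params.delta
        if np.any(d <= _SINGULARITY_RTOL * scale):
            raise SingularityError(
                f"observation coordinate lies on the band's {name}-edge circle: "
                f"the {name}-edge denominator of the source potential vanishes"
            )
        dist.append(d)
    d_inner, d_outer = dist

    term_outer = (u - edges[1] * cos_t) / d_outer
    term_inner = (u - edges[0] * cos_t) / d_inner
    density = band_density(params, R)
    out = -density / (2.0 * params.eps0) * (term_outer - term_inner)
    return float(out) if out.ndim == 0 else out


def source_potential(params: DipoleBandParams, zeta, t):
    """Source potential at axial coordinate ``zeta`` (mm) at time ``t`` (s).

    The band position is taken from the round-trip driver
    (:func:`band_axial_position`); singular configurations (observation
    point on one of the band-edge circles) raise
    :class:`~ehgsim.exceptions.SingularityError` naming the offending term.
    """
    z_band = band_axial_position(params, t)
    return _potential_from_band_position(params, zeta, z_band)


def simulate_round_trip(
    params: DipoleBandParams,
    zetas,
    dt: float = 0.1,
) -> list[SourceWaveform]:
    """Sample source waveforms for a full fundus -> cervix -> fundus trip.

    Parameters
    ----------
    params:
        Band parameters.
    zetas:
        Observation coordinates on the axis, mm (nonempty).
    dt:
        Time step, s.  The default 0.1 s resolves the waveform peaks well
        below the band transit time across its own width.

    Returns
    -------
    One :class:`SourceWaveform` per observation coordinate, all sharing the
    same time base ``0, dt, ..., 4*Ros/c``.
    """
    if dt <= 0:
        raise DomainError("time step dt must be positive")
    zetas = np.atleast_1d(np.asarray(zetas, dtype=float))
    if zetas.size == 0:
        raise DomainError("at least one observation coordinate is required")
    n_steps = int(np.floor(params.round_trip_time / dt + 1e-9))
    times = np.arange(n_steps + 1) * dt
    band_z = band_axial_position(params, times)
    waveforms = []
    for zeta in zetas:
        values = _potential_from_band_position(params, float(zeta), band_z)
        waveforms.append(
            SourceWaveform(times=times, band_z=band_z, values=values, zeta=float(zeta))
        )
    return waveforms
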