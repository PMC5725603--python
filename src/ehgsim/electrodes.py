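"""Surface-electrode read-out models.

Four electrode designs read the abdominal surface potential:

* **monopolar** — an Ag/AgCl disc of radius ``2r``; the reading is the
  area-averaged potential.
* **bipolar** concentric ring — central disc plus one ring at radius ``r``;
  estimates the surface Laplacian as ``(4/r^2) * (ring_mean - v0)``.
* **quasi-bipolar** — disc, middle ring ``r`` and outer ring ``2r`` with
  disc and outer ring shorted; the reading is the unnormalized difference
  ``(v_or + v0)/2 - v_mr``.
* **tri-polar** — three independent elements combined as
  ``(1/3r^2) * (16*(v_mr - v0) - (v_or - v0))``, which cancels the
  fourth-order truncation term and is exact for polynomials of degree <= 5.

The five-point and nine-point finite-difference stencils that the ring
formulas generalize are provided as independent oracles.

Estimators operate on a *plane field*: either a callable ``f(u, v)`` in
local tangent-plane millimetre coordinates, or any object exposing
``plane_at(center)`` (such as the solver's
:class:`~ehgsim.volume_conductor.PotentialField`, which projects plane
samples onto the curved abdominal surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DomainError

__all__ = [
    "ELECTRODE_KINDS",
    "ElectrodeSpec",
    "electrode_sample_functional",
    "ring_average",
    "disc_average",
    "read_monopolar",
    "laplacian_bipolar",
    "laplacian_quasi_bipolar",
    "laplacian_tripolar",
    "laplacian_five_point",
    "laplacian_nine_point",
    "read_electrode",
]

ELECTRODE_KINDS = ("monopolar", "bipolar", "quasi_bipolar", "tripolar")

#: Gauss-Legendre nodes/weights cache keyed by point count.
_GAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss01(n: int):
    """Gauss-Legendre nodes and weights on [0, 1]."""
    if n not in _GAUSS_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _GAUSS_CACHE[n] = (0.5 * (x + 1.0), 0.5 * w)
    return _GAUSS_CACHE[n]


@dataclass(frozen=True)
class ElectrodeSpec:
    """Geometry of one electrode.

    ``r`` is the middle-ring radius; the outer ring sits at exactly ``2r``
    and the monopolar disc radius equals ``2r`` as well, so a single ``r``
    fixes every design's footprint.  ``ring_width`` is shared by all
    Laplacian kinds; 0 means an idealized line ring.  ``v0_mode`` selects
    whether the central-disc potential is the physical disc average
    ("disc") or the idealized centre-point sample ("point").
    """

    kind: str
    r: float
    disc_radius: float = 2.5
    ring_width: float = 1.0
    center: tuple[float, float, float] | None = None
    n_quadrature: int = 360
    v0_mode: str = "disc"

    def __post_init__(self) -> None:
        if self.kind not in ELECTRODE_KINDS:
            raise ConfigError(
                f"unknown electrode kind {self.kind!r}; expected one of {ELECTRODE_KINDS}"
            )
        if not 6.0 <= 2.0 * self.r <= 26.0:
            raise ConfigError(
                f"outer ring radius 2r must lie in 6-26 mm, got {2 * self.r} mm"
            )
        if not 0.0 < self.disc_radius < self.r:
            raise ConfigError(
                f"disc radius must be positive and smaller than r={self.r} mm"
            )
        if self.ring_width < 0:
            raise ConfigError("ring_width must be >= 0")
        if self.n_quadrature < 8:
            raise ConfigError("n_quadrature must be >= 8")
        if self.v0_mode not in ("disc", "point"):
            raise ConfigError("v0_mode must be 'disc' or 'point'")

    @property
    def outer_radius(self) -> float:
        """Outer-ring (and monopolar disc) radius, always exactly 2r."""
        return 2.0 * self.r


def _ring_samples(radius: float, n_samples: int, ring_width: float = 0.0,
                  n_radial: int = 3):
    """Plane sample offsets (u, v) and weights (summing to 1) for a ring mean.

    Uniform angles (trapezoidal rule, spectrally accurate for the periodic
    integrand); for a finite ``ring_width`` the annulus is integrated with
    Gauss points placed uniformly in rho^2, which absorbs the area weight.
    """
    if radius <= 0:
        raise DomainError("ring radius must be positive")
    if n_samples < 8:
        raise DomainError("n_samples must be >= 8")
    phis = 2.0 * np.pi * np.arange(n_samples) / n_samples
    cos_p, sin_p = np.cos(phis), np.sin(phis)
    if ring_width == 0.0:
        rhos, wr = np.array([radius]), np.array([1.0])
    else:
        if ring_width < 0 or ring_width >= 2 * radius:
            raise DomainError("ring_width must be in [0, 2*radius)")
        lo2 = (radius - 0.5 * ring_width) ** 2
        hi2 = (radius + 0.5 * ring_width) ** 2
        xg, wg = _gauss01(n_radial)
        rhos, wr = np.sqrt(lo2 + (hi2 - lo2) * xg), wg
    u = np.concatenate([rho * cos_p for rho in rhos])
    v = np.concatenate([rho * sin_p for rho in rhos])
    w = np.concatenate([np.full(n_samples, wi / n_samples) for wi in wr])
    return u, v, w


def _disc_samples(radius: float, n_samples: int, n_rings: int = 8):
    """Plane sample offsets and weights for a disc area-average."""
    if radius <= 0:
        raise DomainError("disc radius must be positive")
    xg, wg = _gauss01(n_rings)
    rhos = radius * np.sqrt(xg)  # uniform in rho^2 <=> area weighting
    phis = 2.0 * np.pi * np.arange(n_samples) / n_samples
    cos_p, sin_p = np.cos(phis), np.sin(phis)
    u = np.concatenate([rho * cos_p for rho in rhos])
    v = np.concatenate([rho * sin_p for rho in rhos])
    w = np.concatenate([np.full(n_samples, wi / n_samples) for wi in wg])
    return u, v, w


def electrode_sample_functional(spec: ElectrodeSpec):
    """The electrode reading as one linear functional of the plane field.

    Returns ``(uv, weights)`` — plane offsets (k, 2) and signed weights —
    such that ``sum(w * v(u, v)) == read_electrode`` for the same spec.
    Used to build reciprocal (lead-field) readers.
    """
    r = spec.r
    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
    if spec.kind == "monopolar":
        parts.append((*_disc_samples(spec.outer_radius, spec.n_quadrature), 1.0))
    else:
        if spec.v0_mode == "point":
            v0 = (np.zeros(1), np.zeros(1), np.ones(1))
        else:
            v0 = _disc_samples(spec.disc_radius, spec.n_quadrature)
        mr = _ring_samples(r, spec.n_quadrature, spec.ring_width)
        if spec.kind == "bipolar":
            parts = [(*mr, 4.0 / r**2), (*v0, -4.0 / r**2)]
        elif spec.kind == "quasi_bipolar":
            outer = _ring_samples(2 * r, spec.n_quadrature, spec.ring_width)
            parts = [(*outer, 0.5), (*v0, 0.5), (*mr, -1.0)]
        elif spec.kind == "tripolar":
            outer = _ring_samples(2 * r, spec.n_quadrature, spec.ring_width)
            parts = [
                (*mr, 16.0 / (3.0 * r**2)),
                (*v0, -15.0 / (3.0 * r**2)),
                (*outer, -1.0 / (3.0 * r**2)),
            ]
    uv = np.vstack([np.stack([u, v], axis=1) for u, v, _, _ in parts])
    weights = np.concatenate([w * coeff for _, _, w, coeff in parts])
    return uv, weights


def _as_plane(field, center=None):
    """Normalize ``field`` to a plane callable f(u, v)."""
    if callable(field) and not hasattr(field, "plane_at"):
        if center is not None and np.any(np.asarray(center, float) != 0.0):
            cu, cv = float(center[0]), float(center[1])
            return lambda u, v: field(np.asarray(u) + cu, np.asarray(v) + cv)
        return field
    if hasattr(field, "plane_at"):
        return field.plane_at(center)
    raise ConfigError(
        "field must be a plane callable f(u, v) or expose plane_at(center)"
    )


def ring_average(
    field,
    center=None,
    radius: float = 5.0,
    n_samples: int = 360,
    ring_width: float = 0.0,
    n_radial: int = 3,
) -> float:
    """Mean potential over a circle (or annulus) on the electrode plane.

    Trapezoidal quadrature in angle — spectrally accurate for the periodic
    integrand — and, for ``ring_width > 0``, Gauss quadrature over the
    annulus ``[radius - w/2, radius + w/2]`` with the area weight ``rho``.
    """
    plane = _as_plane(field, center)
    u, v, w = _ring_samples(radius, n_samples, ring_width, n_radial)
    return float(np.sum(w * plane(u, v)))


def disc_average(
    field,
    center=None,
    radius: float = 2.5,
    n_rings: int = 8,
    n_samples: int = 360,
) -> float:
    """Area-averaged potential over a disc on the electrode plane."""
    plane = _as_plane(field, center)
    u, v, w = _disc_samples(radius, n_samples, n_rings)
    return float(np.sum(w * plane(u, v)))


def _v0(field, center, spec: ElectrodeSpec) -> float:
    plane = _as_plane(field, center)
    if spec.v0_mode == "point":
        return float(plane(0.0, 0.0))
    return disc_average(field, center, spec.disc_radius, n_samples=spec.n_quadrature)


def read_monopolar(field, spec: ElectrodeSpec, center=None) -> float:
    """Disc-averaged potential of the monopolar electrode (radius 2r)."""
    if spec.kind != "monopolar":
        raise ConfigError(f"read_monopolar requires kind='monopolar', got {spec.kind!r}")
    center = spec.center if center is None else center
    return disc_average(field, center, spec.outer_radius, n_samples=spec.n_quadrature)


def laplacian_bipolar(field, spec: ElectrodeSpec, center=None) -> float:
    """Bipolar concentric-ring Laplacian estimate ``(4/r^2)(v_ring - v0)``."""
    if spec.kind != "bipolar":
        raise ConfigError(f"laplacian_bipolar requires kind='bipolar', got {spec.kind!r}")
    center = spec.center if center is None else center
    v_mr = ring_average(
        field, center, spec.r, spec.n_quadrature, ring_width=spec.ring_width
    )
    return (4.0 / spec.r**2) * (v_mr - _v0(field, center, spec))


def laplacian_quasi_bipolar(field, spec: ElectrodeSpec, center=None) -> float:
    """Quasi-bipolar reading ``(v_or + v0)/2 - v_mr`` (unnormalized).

    The disc and outer ring are shorted in this design, so the combination
    is kept exactly as the electrode delivers it, without a ``4/r^2``
    scaling; attenuation ratios in dB are unaffected by any fixed scale.
    """
    if spec.kind != "quasi_bipolar":
        raise ConfigError(
            f"laplacian_quasi_bipolar requires kind='quasi_bipolar', got {spec.kind!r}"
        )
    center = spec.center if center is None else center
    v_mr = ring_average(
        field, center, spec.r, spec.n_quadrature, ring_width=spec.ring_width
    )
    v_or = ring_average(
        field, center, spec.outer_radius, spec.n_quadrature, ring_width=spec.ring_width
    )
    return 0.5 * (v_or + _v0(field, center, spec)) - v_mr


def laplacian_tripolar(field, spec: ElectrodeSpec, center=None) -> float:
    """Tri-polar Laplacian estimate with fourth-order error cancellation:

    ``(1/3r^2) * {16*(v_mr - v0) - (v_or - v0)}``.
    """
    if spec.kind != "tripolar":
        raise ConfigError(f"laplacian_tripolar requires kind='tripolar', got {spec.kind!r}")
    center = spec.center if center is None else center
    v0 = _v0(field, center, spec)
    v_mr = ring_average(
        field, center, spec.r, spec.n_quadrature, ring_width=spec.ring_width
    )
    v_or = ring_average(
        field, center, spec.outer_radius, spec.n_quadrature, ring_width=spec.ring_width
    )
    return (16.0 * (v_mr - v0) - (v_or - v0)) / (3.0 * spec.r**2)


def laplacian_five_point(field, center=None, r: float = 5.0) -> float:
    """Five-point compass-stencil Laplacian oracle ``(4/r^2)(mean(v1..v4) - v0)``."""
    if r <= 0:
        raise DomainError("stencil spacing r must be positive")
    plane = _as_plane(field, center)
    u = np.array([r, 0.0, -r, 0.0, 0.0])
    v = np.array([0.0, r, 0.0, -r, 0.0])
    vals = plane(u, v)
    return float((4.0 / r**2) * (np.mean(vals[:4]) - vals[4]))


def laplacian_nine_point(field, center=None, r: float = 5.0) -> float:
    """Nine-point stencil oracle with compass points at r and 2r:

    ``(1/12r^2) * {16*sum(v1..v4) - 60*v0 - sum(v5..v8)}``.
    """
    if r <= 0:
        raise DomainError("stencil spacing r must be positive")
    plane = _as_plane(field, center)
    u = np.array([r, 0.0, -r, 0.0, 2 * r, 0.0, -2 * r, 0.0, 0.0])
    v = np.array([0.0, r, 0.0, -r, 0.0, 2 * r, 0.0, -2 * r, 0.0])
    vals = plane(u, v)
    inner = np.sum(vals[:4])
    outer = np.sum(vals[4:8])
    return float((16.0 * inner - 60.0 * vals[8] - outer) / (12.0 * r**2))


_READERS = {
    "monopolar": read_monopolar,
    "bipolar": laplacian_bipolar,
    "quasi_bipolar": laplacian_quasi_bipolar,
    "tripolar": laplacian_tripolar,
}


def read_electrode(field, spec: ElectrodeSpec, center=None) -> float:
    """Kind-appropriate scalar reading; the uniform experiment entry point."""
    try:
        reader = _READERS[spec.kind]
    except KeyError:  # pragma: no cover - ElectrodeSpec already validates
        raise ConfigError(f"unknown electrode kind {spec.kind!r}") from None
    return reader(field, spec, center=center)
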