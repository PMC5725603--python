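"""Quasi-static volume-conductor forward solver for a layered abdomen.

The abdomen of a pregnant woman is modelled as a hemisphere (radius 100 mm,
dome along +y) carrying three concentric tissue shells — skin, fat, muscle —
over a uterine interior, embedded in a box of near-insulating air whose
outer boundary is grounded (potential 0), emulating an unbounded medium.
Sub-Hz uterine activity justifies the DC (quasi-static) approximation, so
the potential solves the conductivity-weighted Poisson equation

    div( sigma(x) grad phi ) = -s(x)

discretized with a 7-point finite-difference stencil on a regular grid.
Face conductivities are harmonic means of sub-sampled values along each
inter-node segment, which keeps fluxes conservative across layer
interfaces and represents layers thinner than the grid spacing by their
correct series resistance.  Point dipoles are injected as +/- monopole
pairs separated by one grid spacing along the moment direction and
deposited onto the surrounding nodes with trilinear weights.

All lengths are mm, conductivities S/m, potentials in the model units of
the source moments; ratios (attenuation in dB) are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .dipole_band import DipoleBandParams, band_axial_position
from .exceptions import (
    DomainError,
    FieldQueryError,
    PlacementError,
    SingularityError,
    SolverError,
)

__all__ = [
    "TissueLayer",
    "AbdomenModel",
    "UniformBox",
    "PointDipole",
    "NoiseConfig",
    "PotentialField",
    "PlaneField",
    "ForwardSolver",
    "LeadField",
    "tangent_plane_points",
    "default_layers",
    "discretize_band",
    "band_dipoles_at",
    "uterine_band_ring",
    "dipole_potential_homogeneous",
    "solve_forward",
    "place_noise_dipoles",
]


@dataclass(frozen=True)
class TissueLayer:
    """One concentric tissue shell of the abdomen model.

    Thicknesses are taken from the model's anatomy table; the relative
    permittivity is carried along for completeness but does not enter the
    quasi-static solve.  Conductivities are standard low-frequency tissue
    values (the anatomy table specifies none), configurable per layer.
    """

    name: str
    thickness: float
    conductivity: float
    relative_permittivity: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise DomainError(f"layer {self.name}: thickness must be >= 0")
        if not self.conductivity > 0:
            raise DomainError(f"layer {self.name}: conductivity must be > 0")


def default_layers() -> tuple[TissueLayer, TissueLayer, TissueLayer]:
    """Default skin/fat/muscle shells (ordered outermost first)."""
    return (
        TissueLayer("skin", 2.0, 2e-4, 40.01),
        TissueLayer("fat", 15.0, 0.04, 12.79),
        TissueLayer("muscle", 8.0, 0.35, 66.21),
    )


@dataclass(frozen=True)
class AbdomenModel:
    """Three-layer abdominal dome in a grounded air box.

    The measurement surface is the hemispherical belly dome along +y
    (radius ``hemisphere_radius``) carrying the skin/fat/muscle shells; the
    -y half continues the same concentric tissue, standing in for the
    maternal trunk behind the belly so that the uterus (whose wall carries
    the dipole band) is fully surrounded by conductor, as it is in a
    pregnant abdomen.  Everything outside is air with a small
    regularization conductivity, so the skin surface behaves as (nearly)
    insulated while one uniform discrete operator covers the whole box;
    the grounded box boundary emulates the unbounded surroundings.
    """

    hemisphere_radius: float = 100.0
    layers: tuple[TissueLayer, ...] = field(default_factory=default_layers)
    grid_spacing: float = 4.0
    bounding_box_half_width: float = 120.0
    air_conductivity: float = 1e-8
    interior_conductivity: float | None = None

    def __post_init__(self) -> None:
        if not self.grid_spacing > 0:
            raise DomainError("grid_spacing must be positive")
        total = sum(layer.thickness for layer in self.layers)
        if not total < self.hemisphere_radius:
            raise DomainError(
                f"layer thicknesses ({total} mm) must sum to less than the "
                f"hemisphere radius ({self.hemisphere_radius} mm)"
            )
        if not self.bounding_box_half_width > self.hemisphere_radius:
            raise DomainError("bounding box must strictly contain the hemisphere")

    @property
    def inner_radius(self) -> float:
        """Radius of the innermost (uterine) region, mm."""
        return self.hemisphere_radius - sum(layer.thickness for layer in self.layers)

    @property
    def _interior_sigma(self) -> float:
        if self.interior_conductivity is not None:
            return self.interior_conductivity
        return self.layers[-1].conductivity  # uterine wall is muscle

    def surface_point(self) -> np.ndarray:
        """Electrode mounting point: dome surface on the +y axis."""
        return np.array([0.0, self.hemisphere_radius, 0.0])

    def conductivity_at(self, points: np.ndarray) -> np.ndarray:
        """Conductivity at each point, shape (..., 3) -> (...)."""
        points = np.asarray(points, dtype=float)
        r = np.linalg.norm(points, axis=-1)
        sigma = np.full(r.shape, self.air_conductivity)
        inside = r <= self.hemisphere_radius
        bound = self.hemisphere_radius
        assigned = ~inside  # air already assigned
        for layer in self.layers:
            lower = bound - layer.thickness
            here = inside & ~assigned & (r > lower)
            sigma[here] = layer.conductivity
            assigned |= here
            bound = lower
        sigma[inside & ~assigned] = self._interior_sigma
        return sigma


@dataclass(frozen=True)
class UniformBox:
    """Homogeneous conductor filling the whole bounding box.

    Used to validate the discrete operator against the closed-form
    point-dipole potential of an unbounded medium.
    """

    conductivity: float = 0.35
    grid_spacing: float = 2.0
    bounding_box_half_width: float = 60.0

    def __post_init__(self) -> None:
        if not self.conductivity > 0:
            raise DomainError("conductivity must be positive")
        if not self.grid_spacing > 0:
            raise DomainError("grid_spacing must be positive")

    def conductivity_at(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return np.full(points.shape[:-1], self.conductivity)


@dataclass(frozen=True)
class PointDipole:
    """A point current dipole: position (mm) and moment vector (model units)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        position = np.asarray(self.position, dtype=float).reshape(3)
        moment = np.asarray(self.moment, dtype=float).reshape(3)
        if not (np.all(np.isfinite(position)) and np.all(np.isfinite(moment))):
            raise DomainError("dipole position and moment must be finite")
        object.__setattr__(self, "position", position)
        object.__setattr__(self, "moment", moment)


@dataclass(frozen=True)
class NoiseConfig:
    """Interfering sources: dipoles at random spots in the +x muscle shell."""

    n_dipoles: int = 6
    seed: int = 0
    moment_scale: float = 0.1  # fraction of the band moment p0

    def __post_init__(self) -> None:
        if self.n_dipoles < 0:
            raise DomainError("n_dipoles must be >= 0")
        if self.moment_scale < 0:
            raise DomainError("moment_scale must be >= 0")


# ---------------------------------------------------------------------------
# Band discretization
# ---------------------------------------------------------------------------

def band_dipoles_at(
    params: DipoleBandParams,
    z_band: float,
    n_segments: int = 72,
    center=(0.0, 0.0, 0.0),
) -> list[PointDipole]:
    """Point-dipole discretization of the band at signed axial position ``z_band``.

    The band circle has radius ``|z_band|*tan(theta)`` and lies in the plane
    ``z = center_z + z_band``; each of the ``n_segments`` dipoles carries
    moment ``p0/n_segments`` directed along the local wall meridian, so the
    segment moment magnitudes sum exactly to ``p0``.  A band at the cone
    apex degenerates to a single axial dipole of moment ``p0``.
    """
    if n_segments < 1:
        raise DomainError("n_segments must be >= 1")
    center = np.asarray(center, dtype=float).reshape(3)
    theta = params.theta
    rho = abs(z_band) * np.tan(theta)
    axial = center + np.array([0.0, 0.0, z_band])
    if rho < 1e-12:
        return [PointDipole(axial, np.array([0.0, 0.0, params.p0]))]
    s = 1.0 if z_band >= 0 else -1.0
    phis = 2.0 * np.pi * np.arange(n_segments) / n_segments
    positions = axial[None, :] + rho * np.stack(
        [np.cos(phis), np.sin(phis), np.zeros_like(phis)], axis=1
    )
    # wall meridian direction: radially outward + axially along the cone
    directions = np.stack(
        [
            s * np.sin(theta) * np.cos(phis),
            s * np.sin(theta) * np.sin(phis),
            np.full_like(phis, np.cos(theta)),
        ],
        axis=1,
    )
    moment = params.p0 / n_segments
    return [PointDipole(p, moment * d) for p, d in zip(positions, directions)]


def discretize_band(
    params: DipoleBandParams,
    t: float,
    n_segments: int = 72,
    center=(0.0, 0.0, 0.0),
) -> list[PointDipole]:
    """Discretize the band at round-trip time ``t`` (s) into point dipoles."""
    return band_dipoles_at(params, float(band_axial_position(params, t)), n_segments, center)


def uterine_band_ring(
    p0: float,
    ring_radius: float,
    z_band: float = 0.0,
    n_segments: int = 72,
    center=(0.0, 0.0, 0.0),
    orientation: str = "radial",
    theta: float = 0.0,
) -> list[PointDipole]:
    """The band as a rigid ring on the uterine wall inside the abdomen.

    The full-term uterus does not fit the abdominal dome, so for the
    forward experiments the band is the annulus where the uterine wall
    passes closest to the abdominal surface: a circle of fixed
    ``ring_radius`` coaxial with the z (fundus-cervix) axis, displaced
    rigidly as the activity travels.  ``orientation`` sets the dipole
    direction: "radial" (normal to the locally cylindrical wall, the
    component the surface electrodes sense; default), "meridian" (along the
    propagation direction on a cone of half-angle ``theta``) or "axial".
    Total moment magnitude is ``p0``.
    """
    if n_segments < 1:
        raise DomainError("n_segments must be >= 1")
    if ring_radius <= 0:
        raise DomainError("ring_radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    phis = 2.0 * np.pi * np.arange(n_segments) / n_segments
    cos_p, sin_p = np.cos(phis), np.sin(phis)
    positions = (
        center[None, :]
        + np.array([0.0, 0.0, z_band])[None, :]
        + ring_radius * np.stack([cos_p, sin_p, np.zeros_like(phis)], axis=1)
    )
    if orientation == "radial":
        directions = np.stack([cos_p, sin_p, np.zeros_like(phis)], axis=1)
    elif orientation == "meridian":
        directions = np.stack(
            [np.sin(theta) * cos_p, np.sin(theta) * sin_p,
             np.full_like(phis, np.cos(theta))],
            axis=1,
        )
    elif orientation == "axial":
        directions = np.stack(
            [np.zeros_like(phis), np.zeros_like(phis), np.ones_like(phis)], axis=1
        )
    else:
        raise DomainError("orientation must be 'radial', 'meridian' or 'axial'")
    moment = p0 / n_segments
    return [PointDipole(p, moment * d) for p, d in zip(positions, directions)]


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def dipole_potential_homogeneous(d: PointDipole, x, sigma: float):
    """Potential of a point dipole in an unbounded homogeneous medium.

    ``m . r_hat / (4 pi sigma |r|^2)`` with ``r = x - position``; the
    closed-form oracle against which the finite-difference solver is
    validated.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    r = pts - d.position[None, :]
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn == 0.0):
        raise SingularityError("observation point coincides with the dipole position")
    out = (r @ d.moment) / (4.0 * np.pi * sigma * rn**3)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Potential field container
# ---------------------------------------------------------------------------

class PlaneField:
    """Field restricted to an electrode tangent plane.

    Local plane coordinates ``(u, v)`` map to 3-D points
    ``center + u*e1 + v*e2``; if ``projection_radius`` is set the point is
    then projected radially onto the sphere of that radius before querying
    the underlying field, so ring and stencil samples follow the curved
    abdominal surface.
    """

    def __init__(self, field, center, e1, e2, projection_radius=None):
        self.field = field
        self.center = np.asarray(center, dtype=float).reshape(3)
        self.e1 = np.asarray(e1, dtype=float).reshape(3)
        self.e2 = np.asarray(e2, dtype=float).reshape(3)
        self.projection_radius = projection_radius

    def __call__(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        pts = (
            self.center[None, :]
            + np.ravel(u)[:, None] * self.e1[None, :]
            + np.ravel(v)[:, None] * self.e2[None, :]
        )
        if self.projection_radius is not None:
            norms = np.linalg.norm(pts, axis=1, keepdims=True)
            pts = pts * (self.projection_radius / norms)
        vals = self.field.point(pts)
        out = np.reshape(vals, np.broadcast(u, v).shape)
        return float(out) if out.ndim == 0 else out


def tangent_plane_points(center, u, v, projection_radius=None) -> np.ndarray:
    """Map local tangent-plane offsets at a surface point to 3-D points.

    ``center`` is a point on the measurement surface; offsets ``(u, v)``
    span its tangent plane.  With ``projection_radius`` set, points are
    projected radially onto that sphere, following the curved surface.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    e1, e2 = _orthonormal_tangent_basis(center)
    u = np.ravel(np.asarray(u, dtype=float))
    v = np.ravel(np.asarray(v, dtype=float))
    pts = center[None, :] + u[:, None] * e1[None, :] + v[:, None] * e2[None, :]
    if projection_radius is not None:
        pts = pts * (projection_radius / np.linalg.norm(pts, axis=1))[:, None]
    return pts


def _orthonormal_tangent_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 0.0, 1.0])
    e1 = seed - (seed @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


class PotentialField:
    """Scalar potential solved on a regular grid, queryable by interpolation.

    The contract between the forward solver and the electrode estimators:
    smooth interpolation inside the solved box, a hard error outside (never
    extrapolation), and linearity in the source set (fields from separate
    solves on the same grid may be added).

    The default interpolant is an order-3 B-spline (C-squared continuous):
    the ring estimators read second differences of the field, which
    trilinear interpolation corrupts with grid-scale kinks, so the smooth
    spline is essential for usable Laplacian readings.  ``method="linear"``
    restores plain trilinear interpolation.  Values are normalized by the
    field's magnitude internally; queries return the original scale.

    ``analytic_sources`` — pairs of (dipole, local conductivity) — carry a
    singular part that is evaluated in closed form at every query, on top
    of the interpolated grid values (which then hold only the smooth
    correction); see ``ForwardSolver.solve``.
    """

    def __init__(self, coords, phi, surface_radius=None, method: str = "cubic",
                 analytic_sources=None):
        self.coords = tuple(np.asarray(c, dtype=float) for c in coords)
        self.phi = np.asarray(phi, dtype=float)
        self.surface_radius = surface_radius
        self.analytic_sources = list(analytic_sources or [])
        if method not in ("cubic", "linear"):
            raise DomainError("interpolation method must be 'cubic' or 'linear'")
        self.method = method
        self._order = 3 if method == "cubic" else 1
        self._origin = np.array([c[0] for c in self.coords])
        steps = [np.diff(c) for c in self.coords]
        if any(not np.allclose(s, s[0]) for s in steps):
            raise DomainError("PotentialField requires a uniformly spaced grid")
        self._step = np.array([s[0] for s in steps])
        self._hi = np.array([c[-1] for c in self.coords])
        self._scale = float(np.max(np.abs(self.phi))) or 1.0
        data = self.phi / self._scale
        self._coeff = (
            ndimage.spline_filter(data, order=3) if method == "cubic" else data
        )

    def point(self, p):
        """Potential at 3-D point(s) ``p`` (shape (3,) or (N, 3))."""
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        pts = np.atleast_2d(p)
        if np.any(pts < self._origin) or np.any(pts > self._hi):
            raise FieldQueryError(
                "query outside the solved domain; the field never extrapolates"
            )
        idx = ((pts - self._origin) / self._step).T
        vals = self._scale * ndimage.map_coordinates(
            self._coeff, idx, order=self._order, prefilter=False
        )
        for d, sigma in self.analytic_sources:
            vals = vals + dipole_potential_homogeneous(d, pts, sigma)
        return float(vals[0]) if single else vals

    def plane_at(self, center, project_to_surface: bool = True) -> PlaneField:
        """Tangent-plane view of the field around a surface point."""
        center = np.asarray(center, dtype=float).reshape(3)
        e1, e2 = _orthonormal_tangent_basis(center)
        radius = None
        if project_to_surface:
            radius = self.surface_radius
            if radius is None:
                radius = float(np.linalg.norm(center))
        return PlaneField(self, center, e1, e2, projection_radius=radius)

    def _check_same_grid(self, other: "PotentialField") -> None:
        if len(self.coords) != len(other.coords) or any(
            a.shape != b.shape or not np.array_equal(a, b)
            for a, b in zip(self.coords, other.coords)
        ):
            raise DomainError("fields live on different grids and cannot be combined")

    def __add__(self, other: "PotentialField") -> "PotentialField":
        self._check_same_grid(other)
        return PotentialField(
            self.coords, self.phi + other.phi, self.surface_radius, self.method,
            self.analytic_sources + other.analytic_sources,
        )

    def __sub__(self, other: "PotentialField") -> "PotentialField":
        self._check_same_grid(other)
        flipped = [
            (PointDipole(d.position, -d.moment), s)
            for d, s in other.analytic_sources
        ]
        return PotentialField(
            self.coords, self.phi - other.phi, self.surface_radius, self.method,
            self.analytic_sources + flipped,
        )

    def __mul__(self, scalar: float) -> "PotentialField":
        scaled = [
            (PointDipole(d.position, float(scalar) * d.moment), s)
            for d, s in self.analytic_sources
        ]
        return PotentialField(
            self.coords, self.phi * float(scalar), self.surface_radius, self.method,
            scaled,
        )

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# Finite-difference solver
# ---------------------------------------------------------------------------

class ForwardSolver:
    """7-point finite-difference solver with a reusable factorization.

    The system matrix depends only on the geometry, so one instance solves
    any number of source configurations cheaply (each solve is a single
    triangular backsubstitution).  Grounded (Dirichlet 0) box boundary.

    Parameters
    ----------
    model:
        :class:`AbdomenModel` or :class:`UniformBox` (anything exposing
        ``grid_spacing``, ``bounding_box_half_width``, ``conductivity_at``).
    face_subsamples:
        Number of conductivity samples per inter-node segment used for the
        harmonic face average; > 1 captures layers thinner than the grid.
    direct_limit:
        Unknown count up to which a sparse LU factorization is used;
        larger systems fall back to diagonally preconditioned CG.
    cg_tol:
        Relative tolerance of the iterative fallback.
    """

    def __init__(self, model, face_subsamples: int = 4, direct_limit: int = 150_000,
                 cg_tol: float = 1e-8):
        self.model = model
        self.h = float(model.grid_spacing)
        half = float(model.bounding_box_half_width)
        n = int(round(2.0 * half / self.h)) + 1
        if n < 5:
            raise DomainError("grid too coarse: fewer than 5 nodes per axis")
        self.axis = -half + self.h * np.arange(n)
        self.n = n
        self.cg_tol = cg_tol
        self._build_grid()
        self._assemble(face_subsamples)
        self._factorize(direct_limit)

    # -- setup ------------------------------------------------------------
    def _build_grid(self) -> None:
        n = self.n
        X, Y, Z = np.meshgrid(self.axis, self.axis, self.axis, indexing="ij")
        self.nodes = np.stack([X, Y, Z], axis=-1)
        interior = np.zeros((n, n, n), dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        self.interior = interior.ravel()
        self.unknown_index = np.full(n**3, -1, dtype=np.int64)
        self.unknown_index[self.interior] = np.arange(self.interior.sum())
        self.n_unknowns = int(self.interior.sum())
        self.node_sigma = self.model.conductivity_at(self.nodes).ravel()

    def _face_sigma(self, axis_dim: int, k_sub: int) -> np.ndarray:
        """Homogenized conductivity of the faces along one axis.

        Series (harmonic) average of ``k_sub`` samples along each inter-node
        segment — the conservative-flux choice across layer interfaces,
        which also represents layers thinner than the grid by their correct
        series resistance — combined with a parallel (arithmetic) average
        over four transverse offsets spanning the face.  The transverse
        averaging makes the effective conductance vary smoothly along the
        voxelized curved interfaces instead of jumping cell by cell, which
        is what lets surface-potential differences converge under grid
        refinement.
        """
        n = self.n
        shape = [n, n, n]
        shape[axis_dim] = n - 1
        base = self.nodes.take(indices=range(n - 1), axis=axis_dim)
        offsets = (np.arange(k_sub) + 0.5) / k_sub * self.h
        step = np.zeros(3)
        step[axis_dim] = 1.0
        t1, t2 = np.zeros(3), np.zeros(3)
        dims = [d for d in range(3) if d != axis_dim]
        t1[dims[0]] = 1.0
        t2[dims[1]] = 1.0
        total = np.zeros(tuple(shape))
        jitter = ((-0.25, -0.25), (-0.25, 0.25), (0.25, -0.25), (0.25, 0.25))
        for a, b in jitter:
            inv = np.zeros(tuple(shape))
            shift = a * self.h * t1 + b * self.h * t2
            for off in offsets:
                inv += 1.0 / self.model.conductivity_at(base + off * step + shift)
            total += k_sub / inv
        return total / len(jitter)

    def _assemble(self, face_subsamples: int) -> None:
        n, h = self.n, self.h
        idx = np.arange(n**3).reshape(n, n, n)
        rows, cols, data = [], [], []
        diag = np.zeros(n**3)
        for dim in range(3):
            sig = self._face_sigma(dim, face_subsamples)
            w = (sig * h).ravel()  # conductance of each face, S*mm
            left = np.delete(idx, n - 1, axis=dim).ravel()
            right = np.delete(idx, 0, axis=dim).ravel()
            np.add.at(diag, left, w)
            np.add.at(diag, right, w)
            both = self.interior[left] & self.interior[right]
            li = self.unknown_index[left[both]]
            ri = self.unknown_index[right[both]]
            wv = w[both]
            rows.extend([li, ri])
            cols.extend([ri, li])
            data.extend([-wv, -wv])
        ui = self.unknown_index[self.interior]
        rows.append(ui)
        cols.append(ui)
        data.append(diag[self.interior])
        A = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_unknowns, self.n_unknowns),
        ).tocsc()
        self.A = A

    def _factorize(self, direct_limit: int) -> None:
        if self.n_unknowns <= direct_limit:
            try:
                # symmetric-mode minimum-degree ordering: far less fill-in
                # than the default on this SPD 7-point operator
                self._lu = spla.splu(
                    self.A,
                    permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True),
                )
            except RuntimeError as exc:  # singular factorization
                raise SolverError(
                    f"sparse factorization failed on a {self.n}^3 grid "
                    f"({self.n_unknowns} unknowns): {exc}"
                ) from exc
            self._solve_vec = self._lu.solve
        else:
            d = self.A.diagonal()
            M = sp.diags(1.0 / d)

            def _cg_solve(b, _A=self.A, _M=M):
                x, info = spla.cg(_A, b, rtol=self.cg_tol, maxiter=20_000, M=_M)
                if info != 0:
                    raise SolverError(
                        f"CG did not converge (info={info}) on a {self.n}^3 grid"
                    )
                return x

            self._solve_vec = _cg_solve

    # -- sources ----------------------------------------------------------
    def _cic_indices(self, pos: np.ndarray):
        """Trilinear (cloud-in-cell) node indices and weights for one point."""
        n = self.n
        f = (pos - self.axis[0]) / self.h
        base = np.floor(f).astype(int)
        if np.any(base < 0) or np.any(base >= n - 1):
            raise PlacementError(f"point {pos} deposits outside the grid")
        frac = f - base
        flats, wgts = [], []
        for corner in range(8):
            ox, oy, oz = corner & 1, (corner >> 1) & 1, (corner >> 2) & 1
            wgt = (
                (frac[0] if ox else 1 - frac[0])
                * (frac[1] if oy else 1 - frac[1])
                * (frac[2] if oz else 1 - frac[2])
            )
            flats.append((base[0] + ox) * n * n + (base[1] + oy) * n + (base[2] + oz))
            wgts.append(wgt)
        return np.array(flats), np.array(wgts)

    def _deposit_samples(self, points: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """CIC-deposit arbitrary weighted samples onto the node vector."""
        b = np.zeros(self.n**3)
        for pos, w in zip(np.atleast_2d(points), np.ravel(weights)):
            flats, wgts = self._cic_indices(np.asarray(pos, dtype=float))
            b[flats] += w * wgts
        return b

    def lead_field(self, points: np.ndarray, weights: np.ndarray) -> "LeadField":
        """Reciprocal reader for the sampling functional ``sum w*phi(points)``.

        Solves one adjoint problem with the functional as source; because
        the discrete operator is symmetric, ``m . grad(psi)`` at a dipole's
        location then equals the functional applied to that dipole's field.
        Readings of interior sources evaluate the lead field where it is
        smooth and well-resolved, far from the voxelized tissue surface, so
        they are much less sensitive to surface discretization error than
        direct field queries — and each additional source configuration
        costs no extra solve.
        """
        L = self._deposit_samples(points, weights)
        psi = np.zeros(self.n**3)
        psi[self.interior] = self._solve_vec(L[self.interior])
        return LeadField(self.axis, psi.reshape(self.n, self.n, self.n), self.h)

    def _deposit(self, sources) -> np.ndarray:
        """Trilinear (cloud-in-cell) deposition of +/- monopole pairs."""
        h = self.h
        b = np.zeros(self.n**3)
        air = 10.0 * _air_sigma(self.model)
        for d in sources:
            m = np.linalg.norm(d.moment)
            if m == 0.0:
                continue
            mhat = d.moment / m
            for sgn in (+1.0, -1.0):
                flats, wgts = self._cic_indices(d.position + sgn * 0.5 * h * mhat)
                touched = flats[wgts > 0.0]
                if np.any(self.node_sigma[touched] <= air):
                    raise PlacementError(
                        f"source at {d.position} deposits current into the "
                        "near-insulating air region; place sources inside tissue"
                    )
                b[flats] += sgn * (m / h) * wgts
        return b

    #: radius (in cells) of the near-source zone whose operator residual
    #: is dropped in the singularity-subtracted solve
    subtract_zone_cells: float = 8.0

    def solve(self, sources, subtract_singularity: bool = True) -> PotentialField:
        """Solve for the potential field of the given point-dipole sources.

        With ``subtract_singularity`` (default) the solution is represented
        as ``phi = phi_free + w``: the analytic unbounded-medium dipole
        potential of every source (with its local conductivity) is
        evaluated in closed form at query time, and the grid holds only a
        smooth correction ``w`` driven by the operator residual of the
        analytic part — the real sources of the correction (boundaries and
        conductivity contrasts) plus discretization noise.  Within
        ``subtract_zone_cells`` of a source, residuals at nodes whose
        conductivity matches the source's local value are pure
        source-representation error and are dropped; residuals at
        conductivity contrasts are always kept.  This removes the dominant
        near-source error of the discrete +/- monopole pair (the raw
        discrete solution is ~8% off five cells from a dipole; the
        subtracted one is within ~2%).

        With ``subtract_singularity=False`` the raw discrete system is
        solved; that path is exactly linear in the sources, while the
        subtracted path is linear only up to the (source-dependent)
        residual masking.
        """
        b = self._deposit(sources)  # also validates source placement
        phi = np.zeros(self.n**3)
        b_int = b[self.interior]
        active = [d for d in sources if np.linalg.norm(d.moment) > 0.0]
        surface_radius = getattr(self.model, "hemisphere_radius", None)
        if subtract_singularity and active:
            nodes_int = self.nodes.reshape(-1, 3)[self.interior]
            sigma_grid = self.node_sigma.reshape(self.n, self.n, self.n)
            # nodes strictly inside a uniform-conductivity neighbourhood:
            # residuals at (or next to) a contrast are genuine physics and
            # must never be masked
            uniform = np.zeros((self.n, self.n, self.n), dtype=bool)
            core = np.ones((self.n - 2, self.n - 2, self.n - 2), dtype=bool)
            for dim in range(3):
                for shift in (-1, 1):
                    core &= np.isclose(
                        sigma_grid[1:-1, 1:-1, 1:-1],
                        np.roll(sigma_grid, shift, axis=dim)[1:-1, 1:-1, 1:-1],
                        rtol=1e-9,
                    )
            uniform[1:-1, 1:-1, 1:-1] = core
            uniform_int = uniform.reshape(-1)[self.interior]
            sigma_int = self.node_sigma[self.interior]
            analytic = []
            phi_free = np.zeros(self.n_unknowns)
            masked = np.zeros(self.n_unknowns, dtype=bool)
            zone = self.subtract_zone_cells * self.h
            for d in active:
                sigma_local = float(
                    np.atleast_1d(self.model.conductivity_at(d.position[None, :]))[0]
                )
                rvec = nodes_int - d.position[None, :]
                rn = np.linalg.norm(rvec, axis=1)
                # a source sitting exactly on a node would make phi_free
                # singular there; the capped value is harmless because that
                # node's residual lies inside the masked zone
                rn_safe = np.maximum(rn, 0.25 * self.h)
                phi_free += (rvec @ d.moment) / (
                    4.0 * np.pi * sigma_local * rn_safe**3
                )
                near = rn <= zone
                same_sigma = np.isclose(sigma_int, sigma_local, rtol=1e-9)
                masked |= near & same_sigma & uniform_int
                analytic.append((d, sigma_local))
            resid = -(self.A @ phi_free)
            if np.any(masked):
                # dropping residual must not change the net injected
                # current: in the nearly air-isolated tissue even a tiny
                # imbalance shows up as a large floating-potential offset,
                # so the masked zone's net sum is returned to the node
                # nearest the first source
                balance = resid[masked].sum()
                resid[masked] = 0.0
                anchor = int(
                    np.argmin(
                        np.linalg.norm(nodes_int - active[0].position[None, :], axis=1)
                    )
                )
                resid[anchor] += balance
            phi[self.interior] = self._solve_vec(resid)
            return PotentialField(
                (self.axis, self.axis, self.axis),
                phi.reshape(self.n, self.n, self.n),
                surface_radius=surface_radius,
                analytic_sources=analytic,
            )
        if np.any(b_int != 0.0):
            phi[self.interior] = self._solve_vec(b_int)
        return PotentialField(
            (self.axis, self.axis, self.axis),
            phi.reshape(self.n, self.n, self.n),
            surface_radius=surface_radius,
        )


class LeadField:
    """Adjoint (reciprocal) potential of an electrode's sampling functional.

    ``read(dipoles)`` returns the electrode reading of those dipoles as
    ``sum_i m_i . grad(psi)(x_i)``, with the gradient formed by centred
    node differences and interpolated trilinearly — a purely local
    evaluation with no global spline prefilter, so small far-field values
    are not contaminated by ringing from the large values near the
    electrode.
    """

    def __init__(self, axis: np.ndarray, psi: np.ndarray, h: float):
        self.axis = axis
        self.psi = psi
        self.h = h
        grads = np.gradient(psi, h, edge_order=2)
        self._origin = axis[0]
        self._grads = grads

    def _interp_grad(self, pts: np.ndarray) -> np.ndarray:
        idx = ((pts - self._origin) / self.h).T
        out = np.empty((len(pts), 3))
        for k in range(3):
            out[:, k] = ndimage.map_coordinates(
                self._grads[k], idx, order=1, mode="nearest"
            )
        return out

    def read(self, sources) -> float:
        """Electrode reading of the given point dipoles."""
        if not sources:
            return 0.0
        P = np.array([d.position for d in sources])
        M = np.array([d.moment for d in sources])
        return float(np.sum(self._interp_grad(P) * M))


def _air_sigma(model) -> float:
    return getattr(model, "air_conductivity", 0.0)


def solve_forward(model, sources) -> PotentialField:
    """One-shot forward solve (builds a solver, factorizes, solves).

    Experiment drivers that solve many source configurations on the same
    geometry should construct a :class:`ForwardSolver` once and call its
    ``solve`` repeatedly instead.
    """
    return ForwardSolver(model).solve(sources)


# ---------------------------------------------------------------------------
# Noise sources
# ---------------------------------------------------------------------------

def place_noise_dipoles(
    cfg: NoiseConfig,
    model: AbdomenModel,
    p0: float,
    seed: int | None = None,
) -> list[PointDipole]:
    """Random interfering dipoles in the +x half of the muscle shell.

    Positions are uniform over the shell volume restricted to x > 0;
    moments have magnitude ``moment_scale * p0`` and uniformly random
    orientation.  Reproducible for a fixed seed.  If the muscle layer is
    degenerate (thinner than 1 mm, as in a thickness sweep down to zero),
    the dipoles are placed in a 2 mm shell just inside the innermost
    boundary — the same tissue depth the muscle would occupy.
    """
    if cfg.n_dipoles == 0:
        return []
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    muscle = model.layers[-1]
    r_in = model.inner_radius
    r_out = r_in + muscle.thickness
    if muscle.thickness < 1.0:
        r_in, r_out = max(r_in - 2.0, 0.0), r_in
    dipoles: list[PointDipole] = []
    while len(dipoles) < cfg.n_dipoles:
        p = rng.uniform([-r_out, -r_out, -r_out], [r_out, r_out, r_out])
        r = np.linalg.norm(p)
        if not (r_in <= r <= r_out and p[0] > 0.0):
            continue
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dipoles.append(PointDipole(p, cfg.moment_scale * p0 * direction))
    return dipoles
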