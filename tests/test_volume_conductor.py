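"""Tests for the finite-difference volume conductor and its source models."""

import numpy as np
import pytest

from ehgsim import (
    AbdomenModel,
    DipoleBandParams,
    DomainError,
    FieldQueryError,
    ForwardSolver,
    NoiseConfig,
    PlacementError,
    PointDipole,
    SingularityError,
    TissueLayer,
    UniformBox,
    band_dipoles_at,
    dipole_potential_homogeneous,
    discretize_band,
    place_noise_dipoles,
    uterine_band_ring,
)


@pytest.fixture(scope="module")
def small_uniform_solver():
    """Tiny homogeneous box with a direct (LU) factorization."""
    return ForwardSolver(
        UniformBox(conductivity=0.35, grid_spacing=4.0, bounding_box_half_width=40.0)
    )


@pytest.fixture(scope="module")
def oracle_solver():
    """Homogeneous box large enough for free-space comparisons."""
    return ForwardSolver(
        UniformBox(conductivity=0.35, grid_spacing=2.0, bounding_box_half_width=80.0)
    )


class TestGeometryTypes:
    def test_layer_validation(self):
        with pytest.raises(DomainError):
            TissueLayer("skin", -1.0, 0.1, 40.0)
        with pytest.raises(DomainError):
            TissueLayer("skin", 2.0, 0.0, 40.0)

    def test_model_validation(self):
        with pytest.raises(DomainError):
            AbdomenModel(hemisphere_radius=20.0)  # layers exceed radius
        with pytest.raises(DomainError):
            AbdomenModel(bounding_box_half_width=90.0)  # box inside dome

    def test_inner_radius_and_conductivity_shells(self, abdomen_model):
        assert abdomen_model.inner_radius == pytest.approx(75.0)
        pts = np.array(
            [[0, 99.5, 0], [0, 90.0, 0], [0, 79.0, 0], [0, 40.0, 0], [0, 110.0, 0]]
        )
        sig = abdomen_model.conductivity_at(pts)
        assert sig == pytest.approx([2e-4, 0.04, 0.35, 0.35, 1e-8])


class TestDipoleOracle:
    def test_perpendicular_moment_gives_zero(self):
        d = PointDipole((0, 0, 0), (0, 0, 1.0))
        assert dipole_potential_homogeneous(d, (5.0, 0.0, 0.0), 0.35) == 0.0

    def test_antisymmetric_in_moment(self):
        d1 = PointDipole((0, 0, 0), (0.3, 0.2, 1.0))
        d2 = PointDipole((0, 0, 0), (-0.3, -0.2, -1.0))
        x = (3.0, -2.0, 5.0)
        assert dipole_potential_homogeneous(d1, x, 0.35) == pytest.approx(
            -dipole_potential_homogeneous(d2, x, 0.35)
        )

    def test_inverse_square_decay_on_axis(self):
        d = PointDipole((0, 0, 0), (0, 0, 1.0))
        v1 = dipole_potential_homogeneous(d, (0, 0, 10.0), 0.35)
        v2 = dipole_potential_homogeneous(d, (0, 0, 20.0), 0.35)
        assert v2 / v1 == pytest.approx(0.25)

    def test_coincident_point_raises(self):
        d = PointDipole((1, 2, 3), (0, 0, 1.0))
        with pytest.raises(SingularityError):
            dipole_potential_homogeneous(d, (1.0, 2.0, 3.0), 0.35)


class TestBandDiscretization:
    def test_segment_moments_sum_to_p0(self, band_params):
        for dipoles in (
            discretize_band(band_params, t=5.0, n_segments=72),
            uterine_band_ring(band_params.p0, 70.0, 10.0, n_segments=48),
        ):
            total = sum(np.linalg.norm(d.moment) for d in dipoles)
            assert total == pytest.approx(band_params.p0, rel=1e-12)

    def test_single_segment_carries_full_moment(self, band_params):
        (d,) = discretize_band(band_params, t=5.0, n_segments=1)
        assert np.linalg.norm(d.moment) == pytest.approx(band_params.p0)

    def test_apex_degenerates_to_axial_dipole(self, band_params):
        t_apex = band_params.Ros / band_params.c
        dipoles = discretize_band(band_params, t=t_apex, n_segments=72)
        assert len(dipoles) == 1
        np.testing.assert_allclose(
            dipoles[0].moment, [0.0, 0.0, band_params.p0], atol=1e-25
        )

    def test_ring_orientations(self, band_params):
        radial = uterine_band_ring(band_params.p0, 70.0, 0.0, 36, orientation="radial")
        for d in radial:
            assert d.moment[2] == 0.0
            rho = d.position - np.array([0, 0, 0.0])
            assert np.dot(d.moment, rho) > 0.0  # outward
        with pytest.raises(DomainError):
            uterine_band_ring(band_params.p0, 70.0, 0.0, 36, orientation="sideways")
        with pytest.raises(DomainError):
            uterine_band_ring(band_params.p0, -1.0, 0.0, 36)

    def test_refinement_converges_below_0p1_percent(self, band_params):
        """Doubling the segment count changes the (analytic, superposed)
        potential 100 mm away by < 0.1% once n_segments >= 72."""
        x = np.array([[0.0, 100.0, 0.0]])

        def potential(n):
            dipoles = band_dipoles_at(band_params, 300.0, n_segments=n)
            return sum(
                dipole_potential_homogeneous(d, x, 0.35)[0] for d in dipoles
            )

        v72, v144 = potential(72), potential(144)
        assert abs(v144 - v72) < 1e-3 * abs(v144)


class TestForwardSolver:
    def test_zero_sources_give_zero_field(self, small_uniform_solver):
        f = small_uniform_solver.solve([])
        assert np.all(f.phi == 0.0)
        f2 = small_uniform_solver.solve(
            [PointDipole((0, 0, 0), (0.0, 0.0, 0.0))]
        )
        assert np.all(f2.phi == 0.0)

    def test_raw_path_superposition_is_exact(self, small_uniform_solver):
        d1 = PointDipole((0.3, -0.2, 0.1), (0.4, -1.0, 0.7))
        d2 = PointDipole((-6.1, 4.2, 3.3), (1.0, 0.2, -0.5))
        s = small_uniform_solver
        f1 = s.solve([d1], subtract_singularity=False)
        f2 = s.solve([d2], subtract_singularity=False)
        f12 = s.solve([d1, d2], subtract_singularity=False)
        err = np.abs(f12.phi - (f1.phi + f2.phi)).max() / np.abs(f12.phi).max()
        assert err < 1e-10

    def test_subtracted_path_matches_free_space_oracle(self, oracle_solver):
        """A single dipole in a uniform box agrees with the closed-form
        unbounded-medium potential to 2% at 5-8 cell separations (away from
        the dipole's null plane, where relative error is undefined)."""
        d = PointDipole((0.3, -0.2, 0.1), (0.4, -1.0, 0.7))
        f = oracle_solver.solve([d])
        rng = np.random.default_rng(1)
        pts = []
        while len(pts) < 500:
            p = rng.uniform(-1, 1, 3)
            n = np.linalg.norm(p)
            if n < 0.3:
                continue
            pts.append(p / n * rng.uniform(10.0, 16.0))
        pts = np.array(pts)
        num = f.point(pts)
        ana = dipole_potential_homogeneous(d, pts, 0.35)
        mask = np.abs(ana) >= 0.1 * np.abs(ana).max()
        rel = np.abs(num - ana)[mask] / np.abs(ana)[mask]
        assert rel.max() < 0.02

    def test_source_outside_tissue_rejected(self, abdomen_solver):
        with pytest.raises(PlacementError):
            abdomen_solver.solve([PointDipole((0, 110.0, 0), (0, 0, 1.0))])

    def test_grid_refinement_error_decreases(self):
        d = PointDipole((0.3, -0.2, 0.1), (0.0, 0.0, 1.0))
        probe = np.array([[0.0, 0.0, 18.3]])
        errs = []
        for h in (8.0, 4.0, 2.0):
            s = ForwardSolver(
                UniformBox(conductivity=0.35, grid_spacing=h,
                           bounding_box_half_width=64.0)
            )
            f = s.solve([d], subtract_singularity=False)
            ana = dipole_potential_homogeneous(d, probe, 0.35)[0]
            errs.append(abs(f.point(probe)[0] - ana))
        assert errs[1] < errs[0] and errs[2] < errs[1]

    def test_discrete_maximum_principle(self, coarse_solver):
        """In a source-free subregion, |phi| of the raw discrete solution
        attains its maximum on the subregion's boundary."""
        f = coarse_solver.solve(
            [PointDipole((0, 60.0, 0), (0, 1e-13, 0))], subtract_singularity=False
        )
        phi = f.phi
        sub = phi[3:10, 3:10, 3:10]  # far corner, source-free
        interior_max = np.abs(sub[1:-1, 1:-1, 1:-1]).max()
        boundary = np.abs(sub).max()
        assert interior_max <= boundary + 1e-30

    def test_layer_partition_does_not_matter_when_conductivity_is_uniform(self):
        """Relabelling equal-conductivity layers leaves the operator, and
        hence the field, bit-identical."""
        def model(partition):
            layers = tuple(
                TissueLayer(name, th, 0.35, 40.0) for name, th in partition
            )
            return AbdomenModel(layers=layers, grid_spacing=8.0)

        m1 = model((("skin", 2.0), ("fat", 15.0), ("muscle", 8.0)))
        m2 = model((("skin", 10.0), ("fat", 5.0), ("muscle", 10.0)))
        d = [PointDipole((0.5, 20.3, 0.2), (0.2, 1.0, -0.3))]
        f1 = ForwardSolver(m1).solve(d)
        f2 = ForwardSolver(m2).solve(d)
        np.testing.assert_array_equal(f1.phi, f2.phi)

    def test_degenerate_layers_approach_homogeneous_oracle(self):
        """With all conductivities equal the interior field matches the
        unbounded-medium dipole formula; the small residual deviation is
        the genuine insulated-surface (air boundary) correction."""
        layers = tuple(
            TissueLayer(n_, t_, 0.35, e_)
            for n_, t_, e_ in
            (("skin", 2.0, 40.01), ("fat", 15.0, 12.79), ("muscle", 8.0, 66.21))
        )
        m = AbdomenModel(layers=layers, grid_spacing=4.0)
        sv = ForwardSolver(m)
        d = PointDipole((0.5, 15.3, 0.2), (0.2, 1.0, -0.3))
        f = sv.solve([d])
        rng = np.random.default_rng(3)
        pts = []
        while len(pts) < 300:
            p = rng.uniform(-1, 1, 3)
            n = np.linalg.norm(p)
            if n < 0.3:
                continue
            pts.append(d.position + p / n * rng.uniform(8.0, 14.0))
        pts = np.array(pts)
        num = f.point(pts)
        ana = dipole_potential_homogeneous(d, pts, 0.35)
        mask = np.abs(ana) >= 0.1 * np.abs(ana).max()
        rel = np.abs(num - ana)[mask] / np.abs(ana)[mask]
        assert np.percentile(rel, 95) < 0.02
        assert rel.max() < 0.035


class TestPotentialField:
    def test_query_outside_domain_raises(self, small_uniform_solver):
        f = small_uniform_solver.solve([PointDipole((0, 0, 0), (0, 0, 1.0))])
        with pytest.raises(FieldQueryError):
            f.point((0.0, 0.0, 45.0))

    def test_field_arithmetic(self, small_uniform_solver):
        s = small_uniform_solver
        d1 = PointDipole((0, 0, 0), (0, 0, 1.0))
        f = s.solve([d1])
        p = np.array([[3.0, 5.0, 11.0]])
        assert (2.0 * f).point(p)[0] == pytest.approx(2 * f.point(p)[0], rel=1e-12)
        assert (f + f).point(p)[0] == pytest.approx(2 * f.point(p)[0], rel=1e-12)
        assert abs((f - f).point(p)[0]) <= 1e-12 * abs(f.point(p)[0])

    def test_plane_projection_lands_on_sphere(self, abdomen_solver, band_params):
        src = uterine_band_ring(band_params.p0, 70.0, 0.0)
        f = abdomen_solver.solve(src)
        plane = f.plane_at((0.0, 100.0, 0.0))
        pts = plane.center + 10.0 * plane.e1
        projected = pts * (100.0 / np.linalg.norm(pts))
        assert plane(10.0, 0.0) == pytest.approx(float(f.point(projected)), rel=1e-12)


class TestNoiseDipoles:
    def test_positions_in_positive_x_muscle_shell(self, abdomen_model, band_params):
        cfg = NoiseConfig(n_dipoles=6, seed=3)
        dipoles = place_noise_dipoles(cfg, abdomen_model, band_params.p0)
        assert len(dipoles) == 6
        for d in dipoles:
            r = np.linalg.norm(d.position)
            assert d.position[0] > 0.0
            assert 75.0 <= r <= 83.0
            assert np.linalg.norm(d.moment) == pytest.approx(0.1 * band_params.p0)

    def test_same_seed_reproduces(self, abdomen_model, band_params):
        cfg = NoiseConfig(seed=11)
        a = place_noise_dipoles(cfg, abdomen_model, band_params.p0)
        b = place_noise_dipoles(cfg, abdomen_model, band_params.p0)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.position, db.position)
            np.testing.assert_array_equal(da.moment, db.moment)

    def test_zero_dipoles(self, abdomen_model, band_params):
        assert place_noise_dipoles(
            NoiseConfig(n_dipoles=0), abdomen_model, band_params.p0
        ) == []

    def test_degenerate_muscle_layer_falls_back_inward(self, band_params):
        layers = (
            TissueLayer("skin", 2.0, 2e-4, 40.01),
            TissueLayer("fat", 15.0, 0.04, 12.79),
            TissueLayer("muscle", 0.0, 0.35, 66.21),
        )
        m = AbdomenModel(layers=layers)
        dipoles = place_noise_dipoles(NoiseConfig(seed=0), m, band_params.p0)
        for d in dipoles:
            assert np.linalg.norm(d.position) <= m.inner_radius + 1e-9
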