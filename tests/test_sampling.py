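"""Grid scans, pseudo-particles, per-sphere densities and void statistics."""

import numpy as np
import pytest

from microhet import (
    Observation,
    ParticleConfiguration,
    PeriodicCell,
    RelativeDensityField,
    SamplingSpec,
    empty_fraction,
    generate_ideal_gas,
    generate_lattice,
    make_pseudo_particles,
    minimum_image_distance,
    overlap_factor,
    scan_field,
    sphere_density,
)
from microhet.sampling import grid_points


def single_site_config(position, cell_edge=100.0, radius=1.0, mass=2.5):
    return ParticleConfiguration(
        positions=np.array([position], dtype=float),
        radii=np.array([radius]),
        masses=np.array([mass]),
        cell=PeriodicCell.cubic(cell_edge),
        elements=["X"],
    )


class TestMakePseudoParticles:
    def test_single_atom_identity(self):
        config = single_site_config([1.0, 1.0, 1.0])
        pseudo = make_pseudo_particles(config, [[0]], radius=3.0)
        assert pseudo.positions[0] == pytest.approx([1.0, 1.0, 1.0])
        assert pseudo.radii[0] == 3.0
        assert pseudo.masses[0] == 2.5

    def test_center_unwraps_across_boundary(self):
        cell = PeriodicCell.cubic(10.0)
        config = ParticleConfiguration(
            positions=np.array([[0.4, 0, 0], [9.8, 0, 0]]),
            radii=np.ones(2),
            masses=np.ones(2),
            cell=cell,
        )
        pseudo = make_pseudo_particles(config, [[0, 1]], radius=1.0)
        # second atom's nearest image to the first sits at -0.2
        assert pseudo.positions[0] == pytest.approx([0.1, 0.0, 0.0], abs=1e-12)

    def test_pentagon_center(self):
        angles = 2 * np.pi * np.arange(5) / 5
        ring = np.stack([50 + 3 * np.cos(angles), 50 + 3 * np.sin(angles), np.full(5, 50.0)], axis=1)
        config = ParticleConfiguration(
            positions=ring, radii=np.ones(5), masses=np.ones(5), cell=PeriodicCell.cubic(100.0)
        )
        pseudo = make_pseudo_particles(config, [np.arange(5)], radius=3.0)
        assert pseudo.positions[0] == pytest.approx([50.0, 50.0, 50.0], abs=1e-9)
        assert pseudo.masses[0] == pytest.approx(5.0)

    def test_group_spanning_half_cell_rejected(self):
        cell = PeriodicCell.cubic(10.0)
        line = np.stack([np.linspace(0, 8.0, 5), np.zeros(5), np.zeros(5)], axis=1)
        config = ParticleConfiguration(
            positions=line, radii=np.ones(5), masses=np.ones(5), cell=cell
        )
        with pytest.raises(ValueError, match="half the cell"):
            make_pseudo_particles(config, [np.arange(5)], radius=1.0)

    def test_empty_group_rejected(self):
        config = single_site_config([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            make_pseudo_particles(config, [[]], radius=1.0)


class TestSphereDensity:
    def test_far_empty_region_is_zero(self):
        config = single_site_config([10.0, 10.0, 10.0], cell_edge=100.0, radius=1.0)
        assert sphere_density(config, [60.0, 60.0, 60.0], 5.0, Observation("all")) == 0.0

    def test_fully_contained_site_particle_mode(self):
        config = single_site_config([50.0, 50.0, 50.0], radius=1.0)
        r_s = 10.0
        rho = sphere_density(config, [50.0, 50.0, 50.0], r_s, Observation("all"))
        assert rho == pytest.approx(1.0 / (4 / 3 * np.pi * r_s**3))

    def test_probe_inside_large_site_gives_atom_internal_density(self):
        # f = (rS/rA)^3 divided by the probe volume equals 3/(4 pi rA^3)
        rA = 8.0
        config = single_site_config([50.0, 50.0, 50.0], radius=rA)
        rho = sphere_density(config, [50.0, 50.0, 50.0], 2.0, Observation("all"))
        assert rho == pytest.approx(3.0 / (4 * np.pi * rA**3))

    def test_mass_mode_scales_by_site_mass(self):
        config = single_site_config([50.0, 50.0, 50.0], radius=1.0, mass=2.5)
        r_s = 10.0
        particle = sphere_density(config, [50.0] * 3, r_s, Observation("all", mode="particle"))
        mass = sphere_density(config, [50.0] * 3, r_s, Observation("all", mode="mass"))
        assert mass == pytest.approx(2.5 * particle)


class TestScanField:
    def test_single_site_matches_direct_enumeration(self):
        """Grid scan equals a brute-force loop over grid points."""
        config = single_site_config([13.0, 40.0, 77.0], cell_edge=100.0, radius=2.0)
        r_s, grid = 9.0, (5, 4, 3)
        field = scan_field(config, grid, Observation("all"), r_s)
        pts = grid_points(config.cell, grid)
        v_s = 4 / 3 * np.pi * r_s**3
        ref = 1.0 / config.cell.volume
        expected = np.empty(len(pts))
        for i, c in enumerate(pts):
            d = minimum_image_distance(c, config.positions[0], config.cell)
            expected[i] = overlap_factor(d, 2.0, r_s) / v_s / ref
        np.testing.assert_allclose(field.values, expected, atol=1e-12)
        # nonzero only within reach of the site
        nz = field.values > 0
        dists = np.array(
            [minimum_image_distance(c, config.positions[0], config.cell) for c in pts]
        )
        assert np.all(dists[nz] < 2.0 + r_s)

    def test_lattice_large_probe_is_uniform(self):
        config = generate_lattice(10, PeriodicCell.cubic(600.0), radius=10.0)
        field = scan_field(config, 20, Observation("all"), 290.0)
        assert field.mu == pytest.approx(1.0, abs=5e-3)
        assert np.all(np.abs(field.values - 1.0) < 0.05)

    def test_mean_tightens_under_grid_refinement(self, ideal_gas_config):
        obs = Observation("all")
        err = []
        for grid in (16, 32, 64):
            field = scan_field(ideal_gas_config, grid, obs, 500.0)
            err.append(abs(field.mu - 1.0))
        assert err[2] < err[0]
        assert err[2] < 1e-2

    def test_confined_octant_has_voids_and_enrichment(self, rng):
        cell = PeriodicCell.cubic(1000.0)
        pos = rng.uniform(0, 500.0, size=(400, 3))
        config = ParticleConfiguration(pos, np.full(400, 10.0), np.ones(400), cell)
        field = scan_field(config, 16, Observation("all"), 60.0)
        assert np.any(field.values == 0.0)
        assert np.any(field.values > 1.0)
        assert field.mu == pytest.approx(1.0, abs=0.05)

    def test_translation_invariance_by_grid_multiples(self, ideal_gas_config):
        obs = Observation("all")
        grid = 16
        shift = ideal_gas_config.cell.edges / grid * np.array([3, 1, 7])
        shifted = ParticleConfiguration(
            ideal_gas_config.positions + shift,
            ideal_gas_config.radii,
            ideal_gas_config.masses,
            ideal_gas_config.cell,
        )
        f0 = scan_field(ideal_gas_config, grid, obs, 400.0)
        f1 = scan_field(shifted, grid, obs, 400.0)
        np.testing.assert_allclose(np.sort(f0.values), np.sort(f1.values), atol=1e-9)

    def test_particle_and_mass_mode_agree_for_equal_masses(self, ideal_gas_config):
        fp = scan_field(ideal_gas_config, 12, Observation("all", mode="particle"), 400.0)
        fm = scan_field(ideal_gas_config, 12, Observation("all", mode="mass"), 400.0)
        np.testing.assert_allclose(fp.values, fm.values, rtol=1e-12)

    def test_pooling_two_frames_equals_joint_scan(self, cubic_cell):
        f1 = generate_ideal_gas(64, cubic_cell, seed=1)
        f2 = generate_ideal_gas(64, cubic_cell, seed=2)
        obs = Observation("all")
        joint = scan_field([f1, f2], 8, obs, 400.0)
        merged = scan_field(f1, 8, obs, 400.0).merge(scan_field(f2, 8, obs, 400.0))
        np.testing.assert_allclose(joint.values, merged.values)
        assert joint.n == 2 * 8**3

    def test_image_safety_bound_enforced(self, ideal_gas_config):
        with pytest.raises(ValueError, match="image-safety"):
            scan_field(ideal_gas_config, 8, Observation("all"), 2600.0)


class TestEmptyFraction:
    def test_single_site_matches_geometric_volume(self):
        """P(empty) ~ 1 - reach-ball volume / cell volume for one site."""
        rA, r_s, L = 5.0, 20.0, 200.0
        config = single_site_config([37.0, 111.0, 64.0], cell_edge=L, radius=rA)
        field = scan_field(config, 48, Observation("all"), r_s)
        expected = 1.0 - (4 / 3 * np.pi * (rA + r_s) ** 3) / L**3
        assert empty_fraction(field) == pytest.approx(expected, abs=5e-3)

    def test_dense_liquid_large_probe_has_no_voids(self, ideal_gas_config):
        field = scan_field(ideal_gas_config, 12, Observation("all"), 1500.0)
        assert empty_fraction(field) == 0.0

    def test_field_with_nothing_reachable_is_all_void(self):
        field = RelativeDensityField(
            r_s=10.0,
            observation="nothing",
            values=np.zeros(64),
            empty=np.ones(64, dtype=bool),
            grid=(4, 4, 4),
            n_frames=1,
            reference_density=0.0,
        )
        assert empty_fraction(field) == 1.0


class TestObservationSelection:
    def test_element_and_index_selections(self):
        cell = PeriodicCell.cubic(100.0)
        config = ParticleConfiguration(
            positions=np.arange(15, dtype=float).reshape(5, 3),
            radii=np.ones(5),
            masses=np.ones(5),
            cell=cell,
            elements=["Ar", "Cl", "Ar", "C", "Cl"],
        )
        assert list(Observation("ar", "element Ar").indices(config)) == [0, 2]
        assert list(Observation("cl", "Cl").indices(config)) == [1, 4]
        assert list(Observation("idx", "index 0,2-4").indices(config)) == [0, 2, 3, 4]
        assert list(Observation("bare", "1,3").indices(config)) == [1, 3]
        assert list(Observation("expl", [4, 0]).indices(config)) == [4, 0]

    def test_empty_selection_rejected(self):
        config = single_site_config([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="selects no sites"):
            Observation("none", "element Kr").indices(config)

    def test_radius_override_applies(self):
        config = single_site_config([50.0, 50.0, 50.0], radius=1.0)
        obs = Observation("big", "all", radius=8.0)
        rho = sphere_density(config, [50.0] * 3, 2.0, obs)
        assert rho == pytest.approx(3.0 / (4 * np.pi * 8.0**3))


def test_sampling_spec_validation():
    with pytest.raises(ValueError):
        SamplingSpec(grid=(1, 4, 4), radii=(100.0,))
    with pytest.raises(ValueError):
        SamplingSpec(grid=(4, 4, 4), radii=(200.0, 100.0))
    spec = SamplingSpec(grid=8, radii=(100.0, 200.0))
    assert spec.grid == (8, 8, 8)
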