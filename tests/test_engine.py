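"""Simulation-engine tests: restraint energies, initial placement,
Langevin statistics, quenching, deformation, and multi-chain assembly."""

from dataclasses import replace

import numpy as np
import pytest

from rablchrom.engine import (
    NucleusGeometry,
    SimulationConfig,
    anchor_energy,
    build_full_nucleus,
    confinement_energy,
    confinement_forces,
    deform_nucleus,
    initialize_conformation,
    quench,
    run_langevin,
)
from rablchrom.michrom import GenomeSpec, MiChroMParameters
from rablchrom.synth import make_synthetic_genome


@pytest.fixture
def geometry():
    return NucleusGeometry(pole_separation=10.0, equatorial_radius=5.0)


def dimer_spec():
    return GenomeSpec(2, 100_000, np.zeros(2, dtype=int),
                      np.array(["A", "A"]), np.array([0]), np.array([1]))


class TestConfinement:
    def test_zero_inside_and_on_wall(self, geometry):
        assert confinement_energy(np.zeros((1, 3)), geometry) == 0.0
        on_wall = np.array([[0.0, 0.0, 5.0]])  # pole, s = 1
        assert confinement_energy(on_wall, geometry) == pytest.approx(0.0)

    def test_value_at_s_equals_two(self, geometry):
        # s = 2 along the pole axis: z = 5 * sqrt(2)
        x = np.array([[0.0, 0.0, 5.0 * np.sqrt(2.0)]])
        assert confinement_energy(x, geometry) == pytest.approx(
            0.5 * geometry.wall_stiffness
        )

    def test_force_matches_finite_difference(self, geometry):
        x = np.array([[1.0, 2.0, 5.5]])
        f = confinement_forces(x, geometry)
        h = 1e-6
        for k in range(3):
            xp, xm = x.copy(), x.copy()
            xp[0, k] += h
            xm[0, k] -= h
            fd = -(confinement_energy(xp, geometry)
                   - confinement_energy(xm, geometry)) / (2 * h)
            assert f[0, k] == pytest.approx(fd, abs=1e-5)


class TestAnchors:
    def test_zero_at_poles(self, geometry):
        spec = dimer_spec()
        x = np.vstack([geometry.telomere_pole, geometry.centromere_pole])
        assert anchor_energy(x, spec, geometry) == 0.0

    def test_harmonic_at_unit_displacement(self, geometry):
        spec = dimer_spec()
        x = np.vstack([geometry.telomere_pole + np.array([1.0, 0, 0]),
                       geometry.centromere_pole])
        assert anchor_energy(x, spec, geometry) == pytest.approx(
            0.5 * geometry.anchor_stiffness
        )

    def test_misplaced_centromere_increases_energy(self, geometry):
        spec = dimer_spec()
        good = np.vstack([geometry.telomere_pole, geometry.centromere_pole])
        drifted = good.copy()
        drifted[1] = 0.7 * geometry.centromere_pole + 0.3 * geometry.telomere_pole
        worse = good.copy()
        worse[1] = geometry.telomere_pole
        e0 = anchor_energy(good, spec, geometry)
        e1 = anchor_energy(drifted, spec, geometry)
        e2 = anchor_energy(worse, spec, geometry)
        assert e0 < e1 < e2

    def test_empty_anchor_sets_rejected(self, geometry):
        spec = GenomeSpec(3, 100_000, np.zeros(3, dtype=int),
                          np.array(["A"] * 3), np.array([], dtype=int),
                          np.array([1]))
        with pytest.raises(ValueError, match="polarization"):
            anchor_energy(np.zeros((3, 3)), spec, geometry)


class TestInitialConformation:
    def test_deterministic_given_seed(self, geometry):
        spec = make_synthetic_genome(n_beads=60, seed=0)
        a = initialize_conformation(spec, geometry, seed=5)
        b = initialize_conformation(spec, geometry, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_telomeres_start_near_their_pole(self):
        spec = make_synthetic_genome(n_beads=100, seed=0)
        geo = NucleusGeometry(pole_separation=12.0, equatorial_radius=6.0)
        x = initialize_conformation(spec, geo, seed=1)
        d = np.linalg.norm(x[spec.telomere_beads] - geo.telomere_pole, axis=1)
        assert d.max() < 2.5

    def test_minimum_pairwise_separation(self, geometry):
        spec = make_synthetic_genome(n_beads=80, seed=0)
        x = initialize_conformation(spec, geometry, seed=2)
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 0.5

    def test_coil_style_unpolarized(self, geometry):
        spec = make_synthetic_genome(n_beads=80, seed=0)
        x = initialize_conformation(spec, geometry, seed=2, style="coil")
        ax = x @ geometry.pole_axis
        # ends not pinned at the poles
        assert np.abs(ax[spec.telomere_beads]).max() < 0.6 * geometry.pole_separation


class TestLangevin:
    def test_bit_identical_trajectories_for_same_seed(self):
        spec = make_synthetic_genome(n_beads=40, seed=0)
        geo = NucleusGeometry(pole_separation=10.0, equatorial_radius=5.0)
        params = MiChroMParameters(d_cutoff=10, gamma=np.full(8, -0.2))
        cfg = SimulationConfig(seed=9, n_steps=200, save_every=20)
        t1 = run_langevin(spec, params, geo, cfg)
        t2 = run_langevin(spec, params, geo, cfg)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_zero_temperature_stationary_at_minimum(self):
        # harmonic anchor pair placed exactly at the poles, unbonded
        # (separate chromosomes): at T = 0 with zero velocity it must
        # not move
        spec = GenomeSpec(2, 100_000, np.array([0, 1]),
                          np.array(["A", "A"]), np.array([0]), np.array([1]))
        geo = NucleusGeometry(pole_separation=4.0, equatorial_radius=2.0,
                              anchor_inset=0.0)
        params = MiChroMParameters(d_cutoff=2, gamma=np.zeros(0), ev_k=0.0)
        x0 = np.vstack([geo.telomere_pole, geo.centromere_pole])
        cfg = SimulationConfig(seed=0, n_steps=100, save_every=100,
                               temperature=0.0)
        traj = run_langevin(spec, params, geo, cfg, initial_coords=x0)
        np.testing.assert_allclose(traj.final, x0, atol=1e-8)

    def test_free_bead_diffusion_einstein_relation(self):
        # single untethered bead: MSD ~ 6 (T / friction) t at long times
        spec = GenomeSpec(1, 100_000, np.zeros(1, dtype=int),
                          np.array(["A"]), np.array([0]), np.array([], int))
        geo = NucleusGeometry(pole_separation=1e6, equatorial_radius=1e6,
                              anchor_stiffness=0.0)
        cfg = SimulationConfig(seed=4, n_steps=400_000, save_every=200,
                               friction=1.0)
        params = MiChroMParameters(d_cutoff=2, gamma=np.zeros(0))
        traj = run_langevin(spec, params, geo, cfg)
        pos = traj.frames[:, 0, :]
        lag = 25  # frames = 5e3 steps = 50 time units
        disp = pos[lag:] - pos[:-lag]
        msd = (disp**2).sum(axis=1).mean()
        t_lag = lag * cfg.save_every * cfg.timestep
        expected = 6.0 * cfg.temperature / cfg.friction * t_lag
        assert msd == pytest.approx(expected, rel=0.35)

    def test_harmonic_dimer_equipartition(self):
        # two beads tethered to the same point behave as independent 3D
        # oscillators: <x^2> per mode = T / k
        spec = dimer_spec()
        geo = NucleusGeometry(pole_separation=2e-6, equatorial_radius=1e6,
                              anchor_stiffness=10.0, wall_stiffness=0.0,
                              anchor_inset=0.0)
        params = MiChroMParameters(d_cutoff=2, gamma=np.zeros(0), ev_k=0.0,
                                   bond_k=0.0, angle_k=0.0, bond_r0=1e9)
        cfg = SimulationConfig(seed=8, n_steps=120_000, save_every=60,
                               friction=0.5)
        x0 = np.array([[0.1, 0, 0], [0, 0.1, 0]])
        traj = run_langevin(spec, params, geo, cfg, initial_coords=x0)
        var = traj.frames.reshape(-1, 3).var(axis=0).mean()
        assert var == pytest.approx(cfg.temperature / 10.0, rel=0.1)


class TestPolarization:
    def test_anchors_order_telomeres_below_centromeres(self):
        from rablchrom.synth import default_geometry, make_ground_truth_params

        spec = make_synthetic_genome(n_beads=100, seed=0)
        params = make_ground_truth_params("aedes_like", seed=0, d_cutoff=30)
        geo = default_geometry(100)
        traj = run_langevin(spec, params, geo,
                            SimulationConfig(seed=2, n_steps=3000,
                                             save_every=100))
        fin = np.asarray(traj.frames[15:])
        ax = fin.reshape(-1, 100, 3) @ geo.pole_axis
        tel = ax[:, spec.telomere_beads].mean()
        cen = ax[:, spec.centromere_beads].mean()
        assert tel < cen

    def test_confinement_holds_interior_beads(self):
        from rablchrom.synth import default_geometry, make_ground_truth_params

        spec = make_synthetic_genome(n_beads=100, seed=0)
        params = make_ground_truth_params("aedes_like", seed=0, d_cutoff=30)
        geo = default_geometry(100)
        traj = run_langevin(spec, params, geo,
                            SimulationConfig(seed=2, n_steps=3000,
                                             save_every=100))
        anchored = np.concatenate([spec.telomere_beads,
                                   spec.centromere_beads])
        interior = np.setdiff1d(np.arange(100), anchored)
        s = np.array([geo.spheroidal_coordinate(f)[interior]
                      for f in traj.frames[15:]])
        assert (s <= 1.05).mean() >= 0.99


class TestQuench:
    def test_empty_schedule_segment_is_identity(self):
        spec = make_synthetic_genome(n_beads=30, seed=0)
        geo = NucleusGeometry(pole_separation=8.0, equatorial_radius=4.0)
        params = MiChroMParameters(d_cutoff=10)
        x0 = initialize_conformation(spec, geo, seed=3)
        out = quench(spec, params, geo, SimulationConfig(seed=3),
                     schedule=[(1.0, 0)], initial_coords=x0)
        np.testing.assert_array_equal(out, x0)

    def test_increasing_schedule_rejected(self):
        spec = make_synthetic_genome(n_beads=30, seed=0)
        geo = NucleusGeometry(pole_separation=8.0, equatorial_radius=4.0)
        with pytest.raises(ValueError, match="non-increasing"):
            quench(spec, MiChroMParameters(d_cutoff=10), geo,
                   SimulationConfig(seed=0),
                   schedule=[(0.5, 10), (1.0, 10)])

    def test_quench_lowers_energy_in_most_replicas(self):
        from rablchrom.engine import anchor_energy, confinement_energy
        from rablchrom.michrom import total_energy

        spec = make_synthetic_genome(n_beads=60, seed=0)
        geo = NucleusGeometry(pole_separation=10.0, equatorial_radius=5.0)
        params = MiChroMParameters(d_cutoff=15, gamma=np.full(13, -0.3))

        def total(x):
            return (total_energy(x, spec, params)
                    + confinement_energy(x, geo)
                    + anchor_energy(x, spec, geo))

        wins = 0
        for seed in range(6):
            cfg = SimulationConfig(seed=seed, n_steps=100, save_every=100)
            warm = run_langevin(spec, params, geo,
                                replace(cfg, n_steps=500, save_every=500))
            x0 = warm.final
            xq = quench(spec, params, geo, cfg,
                        schedule=[(0.5, 400), (0.1, 400), (0.01, 400)],
                        initial_coords=x0)
            wins += total(xq) < total(x0)
        assert wins >= 5

    def test_dimer_quenched_to_rest_length(self):
        spec = dimer_spec()
        geo = NucleusGeometry(pole_separation=1e6, equatorial_radius=1e6,
                              anchor_stiffness=0.0)
        params = MiChroMParameters(d_cutoff=2, gamma=np.zeros(0))
        x0 = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        xq = quench(spec, params, geo,
                    SimulationConfig(seed=1, friction=1.0),
                    schedule=[(0.1, 1500), (0.0, 4000)], initial_coords=x0)
        bond = np.linalg.norm(xq[1] - xq[0])
        assert bond == pytest.approx(params.bond_rest_length, abs=1e-3)


class TestDeformation:
    def test_zero_strain_identity(self, geometry):
        g = deform_nucleus(geometry, 0.0)
        assert g.pole_separation == geometry.pole_separation
        assert g.equatorial_radius == geometry.equatorial_radius

    @pytest.mark.parametrize("strain,factor", [(0.3, 1.3), (-0.3, 0.7)])
    def test_pole_separation_scales(self, geometry, strain, factor):
        g = deform_nucleus(geometry, strain)
        assert g.pole_separation == pytest.approx(factor * 10.0)

    def test_volume_preserved_by_default(self, geometry):
        g = deform_nucleus(geometry, 0.3)
        v0 = geometry.pole_separation * geometry.equatorial_radius**2
        assert g.pole_separation * g.equatorial_radius**2 == pytest.approx(v0)

    def test_fixed_equator_variant(self, geometry):
        g = deform_nucleus(geometry, 0.3, preserve_volume=False)
        assert g.equatorial_radius == geometry.equatorial_radius

    def test_anchor_poles_move_with_wall(self, geometry):
        g = deform_nucleus(geometry, 0.3)
        np.testing.assert_allclose(
            g.centromere_pole,
            (0.5 * 13.0 - g.anchor_inset) * g.pole_axis,
        )

    def test_overcompression_rejected(self, geometry):
        with pytest.raises(ValueError, match="strain"):
            deform_nucleus(geometry, -1.0)


class TestTrajectoryOutput:
    def test_hdf5_and_pdb_writers(self, tmp_path):
        import h5py

        spec = make_synthetic_genome(n_beads=30, seed=0)
        geo = NucleusGeometry(pole_separation=8.0, equatorial_radius=4.0)
        traj = run_langevin(spec, MiChroMParameters(d_cutoff=10), geo,
                            SimulationConfig(seed=1, n_steps=100,
                                             save_every=50))
        h5 = tmp_path / "t.h5"
        traj.to_hdf5(h5)
        with h5py.File(h5) as h:
            np.testing.assert_array_equal(h["frames"][()], traj.frames)
        pdb = tmp_path / "t.pdb"
        traj.to_pdb(pdb)
        text = pdb.read_text()
        assert text.count("MODEL") == traj.n_frames
        assert text.count("ATOM") == traj.n_frames * 30


class TestFullNucleus:
    def test_three_chromosomes_two_copies(self):
        specs = [make_synthetic_genome(n_beads=40, seed=s) for s in range(3)]
        full = build_full_nucleus(specs, copies=2)
        assert full.n_beads == 240
        assert full.n_chroms == 6
        assert len(full.bonds()) == 6 * 39  # no bonds across chains

    def test_single_copy_identity_layout(self):
        spec = make_synthetic_genome(n_beads=40, seed=0)
        full = build_full_nucleus([spec], copies=1)
        assert full.n_beads == spec.n_beads
        np.testing.assert_array_equal(full.type_of, spec.type_of)
        np.testing.assert_array_equal(full.telomere_beads, spec.telomere_beads)

    def test_chain_ranges_partition_beads(self):
        specs = [make_synthetic_genome(n_beads=30, seed=s) for s in range(2)]
        full = build_full_nucleus(specs, copies=2)
        starts = full.chrom_starts
        assert starts.tolist() == [0, 30, 60, 90]
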