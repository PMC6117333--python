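"""Rigid-body and point-particle integration: conservation properties."""

import numpy as np
import pytest

from macroioncg.builder import (ChargeLayout, Macroion, SimulationSystem,
                                make_template)
from macroioncg.engine import (ForceField, Integrator, ParticleSystem,
                               RunConfig, compute_forces, run, step_nve)


def fcc_crystal(ncell=2, density=1.2):
    a0 = (4.0 / density) ** (1 / 3)
    base = np.array([[0, 0, 0], [0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
    cells = np.array([[i, j, k] for i in range(ncell)
                      for j in range(ncell) for k in range(ncell)])
    pos = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * a0
    box_l = ncell * a0
    n = len(pos)
    return ParticleSystem(
        box=np.full(3, box_l), positions=pos - box_l / 2,
        velocities=np.zeros((n, 3)), charges=np.zeros(n),
        masses=np.ones(n), body_id=np.full(n, -1))


def isolated_macroion(radius=2.5, n_charges=10, spin=(3.0, -1.0, 2.0)):
    t = make_template(radius, ChargeLayout("random", n_charges), seed=0)
    s = SimulationSystem(
        box=np.full(3, 20.0), templates=[t],
        macroions=[Macroion(0, np.zeros(3), np.array([1.0, 0, 0, 0]))],
        counterions=np.empty((0, 3)), solvent=np.empty((0, 3)))
    ps = ParticleSystem.from_simulation_system(s)
    ps.charges[:] = 0.0          # nothing to interact with
    ps.body_angmom[0] = np.array(spin)
    return ps


class TestFreeRotor:
    def test_angular_momentum_conserved(self):
        """Torque-free rigid macroion: L constant over 1e4 steps."""
        ps = isolated_macroion()
        cfg = RunConfig(ensemble="NVE", n_steps=10000,
                        initialize_velocities=False, output_stride=10000)
        Integrator(ps, ForceField(), cfg).run()
        assert np.allclose(ps.body_angmom[0], [3.0, -1.0, 2.0], atol=1e-9)

    def test_rigid_shape_preserved(self):
        ps = isolated_macroion()
        idx = ps.body_index[0]
        ref = np.linalg.norm(ps.positions[idx[0]] - ps.positions[idx[1:]],
                             axis=1)
        cfg = RunConfig(ensemble="NVE", n_steps=5000,
                        initialize_velocities=False, output_stride=5000)
        Integrator(ps, ForceField(), cfg).run()
        now = np.linalg.norm(ps.positions[idx[0]] - ps.positions[idx[1:]],
                             axis=1)
        assert np.max(np.abs(now - ref) / ref) < 1e-8

    def test_quaternion_stays_normalised(self):
        ps = isolated_macroion()
        cfg = RunConfig(ensemble="NVE", n_steps=2000,
                        initialize_velocities=False, output_stride=2000)
        Integrator(ps, ForceField(), cfg).run()
        assert abs(np.linalg.norm(ps.body_quat[0]) - 1.0) < 1e-9


class TestNVE:
    def test_energy_conservation(self):
        """Drift < 1e-3 relative over 1e4 steps at dt = 0.005.

        Measured on a compressed fcc crystal whose neighbour shells stay
        away from the cutoff, so the unshifted LJ truncation injects no
        crossing noise and the check isolates integrator quality."""
        ps = fcc_crystal()
        cfg = RunConfig(ensemble="NVE", n_steps=10000, seed=5,
                        temperature=0.02, output_stride=1000)
        integ = Integrator(ps, ForceField(), cfg)
        e0 = integ.total_energy()
        traj = integ.run()
        es = traj.series("total")
        assert np.max(np.abs(es - e0)) / abs(e0) < 1e-3

    def test_momentum_conserved(self):
        ps = fcc_crystal()
        cfg = RunConfig(ensemble="NVE", n_steps=2000, seed=2,
                        temperature=0.5, output_stride=2000)
        integ = Integrator(ps, ForceField(), cfg)
        Integrator.run(integ)
        mom = (ps.masses[:, None] * ps.velocities).sum(axis=0)
        assert np.abs(mom).max() < 1e-9

    def test_single_step_wrapper(self):
        ps = fcc_crystal()
        rng = np.random.default_rng(0)
        ps.velocities[:] = rng.normal(scale=0.1, size=ps.velocities.shape)
        before = ps.positions.copy()
        step_nve(ps, ForceField(), 1e-8)
        # dt -> 0: positions unchanged to first order
        assert np.abs(ps.positions - before).max() < 1e-8

    def test_determinism_same_seed(self):
        outs = []
        for _ in range(2):
            ps = fcc_crystal()
            cfg = RunConfig(ensemble="NVT", n_steps=500, seed=42,
                            temperature=0.5, output_stride=500)
            Integrator(ps, ForceField(), cfg).run()
            outs.append(ps.positions.copy())
        assert np.array_equal(outs[0], outs[1])


class TestForces:
    def test_newtons_third_law_totals(self):
        t = make_template(1.5, ChargeLayout("random", 5), seed=2)
        from macroioncg.builder import build_system
        s = build_system([t], [1], box=8.0, solvent_density=0.02, seed=3)
        ps = ParticleSystem.from_simulation_system(s)
        f, _, _, _, _ = compute_forces(ps, ForceField())
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * max(np.abs(f).max(), 1)

    def test_forces_match_finite_difference(self):
        """Central-difference gradient of the total potential, h = 1e-6."""
        from macroioncg.builder import build_system
        from macroioncg.engine import ForceCalculator
        t = make_template(1.5, ChargeLayout("random", 5), seed=2)
        s = build_system([t], [1], box=8.0, solvent_density=0.02, seed=3)
        ps = ParticleSystem.from_simulation_system(s)
        ff = ForceField()
        calc = ForceCalculator(ps, ff)
        f, _, _ = calc.compute(ps)
        scale = np.abs(f).max()
        h = 1e-6
        for i in ps.free_index[:3]:
            for ax in range(3):
                p0 = ps.positions[i, ax]
                ps.positions[i, ax] = p0 + h
                ep = calc.compute(ps)[1]["potential"]
                ps.positions[i, ax] = p0 - h
                em = calc.compute(ps)[1]["potential"]
                ps.positions[i, ax] = p0
                fd = -(ep - em) / (2 * h)
                assert abs(fd - f[i, ax]) < 1e-6 * scale

    def test_isolated_macroion_no_net_force_or_torque(self):
        ps = isolated_macroion(spin=(0, 0, 0))
        _, _, _, f_b, tau_b = compute_forces(ps, ForceField())
        assert np.abs(f_b).max() < 1e-10
        assert np.abs(tau_b).max() < 1e-10

    def test_overlap_flagged(self):
        n = 2
        ps = ParticleSystem(
            box=np.full(3, 10.0),
            positions=np.array([[0.0, 0, 0], [0.05, 0, 0]]),
            velocities=np.zeros((n, 3)), charges=np.zeros(n),
            masses=np.ones(n), body_id=np.full(n, -1))
        with pytest.raises(RuntimeError, match="overlap"):
            compute_forces(ps, ForceField())


class TestThermostatBarostat:
    def test_nvt_reaches_set_point(self):
        """Short solvent NVT run: mean T within 0.03 of the set point."""
        from macroioncg.scenarios import solvent_box
        ps = solvent_box(n_side=6, density=0.8)
        cfg = RunConfig(ensemble="NVT", temperature=1.0, n_steps=6000,
                        seed=7, output_stride=20)
        integ = Integrator(ps, ForceField(), cfg)
        traj = integ.run()
        steps = traj.series("step")
        mean_t = np.mean(traj.series("temperature")[steps > 2000])
        assert mean_t == pytest.approx(1.0, abs=0.03)

    def test_npt_relaxes_pressure(self):
        """Berendsen NPT drives the LJ fluid towards the target pressure."""
        from macroioncg.scenarios import solvent_box
        ps = solvent_box(n_side=6, density=0.85)
        cfg = RunConfig(ensemble="NPT", temperature=1.0, pressure=0.1,
                        n_steps=8000, seed=8, output_stride=20)
        integ = Integrator(ps, ForceField(), cfg)
        traj = integ.run()
        steps = traj.series("step")
        p = traj.series("pressure")[steps > 4000]
        assert np.mean(p) == pytest.approx(0.1, abs=0.15)
        # density actually changed from the start value
        assert not np.isclose(np.prod(traj[0].box), np.prod(traj[-1].box),
                              rtol=1e-3)

    def test_rigid_body_equipartition(self):
        """Thermostatted macroion gains rotational kinetic energy ~ 3/2 T."""
        ps = isolated_macroion(spin=(0, 0, 0))
        cfg = RunConfig(ensemble="NVT", temperature=1.0, n_steps=4000,
                        seed=9, output_stride=10, friction=2.0)
        integ = Integrator(ps, ForceField(), cfg)
        integ.run()
        # single body: wide tolerance, just check it thermalised
        k_rot = ps.kinetic_energy()["body_rot"]
        assert 0.1 < k_rot < 8.0
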