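"""Time integration: NVE / NVT (Langevin) / NPT (Langevin + Berendsen).

Free particles follow velocity-Verlet; with a thermostat, the BAOAB
splitting (kick - drift - Ornstein-Uhlenbeck - drift - kick) is used, which
reduces exactly to velocity-Verlet when the friction is zero.  Rigid
macroions carry centre-of-mass and quaternion/angular-momentum states: the
angular velocity is held constant in the body frame across each half-drift
(an excellent approximation for the nearly spherical bead shells used
here), which preserves every intra-body distance to machine precision.
The NPT ensemble adds an isotropic Berendsen box rescaling driven by the
instantaneous virial pressure; it is intended for density equilibration,
as production sampling is done in NVT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceField
from .forces import ForceCalculator, body_forces_torques
from .system import ParticleSystem, quat_exp, quat_multiply
from ..builder import SimulationSystem, quaternion_matrix

ENSEMBLES = ("NVE", "NVT", "NPT")


@dataclass(frozen=True)
class RunConfig:
    """Protocol for one simulation stage (reduced units throughout)."""

    ensemble: str = "NVT"
    temperature: float = 1.0
    pressure: float = 0.1
    timestep: float = 0.005
    n_steps: int = 1000
    seed: int = 0
    output_stride: int = 100
    friction: float = 1.0            # Langevin gamma (1/tau)
    friction_rotational: float | None = None   # body-rotation gamma
    tau_p: float = 2.0               # Berendsen pressure time constant
    compressibility: float = 0.05    # Berendsen kappa (reduced)
    freeze_bodies: bool = False      # hold macroions fixed (sampling runs)
    initialize_velocities: bool = True

    def __post_init__(self):
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"ensemble must be one of {ENSEMBLES}")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass
class Frame:
    step: int
    box: np.ndarray
    positions: np.ndarray
    body_com: np.ndarray
    body_quat: np.ndarray
    energies: dict
    temperature: float
    pressure: float


@dataclass
class Trajectory:
    frames: list = field(default_factory=list)

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def series(self, key: str) -> np.ndarray:
        if key in ("temperature", "pressure", "step"):
            return np.array([getattr(f, key) for f in self.frames])
        return np.array([f.energies[key] for f in self.frames])


class Integrator:
    """Stateful stepper bound to one ParticleSystem and ForceField."""

    def __init__(self, psys: ParticleSystem, ff: ForceField,
                 cfg: RunConfig):
        self.psys = psys
        self.ff = ff
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.calc = ForceCalculator(psys, ff)
        if cfg.initialize_velocities:
            self._init_velocities(cfg.temperature)
        self.forces, self.energies, self.virial = self.calc.compute(psys)
        self.body_f, self.body_tau = body_forces_torques(psys, self.forces)

    # -- setup -------------------------------------------------------------

    def _init_velocities(self, temperature: float) -> None:
        ps = self.psys
        free = ps.free_index
        if len(free):
            sd = np.sqrt(temperature / ps.masses[free])[:, None]
            v = self.rng.normal(size=(len(free), 3)) * sd
            v -= np.average(v, axis=0, weights=ps.masses[free])
            ps.velocities[free] = v
        if ps.n_bodies and not self.cfg.freeze_bodies:
            sd = np.sqrt(temperature / ps.body_mass)[:, None]
            ps.body_vel = self.rng.normal(size=(ps.n_bodies, 3)) * sd
            for b in range(ps.n_bodies):
                pi = self.rng.normal(size=3) * np.sqrt(
                    temperature * ps.body_inertia[b])
                r = quaternion_matrix(ps.body_quat[b])
                ps.body_angmom[b] = r @ pi

    # -- elementary updates ------------------------------------------------

    def _kick(self, half_dt: float) -> None:
        ps = self.psys
        free = ps.free_index
        ps.velocities[free] += self.forces[free] / \
            ps.masses[free, None] * half_dt
        if ps.n_bodies and not self.cfg.freeze_bodies:
            ps.body_vel += self.body_f / ps.body_mass[:, None] * half_dt
            ps.body_angmom += self.body_tau * half_dt

    def _drift(self, half_dt: float) -> None:
        ps = self.psys
        free = ps.free_index
        ps.positions[free] += ps.velocities[free] * half_dt
        if ps.n_bodies and not self.cfg.freeze_bodies:
            ps.body_com += ps.body_vel * half_dt
            for b in range(ps.n_bodies):
                omega_b = ps.body_omega_body(b)
                dq = quat_exp(omega_b * half_dt)
                q = quat_multiply(ps.body_quat[b], dq)
                ps.body_quat[b] = q / np.linalg.norm(q)
            ps.sync_bodies()

    def _ou(self, dt: float) -> None:
        ps, cfg = self.psys, self.cfg
        c = np.exp(-cfg.friction * dt)
        s = np.sqrt(1.0 - c * c)
        free = ps.free_index
        if len(free):
            sd = np.sqrt(cfg.temperature / ps.masses[free])[:, None]
            ps.velocities[free] = c * ps.velocities[free] + \
                s * sd * self.rng.normal(size=(len(free), 3))
        if ps.n_bodies and not cfg.freeze_bodies:
            sd = np.sqrt(cfg.temperature / ps.body_mass)[:, None]
            ps.body_vel = c * ps.body_vel + \
                s * sd * self.rng.normal(size=(ps.n_bodies, 3))
            g_rot = cfg.friction_rotational
            cr = c if g_rot is None else np.exp(-g_rot * dt)
            sr = np.sqrt(1.0 - cr * cr)
            for b in range(ps.n_bodies):
                r = quaternion_matrix(ps.body_quat[b])
                pi = r.T @ ps.body_angmom[b]
                pi = cr * pi + sr * np.sqrt(
                    cfg.temperature * ps.body_inertia[b]) * \
                    self.rng.normal(size=3)
                ps.body_angmom[b] = r @ pi

    def _berendsen(self, dt: float) -> None:
        ps, cfg = self.psys, self.cfg
        p_inst = self.pressure()
        mu3 = 1.0 - cfg.compressibility * dt / cfg.tau_p * \
            (cfg.pressure - p_inst)
        mu = float(np.clip(mu3, 0.97, 1.03)) ** (1.0 / 3.0)
        ps.box *= mu
        free = ps.free_index
        ps.positions[free] *= mu
        if ps.n_bodies:
            ps.body_com *= mu
            ps.sync_bodies()

    # -- observables -------------------------------------------------------

    def pressure(self) -> float:
        ps = self.psys
        k = ps.kinetic_energy()
        k_trans = k["free"] + k["body_trans"]
        vol = float(np.prod(ps.box))
        return (2.0 * k_trans + self.virial) / (3.0 * vol)

    def total_energy(self) -> float:
        return self.energies["potential"] + \
            self.psys.kinetic_energy()["total"]

    # -- stepping ----------------------------------------------------------

    def step(self) -> None:
        """One BAOAB step (velocity-Verlet when ensemble is NVE)."""
        dt = self.cfg.timestep
        self._kick(dt / 2.0)
        self._drift(dt / 2.0)
        if self.cfg.ensemble in ("NVT", "NPT"):
            self._ou(dt)
        self._drift(dt / 2.0)
        self.forces, self.energies, self.virial = self.calc.compute(self.psys)
        self.body_f, self.body_tau = body_forces_torques(self.psys,
                                                         self.forces)
        self._kick(dt / 2.0)
        if self.cfg.ensemble == "NPT":
            self._berendsen(dt)

    def run(self) -> Trajectory:
        cfg = self.cfg
        traj = Trajectory()
        self._record(traj, 0)
        e_prev = self.total_energy()
        for i in range(1, cfg.n_steps + 1):
            self.step()
            if cfg.ensemble == "NVE":
                e_now = self.total_energy()
                if abs(e_now - e_prev) > 0.1 * (abs(e_prev) + 1.0):
                    raise RuntimeError(
                        f"energy blow-up at step {i}: {e_prev} -> {e_now}; "
                        "reduce the timestep or fix overlaps")
                e_prev = e_now
            if i % cfg.output_stride == 0 or i == cfg.n_steps:
                self._record(traj, i)
        return traj

    def _record(self, traj: Trajectory, step: int) -> None:
        ps = self.psys
        en = dict(self.energies)
        en["kinetic"] = ps.kinetic_energy()["total"]
        en["total"] = en["potential"] + en["kinetic"]
        traj.frames.append(Frame(
            step=step, box=ps.box.copy(), positions=ps.positions.copy(),
            body_com=ps.body_com.copy() if ps.n_bodies else np.empty((0, 3)),
            body_quat=ps.body_quat.copy() if ps.n_bodies
            else np.empty((0, 4)),
            energies=en, temperature=ps.temperature(),
            pressure=self.pressure()))


def step_nve(psys: ParticleSystem, ff: ForceField, dt: float) -> ParticleSystem:
    """Advance the system by a single NVE step (in place; also returned)."""
    cfg = RunConfig(ensemble="NVE", timestep=dt, n_steps=1,
                    initialize_velocities=False, output_stride=1)
    Integrator(psys, ff, cfg).step()
    return psys


def run(system, ff: ForceField, cfg: RunConfig):
    """Run a trajectory from a SimulationSystem or ParticleSystem.

    Returns (trajectory, final ParticleSystem) — the final state can be
    saved and used to restart.
    """
    psys = (ParticleSystem.from_simulation_system(system)
            if isinstance(system, SimulationSystem) else system)
    integ = Integrator(psys, ff, cfg)
    traj = integ.run()
    return traj, psys
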