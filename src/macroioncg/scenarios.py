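"""End-to-end scaled-down scenarios.

Each scenario builds a small solution system, runs seeded dynamics and
returns the analyses relevant to monolayer self-assembly.  Sizes are
chosen so every scenario completes in minutes on one CPU core; full
monolayer morphologies (dozens of macroions, millions of solvent beads,
>100 ns) require cluster-scale runs and are outside what these demos can
show — they probe direction and mechanism, not converged morphology.
"""

from __future__ import annotations

import numpy as np

from .builder import (ChargeLayout, Macroion, SimulationSystem,
                      build_system, make_template)
from .engine import ForceField, Integrator, ParticleSystem, RunConfig, run
from .analysis import (cluster_time_series, compute_rdf, find_clusters,
                       planarity_ratio, surface_gap_statistics)


def solvent_box(n_side: int = 10, density: float = 0.8,
                seed: int = 0) -> ParticleSystem:
    """Cubic lattice of n_side^3 solvent beads at the given density."""
    n = n_side**3
    box_l = (n / density) ** (1.0 / 3.0)
    g = (np.arange(n_side) + 0.5) / n_side * box_l - box_l / 2
    pos = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return ParticleSystem(
        box=np.full(3, box_l), positions=pos,
        velocities=np.zeros((n, 3)), charges=np.zeros(n),
        masses=np.ones(n), body_id=np.full(n, -1))


def nvt_temperature_check(n_side: int = 10, density: float = 0.8,
                          n_steps: int = 50000, n_equil: int = 5000,
                          temperature: float = 1.0, seed: int = 0,
                          stride: int = 25) -> dict:
    """Thermostatted solvent run; time-mean reduced kinetic temperature.

    Returns the mean instantaneous temperature over the post-equilibration
    window together with the trajectory series.
    """
    psys = solvent_box(n_side, density, seed)
    cfg = RunConfig(ensemble="NVT", temperature=temperature,
                    n_steps=n_steps + n_equil, seed=seed,
                    output_stride=stride)
    integ = Integrator(psys, ForceField(), cfg)
    traj = integ.run()
    t_series = traj.series("temperature")
    steps = traj.series("step")
    mean_t = float(np.mean(t_series[steps > n_equil]))
    return {"mean_temperature": mean_t, "series": t_series, "steps": steps,
            "n_particles": psys.n_particles}


def dimer_attraction(seed: int = 0, radius: float = 2.5, n_charges: int = 20,
                     gap0: float = 2.5, solvent_density: float = 0.7,
                     n_pin: int = 3000, n_steps: int = 15000) -> dict:
    """Counterion-mediated attraction between two like-charged macroions.

    Two macroions (20 random surface charges each by default) start at a
    mediation-range surface gap in a liquid-density CG solvent bath with
    their counterions condensed on the charged sites.  The bath and ions
    first equilibrate with the bodies pinned; the bodies are then released
    and the system evolves freely under the NVT thermostat.  With charges
    on, counterion mediation pulls the pair into contact and the mean
    potential energy of the bound tail of the trajectory lies well below
    the separated early window.  With every charge switched off (identical
    construction) the liquid solvent screens the bare surface-surface van
    der Waals attraction, the pair does not durably bind, and the energy
    difference collapses to residual noise.

    Returns the separated-minus-bound energy differences and the early /
    late mean surface gaps for both arms.
    """
    template = make_template(radius, ChargeLayout("random", n_charges),
                             seed=seed)
    d = 2.0 * radius + gap0
    box = np.array([18.0, 11.0, 11.0]) * (radius / 2.5)
    from .builder import _rejection_fill, quaternion_matrix
    out = {}
    for charged in (True, False):
        rng = np.random.default_rng(seed)
        macs = [Macroion(0, np.array([-d / 2, 0.0, 0.0]),
                         np.array([1.0, 0.0, 0.0, 0.0])),
                Macroion(0, np.array([d / 2, 0.0, 0.0]),
                         np.array([0.5, 0.5, 0.5, 0.5]))]
        sys_ = SimulationSystem(box=box, templates=[template],
                                macroions=macs,
                                counterions=np.empty((0, 3)),
                                solvent=np.empty((0, 3)))
        surface = sys_.macroion_bead_positions()
        centers = [m.com for m in macs]
        radii = [radius, radius]
        dirs = template.positions[template.charges != 0] / radius
        # counterions condensed one bead above their charged site; sites
        # blocked by the partner macroion fall back to bulk insertion
        ci: list = []
        for m in macs:
            rot = quaternion_matrix(m.quaternion)
            for u in dirs @ rot.T:
                s = m.com + u * (radius + 1.0)
                pool = np.vstack([surface] + ([np.asarray(ci)] if ci
                                              else []))
                if np.linalg.norm(pool - s, axis=1).min() >= 0.95:
                    ci.append(s)
                else:
                    ci.append(_rejection_fill(rng, 1, box, pool, centers,
                                              radii, 0.95, 1.0)[0])
        ci = np.asarray(ci)
        v_excl = 2 * 4 / 3 * np.pi * (radius + 0.5) ** 3
        n_solv = int(solvent_density * (np.prod(box) - v_excl))
        solv = _rejection_fill(rng, n_solv, box, np.vstack([surface, ci]),
                               centers, radii, 0.8, 1.0)
        sys_.counterions, sys_.solvent = ci, solv
        psys = ParticleSystem.from_simulation_system(sys_)
        if not charged:
            psys.charges[:] = 0.0
        ff = ForceField(ewald_accuracy=1e-4)
        pin = RunConfig(ensemble="NVT", temperature=1.0, n_steps=n_pin,
                        seed=seed, output_stride=n_pin, freeze_bodies=True)
        Integrator(psys, ff, pin).run()
        free = RunConfig(ensemble="NVT", temperature=1.0, n_steps=n_steps,
                         seed=seed + 7, output_stride=50, friction=0.2,
                         initialize_velocities=True)
        traj = Integrator(psys, ff, free).run()
        steps = traj.series("step")
        u = traj.series("potential")
        gaps = []
        for f in traj:
            dr = f.body_com[1] - f.body_com[0]
            dr -= psys.box * np.round(dr / psys.box)
            gaps.append(np.linalg.norm(dr) - 2.0 * radius)
        gaps = np.array(gaps)
        early = (steps > 0) & (steps <= 2500)
        late = steps > n_steps - 5000
        key = "charged" if charged else "uncharged"
        out["delta_" + key] = float(u[early].mean() - u[late].mean())
        out["gap_early_" + key] = float(gaps[early].mean())
        out["gap_late_" + key] = float(gaps[late].mean())
    return out


def scenario_monolayer_demo(seed: int = 0, layout: str = "equatorial",
                            n_macroions: int = 8, radius: float = 2.5,
                            n_charges: int = 10, box: float = 16.0,
                            solvent_density: float = 0.12,
                            n_steps: int = 25000,
                            cluster_cutoff: float = 2.0) -> dict:
    """Scaled-down monolayer-formation run with full analysis.

    Builds ``n_macroions`` macroions with the requested charge layout plus
    counterions and reduced solvent, runs NVT dynamics, and returns cluster
    kinetics, the macroion-macroion RDF, surface-gap statistics and the
    aggregate planarity ratio (smallest/largest gyration-tensor eigenvalue
    of the macroion centres; < 0.2 indicates a flat, monolayer-like
    aggregate, the qualitative signature tracked here).
    """
    template = make_template(radius, ChargeLayout(layout, n_charges),
                             seed=seed)
    sys_ = build_system([template], [n_macroions], box=box,
                        solvent_density=solvent_density, seed=seed)
    cfg = RunConfig(ensemble="NVT", temperature=1.0, n_steps=n_steps,
                    seed=seed, output_stride=max(n_steps // 100, 1),
                    friction=0.2, friction_rotational=0.05)
    traj, psys = run(sys_, ForceField(ewald_accuracy=1e-4), cfg)
    frames_centers = [f.body_com for f in traj]
    ts = cluster_time_series(frames_centers, radius, psys.box,
                             cutoff=cluster_cutoff)
    final_centers = frames_centers[-1]
    clusters = find_clusters(final_centers, radius, psys.box,
                             cutoff=cluster_cutoff)
    gaps = surface_gap_statistics(final_centers, radius, psys.box,
                                  cutoff=cluster_cutoff)
    # planarity of the largest final cluster (needs >= 4 centres),
    # averaged over the trajectory tail to damp shape fluctuations;
    # centres are unwrapped along the cluster's own linkage graph
    biggest = np.flatnonzero(clusters.labels == np.argmax(clusters.sizes))
    link = 2.0 * radius + cluster_cutoff
    if len(biggest) >= 4:
        tail_frames = frames_centers[-max(len(traj) // 10, 1):]
        planarity = float(np.mean([
            planarity_ratio(fc[biggest], psys.box, link_cutoff=link)
            for fc in tail_frames]))
    else:
        planarity = np.nan
    # bond-equator alignment: |cos| of the angle between each linked
    # bond and the partners' equatorial normals (body z in the lab
    # frame), tail-averaged.  Equatorially charged macroions bond in
    # their equatorial plane (|cos| << 0.5); isotropic layouts bond
    # isotropically (|cos| ~ 0.5).
    from .builder import minimum_image, quaternion_matrix
    tail = traj.frames[-max(len(traj) // 10, 1):]
    cosines = []
    for f in tail:
        normals = np.array([quaternion_matrix(q)[:, 2] for q in f.body_quat])
        cl = find_clusters(f.body_com, radius, psys.box,
                           cutoff=cluster_cutoff)
        n = len(f.body_com)
        for i in range(n):
            for j in range(i + 1, n):
                dr = minimum_image(f.body_com[j] - f.body_com[i], psys.box)
                dist = np.linalg.norm(dr)
                if dist - 2 * radius <= cluster_cutoff:
                    u = dr / dist
                    cosines.append(abs(u @ normals[i]))
                    cosines.append(abs(u @ normals[j]))
    bond_axis_alignment = float(np.mean(cosines)) if cosines else np.nan
    tail = max(len(traj) // 4, 2)
    rdf = compute_rdf([(f.body_com, f.box) for f in traj.frames[-tail:]],
                      bin_width=0.1)
    return {"trajectory": traj, "system": psys,
            "cluster_time_series": ts, "final_clusters": clusters,
            "surface_gaps": gaps, "planarity": planarity,
            "bond_axis_alignment": bond_axis_alignment, "rdf": rdf,
            "layout": layout, "seed": seed}
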