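"""RDF/coordination, clustering, gaps, belt geometry and field maps."""

import numpy as np
import pytest

from macroioncg.analysis import (belt_charge_density, belt_width_from_gaps,
                                 compute_rdf, electric_field_grid,
                                 exact_belt_width, find_clusters,
                                 nearest_neighbor_count, planarity_ratio,
                                 sigmoid_fit_quality, surface_gap_statistics)
from macroioncg.builder import (ChargeLayout, icosidodecahedron_axes,
                                make_template, uncharged_template)


def hexagonal_monolayer(a=1.0, nx=12, ny=12, lz=30.0):
    pts = [[(i + 0.5 * (j % 2)) * a, j * a * np.sqrt(3) / 2, 0.0]
           for i in range(nx) for j in range(ny)]
    box = np.array([nx * a, ny * a * np.sqrt(3) / 2, lz])
    return np.array(pts), box


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        frames = [(rng.uniform(-8, 8, size=(600, 3)), np.full(3, 16.0))
                  for _ in range(8)]
        rdf = compute_rdf(frames, bin_width=0.25)
        far = rdf.r > 1.0
        assert np.all(np.abs(rdf.g[far] - 1.0) < 0.25)
        assert np.abs(np.mean(rdf.g[far]) - 1.0) < 0.05

    def test_hexagonal_lattice_peak_positions(self):
        """First three peaks at a, sqrt(3) a, 2a."""
        pts, box = hexagonal_monolayer()
        rdf = compute_rdf([(pts, box)], bin_width=0.02, r_max=3.0)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(rdf.g, height=1.5)
        assert np.allclose(rdf.r[peaks][:3], [1.0, np.sqrt(3), 2.0],
                           atol=0.03)

    def test_single_pair_single_bin(self):
        pos = np.array([[0.0, 0, 0], [1.3, 0, 0]])
        rdf = compute_rdf([(pos, np.full(3, 10.0))], bin_width=0.1)
        nonzero = np.flatnonzero(rdf.g)
        assert len(nonzero) == 1
        assert rdf.r[nonzero[0]] == pytest.approx(1.35, abs=0.051)

    def test_r_max_beyond_half_box_rejected(self):
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match="half box"):
            compute_rdf([(pos, np.full(3, 10.0))], r_max=6.0)

    def test_coordination_closure(self):
        """n(r) closure: at r = L/2 the integral counts the expected
        fraction of the N-1 partners (sphere volume / box volume)."""
        rng = np.random.default_rng(1)
        pos = rng.uniform(-5, 5, size=(50, 3))
        rdf = compute_rdf([(pos, np.full(3, 10.0))], bin_width=0.1)
        frac = 4 / 3 * np.pi * 5**3 / 1000.0
        assert rdf.coordination[-1] == pytest.approx(frac * 49, rel=0.15)


class TestNearestNeighbours:
    def test_hexagonal_first_two_shells(self):
        """6 + 6 neighbours under the first two peaks of the lattice."""
        pts, box = hexagonal_monolayer()
        rdf = compute_rdf([(pts, box)], bin_width=0.02, r_max=3.0)
        count, found = nearest_neighbor_count(rdf)
        assert found
        assert count == pytest.approx(12.0, abs=0.1)

    def test_dilute_gas_returns_zero_flagged(self):
        rng = np.random.default_rng(2)
        frames = [(rng.uniform(-20, 20, size=(40, 3)), np.full(3, 40.0))
                  for _ in range(4)]
        rdf = compute_rdf(frames, bin_width=0.5)
        count, found = nearest_neighbor_count(rdf)
        assert not found
        assert count == 0.0

    def test_assembled_exceeds_unassembled(self):
        pts, box = hexagonal_monolayer()
        rdf_a = compute_rdf([(pts, box)], bin_width=0.02, r_max=3.0)
        n_a, _ = nearest_neighbor_count(rdf_a)
        rng = np.random.default_rng(3)
        rnd = rng.uniform(0, 12, size=pts.shape)
        rdf_b = compute_rdf([(rnd, box)], bin_width=0.02, r_max=3.0)
        n_b, _ = nearest_neighbor_count(rdf_b)
        assert n_a > n_b


class TestClusters:
    def test_all_separate(self):
        c = find_clusters(np.diag([10.0, 20.0, 30.0]), 1.0, 100.0,
                          cutoff=1.0)
        assert c.n_clusters == 3
        assert np.all(c.sizes == 1)

    def test_one_dimer(self):
        centers = np.array([[0, 0, 0], [2.5, 0, 0], [20, 0, 0],
                            [40, 0, 0]], dtype=float)
        c = find_clusters(centers, 1.0, 100.0, cutoff=1.0)
        assert sorted(c.sizes) == [1, 1, 2]

    def test_chain_is_transitive(self):
        centers = np.array([[0, 0, 0], [2.6, 0, 0], [5.2, 0, 0]])
        c = find_clusters(centers, 1.0, 50.0, cutoff=1.0)
        assert c.n_clusters == 1
        assert c.max_size == 3

    def test_sizes_partition_macroions(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(-10, 10, size=(17, 3))
        c = find_clusters(centers, 1.0, 20.0, cutoff=1.5)
        assert c.sizes.sum() == 17

    def test_periodic_linkage(self):
        centers = np.array([[-9.5, 0, 0], [9.5, 0, 0]])
        c = find_clusters(centers, 1.0, 20.0, cutoff=1.5)
        assert c.n_clusters == 1


class TestSurfaceGaps:
    def test_two_spheres_arithmetic(self):
        """1.25-nm-radius spheres 3.1 nm apart -> 0.6 nm gap (nm units)."""
        centers = np.array([[0, 0, 0], [3.1, 0, 0]])
        r = surface_gap_statistics(centers, 1.25, 50.0, cutoff=1.0)
        assert r["found"]
        assert r["mean"] == pytest.approx(0.6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(-3, 3, size=(5, 3))
        base = surface_gap_statistics(centers, 1.0, 60.0, cutoff=5.0)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        moved = centers @ rot.T + np.array([1.0, -2.0, 0.5])
        other = surface_gap_statistics(moved, 1.0, 60.0, cutoff=5.0)
        assert np.allclose(np.sort(base["gaps"]), np.sort(other["gaps"]),
                           atol=1e-9)

    def test_no_clustered_pairs_flagged(self):
        centers = np.array([[0, 0, 0], [30.0, 0, 0]])
        r = surface_gap_statistics(centers, 1.0, 100.0, cutoff=1.0)
        assert not r["found"]


class TestBelt:
    @pytest.fixture()
    def icosi(self):
        # R = 2.5 sigma = 1.25 nm
        return make_template(2.5, ChargeLayout("icosidodecahedron"))

    def test_pentagon_orientation_excess(self, icosi):
        """Belt density 57% higher when sitting on a pentagonal face."""
        res = belt_charge_density(icosi, icosidodecahedron_axes()["five_fold"],
                                  2.8)
        assert res.charges_in_belt == 20
        assert res.percent_difference == pytest.approx(57.1, abs=0.5)

    def test_triangle_orientation_deficit(self, icosi):
        """Belt density 47% lower when sitting on a triangular face."""
        res = belt_charge_density(icosi,
                                  icosidodecahedron_axes()["three_fold"], 2.8)
        assert res.charges_in_belt == 12
        assert res.percent_difference == pytest.approx(-47.6, abs=0.5)

    def test_area_closure(self, icosi):
        res = belt_charge_density(icosi, [0, 0, 1.0], 2.8)
        total = 4 * np.pi * icosi.radius**2
        assert res.belt_area + res.rest_area == pytest.approx(
            total, rel=1e-12)
        assert res.charges_in_belt + res.charges_outside == 30

    def test_rotation_about_axis_invariance(self, icosi):
        from scipy.spatial.transform import Rotation
        from dataclasses import replace
        axis = icosidodecahedron_axes()["five_fold"]
        rot = Rotation.from_rotvec(axis * 1.234).as_matrix()
        spun = replace(icosi, positions=icosi.positions @ rot.T)
        a = belt_charge_density(icosi, axis, 2.8)
        b = belt_charge_density(spun, axis, 2.8)
        assert a.charges_in_belt == b.charges_in_belt

    def test_mirror_symmetry(self, icosi):
        from dataclasses import replace
        axis = icosidodecahedron_axes()["five_fold"]
        flipped = replace(icosi, positions=icosi.positions * [1, 1, -1])
        a = belt_charge_density(icosi, axis, 2.8)
        b = belt_charge_density(flipped, axis, 2.8)
        assert a.percent_difference == pytest.approx(b.percent_difference)

    def test_uniform_coverage_near_zero(self):
        t = make_template(5.0, ChargeLayout("all_charged"))
        res = belt_charge_density(t, [0, 0, 1.0], 2.8)
        assert abs(res.percent_difference) < 5.0

    def test_width_sweep_steps_at_axial_levels(self, icosi):
        """Charge fraction vs width: non-decreasing staircase with jumps
        exactly at twice the |z| levels (0, 1.314, 2.126 sigma doubled)."""
        axis = icosidodecahedron_axes()["five_fold"]
        widths = np.linspace(0.05, 4.8, 200)
        frac = np.array([belt_charge_density(icosi, axis, w).charges_in_belt
                         for w in widths], dtype=float)
        assert np.all(np.diff(frac) >= 0)
        jump_w = widths[1:][np.diff(frac) > 0]
        expected = {2 * 1.314, 2 * 2.126}
        for w in jump_w:
            assert min(abs(w - e) for e in expected) < 0.05

    def test_all_charges_in_belt_flagged_infinite(self):
        t = make_template(2.5, ChargeLayout("equatorial", 10))
        res = belt_charge_density(t, [0, 0, 1.0], 2.0)
        assert res.flagged_infinite
        assert np.isinf(res.percent_difference)


class TestBeltWidth:
    def test_printed_geometry(self):
        """gap 0.6 nm, mediation 1.0 nm, R = 1.25 nm -> 1.4 nm width."""
        w = belt_width_from_gaps(0.6, 1.0, 1.25)
        assert round(w, 1) == 1.4

    def test_width_vanishes_in_limit(self):
        w = belt_width_from_gaps(0.6, 0.6 + 1e-12, 1.25)
        assert w < 1e-5

    def test_parabolic_close_to_exact(self):
        """Parabolic approximation within 15% of the root-found width."""
        approx = belt_width_from_gaps(0.6, 1.0, 1.25)
        exact = exact_belt_width(0.6, 1.0, 1.25)
        assert abs(approx - exact) / exact < 0.15

    def test_invalid_gap_order_rejected(self):
        with pytest.raises(ValueError):
            belt_width_from_gaps(1.0, 0.6, 1.25)


class TestFieldGrid:
    def test_single_charge_coulomb_field(self):
        pts = np.array([[2.0, 0, 0], [0, 3.0, 0], [0, 0, -4.0]])
        fg = electric_field_grid(pts, np.zeros((1, 3)), [1.0], 100.0,
                                 k_q=2.0)
        assert np.allclose(fg.magnitude, [2 / 4, 2 / 9, 2 / 16])

    def test_dipole_antisymmetry(self):
        charges_pos = np.array([[0, 0, 0.5], [0, 0, -0.5]])
        q = [1.0, -1.0]
        pts = np.array([[1.0, 0.4, 0.7], [1.0, 0.4, -0.7]])
        fg = electric_field_grid(pts, charges_pos, q, 100.0, k_q=1.0)
        ea, eb = fg.field
        # mirror z -> -z: Ex,Ey flip sign, Ez equal
        assert np.allclose(ea * [-1, -1, 1], eb, atol=1e-9)

    def test_exclusion_radius_masks_not_poisons(self):
        pts = np.array([[0.1, 0, 0], [3.0, 0, 0]])
        fg = electric_field_grid(pts, np.zeros((1, 3)), [1.0], 100.0,
                                 k_q=1.0, exclusion_radius=0.25)
        assert fg.masked[0] and not fg.masked[1]
        assert np.isnan(fg.magnitude[0])
        assert np.isfinite(fg.magnitude[1])

    def test_neutral_cluster_decays_faster_than_monopole(self):
        rng = np.random.default_rng(6)
        cp = rng.uniform(-0.5, 0.5, size=(10, 3))
        q = np.array([1.0] * 5 + [-1.0] * 5)
        pts = np.array([[r, 0, 0] for r in (5.0, 10.0)])
        fg = electric_field_grid(pts, cp, q, 1e4, k_q=1.0)
        mono = np.abs(q).sum() / np.array([25.0, 100.0])
        assert np.all(fg.magnitude < mono)
        # decays faster than 1/r^2
        assert fg.magnitude[1] < fg.magnitude[0] / 4.0


class TestMorphologyKinetics:
    def test_planarity_of_flat_vs_blob(self):
        rng = np.random.default_rng(7)
        flat = np.column_stack([rng.uniform(-5, 5, 40),
                                rng.uniform(-5, 5, 40),
                                rng.normal(scale=0.05, size=40)])
        blob = rng.normal(scale=3.0, size=(40, 3))
        assert planarity_ratio(flat) < 0.01
        assert planarity_ratio(blob) > 0.3

    def test_sigmoid_beats_line_on_logistic_data(self):
        t = np.linspace(0, 10, 60)
        y = 1 + 5 / (1 + np.exp(-1.5 * (t - 5)))
        y += np.random.default_rng(8).normal(scale=0.1, size=60)
        r2_log, r2_lin = sigmoid_fit_quality(t, y)
        assert r2_log > r2_lin
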