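"""Quantitative analyses of macroion self-assembly trajectories.

Covers the toolkit used to characterise 2-D monolayer ("blackberry"
precursor) formation: radial distribution functions and running
coordination numbers, nearest-neighbour counts from the first two RDF
peaks, single-linkage cluster kinetics, surface-to-surface gap statistics,
the equatorial belt charge-density anisotropy of polyhedral charge
layouts, the belt-width construction from counterion-mediation gaps, and
direct-sum electric-field grids.

Distances are reduced (sigma = 1) unless noted; conversions to nm go
through units.UnitSystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import brentq, curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .builder import minimum_image

__all__ = [
    "RDFResult", "compute_rdf", "nearest_neighbor_count",
    "ClusterResult", "find_clusters", "cluster_time_series",
    "surface_gap_statistics", "BeltAnalysisResult", "belt_charge_density",
    "belt_width_from_gaps", "exact_belt_width", "FieldGrid",
    "electric_field_grid", "planarity_ratio", "unwrap_cluster",
    "sigmoid_fit_quality",
]


# ---------------------------------------------------------------------------
# RDF and coordination
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray                  # bin centres
    g: np.ndarray                  # g(r)
    coordination: np.ndarray       # running n(r) = integral 4 pi rho r^2 g
    density: float                 # number density of the partner species
    n_frames: int
    species: tuple = ("all", "all")


def _frame_positions(frames):
    """Accepts an iterable of (positions, box) tuples or Frame objects."""
    for f in frames:
        if hasattr(f, "positions"):
            yield f.positions, f.box
        else:
            yield f


def compute_rdf(frames, bin_width: float = 0.05, r_max: float | None = None,
                species: tuple = ("all", "all"),
                selector=None) -> RDFResult:
    """Frame-averaged radial distribution function of one particle set.

    ``frames`` is a sequence of (positions, box) pairs (or engine Frames);
    ``selector`` optionally maps a frame to the (M, 3) positions to
    correlate (e.g. macroion centres).  Normalisation is by ideal-gas shell
    counts at the frame's mean density; r_max defaults to (and may not
    exceed) half the minimum box length.
    """
    counts = None
    n_frames = 0
    dens_acc = 0.0
    n_acc = 0.0
    for pos, box in _frame_positions(frames):
        if selector is not None:
            pos = selector(pos)
        box = np.asarray(box, dtype=float) * np.ones(3)
        half = float(box.min()) / 2.0
        if r_max is None:
            r_max = half
        if r_max > half + 1e-9:
            raise ValueError(f"r_max {r_max} exceeds half box {half}")
        edges = np.arange(0.0, r_max + bin_width, bin_width)
        m = len(pos)
        if m < 2:
            raise ValueError("need at least two particles for an RDF")
        iu, ju = np.triu_indices(m, k=1)
        dr = minimum_image(pos[iu] - pos[ju], box)
        d = np.linalg.norm(dr, axis=1)
        h, _ = np.histogram(d, bins=edges)
        counts = h if counts is None else counts + h
        n_frames += 1
        dens_acc += m / float(np.prod(box))
        n_acc += m
    if n_frames == 0:
        raise ValueError("no frames supplied")
    density = dens_acc / n_frames
    n_mean = n_acc / n_frames
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = shell * density * n_mean / 2.0     # expected pair count per bin
    g = counts / (ideal * n_frames)
    coord = np.cumsum(counts / n_frames) * 2.0 / n_mean
    return RDFResult(r=centres, g=g, coordination=coord, density=density,
                     n_frames=n_frames, species=species)


def nearest_neighbor_count(rdf: RDFResult, smooth_window: int = 7,
                           min_peak_height: float = 1.5,
                           min_coordination: float = 0.5) -> tuple[float, bool]:
    """Coordination number under the first two RDF peaks.

    Integrates 4 pi rho r^2 g(r) from zero to the first minimum after the
    second peak.  Peaks/minima are found on a Savitzky-Golay smoothed g(r)
    by derivative sign changes; peaks must exceed ``min_peak_height`` and
    enclose at least ``min_coordination`` neighbours to count as structure
    (sparse-statistics g(r) spikes in dilute systems are not shells).
    Returns (count, found): an unassembled system yields (0.0, False).
    """
    g = rdf.g
    if len(g) < smooth_window:
        return 0.0, False
    win = smooth_window if smooth_window % 2 else smooth_window + 1
    gs = signal.savgol_filter(g, win, 3)
    peaks, _ = signal.find_peaks(gs, height=min_peak_height)
    if len(peaks) == 0:
        return 0.0, False
    # first minimum after the second peak (or after the first if only one)
    last_peak = peaks[1] if len(peaks) > 1 else peaks[0]
    minima, _ = signal.find_peaks(-gs)
    after = minima[minima > last_peak]
    if len(after) == 0:
        return 0.0, False
    cut = after[0]
    count = float(rdf.coordination[cut])
    if count < min_coordination:
        return 0.0, False
    return count, True


# ---------------------------------------------------------------------------
# clusters and gaps
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray             # cluster id per macroion
    sizes: np.ndarray              # size of each cluster
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def mean_size(self) -> float:
        return float(self.sizes.mean())

    @property
    def max_size(self) -> int:
        return int(self.sizes.max())


def find_clusters(centers, radii, box, cutoff: float = 2.0) -> ClusterResult:
    """Single-linkage clusters of macroions by surface-to-surface distance.

    Two macroions are linked when |r_ij| - R_i - R_j <= cutoff (minimum
    image).  ``radii`` may be a scalar or per-macroion array.
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    box = np.asarray(box, dtype=float) * np.ones(3)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(minimum_image(centers[iu] - centers[ju], box), axis=1)
    linked = d - radii[iu] - radii[ju] <= cutoff
    adj = coo_matrix((np.ones(linked.sum()), (iu[linked], ju[linked])),
                     shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return ClusterResult(labels=labels, sizes=sizes, cutoff=cutoff)


def cluster_time_series(frames_centers, radii, box, cutoff: float = 2.0):
    """Per-frame cluster count / mean size / max size (pandas DataFrame)."""
    import pandas as pd
    rows = []
    for i, centers in enumerate(frames_centers):
        c = find_clusters(centers, radii, box, cutoff)
        rows.append({"frame": i, "n_clusters": c.n_clusters,
                     "mean_size": c.mean_size, "max_size": c.max_size})
    return pd.DataFrame(rows)


def surface_gap_statistics(centers, radii, box, cutoff: float = 2.0):
    """Nearest surface-to-surface gap per clustered macroion.

    For each macroion belonging to a cluster of size >= 2, the gap to its
    nearest clustered neighbour: |r_ij| - R_i - R_j.  Returns a dict with
    'gaps' (array), 'mean' and 'found'; systems with no clustered pair
    return found=False.
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    box = np.asarray(box, dtype=float) * np.ones(3)
    res = find_clusters(centers, radii, box, cutoff)
    gaps = []
    for i in range(n):
        if res.sizes[res.labels[i]] < 2:
            continue
        mates = np.flatnonzero((res.labels == res.labels[i]) &
                               (np.arange(n) != i))
        d = np.linalg.norm(minimum_image(centers[mates] - centers[i], box),
                           axis=1) - radii[mates] - radii[i]
        gaps.append(d.min())
    gaps = np.array(gaps)
    if len(gaps) == 0:
        return {"gaps": gaps, "mean": np.nan, "found": False}
    return {"gaps": gaps, "mean": float(gaps.mean()), "found": True}


# ---------------------------------------------------------------------------
# belt geometry
# ---------------------------------------------------------------------------

@dataclass
class BeltAnalysisResult:
    axis: np.ndarray
    belt_width: float
    belt_area: float
    rest_area: float
    charges_in_belt: int
    charges_outside: int
    belt_density: float
    rest_density: float
    percent_difference: float      # 100*(rho_belt/rho_rest - 1)
    flagged_infinite: bool = False


def belt_charge_density(template, axis, belt_width: float) -> BeltAnalysisResult:
    """Charge-density contrast of the spherical belt zone vs the rest.

    The belt is the spherical zone |r . axis| <= belt_width/2 (inclusive
    boundary); its area is the exact zone area 2 pi R w.  Densities are
    charges per area; the percent difference is 100*(rho_belt/rho_rest-1).
    """
    r = template.radius
    if belt_width >= 2.0 * r:
        raise ValueError("belt width must be smaller than the diameter")
    if template.n_charged == 0:
        raise ValueError("template carries no charges")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    charged = template.positions[template.charges != 0]
    z = charged @ axis
    in_belt = int(np.count_nonzero(np.abs(z) <= belt_width / 2.0 + 1e-12))
    outside = len(charged) - in_belt
    belt_area = 2.0 * np.pi * r * belt_width
    rest_area = 4.0 * np.pi * r * r - belt_area
    rho_b = in_belt / belt_area
    rho_r = outside / rest_area
    if outside == 0:
        return BeltAnalysisResult(axis, belt_width, belt_area, rest_area,
                                  in_belt, outside, rho_b, rho_r,
                                  np.inf, flagged_infinite=True)
    pct = 100.0 * (rho_b / rho_r - 1.0)
    return BeltAnalysisResult(axis, belt_width, belt_area, rest_area,
                              in_belt, outside, rho_b, rho_r, pct)


def belt_width_from_gaps(equilibrium_gap: float, mediation_gap: float,
                         radius: float) -> float:
    """Belt width from the two-sphere parabolic gap approximation.

    For two equal spheres of radius R at closest surface gap g0, the
    surface separation a lateral distance y off the contact axis is
    approximately g0 + y^2/R; counterions mediate attraction out to a gap
    g_m, so the mediating band has half-width sqrt((g_m - g0) R) and
    width = 2 sqrt((g_m - g0) R).
    """
    if mediation_gap <= equilibrium_gap:
        raise ValueError("mediation gap must exceed the equilibrium gap")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * np.sqrt((mediation_gap - equilibrium_gap) * radius)


def exact_belt_width(equilibrium_gap: float, mediation_gap: float,
                     radius: float) -> float:
    """Root-found exact counterpart of belt_width_from_gaps.

    Solves for the lateral offset y at which the true gap between the two
    sphere surfaces (distance from the mid-plane point at height y to the
    nearer sphere centre, minus R, doubled) equals the mediation gap.
    """
    r = radius
    d = 2.0 * r + equilibrium_gap      # centre-centre distance

    def gap(y):
        return 2.0 * (np.hypot(d / 2.0, y) - r) - mediation_gap

    return 2.0 * brentq(gap, 0.0, 2.0 * r)


# ---------------------------------------------------------------------------
# electric field
# ---------------------------------------------------------------------------

@dataclass
class FieldGrid:
    points: np.ndarray             # (M, 3)
    field: np.ndarray              # (M, 3)
    magnitude: np.ndarray          # (M,)
    masked: np.ndarray             # (M,) bool, True = too close to a charge
    shape: tuple | None = None


def electric_field_grid(points, charge_positions, charges, box, k_q: float,
                        exclusion_radius: float = 0.25,
                        shape=None) -> FieldGrid:
    """Minimum-image direct-sum electric field on a set of grid points.

    E(x) = sum_i k_q q_i (x - x_i)/|x - x_i|^3.  Points within
    ``exclusion_radius`` of any charge are masked (field set to NaN), not
    allowed to poison neighbouring values.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    box = np.asarray(box, dtype=float) * np.ones(3)
    cp = np.asarray(charge_positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    live = q != 0
    cp, q = cp[live], q[live]
    e = np.zeros_like(points)
    masked = np.zeros(len(points), dtype=bool)
    for start in range(0, len(points), 4096):
        sl = slice(start, start + 4096)
        dr = minimum_image(points[sl, None, :] - cp[None, :, :], box)
        r = np.linalg.norm(dr, axis=-1)
        masked[sl] = np.any(r < exclusion_radius, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = k_q * q[None, :, None] * dr / (r ** 3)[..., None]
        e[sl] = np.nansum(np.where((r > 0)[..., None], contrib, 0.0), axis=1)
    e[masked] = np.nan
    mag = np.linalg.norm(e, axis=1)
    return FieldGrid(points=points, field=e, magnitude=mag, masked=masked,
                     shape=shape)


# ---------------------------------------------------------------------------
# morphology and kinetics helpers
# ---------------------------------------------------------------------------

def unwrap_cluster(centers, box, link_cutoff: float) -> np.ndarray:
    """Unwrap a connected set of points across periodic boundaries.

    Breadth-first traversal of the proximity graph (edges where the
    centre-centre minimum-image distance <= link_cutoff): each newly
    reached point is placed at the minimum image relative to its already
    unwrapped neighbour, so clusters larger than half the box are handled
    correctly.  Points not connected to the first component are unwrapped
    relative to the component's mean.
    """
    c = np.asarray(centers, dtype=float).copy()
    box = np.asarray(box, dtype=float) * np.ones(3)
    n = len(c)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(minimum_image(c[iu] - c[ju], box), axis=1)
    adj = [[] for _ in range(n)]
    for a, b in zip(iu[d <= link_cutoff], ju[d <= link_cutoff]):
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n, dtype=bool)
    for root in range(n):
        if seen[root]:
            continue
        if root > 0:
            ref = c[seen].mean(axis=0)
            c[root] = ref + minimum_image(c[root] - ref, box)
        seen[root] = True
        queue = [root]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if not seen[nb]:
                    c[nb] = c[cur] + minimum_image(c[nb] - c[cur], box)
                    seen[nb] = True
                    queue.append(nb)
    return c


def planarity_ratio(centers, box=None, link_cutoff: float | None = None) -> float:
    """Smallest/largest gyration-tensor eigenvalue of macroion centres.

    Near 0 for a flat (monolayer) aggregate, near 1 for an isotropic blob.
    If a box is given, centres are first unwrapped: by connectivity-graph
    traversal when ``link_cutoff`` is given (robust for aggregates larger
    than half the box), else by minimum image relative to the first
    centre.
    """
    c = np.asarray(centers, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float) * np.ones(3)
        if link_cutoff is not None:
            c = unwrap_cluster(c, box, link_cutoff)
        else:
            c = c[0] + minimum_image(c - c[0], box)
    c = c - c.mean(axis=0)
    gyr = c.T @ c / len(c)
    ev = np.linalg.eigvalsh(gyr)
    return float(ev[0] / ev[-1]) if ev[-1] > 0 else 1.0


def sigmoid_fit_quality(t, y):
    """R^2 of logistic vs linear fits to a growth curve.

    Returns (r2_logistic, r2_linear).  Used to quantify the sigmoidal
    character of cluster-growth kinetics.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def logistic(x, a, b, x0, k):
        return a + b / (1.0 + np.exp(-k * (x - x0)))

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    p0 = [y.min(), y.max() - y.min(), t[len(t) // 2], 4.0 / (t[-1] - t[0])]
    try:
        popt, _ = curve_fit(logistic, t, y, p0=p0, maxfev=20000)
        ss_log = float(np.sum((y - logistic(t, *popt)) ** 2))
    except RuntimeError:
        ss_log = ss_tot
    lin = np.polyfit(t, y, 1)
    ss_lin = float(np.sum((y - np.polyval(lin, t)) ** 2))
    r2 = lambda ss: 1.0 - ss / ss_tot if ss_tot > 0 else 0.0
    return r2(ss_log), r2(ss_lin)
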