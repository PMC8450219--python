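"""Generation of periodic 3D fiber networks with prescribed microstructure.

Collagen-gel-like networks are represented as periodic graphs: nodes are
fiber junctions, edges are straight free-fiber segments between adjacent
junctions.  Mechanical behavior of such networks is governed largely by
three geometric descriptors (Lindström-style reconstruction):

* **valency** — number of segments meeting at a node,
* **free-fiber length** — geometric segment length between junctions,
* **inter-fiber cosine** — cosine of the angle between each unordered
  pair of segments joining at a node, with both tangents pointing away
  from the node.

A network is built in two stages.  A periodic Voronoi tessellation of
random seed points provides a topologically sound initial graph
(tetravalent, fully connected).  Then simulated annealing displaces
nodes one at a time, accepting moves by the Metropolis rule against an
energy that penalizes squared bin-wise deviation of the descriptor
histograms from user-supplied targets.  Topology never changes during
annealing, so valency is set entirely by the seed tessellation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import Voronoi

from .periodic import PeriodicBox

SPECIFIC_VOLUME_COLLAGEN = 0.73  # ml/g, specific volume of hydrated collagen fibers
DEFAULT_FIBER_DIAMETER = 0.18  # μm

#: total Voronoi edge length per unit volume of a unit-intensity Poisson
#: point process (Meijering's constant), used to size seed counts.
_POISSON_VORONOI_EDGE_DENSITY = 5.832

# default histogram grids: integer valencies 1-10, 0.5 μm length bins,
# cosine bins of width 0.1 spanning [-1, 1]
VALENCY_BIN_EDGES = np.arange(0.5, 11.0, 1.0)
COSINE_BIN_EDGES = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


def length_bin_edges(max_length: float, width: float = 0.5) -> np.ndarray:
    """Length histogram edges from 0 to at least ``max_length`` (μm)."""
    n = max(2, int(np.ceil(max_length / width)) + 1)
    return np.arange(0.0, (n + 0.5) * width, width)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class NetworkGraph:
    """Periodic 3D fiber network.

    Attributes
    ----------
    box_lengths : (3,) float array
        Edge lengths ``L_i`` of the periodic box (μm).
    nodes : (n, 3) float array
        Node positions, each wrapped into ``[0, L_i)``.
    segments : (m, 2) int array
        Node index pairs ``(a, b)``.
    shifts : (m, 3) int array
        Periodic shift triple of endpoint ``b`` relative to ``a``: the
        segment vector is ``x_b + shift * L - x_a``.
    fiber_diameter : float
        Fiber diameter ``D_f`` (μm).
    provenance : dict
        Free-form metadata (seed, annealing settings, ...).
    """

    box_lengths: np.ndarray
    nodes: np.ndarray
    segments: np.ndarray
    shifts: np.ndarray
    fiber_diameter: float = DEFAULT_FIBER_DIAMETER
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.box_lengths = np.asarray(self.box_lengths, float).reshape(3)
        self.nodes = np.asarray(self.nodes, float).reshape(-1, 3)
        self.segments = np.asarray(self.segments, int).reshape(-1, 2)
        self.shifts = np.asarray(self.shifts, int).reshape(-1, 3)
        if len(self.segments) != len(self.shifts):
            raise ValueError("segments and shifts must have equal length")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def box(self) -> PeriodicBox:
        return PeriodicBox(self.box_lengths)

    def segment_vectors(self) -> np.ndarray:
        """Segment vectors ``x_b + shift * L - x_a`` (m, 3)."""
        a = self.nodes[self.segments[:, 0]]
        b = self.nodes[self.segments[:, 1]]
        return b + self.shifts * self.box_lengths - a

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    @property
    def total_fiber_length(self) -> float:
        return float(self.segment_lengths().sum())

    def validate(self) -> None:
        """Raise ``ValueError`` on violated structural invariants."""
        if self.n_nodes == 0 or self.n_segments == 0:
            raise ValueError("empty network")
        if np.any(self.nodes < 0) or np.any(self.nodes >= self.box_lengths):
            raise ValueError("node coordinates must lie in [0, L_i)")
        if np.any(self.segments[:, 0] == self.segments[:, 1]):
            raise ValueError("self-loop segment present")
        key = {(int(a), int(b), *map(int, s)) for (a, b), s in zip(self.segments, self.shifts)}
        if len(key) != self.n_segments:
            raise ValueError("duplicate segments present")
        if np.any(self.segment_lengths() <= 0):
            raise ValueError("zero-length segment present")

    def copy(self) -> "NetworkGraph":
        return NetworkGraph(
            self.box_lengths.copy(),
            self.nodes.copy(),
            self.segments.copy(),
            self.shifts.copy(),
            self.fiber_diameter,
            dict(self.provenance),
        )


@dataclass
class DescriptorSnapshot:
    """Binned descriptor distributions of a network (probability mass per bin)."""

    valency_edges: np.ndarray
    valency_pmf: np.ndarray
    length_edges: np.ndarray
    length_hist: np.ndarray
    cosine_edges: np.ndarray
    cosine_hist: np.ndarray

    def _check(self) -> None:
        for edges, hist in (
            (self.valency_edges, self.valency_pmf),
            (self.length_edges, self.length_hist),
            (self.cosine_edges, self.cosine_hist),
        ):
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if abs(hist.sum() - 1.0) > 1e-9:
                raise ValueError("histogram mass must sum to 1")


@dataclass
class TargetDistributions:
    """Target descriptor distributions and their weights in the energy."""

    valency_edges: np.ndarray
    valency_pmf: np.ndarray
    length_edges: np.ndarray
    length_hist: np.ndarray
    cosine_edges: np.ndarray
    cosine_hist: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        for name in ("valency_edges", "valency_pmf", "length_edges",
                     "length_hist", "cosine_edges", "cosine_hist", "weights"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        self.validate()

    def validate(self) -> None:
        for edges, hist in (
            (self.valency_edges, self.valency_pmf),
            (self.length_edges, self.length_hist),
            (self.cosine_edges, self.cosine_hist),
        ):
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if len(hist) != len(edges) - 1:
                raise ValueError("histogram length must be len(edges) - 1")
            if np.any(hist < 0):
                raise ValueError("histogram mass must be non-negative")
            if abs(hist.sum() - 1.0) > 1e-9:
                raise ValueError("histogram mass must sum to 1")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 and not all zero")


@dataclass
class AnnealingSchedule:
    """Simulated-annealing schedule for the network reconstruction.

    Temperature is on the scale of the (dimensionless) descriptor energy;
    ``initial_temperature`` may be given as an absolute value or left at
    the default, in which case it is set to ``0.02 * E_initial`` at run
    time so that early sweeps accept moderate uphill moves.
    """

    initial_temperature: float | None = None
    cooling_factor: float = 0.97
    moves_per_sweep: int | None = None  # default: 160 * n_nodes
    max_sweeps: int = 240
    move_amplitude: float = 2.0  # μm, initial proposal amplitude
    final_move_amplitude: float | None = 0.03  # μm, geometric decay target
    min_segment_length: float = 0.2  # μm; moves creating shorter segments are rejected
    #: weight of the total-fiber-length conservation term
    #: ``w * (L_tot / L_ref - 1)**2`` added to the descriptor energy.
    #: Histograms alone underdetermine the geometry: unpenalized node
    #: shuffling accumulates slack length, which softens the network by
    #: orders of magnitude and drifts the collagen concentration away
    #: from the requested value.
    length_conservation_weight: float = 10.0
    energy_tolerance: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0 < self.cooling_factor <= 1):
            raise ValueError("cooling factor must be in (0, 1]")
        if self.move_amplitude <= 0:
            raise ValueError("move amplitude must be positive")


@dataclass
class AnnealingResult:
    network: NetworkGraph
    energy_trace: np.ndarray
    initial_energy: float
    final_energy: float
    n_accepted: int
    n_proposed: int
    converged: bool
    proposals: list | None = None  # (dE, T, accepted) per proposal when recorded


# ---------------------------------------------------------------------------
# Voronoi seeding
# ---------------------------------------------------------------------------


def voronoi_seed_network(
    n_seeds: int,
    box_lengths,
    rng_seed: int | np.random.Generator = 0,
    fiber_diameter: float = DEFAULT_FIBER_DIAMETER,
) -> NetworkGraph:
    """Periodic Voronoi edge graph of ``n_seeds`` uniform random seed points.

    The tessellation of the infinite periodic seed set is obtained by
    tessellating the 27 periodic images of the seeds and collecting every
    Voronoi cell edge with at least one endpoint in the central box.
    Generic Voronoi vertices in 3D join exactly four edges, so the seed
    network is tetravalent.
    """
    if n_seeds < 8:
        raise ValueError("need at least 8 seed points for a periodic tessellation")
    box = PeriodicBox(box_lengths)
    L = box.lengths
    rng = np.random.default_rng(rng_seed)
    seeds = rng.uniform(0.0, 1.0, size=(n_seeds, 3)) * L

    offsets = np.array(list(itertools.product((-1, 0, 1), repeat=3)), float)
    images = (seeds[None, :, :] + (offsets * L)[:, None, :]).reshape(-1, 3)
    vor = Voronoi(images)

    # collect unique Voronoi-cell edges (consecutive vertex pairs of each
    # finite ridge polygon)
    raw_edges: set[tuple[int, int]] = set()
    for poly in vor.ridge_vertices:
        if -1 in poly:
            continue
        for u, v in zip(poly, poly[1:] + poly[:1]):
            raw_edges.add((u, v) if u < v else (v, u))

    verts = vor.vertices
    wrapped, vshift = box.wrap(verts)

    # canonical periodic node ids: hash wrapped coordinates
    node_ids: dict[tuple, int] = {}
    node_pos: list[np.ndarray] = []

    def nid(k: int) -> int:
        key = tuple(np.round(wrapped[k] / L, 7))
        # snap coordinates exactly on the upper face to 0
        key = tuple(0.0 if abs(c - 1.0) < 1e-7 else c for c in key)
        if key not in node_ids:
            node_ids[key] = len(node_pos)
            node_pos.append(wrapped[k])
        return node_ids[key]

    inside = np.all((verts >= 0) & (verts < L), axis=1)
    seg_set: set[tuple] = set()
    for u, v in raw_edges:
        if not (inside[u] or inside[v]):
            continue
        i, j = nid(u), nid(v)
        s = vshift[v] - vshift[u]
        if i == j:
            continue  # drop self-loops (degenerate for very small seed sets)
        if i > j:
            i, j, s = j, i, -s
        seg_set.add((i, j, int(s[0]), int(s[1]), int(s[2])))

    if not seg_set:
        raise ValueError("tessellation produced no usable edges; too few seeds?")
    segs = np.array([(i, j) for i, j, *_ in sorted(seg_set)], int)
    shifts = np.array([s for *_, s0, s1, s2 in sorted(seg_set) for s in [(s0, s1, s2)]], int)

    used = np.unique(segs)
    remap = -np.ones(len(node_pos), int)
    remap[used] = np.arange(len(used))
    net = NetworkGraph(
        L,
        np.array(node_pos)[used],
        remap[segs],
        shifts,
        fiber_diameter,
        provenance={"generator": "voronoi", "n_seeds": n_seeds},
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def _incident_tangents(net: NetworkGraph) -> list[np.ndarray]:
    """Unit tangents of incident segments, pointing away from each node."""
    vec = net.segment_vectors()
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    tangents: list[list[np.ndarray]] = [[] for _ in range(net.n_nodes)]
    for k, (a, b) in enumerate(net.segments):
        tangents[a].append(unit[k])
        tangents[b].append(-unit[k])
    return [np.array(t) if t else np.empty((0, 3)) for t in tangents]


def node_valencies(net: NetworkGraph) -> np.ndarray:
    val = np.zeros(net.n_nodes, int)
    np.add.at(val, net.segments[:, 0], 1)
    np.add.at(val, net.segments[:, 1], 1)
    return val


def pair_cosines(net: NetworkGraph) -> np.ndarray:
    """Inter-fiber cosines for every unordered pair of segments at every node."""
    out = []
    for t in _incident_tangents(net):
        d = len(t)
        if d >= 2:
            g = t @ t.T
            iu = np.triu_indices(d, k=1)
            out.append(g[iu])
    if not out:
        return np.empty(0)
    return np.clip(np.concatenate(out), -1.0, 1.0)


def _mass_hist(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram as probability mass per bin; out-of-range values clamp to end bins."""
    if len(values) == 0:
        raise ValueError("cannot histogram an empty sample")
    lo, hi = edges[0], edges[-1]
    v = np.clip(values, lo + 1e-12, hi - 1e-12)
    counts, _ = np.histogram(v, bins=edges)
    return counts / counts.sum()


def compute_descriptors(
    net: NetworkGraph,
    bin_edges: Mapping[str, np.ndarray] | TargetDistributions | None = None,
) -> DescriptorSnapshot:
    """Valency / free-fiber length / inter-fiber cosine histograms of a network.

    ``bin_edges`` may be a mapping with keys ``valency``, ``length`` and
    ``cosine``, a :class:`TargetDistributions` (whose grids are reused),
    or ``None`` for the default grids.
    """
    if net.n_nodes == 0 or net.n_segments == 0:
        raise ValueError("empty network")
    if isinstance(bin_edges, TargetDistributions):
        ve, le, ce = bin_edges.valency_edges, bin_edges.length_edges, bin_edges.cosine_edges
    elif bin_edges is None:
        lengths = net.segment_lengths()
        ve, le, ce = VALENCY_BIN_EDGES, length_bin_edges(lengths.max()), COSINE_BIN_EDGES
    else:
        ve = np.asarray(bin_edges["valency"], float)
        le = np.asarray(bin_edges["length"], float)
        ce = np.asarray(bin_edges["cosine"], float)
    snap = DescriptorSnapshot(
        valency_edges=ve,
        valency_pmf=_mass_hist(node_valencies(net).astype(float), ve),
        length_edges=le,
        length_hist=_mass_hist(net.segment_lengths(), le),
        cosine_edges=ce,
        cosine_hist=_mass_hist(pair_cosines(net), ce),
    )
    snap._check()
    return snap


def descriptor_energy(snapshot: DescriptorSnapshot, targets: TargetDistributions) -> float:
    """Weighted sum of squared bin-wise histogram differences (dimensionless)."""
    for se, te in (
        (snapshot.valency_edges, targets.valency_edges),
        (snapshot.length_edges, targets.length_edges),
        (snapshot.cosine_edges, targets.cosine_edges),
    ):
        if len(se) != len(te) or not np.allclose(se, te):
            raise ValueError("snapshot and target bin edges differ")
    w = targets.weights
    return float(
        w[0] * np.sum((snapshot.valency_pmf - targets.valency_pmf) ** 2)
        + w[1] * np.sum((snapshot.length_hist - targets.length_hist) ** 2)
        + w[2] * np.sum((snapshot.cosine_hist - targets.cosine_hist) ** 2)
    )


# ---------------------------------------------------------------------------
# collagen concentration bookkeeping
# ---------------------------------------------------------------------------


def collagen_density(
    L_tot: float,
    D_f: float = DEFAULT_FIBER_DIAMETER,
    V_RVE: float = 245.0**3,
    v_c: float = SPECIFIC_VOLUME_COLLAGEN,
    use_quarter_factor: bool = False,
) -> float:
    """Average collagen mass density of the RVE in mg/ml.

    ``rho_c = L_tot * D_f**2 * pi / (V_RVE * v_c)``, with ``L_tot`` the
    summed fiber length (μm), ``D_f`` the fiber diameter (μm), ``V_RVE``
    the box volume (μm³) and ``v_c`` the specific volume of collagen
    (ml/g).  ``use_quarter_factor=True`` multiplies by 1/4 to use the
    true circular cross-section area ``pi D_f**2 / 4`` instead of the
    conventional ``pi D_f**2``.
    """
    if L_tot < 0:
        raise ValueError("total fiber length must be non-negative")
    if V_RVE <= 0 or v_c <= 0 or D_f <= 0:
        raise ValueError("V_RVE, v_c and D_f must be positive")
    rho_g_per_ml = L_tot * D_f**2 * np.pi / (V_RVE * v_c)
    if use_quarter_factor:
        rho_g_per_ml /= 4.0
    return float(rho_g_per_ml * 1e3)  # g/ml -> mg/ml


def required_total_length(
    rho_c: float,
    D_f: float = DEFAULT_FIBER_DIAMETER,
    V_RVE: float = 245.0**3,
    v_c: float = SPECIFIC_VOLUME_COLLAGEN,
    use_quarter_factor: bool = False,
) -> float:
    """Total fiber length (μm) yielding concentration ``rho_c`` (mg/ml)."""
    if rho_c < 0:
        raise ValueError("concentration must be non-negative")
    if V_RVE <= 0 or v_c <= 0 or D_f <= 0:
        raise ValueError("V_RVE, v_c and D_f must be positive")
    L = rho_c * 1e-3 * V_RVE * v_c / (D_f**2 * np.pi)
    if use_quarter_factor:
        L *= 4.0
    return float(L)


def seeds_for_concentration(rho_c: float, box_lengths, D_f: float = DEFAULT_FIBER_DIAMETER) -> int:
    """Voronoi seed count whose tessellation carries ``rho_c`` mg/ml of fiber.

    Uses the Poisson–Voronoi edge-length density ``5.832 * lambda**(2/3)``
    to invert the target total fiber length into a seed intensity.
    """
    box = PeriodicBox(box_lengths)
    L_tot = required_total_length(rho_c, D_f, box.volume)
    ell = L_tot / box.volume
    lam = (ell / _POISSON_VORONOI_EDGE_DENSITY) ** 1.5
    return max(8, int(round(lam * box.volume)))


# ---------------------------------------------------------------------------
# default collagen-gel targets
# ---------------------------------------------------------------------------


def collagen_gel_targets(
    mean_length: float,
    length_cv: float = 0.45,
    weights=(1.0, 1.0, 1.0),
) -> TargetDistributions:
    """Parametric collagen-gel-like target distributions.

    * valency: degenerate at 4 — the valency of a Voronoi seed network,
      which displacement-only annealing cannot change, and close to the
      3–4 connectivity reported for collagen gels;
    * free-fiber length: lognormal (right-skewed) with the given mean
      (μm) and coefficient of variation;
    * cosine: broad distribution with excess mass near −1, i.e. a
      tendency of fibers to continue straight through junctions.
    """
    ve = VALENCY_BIN_EDGES
    vp = np.zeros(len(ve) - 1)
    vp[3] = 1.0  # valency-4 bin

    le = length_bin_edges(4.0 * mean_length)
    sigma2 = np.log(1.0 + length_cv**2)
    mu = np.log(mean_length) - sigma2 / 2.0
    centers = 0.5 * (le[:-1] + le[1:])
    with np.errstate(divide="ignore"):
        dens = np.where(
            centers > 0,
            np.exp(-((np.log(np.maximum(centers, 1e-12)) - mu) ** 2) / (2 * sigma2))
            / np.maximum(centers, 1e-12),
            0.0,
        )
    lh = dens / dens.sum()

    ce = COSINE_BIN_EDGES
    cc = 0.5 * (ce[:-1] + ce[1:])
    cdens = 0.55 + np.exp(-((cc + 1.0) ** 2) / (2 * 0.45**2))
    ch = cdens / cdens.sum()

    return TargetDistributions(ve, vp, le, lh, ce, ch, np.asarray(weights, float))


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


class _DescriptorState:
    """Incrementally maintained descriptor histograms during annealing."""

    def __init__(
        self,
        net: NetworkGraph,
        targets: TargetDistributions,
        length_conservation_weight: float = 0.0,
    ):
        self.w_conc = float(length_conservation_weight)
        self.L = net.box_lengths
        self.pos = net.nodes.copy()
        self.segs = net.segments.copy()
        self.shifts = net.shifts.copy()
        self.targets = targets
        n = net.n_nodes

        self.incident: list[list[int]] = [[] for _ in range(n)]
        for k, (a, b) in enumerate(self.segs):
            self.incident[a].append(k)
            self.incident[b].append(k)
        self.neighbors: list[np.ndarray] = []
        for i in range(n):
            nb = {int(self.segs[k, 0]) + int(self.segs[k, 1]) - i for k in self.incident[i]}
            nb.discard(i)
            self.neighbors.append(np.array(sorted(nb), int))

        self.vec = self.pos[self.segs[:, 1]] + self.shifts * self.L - self.pos[self.segs[:, 0]]
        self.lengths = np.linalg.norm(self.vec, axis=1)
        self.L_tot = float(self.lengths.sum())
        self.L_ref = self.L_tot

        # fixed valency histogram (topology never changes)
        val = np.zeros(n, int)
        np.add.at(val, self.segs[:, 0], 1)
        np.add.at(val, self.segs[:, 1], 1)
        self.valency_pmf = _mass_hist(val.astype(float), targets.valency_edges)

        self.len_edges = targets.length_edges
        self.cos_edges = targets.cosine_edges
        self.len_counts = self._counts(self.lengths, self.len_edges)
        self.node_cos: list[np.ndarray] = [self._cosines_at(i) for i in range(n)]
        allcos = np.concatenate([c for c in self.node_cos if len(c)])
        self.cos_counts = self._counts(allcos, self.cos_edges)
        self.len_total = self.len_counts.sum()
        self.cos_total = self.cos_counts.sum()

    @staticmethod
    def _counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
        v = np.clip(values, edges[0] + 1e-12, edges[-1] - 1e-12)
        counts, _ = np.histogram(v, bins=edges)
        return counts.astype(float)

    def _tangents_at(self, i: int) -> np.ndarray:
        ks = self.incident[i]
        t = np.empty((len(ks), 3))
        for r, k in enumerate(ks):
            v = self.vec[k] / self.lengths[k]
            t[r] = v if self.segs[k, 0] == i else -v
        return t

    def _cosines_at(self, i: int) -> np.ndarray:
        t = self._tangents_at(i)
        d = len(t)
        if d < 2:
            return np.empty(0)
        g = np.clip(t @ t.T, -1.0, 1.0)
        return g[np.triu_indices(d, k=1)]

    def energy(self) -> float:
        w = self.targets.weights
        ev = np.sum((self.valency_pmf - self.targets.valency_pmf) ** 2)
        el = np.sum((self.len_counts / self.len_total - self.targets.length_hist) ** 2)
        ec = np.sum((self.cos_counts / self.cos_total - self.targets.cosine_hist) ** 2)
        econ = self.w_conc * (self.L_tot / self.L_ref - 1.0) ** 2
        return float(w[0] * ev + w[1] * el + w[2] * ec + econ)

    def try_move(self, i: int, delta: np.ndarray, min_len: float):
        """Tentatively displace node ``i``; return (dE, undo-record) or None."""
        ks = self.incident[i]
        new_vec = {}
        new_len = {}
        for k in ks:
            sgn = 1.0 if self.segs[k, 0] == i else -1.0
            v = self.vec[k] - sgn * delta
            l = float(np.linalg.norm(v))
            if l < min_len:
                return None
            new_vec[k], new_len[k] = v, l

        affected = [i, *self.neighbors[i]]
        old_cos = {j: self.node_cos[j] for j in affected}
        old_vecs = {k: self.vec[k].copy() for k in ks}
        old_lens = {k: self.lengths[k] for k in ks}

        # apply tentatively
        for k in ks:
            self.vec[k] = new_vec[k]
            self.lengths[k] = new_len[k]
        new_cos = {j: self._cosines_at(j) for j in affected}

        dlen = self._counts(np.array(list(new_len.values())), self.len_edges) - self._counts(
            np.array(list(old_lens.values())), self.len_edges
        )
        oc = np.concatenate([old_cos[j] for j in affected])
        nc = np.concatenate([new_cos[j] for j in affected])
        dcos = self._counts(nc, self.cos_edges) - self._counts(oc, self.cos_edges)

        dL = float(sum(new_len.values()) - sum(old_lens.values()))
        e_before = self.energy()
        self.len_counts += dlen
        self.cos_counts += dcos
        self.L_tot += dL
        e_after = self.energy()
        dE = e_after - e_before

        undo = (ks, old_vecs, old_lens, old_cos, dlen, dcos, dL)
        for j in affected:
            self.node_cos[j] = new_cos[j]
        return dE, undo

    def revert(self, undo) -> None:
        ks, old_vecs, old_lens, old_cos, dlen, dcos, dL = undo
        for k in ks:
            self.vec[k] = old_vecs[k]
            self.lengths[k] = old_lens[k]
        for j, c in old_cos.items():
            self.node_cos[j] = c
        self.len_counts -= dlen
        self.cos_counts -= dcos
        self.L_tot -= dL

    def commit_position(self, i: int, delta: np.ndarray) -> None:
        """Move the stored position, wrapping and re-shifting incident segments."""
        x = self.pos[i] + delta
        shift = np.floor(x / self.L).astype(int)
        self.pos[i] = x - shift * self.L
        if np.any(shift != 0):
            for k in self.incident[i]:
                if self.segs[k, 0] == i:
                    self.shifts[k] -= shift
                else:
                    self.shifts[k] += shift


def _uniform_width(edges: np.ndarray) -> float:
    widths = np.diff(edges)
    if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
        raise ValueError("annealing requires uniform histogram bins")
    return float(widths[0])


def run_simulated_annealing(
    net: NetworkGraph,
    targets: TargetDistributions,
    schedule: AnnealingSchedule | None = None,
    engine: str = "numba",
    record_proposals: bool = False,
) -> AnnealingResult:
    """Metropolis annealing of node positions toward the target descriptors.

    Single-node random displacements are accepted when they lower the
    energy and otherwise with probability ``exp(-dE / T)``; the
    temperature cools geometrically per sweep while the proposal
    amplitude shrinks geometrically from ``move_amplitude`` to
    ``final_move_amplitude``.  Topology (and hence the valency
    distribution) is unchanged.  Non-convergence is reported via the
    result's ``converged`` flag, never raised.

    ``engine`` selects the JIT-compiled loop (``"numba"``, default) or
    the pure-Python reference implementation (``"python"``); the two
    implement the same algorithm but draw different random streams.
    """
    schedule = schedule or AnnealingSchedule()
    schedule.validate()
    net.validate()
    targets.validate()
    moves_per_sweep = schedule.moves_per_sweep or 160 * net.n_nodes
    amp1 = schedule.final_move_amplitude or schedule.move_amplitude

    state = _DescriptorState(net, targets, schedule.length_conservation_weight)
    E0 = state.energy()
    T0 = schedule.initial_temperature if schedule.initial_temperature is not None else max(2e-3 * E0, 1e-12)

    if engine == "numba":
        from ._anneal import anneal_kernel

        inc_ptr = np.zeros(net.n_nodes + 1, np.int64)
        for a, b in state.segs:
            inc_ptr[a + 1] += 1
            inc_ptr[b + 1] += 1
        inc_ptr = np.cumsum(inc_ptr)
        inc_idx = np.empty(inc_ptr[-1], np.int64)
        cursor = inc_ptr[:-1].copy()
        for k, (a, b) in enumerate(state.segs):
            inc_idx[cursor[a]] = k
            cursor[a] += 1
            inc_idx[cursor[b]] = k
            cursor[b] += 1

        w = targets.weights
        e_val = float(w[0] * np.sum((state.valency_pmf - targets.valency_pmf) ** 2))
        len_w = _uniform_width(targets.length_edges)
        cos_w = _uniform_width(targets.cosine_edges)
        pos = state.pos.copy()
        shifts = state.shifts.copy().astype(np.int64)
        len_counts = state.len_counts.copy()
        cos_counts = state.cos_counts.copy()
        trace, n_acc, n_prop = anneal_kernel(
            pos,
            state.segs.astype(np.int64),
            shifts,
            net.box_lengths.astype(float),
            inc_ptr,
            inc_idx,
            targets.length_hist.astype(float),
            targets.cosine_hist.astype(float),
            float(w[1]),
            float(w[2]),
            e_val,
            float(targets.length_edges[0]),
            len_w,
            float(targets.cosine_edges[0]),
            cos_w,
            len_counts,
            cos_counts,
            float(schedule.length_conservation_weight),
            float(T0),
            float(schedule.cooling_factor),
            int(moves_per_sweep),
            int(schedule.max_sweeps),
            float(schedule.move_amplitude),
            float(amp1),
            float(schedule.min_segment_length),
            int(schedule.seed) % 2**31,
            float(schedule.energy_tolerance),
        )
        final_pos, final_shifts = pos, shifts
        E = float(trace[-1])
        trace = np.asarray(trace)
        proposals = None
    elif engine == "python":
        rng = np.random.default_rng(schedule.seed)
        E = E0
        T = T0
        trace_list = [E]
        n_acc = 0
        n_prop = 0
        n = net.n_nodes
        proposals: list[tuple[float, float, bool]] = []  # (dE, T, accepted)
        amps = np.geomspace(schedule.move_amplitude, amp1, max(schedule.max_sweeps, 1))
        for sweep in range(schedule.max_sweeps):
            amp = amps[sweep]
            for _ in range(moves_per_sweep):
                n_prop += 1
                i = int(rng.integers(n))
                delta = rng.uniform(-amp, amp, 3)
                res = state.try_move(i, delta, schedule.min_segment_length)
                if res is None:
                    continue
                dE, undo = res
                accepted = dE <= 0 or rng.random() < np.exp(-dE / T)
                if accepted:
                    state.commit_position(i, delta)
                    E += dE
                    n_acc += 1
                else:
                    state.revert(undo)
                if record_proposals:
                    proposals.append((dE, T, accepted))
            trace_list.append(E)
            T *= schedule.cooling_factor
            if E <= schedule.energy_tolerance:
                break
        trace = np.array(trace_list)
        final_pos, final_shifts = state.pos, state.shifts
    else:
        raise ValueError(f"unknown annealing engine: {engine!r}")

    out = NetworkGraph(
        net.box_lengths.copy(),
        final_pos,
        state.segs,
        final_shifts,
        net.fiber_diameter,
        provenance={
            **net.provenance,
            "annealing_seed": schedule.seed,
            "annealing_sweeps": len(trace) - 1,
        },
    )
    out.validate()
    return AnnealingResult(
        network=out,
        energy_trace=trace,
        initial_energy=E0,
        final_energy=E,
        n_accepted=int(n_acc),
        n_proposed=int(n_prop),
        converged=bool(E <= max(schedule.energy_tolerance, 1e-2 * E0)),
        proposals=proposals if record_proposals else None,
    )


def generate_network(
    concentration: float,
    box_lengths,
    rng_seed: int = 0,
    fiber_diameter: float = DEFAULT_FIBER_DIAMETER,
    schedule: AnnealingSchedule | None = None,
    targets: TargetDistributions | None = None,
) -> NetworkGraph:
    """End-to-end generation: seed count from concentration, Voronoi, anneal.

    The default length target is centered on the seed network's own mean
    free-fiber length (set by the seed intensity, which in turn is set by
    the requested concentration), so annealing reshapes the distributions
    without drifting the total fiber length, keeping the realized
    collagen concentration close to the request.
    """
    n_seeds = seeds_for_concentration(concentration, box_lengths, fiber_diameter)
    net = voronoi_seed_network(n_seeds, box_lengths, rng_seed, fiber_diameter)
    if targets is None:
        mean_len = net.total_fiber_length / net.n_segments
        targets = collagen_gel_targets(mean_len)
    if schedule is None:
        schedule = AnnealingSchedule(seed=rng_seed)
    result = run_simulated_annealing(net, targets, schedule)
    out = result.network
    out.provenance.update(
        concentration_request=concentration,
        concentration_realized=collagen_density(out.total_fiber_length, fiber_diameter, out.box.volume),
        final_energy=result.final_energy,
        initial_energy=result.initial_energy,
        rng_seed=rng_seed,
    )
    return out
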