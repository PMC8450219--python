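"""Stochastic fiber–fiber cross-linking: slip-bond kinetics and pair search.

Binding spots live on the fibers (here: the interior discretization
nodes of the beam mesh, so a bond can be anchored without remeshing).
When two unoccupied spots on distinct fibers come closer than a capture
interval, a bond forms as a Poisson event with on-rate ``k_on``; an
existing transient bond ruptures as a Poisson event whose off-rate grows
exponentially with the tensile force it carries (Bell slip bond):

    k_off(F) = k_off0 * exp(F * dx / (kB T))

``k_off0 = 0`` makes a bond covalent (permanent).  Each formed bond is a
short beam element that is stress-free in the configuration where it
formed — this is what lets cell-imposed network rearrangement become
entrenched as residual matrix tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mechanics import BeamMesh, BeamProperties, MechanicalState, add_crosslink_element, element_axial_force
from .periodic import PeriodicBox

BOLTZMANN_PN_UM = 1.380649e-5  # pN μm / K


@dataclass
class CrosslinkKinetics:
    """Kinetic constants of fiber–fiber bonds.

    ``k_off0 = 0`` models covalent (permanent) bonds.  The capture
    interval is matched to the binding-spot discretization: spots sit on
    beam-mesh nodes, so the interval is wider than a molecular-scale
    capture radius would be.
    """

    k_on: float = 0.01  # 1/s
    k_off0: float = 0.0  # 1/s; 0 => covalent
    delta_x: float = 4e-4  # μm (0.4 nm Bell parameter)
    kBT: float = BOLTZMANN_PN_UM * 310.0  # pN μm at body temperature
    d_min: float = 0.05  # μm
    d_max: float = 0.75  # μm

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off0 < 0:
            raise ValueError("rates must be non-negative")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive (slip bond)")
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("need 0 <= d_min < d_max")


def event_probability(k: float | np.ndarray, dt: float) -> float | np.ndarray:
    """Probability that a Poisson event with rate ``k`` fires within ``dt``."""
    k = np.asarray(k, float)
    if np.any(k < 0):
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = -np.expm1(-k * dt)
    return float(p) if p.ndim == 0 else p


def bell_off_rate(F: float | np.ndarray, kin: CrosslinkKinetics) -> float | np.ndarray:
    """Force-dependent slip-bond off-rate ``k_off0 * exp(F dx / kB T)``.

    Covalent bonds (``k_off0 = 0``) return exactly zero at any force;
    the exponent is capped to keep very large forces finite (the rate is
    then astronomically large either way).
    """
    F = np.asarray(F, float)
    if kin.k_off0 == 0.0:
        out = np.zeros_like(F)
    else:
        out = kin.k_off0 * np.exp(np.minimum(F * kin.delta_x / kin.kBT, 500.0))
    return float(out) if out.ndim == 0 else out


def candidate_pairs(
    positions: np.ndarray,
    fiber_ids: np.ndarray,
    occupied: np.ndarray,
    box: PeriodicBox,
    d_min: float,
    d_max: float,
) -> np.ndarray:
    """Unordered spot pairs on distinct fibers within the capture interval.

    Uses a fixed-radius KD-tree search on periodic images; the result is
    identical to a brute-force all-pairs minimum-image scan.  Returns an
    ``(n, 2)`` array of spot indices with ``i < j``.
    """
    positions = np.asarray(positions, float)
    n = len(positions)
    if n == 0:
        return np.empty((0, 2), int)
    L = box.current_lengths
    if d_max >= 0.5 * L.min():
        raise ValueError("capture interval exceeds half the box size")
    wrapped, _ = box.wrap(positions)
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), int)
    d = box.distance(wrapped[pairs[:, 0]], wrapped[pairs[:, 1]])
    keep = (
        (d >= d_min)
        & (fiber_ids[pairs[:, 0]] != fiber_ids[pairs[:, 1]])
        & ~occupied[pairs[:, 0]]
        & ~occupied[pairs[:, 1]]
    )
    out = pairs[keep]
    return out[np.lexsort((out[:, 1], out[:, 0]))]


@dataclass
class Crosslink:
    spot_a: int
    spot_b: int
    element_id: int
    formed_at: float
    active: bool = True
    dissolved_at: float | None = None


@dataclass
class CrosslinkRegistry:
    """Binding spots plus the set of runtime-formed cross-link bonds."""

    spot_nodes: np.ndarray  # mesh node id of each binding spot
    spot_fibers: np.ndarray  # owning network segment of each spot
    kinetics: CrosslinkKinetics = field(default_factory=CrosslinkKinetics)
    links: list[Crosslink] = field(default_factory=list)
    occupied: np.ndarray = field(default=None)  # type: ignore[assignment]
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.occupied is None:
            self.occupied = np.zeros(len(self.spot_nodes), bool)

    @classmethod
    def from_mesh(cls, mesh: BeamMesh, kinetics: CrosslinkKinetics | None = None) -> "CrosslinkRegistry":
        """Binding spots at all interior (non-junction) discretization nodes."""
        nodes, fibers = [], []
        for seg, chain in enumerate(mesh.segment_chains):
            for node in chain[1:-1]:
                nodes.append(int(node))
                fibers.append(seg)
        return cls(np.array(nodes, int), np.array(fibers, int), kinetics or CrosslinkKinetics())

    @property
    def n_active(self) -> int:
        return sum(1 for l in self.links if l.active)


def step_crosslinks(
    registry: CrosslinkRegistry,
    mesh: BeamMesh,
    state: MechanicalState,
    props: BeamProperties,
    dt: float,
    rng: np.random.Generator,
    time: float = 0.0,
) -> dict:
    """One stochastic step of bond formation and force-dependent rupture.

    Formation: every eligible spot pair draws an independent Bernoulli
    with ``p = 1 - exp(-k_on dt)`` in randomized order; the first success
    claims its spots (one bond per spot).  Rupture: every active
    transient bond draws against the Bell off-rate evaluated at the
    tensile part of its element's axial force.  Junction bonds of the
    original network never rupture.  Returns event counts.
    """
    kin = registry.kinetics
    n_formed = n_ruptured = 0

    # rupture of existing transient links
    if kin.k_off0 > 0:
        active = [l for l in registry.links if l.active]
        if active:
            eids = np.array([l.element_id for l in active])
            F = np.maximum(element_axial_force(mesh, state, eids), 0.0)
            p = event_probability(bell_off_rate(F, kin), dt)
            hits = rng.random(len(active)) < p
            for link, h, force in zip(active, hits, F):
                if h:
                    link.active = False
                    link.dissolved_at = time
                    mesh.alive[link.element_id] = False
                    registry.occupied[link.spot_a] = False
                    registry.occupied[link.spot_b] = False
                    registry.events.append(
                        {"time": time, "event": "rupture", "spot_a": link.spot_a,
                         "spot_b": link.spot_b, "force": float(force)}
                    )
                    n_ruptured += 1

    # formation on eligible pairs
    if kin.k_on > 0:
        box = PeriodicBox(mesh.box_lengths, state.stretch)
        pos = mesh.X[registry.spot_nodes] + state.u[registry.spot_nodes]
        pairs = candidate_pairs(pos, registry.spot_fibers, registry.occupied, box, kin.d_min, kin.d_max)
        if len(pairs):
            p_on = event_probability(kin.k_on, dt)
            order = rng.permutation(len(pairs))
            draws = rng.random(len(pairs)) < p_on
            for o in order:
                if not draws[o]:
                    continue
                a, b = map(int, pairs[o])
                if registry.occupied[a] or registry.occupied[b]:
                    continue
                eid = add_crosslink_element(
                    mesh, state, int(registry.spot_nodes[a]), int(registry.spot_nodes[b]), props
                )
                registry.links.append(Crosslink(a, b, eid, time))
                registry.occupied[a] = True
                registry.occupied[b] = True
                registry.events.append(
                    {"time": time, "event": "form", "spot_a": a, "spot_b": b, "force": 0.0}
                )
                n_formed += 1

    return {"formed": n_formed, "ruptured": n_ruptured, "active": registry.n_active}


def events_dataframe(registry: CrosslinkRegistry):
    """Event log as a pandas DataFrame (time, event, spot ids, force)."""
    import pandas as pd

    return pd.DataFrame(registry.events, columns=["time", "event", "spot_a", "spot_b", "force"])
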