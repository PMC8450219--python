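"""End-to-end simulation protocols: passive stiffness, homeostasis, RMT.

Every protocol follows the same quasi-static operator splitting: the
stochastic chemistry (stress-fiber contraction, integrin clutch events,
fiber–fiber cross-linking) advances by one time step, then the beam
network is re-equilibrated, then boundary stress is recorded.  The box
is held at stretch 1 with periodic boundary conditions in all directions
for the cell-seeded protocols; the uniaxial test stretches the box
incrementally on an acellular network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bonds import CrosslinkKinetics, CrosslinkRegistry, step_crosslinks
from .cells import (
    CellParams,
    CellSystem,
    build_cell_system,
    contract_stress_fibers,
    form_adhesions,
    seed_cells,
    sever_all_cell_bonds,
    step_clutches,
)
from .mechanics import (
    BeamMesh,
    BeamProperties,
    MechanicalState,
    apply_box_stretch,
    boundary_first_pk_stress,
    discretize,
    solve_equilibrium,
    young_modulus_from_test,
)
from .network import NetworkGraph, generate_network
from .periodic import PeriodicBox


def default_box_edge(concentration: float) -> float:
    """Desk-scale cubic box edge (μm) for a given collagen concentration.

    Chosen inversely with concentration (within 60–80 μm) so networks of
    different density have comparable segment counts and solver cost.
    """
    if concentration < 1.0:
        return 72.0
    if concentration < 2.0:
        return 64.0
    return 60.0


@dataclass
class SimulationConfig:
    """Parameters of a cell-seeded RVE simulation."""

    concentration: float = 1.5  # mg/ml collagen
    box_edge: float | None = None  # μm; None -> default_box_edge(concentration)
    cell_density: float = 0.5e6  # cells/ml
    dt: float = 0.5  # s, chemistry step; mechanics re-solved every step
    horizon: float = 240.0  # s
    seed: int = 0
    elements_per_segment: int = 2
    beam: BeamProperties = field(default_factory=BeamProperties)
    cell: CellParams = field(default_factory=CellParams)
    crosslinks: CrosslinkKinetics | None = None  # None -> no runtime cross-linking
    mechanics_tol: float = 1e-3  # pN
    record_every: int = 4  # record stress every this many steps
    network: NetworkGraph | None = None  # reuse a pre-generated network

    def resolved_box_edge(self) -> float:
        return self.box_edge if self.box_edge is not None else default_box_edge(self.concentration)


@dataclass
class TimeSeries:
    """Stress-over-time record of a protocol run."""

    times: np.ndarray
    stress: np.ndarray  # (n, 3) normal PK stress per axis, Pa
    events: pd.DataFrame
    telemetry: pd.DataFrame
    mesh: BeamMesh
    state: MechanicalState
    initial_state: MechanicalState
    cells: CellSystem | None = None
    crosslinks: CrosslinkRegistry | None = None
    flags: dict = field(default_factory=dict)

    @property
    def mean_stress(self) -> np.ndarray:
        """Mean of the three axial normal stresses (isotropic loading measure)."""
        return self.stress.mean(axis=1)


def _network_for(config: SimulationConfig) -> NetworkGraph:
    if config.network is not None:
        return config.network
    edge = config.resolved_box_edge()
    return generate_network(config.concentration, [edge] * 3, rng_seed=config.seed)


# ---------------------------------------------------------------------------
# passive stiffness
# ---------------------------------------------------------------------------


@dataclass
class UniaxialRecord:
    strain: np.ndarray
    stress: np.ndarray  # PK normal stress along the pull axis, Pa
    times: np.ndarray
    youngs_modulus: float
    converged: bool


def run_uniaxial_test(
    net: NetworkGraph,
    props: BeamProperties | None = None,
    max_strain: float = 0.01,
    n_steps: int = 5,
    elements_per_segment: int = 2,
    loading_rate: float = 0.01,  # μm/s, time bookkeeping only (quasi-static)
    tol: float = 1e-5,
    axis: int = 0,
) -> UniaxialRecord:
    """Quasi-static uniaxial stretch of an acellular network to ``max_strain``.

    The box is stretched along ``axis`` in equal increments with full
    re-equilibration; transverse box dimensions are held (periodic
    all-around).  Returns the stress–strain record and the fitted
    Young's modulus.
    """
    props = props or BeamProperties()
    if net.n_segments == 0:
        strain = np.linspace(0, max_strain, n_steps + 1)
        L = net.box_lengths[axis]
        return UniaxialRecord(strain, np.zeros_like(strain), strain * L / loading_rate, 0.0, True)
    mesh = discretize(net, elements_per_segment, props)
    state = MechanicalState.reference(mesh)
    strains = [0.0]
    stresses = [0.0]
    ok = True
    for eps in np.linspace(0, max_strain, n_steps + 1)[1:]:
        lam = np.ones(3)
        lam[axis] = 1.0 + eps
        apply_box_stretch(mesh, state, lam)
        solve_equilibrium(mesh, state, tol=tol, max_iterations=150)
        ok = ok and state.converged
        rec = boundary_first_pk_stress(mesh, state)
        strains.append(eps)
        stresses.append(rec.normal_stress[axis])
    strain = np.array(strains)
    stress = np.array(stresses)
    E = young_modulus_from_test(strain, stress)
    L = net.box_lengths[axis]
    return UniaxialRecord(strain, stress, strain * L / loading_rate, E, ok)


def power_law_fit(x: np.ndarray, y: np.ndarray) -> float:
    """Exponent of ``y ~ x**b`` by least squares in log–log space."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs positive data")
    A = np.vstack([np.log(x), np.ones_like(x)]).T
    b, _ = np.linalg.lstsq(A, np.log(y), rcond=None)[0]
    return float(b)


@dataclass
class StiffnessScan:
    concentrations_nominal: np.ndarray
    concentrations_realized: np.ndarray
    moduli: np.ndarray  # (n_conc, n_seeds)
    exponent: float


def stiffness_scan(
    concentrations=(0.8, 1.5, 2.5),
    seeds=(0, 1, 2),
    props: BeamProperties | None = None,
    box_edges=None,
    elements_per_segment: int = 2,
) -> StiffnessScan:
    """Young's modulus vs collagen concentration and its power-law exponent.

    Each concentration is simulated with several network seeds; the
    exponent is fitted against the realized (measured) concentrations of
    all individual networks.
    """
    props = props or BeamProperties()
    conc = np.asarray(concentrations, float)
    moduli = np.zeros((len(conc), len(seeds)))
    realized = np.zeros_like(moduli)
    for i, c in enumerate(conc):
        edge = box_edges[i] if box_edges is not None else default_box_edge(c)
        for j, s in enumerate(seeds):
            net = generate_network(c, [edge] * 3, rng_seed=s)
            realized[i, j] = net.provenance["concentration_realized"]
            rec = run_uniaxial_test(net, props, elements_per_segment=elements_per_segment)
            moduli[i, j] = rec.youngs_modulus
    exponent = power_law_fit(realized.ravel(), moduli.ravel())
    return StiffnessScan(conc, realized, moduli, exponent)


# ---------------------------------------------------------------------------
# homeostasis and residual matrix tension
# ---------------------------------------------------------------------------


def run_homeostasis(config: SimulationConfig, removal_time: float | None = None) -> TimeSeries:
    """Tension build-up in a fully constrained, cell-seeded RVE.

    Per chemistry step: stress fibers contract; integrin clutches bind /
    unbind and adhesions form; fiber–fiber cross-links form / rupture
    (when enabled); mechanics re-equilibrates; boundary stress is
    recorded.  The box is held at stretch 1 throughout.  With
    ``removal_time`` set, all cell–ECM bonds are dissolved at that time
    (``k_on^{c-f} = 0``) and the run continues — the residual-matrix-
    tension protocol.
    """
    rng = np.random.default_rng(config.seed + 1)
    net = _network_for(config)
    mesh = discretize(net, config.elements_per_segment, config.beam)
    box = PeriodicBox(net.box_lengths)
    centers = seed_cells(config.cell_density, box, rng, config.cell.radius)
    cellsys, particles = build_cell_system(centers, mesh, config.cell)
    state = MechanicalState.reference(mesh, particles)

    registry = None
    if config.crosslinks is not None:
        registry = CrosslinkRegistry.from_mesh(mesh, config.crosslinks)

    n_steps = int(round(config.horizon / config.dt))
    times = [0.0]
    stresses = [np.zeros(3)]
    removed = False

    solve_equilibrium(mesh, state, cellsys.springs, tol=config.mechanics_tol)
    for step in range(1, n_steps + 1):
        t = step * config.dt
        iters = 60
        if removal_time is not None and not removed and t >= removal_time:
            sever_all_cell_bonds(cellsys)
            removed = True
            # releasing every cellular force is a large perturbation:
            # give the quasi-static solver a bigger budget for this step
            iters = 400
        contract_stress_fibers(cellsys, config.dt)
        step_clutches(cellsys, mesh, state, config.dt, rng, time=t)
        form_adhesions(cellsys, mesh, state, config.dt, rng)
        if registry is not None:
            step_crosslinks(registry, mesh, state, config.beam, config.dt, rng, time=t)
        solve_equilibrium(
            mesh, state, cellsys.springs, tol=config.mechanics_tol, max_iterations=iters
        )
        if step % config.record_every == 0 or step == n_steps:
            rec = boundary_first_pk_stress(mesh, state, cellsys.springs, time=t)
            times.append(t)
            stresses.append(rec.normal_stress)

    events = (
        pd.DataFrame(registry.events, columns=["time", "event", "spot_a", "spot_b", "force"])
        if registry is not None
        else pd.DataFrame(columns=["time", "event", "spot_a", "spot_b", "force"])
    )
    telemetry = pd.DataFrame(cellsys.telemetry)
    return TimeSeries(
        times=np.array(times),
        stress=np.array(stresses),
        events=events,
        telemetry=telemetry,
        mesh=mesh,
        state=state,
        initial_state=MechanicalState.reference(mesh, particles),
        cells=cellsys,
        crosslinks=registry,
        flags={"removal_time": removal_time, "seed": config.seed},
    )


def run_rmt(config: SimulationConfig, removal_time: float) -> TimeSeries:
    """Residual-matrix-tension protocol: homeostasis, then cell-force removal.

    At ``removal_time`` every cell–ECM bond is dissolved and the on-rate
    set to zero; cross-link chemistry and mechanics continue.  The
    surviving boundary stress is the residual matrix tension, entrenched
    by cross-links formed while the cells were pulling.
    """
    if removal_time >= config.horizon:
        raise ValueError("removal_time must lie before the horizon")
    return run_homeostasis(config, removal_time=removal_time)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class PlateauStats:
    plateau: float
    time_to_plateau: float
    is_plateau: bool


def plateau_stats(times: np.ndarray, values: np.ndarray, window: float) -> PlateauStats:
    """Plateau level and the time at which the series settles onto it.

    The plateau is the mean over the final ``window`` seconds; the
    time-to-plateau is the earliest time from which the series stays
    within 5 % of that level.  A series still drifting across the final
    window (first vs second half differing by more than 5 %) is flagged
    as non-plateauing.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times[-1] - times[0] <= window:
        raise ValueError("series shorter than the averaging window")
    sel = times >= times[-1] - window
    plateau = float(values[sel].mean())
    half = times[sel] >= times[-1] - window / 2
    drift = abs(float(values[sel][half].mean()) - float(values[sel][~half].mean()))
    tolerance = 0.05 * max(abs(plateau), 1e-12)
    is_plateau = drift <= tolerance
    inside = np.abs(values - plateau) <= tolerance
    t_on = times[0]
    for i in range(len(times)):
        if inside[i:].all():
            t_on = times[i]
            break
    else:
        t_on = times[-1]
    return PlateauStats(plateau, float(t_on), bool(is_plateau))


@dataclass
class DisplacementField:
    magnitudes: np.ndarray  # per-node displacement magnitude, μm
    distances: np.ndarray  # per-node periodic distance to the cell center, μm
    peak: float  # max magnitude within the radius of interest
    profile_bins: np.ndarray
    profile: np.ndarray  # mean magnitude per distance bin


def cell_displacement_field(
    state_before: MechanicalState,
    state_after: MechanicalState,
    mesh: BeamMesh,
    center: np.ndarray,
    radius_of_interest: float,
    n_bins: int = 12,
) -> DisplacementField:
    """Matrix displacement magnitude around a cell between two states.

    The mean translation over all nodes is removed first (rigid-body
    gauge); distances use the periodic minimum image from the cell
    center in the reference configuration.
    """
    if state_before.u.shape != state_after.u.shape:
        raise ValueError("states live on different meshes")
    du = state_after.u - state_before.u
    du = du - du.mean(axis=0)
    mag = np.linalg.norm(du, axis=1)
    box = PeriodicBox(mesh.box_lengths)
    dist = box.distance(np.asarray(center, float), mesh.X)
    edges = np.linspace(0.0, max(radius_of_interest, dist.max()), n_bins + 1)
    prof = np.zeros(n_bins)
    for b in range(n_bins):
        sel = (dist >= edges[b]) & (dist < edges[b + 1])
        prof[b] = mag[sel].mean() if np.any(sel) else 0.0
    near = dist <= radius_of_interest
    peak = float(mag[near].max()) if np.any(near) else 0.0
    return DisplacementField(mag, dist, peak, edges, prof)


def ensemble_homeostasis(
    config: SimulationConfig, seeds, window: float | None = None
) -> tuple[list[TimeSeries], np.ndarray]:
    """Run the homeostasis protocol over several network seeds.

    Returns the runs plus the per-seed plateau stresses (mean of the
    three axial normal stresses over the final window).
    """
    window = window or max(config.horizon / 4, 4 * config.dt * config.record_every)
    runs = []
    plateaus = []
    for s in seeds:
        cfg = replace(config, seed=int(s))
        ts = run_homeostasis(cfg)
        runs.append(ts)
        plateaus.append(plateau_stats(ts.times, ts.mean_stress, window).plateau)
    return runs, np.array(plateaus)
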