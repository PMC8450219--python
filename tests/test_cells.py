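"""Cell agents: seeding, adhesion formation, molecular-clutch kinetics."""

import numpy as np
import pytest
from scipy.stats import binom

from fibernet.cells import (
    CatchSlipParams,
    CellParams,
    build_cell_system,
    catch_slip_off_rate,
    cell_count_for_density,
    contract_stress_fibers,
    eligible_adhesion_sites,
    form_adhesions,
    integrin_force,
    seed_cells,
    sever_all_cell_bonds,
    step_clutches,
)
from fibernet.fixtures import make_fixture
from fibernet.mechanics import BeamProperties, MechanicalState, discretize
from fibernet.periodic import PeriodicBox


# ---------------------------------------------------------------------------
# cell seeding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "density, expected",
    [(0.2e6, 3), (0.5e6, 8), (1.0e6, 15)],
)
def test_cell_count_at_reference_box(density, expected):
    """ceil(density x (245 μm)³) reproduces the 3 / 8 / 15 cells per RVE."""
    box = PeriodicBox([245.0] * 3)
    assert cell_count_for_density(density, box) == expected


def test_seed_cells_respects_minimum_distance(rng):
    box = PeriodicBox([200.0] * 3)
    centers = seed_cells(0.5e6, box, np.random.default_rng(1), radius=15.0)
    assert len(centers) == 4  # ceil(0.5e6 * 8e-6 ml)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            assert box.distance(centers[i], centers[j]) >= 30.0


def test_seed_cells_zero_density_and_overfull_box():
    box = PeriodicBox([40.0] * 3)
    assert len(seed_cells(0.0, box, np.random.default_rng(0))) == 0
    with pytest.raises(ValueError):
        seed_cells(1e9, box, np.random.default_rng(0), radius=15.0, max_tries=200)


# ---------------------------------------------------------------------------
# catch-slip kinetics
# ---------------------------------------------------------------------------


def test_catch_slip_lifetime_peaks_near_30_pN():
    p = CatchSlipParams()
    F = np.arange(0.0, 100.0001, 0.01)
    k = catch_slip_off_rate(F, p)
    assert np.all(k > 0)
    F_star = F[np.argmax(1.0 / k)]
    assert abs(F_star - 30.0) <= 5.0


def test_catch_slip_formula_and_clamp():
    p = CatchSlipParams()
    expected_b1 = p.a1 + p.a2 * np.exp(-(((p.b1 - p.b2) / p.c2) ** 2))
    # b1 < F_min, so evaluate at an explicit force above the clamp
    F = 20.0
    expected = p.a1 * np.exp(-(((F - p.b1) / p.c1) ** 2)) + p.a2 * np.exp(
        -(((F - p.b2) / p.c2) ** 2)
    )
    assert catch_slip_off_rate(F, p) == pytest.approx(expected, rel=1e-12)
    # low-force clamp: all forces below F_min share the F_min rate
    assert catch_slip_off_rate(0.0, p) == catch_slip_off_rate(p.F_min, p)
    assert catch_slip_off_rate(0.0, p) < p.a1 + p.a2  # clamped below the F=b1 peak value
    assert expected_b1 > 0


def test_integrin_force_sharing():
    assert integrin_force(60.0, 20) == pytest.approx(3.0)
    assert integrin_force(42.0, 1) == 42.0
    n = 7
    assert n * integrin_force(10.0, n) == pytest.approx(10.0)  # conservation
    with pytest.raises(ValueError):
        integrin_force(10.0, 0)


# ---------------------------------------------------------------------------
# adhesion sites and formation
# ---------------------------------------------------------------------------


def _cell_on_network(seed=0, params=None):
    net = make_fixture("small_voronoi", seed=seed)
    props = BeamProperties()
    mesh = discretize(net, 2, props)
    params = params or CellParams(radius=8.0, shell_halfwidth=2.0)
    sys_, centers = build_cell_system(np.array([[15.0, 15.0, 15.0]]), mesh, params)
    state = MechanicalState.reference(mesh, centers)
    return net, mesh, sys_, state


def test_eligible_sites_match_brute_force():
    net, mesh, sys_, state = _cell_on_network()
    sites = eligible_adhesion_sites(state.p[0], sys_.spots, mesh, state, sys_.params)
    box = PeriodicBox(mesh.box_lengths)
    R, dR = sys_.params.radius, sys_.params.shell_halfwidth
    brute = [
        i
        for i in range(mesh.n_nodes)
        if R - dR <= box.distance(state.p[0], mesh.X[i]) <= R + dR
    ]
    assert sites.tolist() == brute
    assert len(sites) > 0


def test_no_adhesions_with_zero_on_rate():
    net, mesh, sys_, state = _cell_on_network()
    sys_.k_on_override = 0.0
    n = form_adhesions(sys_, mesh, state, 1.0, np.random.default_rng(0))
    assert n == 0 and sys_.total_adhesions() == 0


def test_adhesion_cap_and_composition():
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=100.0, max_adhesions=65)
    net, mesh, sys_, state = _cell_on_network(params=params)
    rng = np.random.default_rng(2)
    for _ in range(30):
        form_adhesions(sys_, mesh, state, 1.0, rng)
    n_fa = sys_.total_adhesions()
    assert 0 < n_fa <= 65
    fa = sys_.cells[0].adhesions[0]
    # 50 clusters x up to 20 integrins = up to 1000 integrins per adhesion
    assert len(fa.clusters) == 50
    assert sys_.params.integrins_per_cluster == 20
    assert len(fa.clusters) * sys_.params.integrins_per_cluster == 1000
    # fresh clusters start with one bound integrin on a zero-force fiber
    assert all(cl.n_bonded == 1 for cl in fa.clusters)
    sid = fa.clusters[0].spring_id
    assert sys_.springs.l0[sid] > 0


def test_formation_frequency_binomial():
    """Per-site Bernoulli formation matches p = 1 - exp(-k dt) within 3 SE."""
    params = CellParams(radius=8.0, shell_halfwidth=2.0, k_on_cf=0.15, max_adhesions=10**6)
    net, mesh, sys_, state = _cell_on_network(params=params)
    sites = eligible_adhesion_sites(state.p[0], sys_.spots, mesh, state, params)
    n_sites = len(sites)
    p = 1 - np.exp(-params.k_on_cf * 1.0)
    trials = 400
    total = 0
    for t in range(trials):
        s2, centers = build_cell_system(state.p.copy(), mesh, params)
        st2 = MechanicalState.reference(mesh, centers)
        total += form_adhesions(s2, mesh, st2, 1.0, np.random.default_rng(t))
    n = trials * n_sites
    se = np.sqrt(n * p * (1 - p))
    assert abs(total - n * p) <= 3 * se


# ---------------------------------------------------------------------------
# contraction
# ---------------------------------------------------------------------------


def test_contraction_shortens_rest_length_at_given_rate():
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=100.0)
    net, mesh, sys_, state = _cell_on_network(params=params)
    form_adhesions(sys_, mesh, state, 1.0, np.random.default_rng(0))
    fa = sys_.cells[0].adhesions[0]
    sid = fa.clusters[0].spring_id
    l0_before = sys_.springs.l0[sid]
    dt = 0.7
    contract_stress_fibers(sys_, dt)
    assert sys_.springs.l0[sid] == pytest.approx(l0_before - 0.1 * dt)
    # tension-only: spring force is zero while end-to-end < rest length
    sys_.springs.l0[sid] = 1e3
    from fibernet.mechanics import assemble

    e, g, _ = assemble(mesh, state, sys_.springs, with_hessian=False)
    # all springs slack except those already shorter than their l0
    assert np.isfinite(e)
    # rest length never goes negative
    sys_.springs.l0[:] = 0.01
    contract_stress_fibers(sys_, 10.0)
    alive = [cl.spring_id for c in sys_.cells for f in c.adhesions for cl in f.clusters]
    assert np.all(sys_.springs.l0[alive] >= 0)


# ---------------------------------------------------------------------------
# clutch stepping
# ---------------------------------------------------------------------------


def test_cluster_dissolves_at_zero_bound_and_cap_respected():
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=5.0, reform_delay=np.inf)
    net, mesh, sys_, state = _cell_on_network(params=params)
    form_adhesions(sys_, mesh, state, 1.0, np.random.default_rng(1))
    rng = np.random.default_rng(3)
    for step in range(300):
        stats = step_clutches(sys_, mesh, state, 0.5, rng, time=step * 0.5)
        for cell in sys_.cells:
            for fa in cell.adhesions:
                for cl in fa.clusters:
                    assert 0 <= cl.n_bonded <= params.integrins_per_cluster
                    assert cl.alive == (cl.n_bonded > 0)


def test_zero_on_rate_decays_all_adhesions():
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=5.0)
    net, mesh, sys_, state = _cell_on_network(params=params)
    form_adhesions(sys_, mesh, state, 1.0, np.random.default_rng(1))
    assert sys_.total_adhesions() > 0
    sys_.k_on_override = 0.0
    rng = np.random.default_rng(4)
    counts = [sys_.total_adhesions()]
    for step in range(400):
        step_clutches(sys_, mesh, state, 0.5, rng, time=step * 0.5)
        counts.append(sys_.total_adhesions())
        if counts[-1] == 0:
            break
    assert counts[-1] == 0
    assert all(b <= a for a, b in zip(counts, counts[1:]))  # monotone decay


def test_sever_all_cell_bonds_removes_everything():
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=5.0)
    net, mesh, sys_, state = _cell_on_network(params=params)
    form_adhesions(sys_, mesh, state, 1.0, np.random.default_rng(1))
    sever_all_cell_bonds(sys_)
    assert sys_.total_adhesions() == 0
    assert not np.any(sys_.springs.alive)
    assert sys_.k_on == 0.0
    # nothing reforms afterwards
    n = form_adhesions(sys_, mesh, state, 10.0, np.random.default_rng(2))
    assert n == 0


def test_cluster_lifetime_matches_markov_oracle():
    """Simulated cluster lifetimes match the exact 21-state Markov chain.

    Conditions: slack stress fibers (forces at the low-force clamp) so
    the off-rate is constant, binding at k_on = 0.1 /s, dt = 0.5 s, no
    cluster re-formation.  The oracle computes the exact mean number of
    steps to absorption (all integrins unbound) starting from one bound
    integrin.
    """
    dt = 0.5
    params = CellParams(radius=8.0, shell_halfwidth=6.0, k_on_cf=0.1, reform_delay=np.inf)
    p_on = 1 - np.exp(-params.k_on_cf * dt)
    N = params.integrins_per_cluster
    p_off = 1 - np.exp(-catch_slip_off_rate(0.0, params.catch_slip) * dt)

    # exact absorbing Markov chain over bound counts 0..N
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    for n in range(1, N + 1):
        pl = binom.pmf(np.arange(0, n + 1), n, p_off)
        pg = binom.pmf(np.arange(0, N - n + 1), N - n, p_on)
        for l, a in enumerate(pl):
            for g, b in enumerate(pg):
                P[n, n - l + g] += a * b
    tau = np.linalg.solve(np.eye(N) - P[1:, 1:], np.ones(N))[0]

    net, mesh, sys_, state = _cell_on_network(params=params)
    rng = np.random.default_rng(7)
    lifetimes = []
    batch = 0
    while len(lifetimes) < 10_000:
        batch += 1
        form_adhesions(sys_, mesh, state, 100.0, rng)  # saturate eligible sites
        assert sys_.total_adhesions() > 0
        # keep direct references so clusters of dissolved adhesions are
        # still observed on the step they die
        tracked = [
            cl for cell in sys_.cells for fa in cell.adhesions for cl in fa.clusters
        ]
        recorded = [False] * len(tracked)
        step = 0
        while not all(recorded) and step < 3000:
            step += 1
            step_clutches(sys_, mesh, state, dt, rng, time=step * dt)
            for k, cl in enumerate(tracked):
                if not recorded[k] and not cl.alive:
                    lifetimes.append(step)
                    recorded[k] = True
        # reset for next batch
        for cell in sys_.cells:
            cell.adhesions = []
        sys_.spots.occupied[:] = False
        sys_.springs.alive[:] = False
    # average over complete batches only: cutting a batch short would
    # keep its early (short) lifetimes and bias the mean down
    assert len(lifetimes) >= 10_000
    mean = np.mean(lifetimes)
    assert mean == pytest.approx(tau, rel=0.05)


def test_integrin_turnover_is_seconds_scale():
    """Mean bound duration of a single integrin is O(seconds) under defaults."""
    p = CatchSlipParams()
    rates = catch_slip_off_rate(np.array([0.0, 10.0, 30.0, 60.0]), p)
    lifetimes = 1.0 / rates
    assert np.all(lifetimes >= 0.1)  # bracketing 0.1 x seconds
    assert np.all(lifetimes <= 10.0 * 60.0)  # ... to 10 x a minute
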