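"""Deterministic miniature systems for tests and demos.

Every fixture is generated programmatically from a seed — no data files.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkGraph, voronoi_seed_network
from .periodic import PeriodicBox


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic systems.

    ``single_fiber``
        One straight fiber spanning the box along axis 0 under
        periodicity (two collinear segments forming a closed periodic
        line).  Closed-form modulus: ``E = E_f A_fiber / A_box``.
    ``cross``
        Two perpendicular fibers whose midpoints are 0.4 μm apart — with
        two elements per segment the mid-nodes form exactly one
        cross-link candidate pair at the default capture interval.
    ``small_voronoi``
        A ~50-node periodic Voronoi network in a 30 μm box.
    ``two_cells``
        ``(network, centers)`` with two cell centers one cell diameter
        (30 μm) apart in a 60 μm box network.
    """
    if kind == "single_fiber":
        L = 20.0
        c = 10.0
        return NetworkGraph(
            [L] * 3,
            [[0.0, c, c], [c, c, c]],
            [[0, 1], [1, 0]],
            [[0, 0, 0], [1, 0, 0]],
            provenance={"fixture": kind, "seed": seed},
        )
    if kind == "cross":
        L = 20.0
        return NetworkGraph(
            [L] * 3,
            [
                [5.0, 10.0, 10.0],
                [15.0, 10.0, 10.0],  # fiber A along x
                [10.0, 5.0, 10.4],
                [10.0, 15.0, 10.4],  # fiber B along y, offset 0.4 in z
            ],
            [[0, 1], [2, 3]],
            [[0, 0, 0], [0, 0, 0]],
            provenance={"fixture": kind, "seed": seed},
        )
    if kind == "small_voronoi":
        return voronoi_seed_network(8, [30.0] * 3, rng_seed=seed)
    if kind == "two_cells":
        net = voronoi_seed_network(20, [60.0] * 3, rng_seed=seed)
        centers = np.array([[15.0, 30.0, 30.0], [45.0, 30.0, 30.0]])
        return net, centers
    raise ValueError(f"unknown fixture kind: {kind!r}")
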