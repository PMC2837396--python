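"""Shared fixtures and tiny morphology builders."""

from __future__ import annotations

import numpy as np
import pytest

from arborcost.core import ArborReconstruction, ReconNode, VertexSet


def make_recon(rows, cell_class="unspecified"):
    """Build a reconstruction from (id, kind, (x, y, z), radius, parent)."""
    nodes = [ReconNode(i, k, tuple(map(float, p)), float(r), par)
             for i, k, p, r, par in rows]
    return ArborReconstruction(nodes, cell_class=cell_class)


def straight_chain(points, kinds, radius=0.4):
    """A single unbranched chain of nodes through ``points``."""
    rows = []
    for i, (p, k) in enumerate(zip(points, kinds), start=1):
        rows.append((i, k, p, radius, None if i == 1 else i - 1))
    return make_recon(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def ring8():
    from arborcost.synthetic import ring_arbor

    return ring_arbor(8, 100.0)


@pytest.fixture
def cloud_vs(rng):
    """40 boutons uniform in a 200 µm cube, root at the centre."""
    pts = rng.uniform(-100, 100, size=(40, 3))
    return VertexSet(root=np.zeros(3), boutons=pts)


@pytest.fixture
def small_arbor():
    """Deterministic small synthetic arbor (reduced growth parameters)."""
    from arborcost.synthetic import SyntheticParams, generate_arbor

    params = SyntheticParams(
        cell_class="spiny",
        trunk_length=200.0,
        n_primary=3.0,
        primary_length_mean=300.0,
        primary_length_sd=60.0,
        interstitial_rate=0.008,
        rate_decay=0.9,
        length_decay=0.6,
        length_sd_frac=0.3,
        min_branch_length=30.0,
        max_depth=5,
        angle_mu=80.0,
        angle_sd=35.0,
        ibi_by_order=(12.0, 16.0, 30.0, 60.0),
        bouton_free_prob=(0.0, 0.1, 0.4, 0.9, 1.0),
        tip_overhang_mean=3.0,
        tip_overhang_sd=1.0,
        axon_radius=0.4,
        wm_tail_length=150.0,
    )
    return generate_arbor(params, 11)
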