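"""Shared fixtures: one moderately sized reference simulation reused by the
invariant tests, and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mtalign.geometry import build_cell_domain
from mtalign.simulator import SimParams, run_simulation


@pytest.fixture(scope="session")
def reference_run():
    """Full-rule run at e = 0.9 in the area-matched cell, default rates."""
    domain = build_cell_domain(492, 0.9, "area_matched")
    params = SimParams(rng_seed=42)
    return run_simulation(domain, params)


@pytest.fixture(scope="session")
def small_run():
    """Cheap run for log/structure checks."""
    domain = build_cell_domain(492, 0.8)
    params = SimParams(n_seeds=40, t_end=2.0, rng_seed=7)
    return run_simulation(domain, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
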