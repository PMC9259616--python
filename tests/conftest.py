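"""Shared fixtures.

The expensive simulation fixtures are session-scoped and shared across the
acceptance tests; problem sizes are scaled to single-CPU runtimes while
keeping the qualitative regimes (hundreds of nuclei, densities spanning all
three bins).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import blastosim as bs
from blastosim.pulling import SimConfig


@pytest.fixture(scope="session")
def sphere_domain() -> bs.EmbryoDomain:
    """A 600-um sphere-like ellipsoid, 20-um voxels (fast geometry queries)."""
    return bs.build_domain(bs.ShapeSpec(kind="ellipsoid", length_um=600, width_um=600), voxel_um=20)


@pytest.fixture(scope="session")
def small_capsule_domain() -> bs.EmbryoDomain:
    return bs.build_domain(
        bs.ShapeSpec(kind="capsule", length_um=800, width_um=300, first_division_frac=0.5),
        voxel_um=15,
    )


@pytest.fixture(scope="session")
def gryllus_scaled_config() -> SimConfig:
    """Scaled-down cricket run: 1200 x 450 um capsule, 15-um voxels, to 350 nuclei."""
    shape = bs.ShapeSpec(kind="capsule", length_um=1200, width_um=450, first_division_frac=0.6)
    return SimConfig(shape=shape, seed=11, voxel_um=15, n_start=4, n_end=350)


@pytest.fixture(scope="session")
def gryllus_scaled_run(gryllus_scaled_config):
    """One calibrated pulling run shared by the emergent-behavior tests."""
    domain = bs.build_domain(gryllus_scaled_config.shape, gryllus_scaled_config.voxel_um)
    mu = bs.calibrate_mobility(gryllus_scaled_config, domain)
    table = bs.run_simulation(dataclasses.replace(gryllus_scaled_config, mu=mu), domain)
    return {"table": table, "domain": domain, "mu": mu, "config": gryllus_scaled_config}


@pytest.fixture(scope="session")
def scaled_run_records(gryllus_scaled_run):
    return bs.per_record_metrics(gryllus_scaled_run["table"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
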