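"""Shared fixtures: small simulated movies reused across test modules.

Simulations are session-scoped because rendering + Poisson noise is the
dominant cost; individual tests must not mutate fixture results.
"""

from __future__ import annotations

import numpy as np
import pytest

from embryohub import RunConfig, SimConfig, run_dual, run_mcp, simulate_embryo_movie


# ~32 nuclei in the analyzed (second) cycle, 20-s frames, 63 frames total
MCP_SIM = SimConfig(
    shape=(256, 256),
    cycles=((4.0, 2.0), (13.0, 2.0)),
    n_initial_nuclei=16,
    channels=("polymerase", "mcp"),
    rng_seed=11,
)

DUAL_SIM = SimConfig(
    shape=(256, 256),
    cycles=((4.0, 2.0), (13.0, 2.0)),
    n_initial_nuclei=12,
    channels=("mcp", "pcp"),
    rng_seed=5,
)


@pytest.fixture(scope="session")
def mcp_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("mcp")
    config = RunConfig(pipeline="mcp", out_dir=str(out), sim=MCP_SIM, seed=11)
    return run_mcp(config)


@pytest.fixture(scope="session")
def dual_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("dual")
    config = RunConfig(pipeline="dual", out_dir=str(out), sim=DUAL_SIM, seed=5)
    return run_dual(config)


@pytest.fixture(scope="session")
def cdc7i_result(tmp_path_factory):
    import dataclasses

    out = tmp_path_factory.mktemp("cdc7i")
    sim = dataclasses.replace(MCP_SIM, preset="cdc7i")
    config = RunConfig(pipeline="mcp", out_dir=str(out), sim=sim, seed=11)
    return run_mcp(config)


HUB_SIM = SimConfig(
    shape=(256, 256),
    cycles=((5.0, 2.0), (7.0, 2.0), (9.0, 2.0)),
    n_initial_nuclei=6,
    channels=("bookmark", "kinase", "polymerase"),
    rng_seed=2,
)


@pytest.fixture(scope="session")
def hub_result(tmp_path_factory):
    from embryohub import run_hubdyn

    out = tmp_path_factory.mktemp("hub")
    config = RunConfig(pipeline="hubdyn", out_dir=str(out), sim=HUB_SIM, seed=2)
    return run_hubdyn(config)


@pytest.fixture(scope="session")
def noiseless_movie():
    """Tiny noise-free movie with known rendering for fidelity checks."""
    sim = SimConfig(
        shape=(128, 128),
        cycles=((3.0, 1.0),),
        n_initial_nuclei=3,
        channels=("bookmark", "polymerase", "mcp"),
        drift_px_per_frame=0.0,
        photon_scale=None,
        read_noise_sigma=0.0,
        rng_seed=7,
    )
    movie, truth = simulate_embryo_movie(sim)
    return sim, movie, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
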