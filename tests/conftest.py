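"""Shared fixtures: miniature benchmark networks, coarse look-up tables and
a 1 us reference run, all generated programmatically at session start."""

from __future__ import annotations

import numpy as np
import pytest

from spikesim import (BenchmarkSpec, IntegrationConfig, NeuronParameters,
                      build_benchmark, generate_poisson_train,
                      run_time_driven)
from spikesim.lut import GridSpec, compile_tables


@pytest.fixture(scope="session")
def lif_params():
    return NeuronParameters.lif()


@pytest.fixture(scope="session")
def adex_params():
    return NeuronParameters.adex()


@pytest.fixture(scope="session")
def hh_params():
    return NeuronParameters.hh()


# -- miniature networks ------------------------------------------------------
# size_factor 0.1 keeps per-neuron input in-degree (10 x 7 nS) identical to
# the full benchmark while shrinking layers to 100 + 400 (+ 400) neurons.

@pytest.fixture(scope="session")
def mini_table2():
    return build_benchmark(BenchmarkSpec(preset="table2", model="lif",
                                         seed=11, size_factor=0.1))


@pytest.fixture(scope="session")
def mini_table3():
    return build_benchmark(BenchmarkSpec(preset="table3", model="lif",
                                         seed=12, size_factor=0.1))


@pytest.fixture(scope="session")
def mini_input():
    """5 Hz Poisson input for the 100-relay miniature networks, 400 ms."""
    return generate_poisson_train(100, 5.0, 400.0, seed=13)


# -- look-up tables ----------------------------------------------------------

@pytest.fixture(scope="session")
def lif_tables(lif_params):
    """Coarse LIF tables (10 us compile micro-step, 50 ms horizon)."""
    return compile_tables("lif", lif_params, GridSpec.coarse("lif"))


@pytest.fixture(scope="session")
def lif_tables_fine(lif_params):
    """One doubling of every axis granularity over ``lif_tables``."""
    return compile_tables("lif", lif_params, GridSpec.coarse("lif", scale=2))


# -- reference run -----------------------------------------------------------

REFERENCE_DURATION = 200.0  # ms


@pytest.fixture(scope="session")
def mini_table3_reference(mini_table3, mini_input):
    """1 us fixed-step RK4 reference spike train on the miniature
    three-layer network (the accuracy yardstick)."""
    return run_time_driven(mini_table3, mini_input, REFERENCE_DURATION,
                           IntegrationConfig(method="fixed", step=1e-3))
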