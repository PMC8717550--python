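"""Shared fixtures: schemes, small simulated runs and full benchmark presets."""

import numpy as np
import pytest

from proteosig import (
    MixDesign,
    NoiseParams,
    ReporterChannelSet,
    build_window_scheme,
    emit_experiment,
    generate_truth,
    simulate_run,
)
from proteosig.pipeline import process_experiment


@pytest.fixture(scope="session")
def scheme():
    """The production 80-window scheme (400-800 m/z, 6 Th / 1 Th overlap)."""
    return build_window_scheme(400.0, 800.0, 6.0, 1.0, 8.0)


@pytest.fixture(scope="session")
def tmt10():
    return ReporterChannelSet.tmt10()


@pytest.fixture(scope="session")
def tmt11():
    return ReporterChannelSet.tmt11()


@pytest.fixture(scope="session")
def small_truth():
    """Small, fast ground truth (two human-like populations, 80-s gradient)."""
    return generate_truth(n_peptides=60, n_proteins=12, seed=11, gradient=80.0)


@pytest.fixture(scope="session")
def small_run(small_truth, scheme):
    """One short simulated TMT10 run (10 cycles x 80 windows)."""
    return simulate_run(
        small_truth, MixDesign.mix1(), scheme, gradient=80.0, seed=12, run_id="small"
    )


@pytest.fixture(scope="session")
def clean_noise():
    """Noise-free simulator settings (exact arithmetic checks)."""
    return NoiseParams(cv=0.0, floor=0.0, background_peaks=0, mz_jitter_ppm=0.0)


# full benchmark presets, shared by the acceptance tests -------------------

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def hk_experiment():
    return emit_experiment("helakq562_12runs", seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def hk_pipeline(hk_experiment):
    return process_experiment(hk_experiment)


@pytest.fixture(scope="session")
def tko_experiment():
    return emit_experiment("tko11_4runs", seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def tko_pipeline(tko_experiment):
    return process_experiment(tko_experiment)


@pytest.fixture(scope="session")
def combined_pipeline():
    exp = emit_experiment("combined_16runs", seed=ACCEPTANCE_SEED)
    return process_experiment(exp)
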