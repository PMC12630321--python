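"""Shared fixtures: small seeded synthetic objects reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

from adcfmri import physio, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def paradigm():
    return synth.generate_breathhold_paradigm()


@pytest.fixture(scope="session")
def breathhold_co2(paradigm):
    """Noise-free breath-hold CO2 recording with its ground truth."""
    return synth.generate_co2_trace(paradigm, seed=101)


@pytest.fixture(scope="session")
def resting_co2():
    return synth.generate_co2_trace(synth.RestingParadigm(300.0), seed=202)


@pytest.fixture(scope="session")
def breathhold_regressor(breathhold_co2):
    trace, _ = breathhold_co2
    return physio.process_co2(trace)


@pytest.fixture(scope="session")
def small_masks():
    return synth.default_masks((10, 10, 4))


@pytest.fixture(scope="session")
def bold_subject(breathhold_co2, small_masks):
    """One noisy BOLD run with GM latency 2 s / WM latency 4.5 s."""
    _, truth = breathhold_co2
    driver = synth.vascular_driver(truth)
    grid = (10, 10, 4)
    gt = synth.GroundTruth(
        vascular_amplitude=np.full(grid, 0.008),
        latency_field=np.where(small_masks["GM"], 2.0, 4.5),
        noise_sigma=25.0,
    )
    run = synth.generate_fmri_run(
        "BOLD", gt, driver, TR_s=1.0, n_vols=192, seed=7, masks=small_masks
    )
    return run, gt, driver


@pytest.fixture(scope="session")
def dfmri_noiseless(breathhold_co2, small_masks):
    """Noiseless interleaved diffusion run with T2 coupling, flat ADC."""
    _, truth = breathhold_co2
    driver = synth.vascular_driver(truth)
    grid = (10, 10, 4)
    gt = synth.GroundTruth(
        vascular_amplitude=np.full(grid, 0.006),
        latency_field=np.full(grid, 2.0),
        noise_sigma=0.0,
    )
    run = synth.generate_fmri_run(
        "dfMRI", gt, driver, TR_s=1.0, n_vols=192, seed=8, masks=small_masks
    )
    return run, gt, driver
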