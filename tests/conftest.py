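"""Shared fixtures.

The expensive simulation artefacts (10 s fibrillation records at 256^2,
the small-domain FK3 episode library) are session-scoped so the
dominant-period, spectrum-partition, dose-response and GA tests share
one integration each.
"""

from __future__ import annotations

import numpy as np
import pytest

from defibopt import GridSpec, load_parameter_set
from defibopt.adp import derive_adp_spec, mean_power_spectrum
from defibopt.episodes import (
    build_episode_library,
    estimate_dominant_period_from_record,
    make_fibrillation_ic,
    record_episode,
)

#: One fixed generation seed for the whole suite.
SEED = 11

#: Domain used for the scaled-down FK3 pacing studies.  FK3's short
#: dominant period keeps attempts cheap, and 160^2 is the smallest
#: domain on which its chaotic transients reliably outlive the
#: 5 x T_dom observation horizons used here.
SMALL_N = 160


def _episode_records(model: str):
    """Fibrillation IC plus a 10 s dual-rate (120 Hz / 100 Hz) record."""
    params = load_parameter_set(model)
    ic = make_fibrillation_ic(params, SEED, burn_in=2000.0)
    records, final = record_episode(params, ic, None, 10.0, (120.0, 100.0))
    return records, final


@pytest.fixture(scope="session")
def fk1_records():
    return _episode_records("FK1")


@pytest.fixture(scope="session")
def fk2_records():
    return _episode_records("FK2")


@pytest.fixture(scope="session")
def fk3_records():
    return _episode_records("FK3")


@pytest.fixture(scope="session")
def fk3_t_dom(fk3_records):
    records, _ = fk3_records
    return estimate_dominant_period_from_record(records[120.0], 120.0).t_dom


@pytest.fixture(scope="session")
def fk3_adp_spec(fk3_records):
    records, _ = fk3_records
    spectrum = mean_power_spectrum(records[100.0], sampling_ms=10.0)
    return derive_adp_spec(spectrum, cutoff_hz=33.0, n_pulses=5)


@pytest.fixture(scope="session")
def fk3_small_library(fk3_t_dom):
    """10 validated FK3 fibrillation ICs on the scaled-down domain."""
    grid = GridSpec(SMALL_N, SMALL_N)
    return build_episode_library(
        "FK3",
        n=10,
        seed=SEED,
        burn_in=1200.0,
        grid=grid,
        validate_ms=5.0 * fk3_t_dom,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
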