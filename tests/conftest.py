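"""Shared fixtures: desk-scale subjects and the seeded statistics battery.

Expensive simulated subjects are session-scoped so multiple tests reuse
them; everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from mibci.simulate import SimConfig, SubjectProfile, simulate_subject, default_profile

# small-but-realistic acquisition for fast tests: full montage and trial
# plan, reduced rate/duration
DESK = SimConfig(fs=64.0, epoch_s=1.5)


@pytest.fixture(scope="session")
def desk_config() -> SimConfig:
    return DESK


@pytest.fixture(scope="session")
def efficient_subject():
    prof = default_profile("efficient", "EFF", seed=101)
    return simulate_subject(prof, DESK)


@pytest.fixture(scope="session")
def inefficient_subject():
    prof = default_profile("inefficient", "INEFF", seed=202)
    return simulate_subject(prof, DESK)


@pytest.fixture(scope="session")
def nosignal_subject():
    prof = SubjectProfile("NULL", "efficient", erd_depth=0.0,
                          waveform_contrast=0.0, snr=0.0, seed=303)
    return simulate_subject(prof, DESK)


def statistics_battery():
    """20 fixed seeded samples of varying size and shape (n = 8..46)."""
    rng = np.random.default_rng(20240917)
    kinds = ["normal", "exponential", "uniform", "t3", "lognormal"]
    samples = []
    for i in range(20):
        n = 8 + 2 * i
        kind = kinds[i % 5]
        if kind == "normal":
            x = rng.normal(size=n)
        elif kind == "exponential":
            x = rng.exponential(size=n)
        elif kind == "uniform":
            x = rng.uniform(size=n)
        elif kind == "t3":
            x = rng.standard_t(3, size=n)
        else:
            x = rng.lognormal(size=n)
        samples.append(x)
    return samples
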