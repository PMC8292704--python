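"""Shared fixtures: simulated noiseless acquisitions reused across the
segmentation, sine-fit, envelope and acceptance tests (session-scoped —
the CBCT simulations are the expensive part of the suite)."""

from __future__ import annotations

import numpy as np
import pytest

from traj4d import (
    AcquisitionSpec,
    ImageGrid,
    MotionSpec,
    PhantomSpec,
    simulate_cbct,
    simulate_ct,
)
from traj4d.pipeline import default_cbct_grid, default_ct_grid

RECOVERY_EXCURSIONS = (5.0, 9.0, 14.0, 19.0)


@pytest.fixture(scope="session")
def cbct_sims():
    """Noiseless CBCT simulations (1 mm grid, T=5 s) keyed by excursion."""
    out = {}
    for e in RECOVERY_EXCURSIONS:
        m = MotionSpec(kind="sine", excursion=(e, 0.0, 0.0), cycle_time=5.0)
        out[e] = simulate_cbct(
            PhantomSpec(),
            m,
            AcquisitionSpec(modality="CBCT4D", grid=default_cbct_grid(), noise_sd=0.0),
        )
    return out


@pytest.fixture(scope="session")
def ct_sims():
    """Noiseless cine 4D CT simulations (2.5 mm slices, T=5 s)."""
    out = {}
    for e in RECOVERY_EXCURSIONS:
        m = MotionSpec(kind="sine", excursion=(e, 0.0, 0.0), cycle_time=5.0)
        out[e] = simulate_ct(
            PhantomSpec(),
            m,
            AcquisitionSpec(modality="CT4D", grid=default_ct_grid(), noise_sd=0.0),
        )
    return out


@pytest.fixture()
def small_grid():
    return ImageGrid((1.0, 1.0, 1.0), (-15.5, -15.5, -15.5), (32, 32, 32))
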