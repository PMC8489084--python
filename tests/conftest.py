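"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from tsmr import HarmonizedDataset, HarmonizedRecord, load_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vitd():
    return load_fixture("25OHD")


@pytest.fixture(scope="session")
def calcium():
    return load_fixture("calcium")


@pytest.fixture(scope="session")
def pth():
    return load_fixture("PTH")


def make_dataset(bx, by, sx=None, sy=None, name="X") -> HarmonizedDataset:
    """Build a harmonized dataset from plain beta/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.003) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full_like(bx, 0.03) if sy is None else np.asarray(sy, dtype=float)
    records = [
        HarmonizedRecord(
            rsid=f"rs{i + 1}",
            effect_allele="A",
            beta_exposure=float(bx[i]),
            se_exposure=float(sx[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(sy[i]),
        )
        for i in range(len(bx))
    ]
    return HarmonizedDataset(name, "Y", records)


@st.composite
def harmonized_datasets(draw, min_snps=3, max_snps=10):
    """Random small instrument sets with nonzero exposure betas."""
    k = draw(st.integers(min_snps, max_snps))
    sign = st.sampled_from([-1.0, 1.0])
    bx = [
        draw(sign) * draw(st.floats(0.01, 0.2, allow_nan=False))
        for _ in range(k)
    ]
    if max(bx) - min(bx) < 0.01:  # keep the Egger design well-conditioned
        bx[0] = bx[0] + (0.05 if bx[0] > 0 else -0.05)
    by = [draw(st.floats(-0.2, 0.2, allow_nan=False)) for _ in range(k)]
    sx = [draw(st.floats(1e-3, 0.02, allow_nan=False)) for _ in range(k)]
    sy = [draw(st.floats(5e-3, 0.1, allow_nan=False)) for _ in range(k)]
    return make_dataset(bx, by, sx, sy)
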