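"""Shared fixtures: the heavy reference simulations are session-scoped so
the eight PDE runs and the TF profiles are computed once per test session."""

from __future__ import annotations

import numpy as np
import pytest

from spinalgrn.signaling import DomainGrid, simulate_signaling, signaling_preset, PRESET_COLUMNS
from spinalgrn.tfnet import TFParams, assemble_spatial_profile, extract_domains


@pytest.fixture(scope="session")
def grid() -> DomainGrid:
    return DomainGrid()


@pytest.fixture(scope="session")
def preset_fields(grid):
    """Signaling fields for all eight Hill-constant preset columns."""
    return {col: simulate_signaling(signaling_preset(col), grid)
            for col in PRESET_COLUMNS}


@pytest.fixture(scope="session")
def balance(preset_fields):
    """The FGF-RA balance field (preset II), the reference TF input."""
    return preset_fields["II"]


@pytest.fixture(scope="session")
def control_profile(balance):
    """TF spatial profile under curated Hill constants, unperturbed."""
    return assemble_spatial_profile(balance, TFParams())


@pytest.fixture(scope="session")
def control_domains(control_profile):
    return extract_domains(control_profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
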