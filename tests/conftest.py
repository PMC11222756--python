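"""Shared fixtures: fully processed mock communities reused across tests."""

from __future__ import annotations

import pytest

from lerayhap import simulate
from lerayhap.pipeline import MockBranchResult, run_mock_stages


@pytest.fixture(scope="session")
def mock_run() -> MockBranchResult:
    """Seeded study-scale mock community pushed through the whole mock branch."""
    return run_mock_stages(simulate.default_mock_community(seed=1, depth=1500))


@pytest.fixture(scope="session")
def clean_mock_run() -> MockBranchResult:
    """Error-free, jump-free, chimera-free community (exact-recovery oracle)."""
    return run_mock_stages(
        simulate.default_mock_community(
            seed=2, depth=300, per_base_error_rate=0.0, tag_jump_rate=0.0, chimera_rate=0.0
        )
    )
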