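"""Shared fixtures: small synthetic tables generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dysbiome.synthetic import separated_alpha_matrix, simulate_dmm_counts


@pytest.fixture(scope="session")
def separated_fixture():
    """Well-separated 3-component DMM draw: (table, 1-based labels, alpha)."""
    alpha = separated_alpha_matrix(3, 25)
    table, labels = simulate_dmm_counts(
        alpha, [0.4, 0.35, 0.25], 300, (2000, 10000), seed=11
    )
    return table, labels, alpha


@pytest.fixture(scope="session")
def single_component_fixture():
    """Counts from one symmetric Dirichlet(5) component at fixed depth."""
    alpha = np.full((1, 10), 5.0)
    table, _ = simulate_dmm_counts(alpha, [1.0], 500, (5000, 5000), seed=7)
    return table, alpha
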