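"""Shared test helpers: random tree generation and a deterministic hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_binary_newick(
    rng: np.random.Generator,
    labels: list[str],
    with_lengths: bool = True,
) -> str:
    """Random rooted binary topology over ``labels`` by sequential joining."""
    nodes = list(labels)
    if with_lengths:
        nodes = [f"{lab}:{rng.uniform(0.1, 2.0):.4f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        merged = f"({left},{right})"
        if with_lengths and len(nodes) > 0:
            merged += f":{rng.uniform(0.1, 2.0):.4f}"
        nodes.append(merged)
    return nodes[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
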