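"""Shared fixtures and the independent naive-simulation oracle."""

from __future__ import annotations

import pytest

from macpol import (
    BooleanNetwork,
    fixture_catalog,
    parse_rules,
)
from macpol.expr import eval_expr


# ---------------------------------------------------------------------------
# naive oracle: one-state-at-a-time pure-Python simulation, independent of
# the bit-parallel engine

def naive_step(net: BooleanNetwork, state: int) -> int:
    env = {name: bool((state >> i) & 1)
           for i, name in enumerate(net.node_names)}
    out = 0
    for i, name in enumerate(net.node_names):
        if name in net.clamps:
            bit = net.clamps[name]
        else:
            bit = 1 if eval_expr(net.functions[name], env) else 0
        out |= bit << i
    return out


def naive_attractor(net: BooleanNetwork, state: int):
    """(canonical cycle tuple, transient length) by dict-based walking."""
    seen = {}
    trail = []
    s = state
    while s not in seen:
        seen[s] = len(trail)
        trail.append(s)
        s = naive_step(net, s)
    cycle = trail[seen[s]:]
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:] + cycle[:k]), seen[s]


def naive_landscape(net: BooleanNetwork) -> dict[tuple, int]:
    """Map canonical cycle -> basin size over every free initial state."""
    free = [i for i, n in enumerate(net.node_names) if n not in net.clamps]
    clamp_bits = sum(net.clamps.get(n, 0) << i
                     for i, n in enumerate(net.node_names))
    basins: dict[tuple, int] = {}
    for idx in range(1 << len(free)):
        full = clamp_bits
        for j, i in enumerate(free):
            full |= ((idx >> j) & 1) << i
        cyc, _ = naive_attractor(net, full)
        basins[cyc] = basins.get(cyc, 0) + 1
    return basins


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture
def toggle():
    return parse_rules("targets, factors\nA, !B\nB, !A")


@pytest.fixture
def identity1():
    return parse_rules("targets, factors\nA, A")
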