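import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macpol import (
    Attractor,
    ClampSet,
    CompiledNetwork,
    NetworkError,
    apply_clamps,
    attractors_of_states,
    exhaustive_attractors,
    parse_rules,
    step,
    trajectory_to_attractor,
)
from macpol.synthetic import RandomNetSpec, random_network
from tests.conftest import naive_landscape, naive_attractor


def as_dict(landscape):
    return {a.states: a.basin_size for a in landscape.attractors}


# -- step -------------------------------------------------------------------

def test_step_toggle(toggle):
    assert step(toggle, 0b00) == 0b11
    assert step(toggle, 0b11) == 0b00
    assert step(toggle, 0b01) == 0b01


def test_step_identity_is_fixed():
    net = parse_rules("targets, factors\nA, A\nB, B\nC, C")
    for s in range(8):
        assert step(net, s) == s


def test_step_constant_zero():
    net = parse_rules("targets, factors\nA, 0\nB, 0")
    for s in range(4):
        assert step(net, s) == 0


def test_step_respects_clamps(toggle):
    clamped = apply_clamps(toggle, ClampSet({"A": 1}))
    assert step(clamped, 0b01) == 0b01  # B = !A = 0, A stays 1


# -- trajectories -----------------------------------------------------------

def test_trajectory_toggle_fixed_point(toggle):
    att, transient = trajectory_to_attractor(toggle, 0b01)
    assert att.states == (0b01,)
    assert transient == 0


def test_trajectory_toggle_cycle(toggle):
    att, transient = trajectory_to_attractor(toggle, 0b00)
    assert att.states == (0b00, 0b11)
    assert att.period == 2
    assert transient == 0


def test_trajectory_transient_length():
    net = parse_rules("targets, factors\nA, 0\nB, 0")
    att, transient = trajectory_to_attractor(net, 0b11)
    assert att.states == (0,)
    assert transient == 1
    assert trajectory_to_attractor(net, 0)[1] == 0


def test_attractor_canonical_rotation():
    a = Attractor(states=(5, 2, 9))
    assert a.states == (2, 9, 5)
    assert a.key == 2


# -- exhaustive enumeration -------------------------------------------------

def test_exhaustive_identity1(identity1):
    ls = exhaustive_attractors(identity1)
    assert as_dict(ls) == {(0,): 1, (1,): 1}


def test_exhaustive_toggle(toggle):
    ls = exhaustive_attractors(toggle)
    assert as_dict(ls) == {(1,): 1, (2,): 1, (0, 3): 2}


def test_fixtures_match_stored_vectors(catalog):
    for name, fx in catalog.items():
        ls = exhaustive_attractors(fx.net)
        assert as_dict(ls) == fx.expected, name


def test_exhaustive_matches_naive_oracle_random_nets():
    for seed in range(25):
        n = 4 + seed % 8
        net = random_network(RandomNetSpec(n, 2, 0.5, seed=seed))
        assert as_dict(exhaustive_attractors(net)) == naive_landscape(net)


def test_exhaustive_with_clamps_matches_oracle():
    for seed in (1, 5, 9):
        net = random_network(RandomNetSpec(7, 2, 0.5, seed=seed))
        clamped = apply_clamps(net, ClampSet({"n0": 1, "n3": 0}))
        ls = exhaustive_attractors(clamped)
        assert ls.free_node_count == 5
        assert ls.total_states == 32
        assert as_dict(ls) == naive_landscape(clamped)
        # clamp bits present in every attractor state
        for att in ls.attractors:
            for s in att.states:
                assert s & 1 == 1
                assert (s >> 3) & 1 == 0


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 10),
       k=st.integers(0, 3), p=st.floats(0.1, 0.9))
def test_basin_conservation_property(seed, n, k, p):
    net = random_network(RandomNetSpec(n, min(k, n), p, seed=seed))
    ls = exhaustive_attractors(net)
    assert ls.basin_total() == ls.total_states == 2 ** n
    # attractor state sets pairwise disjoint
    seen = set()
    for att in ls.attractors:
        assert not (set(att.states) & seen)
        seen |= set(att.states)
        assert att.basin_size >= att.period


def test_determinism_identical_landscapes():
    net = random_network(RandomNetSpec(10, 2, 0.5, seed=42))
    a = exhaustive_attractors(net)
    b = exhaustive_attractors(net)
    assert [x.states for x in a.attractors] == [x.states for x in b.attractors]
    assert [x.basin_size for x in a.attractors] == \
           [x.basin_size for x in b.attractors]
    keys = [x.key for x in a.attractors]
    assert keys == sorted(keys)


def test_free_node_cap_enforced():
    net = random_network(RandomNetSpec(12, 2, 0.5, seed=0))
    with pytest.raises(NetworkError, match="cap"):
        exhaustive_attractors(net, free_node_cap=10)


def test_attractors_of_states_matches_naive():
    net = random_network(RandomNetSpec(9, 2, 0.5, seed=7))
    states = list(range(0, 512, 7))
    res = attractors_of_states(net, states)
    for s, att in zip(states, res):
        assert att.states == naive_attractor(net, s)[0]


def test_landscape_table_export(toggle):
    ls = exhaustive_attractors(toggle)
    df = ls.to_table()
    assert set(df.columns) >= {"attractor", "period", "basin_size", "A", "B"}
    assert df["basin_size"].nunique() <= 2
    # one row per attractor state: 1 + 1 + 2
    assert len(df) == 4


def test_step_batch_agrees_with_step(toggle):
    cn = CompiledNetwork(toggle)
    batch = cn.step_batch(np.arange(4))
    assert list(batch) == [step(toggle, s) for s in range(4)]


def test_landscape_json_dump_roundtrip(toggle):
    import json
    ls = exhaustive_attractors(toggle)
    blob = json.loads(json.dumps(ls.to_dict()))
    assert blob["node_names"] == ["A", "B"]
    assert blob["total_states"] == 4
    assert sum(a["basin_size"] for a in blob["attractors"]) == 4
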