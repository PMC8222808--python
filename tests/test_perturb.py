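import math

import pytest

from macpol import (
    ClampSet,
    NetworkError,
    apply_clamps,
    exhaustive_attractors,
    load_macrophage_model,
    parse_rules,
)
from macpol.perturb import (
    BREAST_CANCER_SCENARIOS,
    GAINED,
    LOST,
    MICROENVIRONMENTS,
    STGEM_CLAMPS,
    TGEM_CLAMPS,
    basin_log2_foldchange,
    breast_cancer_scenarios,
    build_stgem,
    build_tgem,
    microenvironment_landscape,
    single_node_scan,
)
from macpol.phenotypes import PhenotypeRule


RULES_A = [PhenotypeRule.from_text("M1", "A")]
RULES_L = [PhenotypeRule.from_text("M1", "L")]


@pytest.fixture
def small_net():
    # 4-node net with some structure: input I, latch L, slaves
    return parse_rules(
        "targets, factors\nI, I\nL, (I | L) & !K\nK, 0\nO, L")


def test_foldchange_identical_is_zero(toggle):
    ls = exhaustive_attractors(toggle)
    res = basin_log2_foldchange(ls, ls, RULES_A)
    assert res.foldchange
    assert all(v == 0.0 for v in res.foldchange.values())


def test_foldchange_doubling():
    wt = exhaustive_attractors(parse_rules("targets, factors\nA, A\nB, B"))
    # clamp B: basins halve per label mass? construct explicit landscapes
    pert = exhaustive_attractors(
        apply_clamps(parse_rules("targets, factors\nA, A\nB, B"),
                     ClampSet({"B": 0})))
    res = basin_log2_foldchange(wt, pert, RULES_A)
    # wt: A=1 mass 2, pert: A=1 mass 1 -> log2(1/2) = -1
    assert res.foldchange["M1"] == pytest.approx(-1.0)


def test_foldchange_lost_and_gained(toggle):
    wt = exhaustive_attractors(toggle)
    pert = exhaustive_attractors(apply_clamps(toggle, ClampSet({"A": 0})))
    res = basin_log2_foldchange(wt, pert, RULES_A)
    # with A=0 the only attractor is A=0,B=1 -> label M0; M1 mass lost
    assert res.foldchange["M1"] == LOST
    fc = basin_log2_foldchange(pert, wt, RULES_A)
    assert fc.foldchange["M1"] == GAINED


def test_foldchange_antisymmetry(small_net):
    wt = exhaustive_attractors(small_net)
    pert = exhaustive_attractors(apply_clamps(small_net, ClampSet({"I": 1})))
    rules = [PhenotypeRule.from_text("M1", "L"),
             PhenotypeRule.from_text("M2b", "O")]
    fwd = basin_log2_foldchange(wt, pert, rules).foldchange
    rev = basin_log2_foldchange(pert, wt, rules).foldchange
    assert set(fwd) == set(rev)
    for key, v in fwd.items():
        if isinstance(v, float):
            assert rev[key] == pytest.approx(-v)
        else:
            assert {v, rev[key]} == {GAINED, LOST}


def test_foldchange_per_attractor_mode(small_net):
    wt = exhaustive_attractors(small_net)
    pert = exhaustive_attractors(apply_clamps(small_net, ClampSet({"I": 0})))
    res = basin_log2_foldchange(wt, pert, per_attractor=True)
    assert any(isinstance(k, tuple) for k in res.foldchange)


# -- scans ------------------------------------------------------------------

def test_scan_completeness(small_net):
    wt = exhaustive_attractors(small_net)
    ko = single_node_scan(small_net, "knockout", wt_landscape=wt,
                         rules=RULES_L)
    oe = single_node_scan(small_net, "overexpress", wt_landscape=wt,
                         rules=RULES_L)
    assert len(ko) == len(oe) == small_net.n_nodes
    for res in ko + oe:
        assert res.landscape.free_node_count == small_net.n_nodes - 1
        assert res.landscape.basin_total() == 2 ** (small_net.n_nodes - 1)


def test_scan_mode_validation(small_net):
    with pytest.raises(NetworkError):
        single_node_scan(small_net, "delete")


def test_overexpress_clamped_constant_idempotent():
    net = apply_clamps(parse_rules("targets, factors\nA, A\nB, !A"),
                       ClampSet({"A": 1}))
    res = single_node_scan(net, "overexpress", nodes=["A"])
    # A already clamped to 1: scan result equals the unperturbed landscape
    assert res[0].landscape.free_node_count == 1
    base = exhaustive_attractors(net)
    assert [a.states for a in res[0].landscape.attractors] == \
           [a.states for a in base.attractors]


def test_knockout_of_irrelevant_node_keeps_labels():
    # K is constant 0 and never active; knocking it out changes nothing
    net = parse_rules("targets, factors\nI, I\nL, (I | L) & !K\nK, 0\nO, L")
    wt = exhaustive_attractors(net)
    rules = [PhenotypeRule.from_text("M1", "L | O")]
    res = single_node_scan(net, "knockout", wt_landscape=wt, rules=rules,
                          nodes=["K"])[0]
    # same label spectrum: nothing lost, nothing gained
    assert all(isinstance(v, float) for v in res.foldchange.values())


# -- microenvironments ------------------------------------------------------

def test_microenvironment_clamp_sets():
    assert MICROENVIRONMENTS["Pro-M0"] == {}
    assert MICROENVIRONMENTS["Pro-M1"] == {"IFNG": 1, "IFNB": 1}
    assert MICROENVIRONMENTS["Pro-M2a"] == {"IL4": 1, "TGFB": 1}
    assert MICROENVIRONMENTS["Pro-M2b"] == {"IGG": 1, "GCGCR": 1}
    assert MICROENVIRONMENTS["Pro-M2c"] == {"IL10": 1, "IL6": 1, "MCSF": 1}
    assert MICROENVIRONMENTS["Pro-M2d"] == \
        {"A2A": 1, "HYPOXIA": 1, "GCGCR": 1}


def test_unknown_microenvironment_lists_valid_names(small_net):
    with pytest.raises(NetworkError, match="Pro-M1"):
        microenvironment_landscape(small_net, "Pro-M9")


def test_tgem_stgem_clamp_sets():
    assert TGEM_CLAMPS.assignments == {"NFKB": 1, "HIF1A": 0}
    assert STGEM_CLAMPS.assignments == {"STAT1": 1, "HIF1A": 0}


def test_scenario_definitions():
    assert len(BREAST_CANCER_SCENARIOS) == 4
    assert set(map(frozenset, BREAST_CANCER_SCENARIOS.values())) == {
        frozenset({"IGG", "A2A"}), frozenset({"IL10", "TGFB"}),
        frozenset({"IL1B", "IL6"}), frozenset({"HYPOXIA", "GCGCR"})}
    assert all(v == 1 for spec in BREAST_CANCER_SCENARIOS.values()
               for v in spec.values())


def test_scenario_conflicting_clamp_is_error():
    net = load_macrophage_model()
    bad = apply_clamps(net, ClampSet({"NFKB": 1, "HIF1A": 0, "IGG": 0}))
    with pytest.raises(NetworkError, match="conflicting"):
        breast_cancer_scenarios(bad, free_node_cap=30)


def test_tgem_free_node_count():
    net = load_macrophage_model()
    assert apply_clamps(net, TGEM_CLAMPS).free_node_count == 27
    assert apply_clamps(net, STGEM_CLAMPS).free_node_count == 27
    pro_m1 = apply_clamps(
        net, ClampSet(dict(MICROENVIRONMENTS["Pro-M1"])))
    assert pro_m1.free_node_count == 27
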