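"""Perturbation analyses: knockout/overexpression scans, label-level basin
fold-changes, microenvironment simulations, TGEM/STGEM construction, and the
four simplified breast-cancer scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import Landscape, exhaustive_attractors
from .network import BooleanNetwork, ClampSet, NetworkError, apply_clamps
from .phenotypes import PhenotypeRule, label_landscape

__all__ = [
    "PerturbationResult",
    "GAINED",
    "LOST",
    "single_node_scan",
    "basin_log2_foldchange",
    "microenvironment_landscape",
    "MICROENVIRONMENTS",
    "TGEM_CLAMPS",
    "STGEM_CLAMPS",
    "BREAST_CANCER_SCENARIOS",
    "build_tgem",
    "build_stgem",
    "breast_cancer_scenarios",
]

GAINED = "gained"
LOST = "lost"

#: Extracellular clamp sets emulating phenotype-adjuvant milieus.
MICROENVIRONMENTS: dict[str, dict[str, int]] = {
    "Pro-M0": {},
    "Pro-M1": {"IFNG": 1, "IFNB": 1},
    "Pro-M2a": {"IL4": 1, "TGFB": 1},
    "Pro-M2b": {"IGG": 1, "GCGCR": 1},
    "Pro-M2c": {"IL10": 1, "IL6": 1, "MCSF": 1},
    "Pro-M2d": {"A2A": 1, "HYPOXIA": 1, "GCGCR": 1},
}

TGEM_CLAMPS = ClampSet({"NFKB": 1, "HIF1A": 0}, label="TGEM")
STGEM_CLAMPS = ClampSet({"STAT1": 1, "HIF1A": 0}, label="STGEM")

#: Simplified breast-cancer microenvironments layered on top of the TGEM.
BREAST_CANCER_SCENARIOS: dict[str, dict[str, int]] = {
    "IgG+A2a": {"IGG": 1, "A2A": 1},
    "IL10+TGFb": {"IL10": 1, "TGFB": 1},
    "IL1b+IL6": {"IL1B": 1, "IL6": 1},
    "Hypoxia+GC": {"HYPOXIA": 1, "GCGCR": 1},
}


@dataclass(frozen=True)
class PerturbationResult:
    """A perturbed landscape, optionally scored against a reference.

    ``foldchange`` maps phenotype label -> log2 basin ratio, or the status
    flags :data:`GAINED` / :data:`LOST`; it is ``None`` when no reference
    landscape was supplied.
    """

    perturbation: ClampSet
    landscape: Landscape
    foldchange: dict[str, float | str] | None = None
    reference: str = ""

    def to_table(self):
        import pandas as pd
        rows = [{"perturbation": self.perturbation.label, "label": lab,
                 "log2fc": val if isinstance(val, float) else None,
                 "flag": val if isinstance(val, str) else ""}
                for lab, val in (self.foldchange or {}).items()]
        return pd.DataFrame(rows)


def _label_basins(landscape: Landscape,
                  rules: list[PhenotypeRule] | None) -> dict[str, int]:
    out: dict[str, int] = {}
    for la in label_landscape(landscape, rules):
        out[la.label] = out.get(la.label, 0) + (la.attractor.basin_size or 0)
    return out


def basin_log2_foldchange(wt: Landscape, pert: Landscape,
                          rules: list[PhenotypeRule] | None = None,
                          perturbation: ClampSet | None = None,
                          per_attractor: bool = False) -> PerturbationResult:
    """Score a perturbed landscape against a reference by basin mass.

    By default basins are aggregated per phenotype label (the heatmap
    semantics); ``per_attractor=True`` compares individual attractors by
    their canonical state set instead.  For every key the result is
    ``log2(pert/wt)`` when both masses are positive, ``"lost"`` when only
    the reference has mass, and ``"gained"`` when only the perturbed
    landscape does.
    """
    import math
    if per_attractor:
        wt_mass = {a.states: a.basin_size for a in wt.attractors}
        pert_mass = {a.states: a.basin_size for a in pert.attractors}
    else:
        wt_mass = _label_basins(wt, rules)
        pert_mass = _label_basins(pert, rules)
    fc: dict = {}
    for key in sorted(set(wt_mass) | set(pert_mass), key=str):
        w = wt_mass.get(key, 0)
        p = pert_mass.get(key, 0)
        if w > 0 and p > 0:
            fc[key] = math.log2(p / w)
        elif w > 0:
            fc[key] = LOST
        else:
            fc[key] = GAINED
    return PerturbationResult(
        perturbation=perturbation or ClampSet({}, label=""),
        landscape=pert, foldchange=fc, reference="wild-type")


def _perturbed(net: BooleanNetwork, clamps: ClampSet,
               wt_landscape: Landscape | None,
               rules: list[PhenotypeRule] | None,
               **engine_kwargs) -> PerturbationResult:
    pert_net = apply_clamps(net, clamps)
    landscape = exhaustive_attractors(pert_net, **engine_kwargs)
    if wt_landscape is None:
        return PerturbationResult(perturbation=clamps, landscape=landscape)
    res = basin_log2_foldchange(wt_landscape, landscape, rules,
                                perturbation=clamps)
    return res


def single_node_scan(net: BooleanNetwork, mode: str,
                     wt_landscape: Landscape | None = None,
                     rules: list[PhenotypeRule] | None = None,
                     nodes: list[str] | None = None,
                     **engine_kwargs) -> list[PerturbationResult]:
    """Clamp every node to 0 (``knockout``) or 1 (``overexpress``), one at a
    time, and enumerate each perturbed landscape over ``2**(N-1)`` states.
    """
    if mode not in ("knockout", "overexpress"):
        raise NetworkError(f"mode must be 'knockout' or 'overexpress', "
                           f"got {mode!r}")
    value = 0 if mode == "knockout" else 1
    results = []
    for node in nodes if nodes is not None else net.node_names:
        if net.clamps.get(node, value) != value:
            raise NetworkError(f"{node} already clamped to {net.clamps[node]}")
        tag = f"{node}={value}"
        if node in net.clamps:  # idempotent re-clamp
            clamps = ClampSet({}, label=tag)
        else:
            clamps = ClampSet({node: value}, label=tag)
        results.append(_perturbed(net, clamps, wt_landscape, rules,
                                  **engine_kwargs))
    return results


def microenvironment_landscape(net: BooleanNetwork, env_name: str,
                               wt_landscape: Landscape | None = None,
                               rules: list[PhenotypeRule] | None = None,
                               **engine_kwargs) -> PerturbationResult:
    """Simulate one of the named cytokine microenvironments."""
    if env_name not in MICROENVIRONMENTS:
        raise NetworkError(
            f"unknown microenvironment {env_name!r}; valid names: "
            f"{', '.join(MICROENVIRONMENTS)}")
    clamps = ClampSet(dict(MICROENVIRONMENTS[env_name]), label=env_name)
    return _perturbed(net, clamps, wt_landscape, rules, **engine_kwargs)


def build_tgem(net: BooleanNetwork,
               wt_landscape: Landscape | None = None,
               rules: list[PhenotypeRule] | None = None,
               **engine_kwargs) -> PerturbationResult:
    """Theoretical genetically modified macrophage: NFKB=1, HIF1A=0."""
    return _perturbed(net, TGEM_CLAMPS, wt_landscape, rules, **engine_kwargs)


def build_stgem(net: BooleanNetwork,
                wt_landscape: Landscape | None = None,
                rules: list[PhenotypeRule] | None = None,
                **engine_kwargs) -> PerturbationResult:
    """STAT1 variant of the TGEM: STAT1=1, HIF1A=0."""
    return _perturbed(net, STGEM_CLAMPS, wt_landscape, rules, **engine_kwargs)


def breast_cancer_scenarios(net: BooleanNetwork,
                            wt_landscape: Landscape | None = None,
                            rules: list[PhenotypeRule] | None = None,
                            **engine_kwargs) -> list[PerturbationResult]:
    """The four simplified breast-cancer microenvironments under the TGEM.

    ``net`` may or may not already carry the TGEM clamps; they are applied
    if absent.  A clamp conflicting with the TGEM is an error.
    """
    if not set(TGEM_CLAMPS.assignments) <= set(net.clamps):
        net = apply_clamps(net, TGEM_CLAMPS)
    results = []
    for name, assignment in BREAST_CANCER_SCENARIOS.items():
        clamps = ClampSet(dict(assignment), label=f"TGEM+{name}")
        results.append(_perturbed(net, clamps, wt_landscape, rules,
                                  **engine_kwargs))
    return results
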