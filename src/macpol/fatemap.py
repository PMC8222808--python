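"""Cell-fate maps: attractor-to-attractor transitions under single bit
flips.

The published procedure sampled random flips; here the enumeration is
exhaustive and deterministic (every state of every attractor, every free
node), which is a superset of any sampling scheme.  Transitions are
aggregated by (source label, target label, flipped node, direction);
``direction`` ``+`` means the bit was 0 and was turned on.  Reversibility
is judged at the label level: a transition is reversible when some single
flip on an attractor carrying the target label reaches an attractor with
the source label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import (
    Attractor,
    CompiledNetwork,
    Landscape,
    attractors_of_states,
)
from .network import BooleanNetwork
from .phenotypes import PhenotypeRule, label_attractor, label_landscape

__all__ = ["FateTransition", "one_bit_neighbors", "fate_graph",
           "fate_graph_to_dot"]


@dataclass(frozen=True)
class FateTransition:
    source_label: str
    target_label: str
    node: str
    direction: str  # "+" bit turned on, "-" bit turned off
    reversible: bool | None = None
    source_attractor_id: int | None = None
    target_attractor_id: int | None = None
    #: witness: the flipped full-state integer that realizes the transition
    witness_state: int | None = None


def _flip_records(net: BooleanNetwork | CompiledNetwork,
                  attractors: list[Attractor]):
    """All (attractor index, state, node index, flipped state) tuples."""
    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    free = [int(i) for i in cn.free_idx]
    recs = []
    for ai, att in enumerate(attractors):
        for s in att.states:
            for ni in free:
                recs.append((ai, s, ni, s ^ (1 << ni)))
    return cn, recs


def one_bit_neighbors(net: BooleanNetwork | CompiledNetwork, a: Attractor,
                      rules: list[PhenotypeRule] | None = None
                      ) -> list[FateTransition]:
    """Exhaustive single-flip transitions out of one attractor.

    Flips whose trajectory returns to ``a`` are omitted; duplicates (same
    node, direction and target) are collapsed to one witness.
    """
    cn, recs = _flip_records(net, [a])
    if not recs:
        return []
    targets = attractors_of_states(cn, [r[3] for r in recs])
    src_label = label_attractor(cn.net, a, rules).label
    seen = set()
    out = []
    for (ai, s, ni, flipped), tgt in zip(recs, targets):
        if tgt.key == a.key:
            continue
        direction = "+" if not (s >> ni) & 1 else "-"
        node = cn.net.node_names[ni]
        tgt_label = label_attractor(cn.net, tgt, rules).label
        key = (node, direction, tgt.key)
        if key in seen:
            continue
        seen.add(key)
        out.append(FateTransition(
            source_label=src_label, target_label=tgt_label, node=node,
            direction=direction, source_attractor_id=a.key,
            target_attractor_id=tgt.key, witness_state=flipped))
    return out


def fate_graph(landscape: Landscape,
               rules: list[PhenotypeRule] | None = None,
               attractor_level: bool = False) -> list[FateTransition]:
    """Aggregated single-flip transition map over a whole landscape.

    With ``attractor_level=True`` aggregation (and reversibility) is by
    attractor identity instead of phenotype label.
    """
    cn = CompiledNetwork(landscape.net)
    labeled = label_landscape(landscape, rules)
    atts = [la.attractor for la in labeled]
    label_of = {la.attractor.key: la.label for la in labeled}

    cn, recs = _flip_records(cn, atts)
    if not recs:
        return []
    flipped = np.array([r[3] for r in recs], dtype=np.int64)
    targets = attractors_of_states(cn, flipped)

    agg: dict[tuple, FateTransition] = {}
    reachable: set[tuple] = set()
    for (ai, s, ni, fs), tgt in zip(recs, targets):
        src = atts[ai]
        if tgt.key == src.key:
            continue
        src_label = label_of[src.key]
        tgt_label = label_of.get(tgt.key)
        if tgt_label is None:  # target outside the landscape (cannot happen
            tgt_label = label_attractor(cn.net, tgt, rules).label  # pragma: no cover
        if attractor_level:
            key = (src.key, tgt.key, ni, (s >> ni) & 1)
            reachable.add((src.key, tgt.key))
        else:
            if src_label == tgt_label:
                continue
            key = (src_label, tgt_label, ni, (s >> ni) & 1)
            reachable.add((src_label, tgt_label))
        if key not in agg:
            direction = "+" if not (s >> ni) & 1 else "-"
            agg[key] = FateTransition(
                source_label=src_label, target_label=tgt_label,
                node=cn.net.node_names[ni], direction=direction,
                source_attractor_id=src.key, target_attractor_id=tgt.key,
                witness_state=fs)

    out = []
    for key, tr in agg.items():
        if attractor_level:
            rev = (key[1], key[0]) in reachable
        else:
            rev = (tr.target_label, tr.source_label) in reachable
        out.append(replace(tr, reversible=rev))
    out.sort(key=lambda t: (t.source_label, t.target_label, t.node,
                            t.direction))
    return out


def fate_graph_to_dot(transitions: list[FateTransition]) -> str:
    """Render an aggregated fate graph in DOT format."""
    lines = ["digraph fatemap {"]
    labels = {t.source_label for t in transitions} | \
             {t.target_label for t in transitions}
    for lab in sorted(labels):
        lines.append(f'  "{lab}";')
    for t in transitions:
        style = "solid" if t.reversible else "dashed"
        lines.append(
            f'  "{t.source_label}" -> "{t.target_label}" '
            f'[label="{t.node}({t.direction})", style={style}];')
    lines.append("}")
    return "\n".join(lines)
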