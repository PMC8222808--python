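"""Phenotype labeling of attractors, landscape census, and 2D clustering.

Labels follow the marker logic of the published phenotype table:

====  =======================================
M1    NFKB | STAT1 | (TNFA & AP1)
M2a   STAT6
M2b   AP1 | ERK
M2c   STAT3
M2d   (TLR4 & A2A) | HIF1A
====  =======================================

A state satisfying several rules gets the concatenation of their labels in
the fixed order M1 < M2a < M2b < M2c < M2d (e.g. ``M1M2b``); a state
satisfying none is ``M0``.  Cyclic attractors join their per-state labels
with ``/`` (consecutive duplicates collapsed), starting from the canonical
first state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Attractor, Landscape
from .expr import Expr, eval_expr, expr_variables, parse_expr
from .network import BooleanNetwork, NetworkError

__all__ = [
    "PhenotypeRule",
    "LabeledAttractor",
    "ClusterAssignment",
    "default_rules",
    "label_state",
    "label_attractor",
    "label_landscape",
    "phenotype_census",
    "embed_and_cluster",
    "LABEL_ORDER",
]

LABEL_ORDER = ("M1", "M2a", "M2b", "M2c", "M2d")


@dataclass(frozen=True)
class PhenotypeRule:
    """A phenotype marker: label plus a Boolean expression over node names."""

    label: str
    expression: Expr

    @classmethod
    def from_text(cls, label: str, text: str) -> "PhenotypeRule":
        return cls(label, parse_expr(text))


@dataclass(frozen=True)
class LabeledAttractor:
    attractor: Attractor
    label: str


@dataclass(frozen=True)
class ClusterAssignment:
    embedding: np.ndarray        # (n_attractors, 2)
    cluster_id: np.ndarray       # (n_attractors,)
    k: int
    seed: int
    index_votes: dict[str, int]  # per-validity-index chosen k


def applicable_rules(net: BooleanNetwork) -> list[PhenotypeRule]:
    """Default rules restricted to those whose markers exist in ``net``.

    Lets the census/labeling stages run on arbitrary rule files; networks
    without any marker node label every attractor ``M0``.
    """
    declared = set(net.node_names)
    return [r for r in default_rules()
            if expr_variables(r.expression) <= declared]


def default_rules() -> list[PhenotypeRule]:
    """The five marker rules, in hybrid-label concatenation order."""
    return [
        PhenotypeRule.from_text("M1", "NFKB | STAT1 | (TNFA & AP1)"),
        PhenotypeRule.from_text("M2a", "STAT6"),
        PhenotypeRule.from_text("M2b", "AP1 | ERK"),
        PhenotypeRule.from_text("M2c", "STAT3"),
        PhenotypeRule.from_text("M2d", "(TLR4 & A2A) | HIF1A"),
    ]


def _check_rules(net: BooleanNetwork, rules: list[PhenotypeRule]) -> None:
    declared = set(net.node_names)
    for rule in rules:
        missing = expr_variables(rule.expression) - declared
        if missing:
            raise NetworkError(
                f"phenotype rule {rule.label} references missing nodes "
                f"{sorted(missing)}")


def label_state(net: BooleanNetwork, state: int,
                rules: list[PhenotypeRule] | None = None) -> str:
    """Label a single state; ``M0`` when no rule is satisfied."""
    if rules is None:
        rules = default_rules()
    _check_rules(net, rules)
    env = {name: bool((state >> i) & 1)
           for i, name in enumerate(net.node_names)}
    parts = [r.label for r in rules if eval_expr(r.expression, env)]
    # canonical hybrid order, independent of the rule list's order
    rank = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    parts.sort(key=lambda lab: (rank.get(lab, len(rank)), lab))
    return "".join(parts) if parts else "M0"


def label_attractor(net: BooleanNetwork, attractor: Attractor,
                    rules: list[PhenotypeRule] | None = None
                    ) -> LabeledAttractor:
    """Label an attractor; cyclic attractors join per-state labels with '/'.

    Consecutive duplicate labels (cyclically) are collapsed, so a 2-cycle
    whose states carry the same label gets that single label.
    """
    if rules is None:
        rules = default_rules()
    per_state = [label_state(net, s, rules) for s in attractor.states]
    dedup: list[str] = []
    for lab in per_state:
        if not dedup or dedup[-1] != lab:
            dedup.append(lab)
    if len(dedup) > 1 and dedup[0] == dedup[-1]:
        dedup.pop()
    return LabeledAttractor(attractor, "/".join(dedup))


def label_landscape(landscape: Landscape,
                    rules: list[PhenotypeRule] | None = None
                    ) -> list[LabeledAttractor]:
    if rules is None:
        rules = default_rules()
    return [label_attractor(landscape.net, a, rules)
            for a in landscape.attractors]


def phenotype_census(landscape: Landscape,
                     rules: list[PhenotypeRule] | None = None):
    """Census table: per label, attractor count and summed basin size."""
    import pandas as pd
    labeled = label_landscape(landscape, rules)
    rows: dict[str, dict] = {}
    for la in labeled:
        rec = rows.setdefault(la.label,
                              {"label": la.label, "n_attractors": 0,
                               "basin_size": 0})
        rec["n_attractors"] += 1
        rec["basin_size"] += la.attractor.basin_size or 0
    df = pd.DataFrame(sorted(rows.values(),
                             key=lambda r: -r["basin_size"]))
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# embedding + clustering

def _validity_votes(points: np.ndarray, labels_by_k: dict[int, np.ndarray]
                    ) -> dict[str, int]:
    """Consensus k from a battery of internal cluster-validity indices."""
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )
    scores: dict[str, dict[int, float]] = {
        "silhouette": {}, "calinski_harabasz": {}, "davies_bouldin": {}}
    for k, lab in labels_by_k.items():
        if len(set(lab)) < 2:
            continue
        scores["silhouette"][k] = silhouette_score(points, lab)
        scores["calinski_harabasz"][k] = calinski_harabasz_score(points, lab)
        # negated: lower Davies-Bouldin is better
        scores["davies_bouldin"][k] = -davies_bouldin_score(points, lab)
    return {name: max(vals, key=vals.get)
            for name, vals in scores.items() if vals}


def embed_and_cluster(net: BooleanNetwork,
                      labeled: list[LabeledAttractor],
                      k_range=range(10, 31),
                      seed: int = 0,
                      perplexity: float | None = None) -> ClusterAssignment:
    """t-SNE embedding of period-1 attractor bit patterns plus k-means.

    ``k`` is chosen by majority vote of the validity-index battery over
    ``k_range``; ties resolve to the smallest k.  Only period-1 attractors
    are embedded, mirroring the published figure.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import TSNE

    fixed = [la for la in labeled if la.attractor.period == 1]
    if len(fixed) < 2:
        raise NetworkError("need at least two period-1 attractors to embed")
    k_range = [k for k in k_range if k < len(fixed)]
    if not k_range:
        raise NetworkError("k_range has no value below the attractor count")

    n = net.n_nodes
    X = np.array([[(la.attractor.states[0] >> i) & 1 for i in range(n)]
                  for la in fixed], dtype=float)
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (len(fixed) - 1) / 3.0))
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(X)

    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels_by_k[k] = km.fit_predict(emb)
    votes = _validity_votes(emb, labels_by_k)
    if votes:
        counts: dict[int, int] = {}
        for k in votes.values():
            counts[k] = counts.get(k, 0) + 1
        best = max(counts.values())
        k_star = min(k for k, c in counts.items() if c == best)
    else:
        k_star = min(k_range)
    return ClusterAssignment(embedding=emb, cluster_id=labels_by_k[k_star],
                             k=k_star, seed=seed, index_votes=votes)
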