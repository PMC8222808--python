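"""Random Boolean network generators and fixture networks.

The random ensemble is the classic N-K model: each node receives K inputs
chosen uniformly with replacement-free sampling (self-loops allowed) and a
truth table whose rows are independently 1 with probability ``p``.  For
K=2, p=0.5 the annealed approximation puts the ensemble at criticality
(Derrida slope ``2*K*p*(1-p) = 1``), which the robustness property tests
rely on.

Fixture networks ship with their hand-enumerated landscapes so every
pipeline stage can be tested without the bundled macrophage model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expr import Expr
from .network import BooleanNetwork, NetworkError

__all__ = ["RandomNetSpec", "random_network", "fixture_catalog", "Fixture"]


@dataclass(frozen=True)
class RandomNetSpec:
    n_nodes: int
    in_degree: int
    bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise NetworkError("n_nodes must be >= 1")
        if not 0 <= self.in_degree <= self.n_nodes:
            raise NetworkError("in_degree must be in [0, n_nodes]")
        if not 0.0 <= self.bias <= 1.0:
            raise NetworkError("bias must be a probability")


def _truth_table_expr(inputs: list[str], table: np.ndarray) -> Expr:
    """Sum-of-products expression for an explicit truth table."""
    k = len(inputs)
    if k == 0 or table.all():
        return ("const", 1) if table.all() else ("const", 0)
    if not table.any():
        return ("const", 0)
    terms = []
    for row in np.nonzero(table)[0]:
        lits = []
        for j, name in enumerate(inputs):
            bit = (int(row) >> j) & 1
            lits.append(("var", name) if bit else ("not", ("var", name)))
        terms.append(lits[0] if len(lits) == 1 else ("and", *lits))
    return terms[0] if len(terms) == 1 else ("or", *terms)


def random_network(spec: RandomNetSpec) -> BooleanNetwork:
    """Draw a seeded random N-K Boolean network."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"n{i}" for i in range(spec.n_nodes))
    functions = {}
    for name in names:
        inputs = [names[i] for i in
                  rng.choice(spec.n_nodes, size=spec.in_degree, replace=False)]
        table = rng.random(1 << spec.in_degree) < spec.bias
        functions[name] = _truth_table_expr(inputs, table)
    return BooleanNetwork(
        names, functions,
        metadata=f"random N-K network n={spec.n_nodes} K={spec.in_degree} "
                 f"p={spec.bias} seed={spec.seed}")


@dataclass(frozen=True)
class Fixture:
    """A network plus its expected landscape as frozen test vectors."""

    net: BooleanNetwork
    #: map attractor (canonical state tuple) -> basin size
    expected: dict[tuple[int, ...], int]

    @property
    def n_attractors(self) -> int:
        return len(self.expected)


def _net(rules: dict[str, str]) -> BooleanNetwork:
    from .expr import parse_expr
    names = tuple(rules)
    return BooleanNetwork(names, {k: parse_expr(v) for k, v in rules.items()})


def fixture_catalog() -> dict[str, Fixture]:
    """Small networks with analytically known synchronous landscapes.

    Expected attractors/basins were derived by hand (they are exhaustively
    re-checked against the engine in the test suite):

    * ``identity1``: 1-node self-copy; two fixed points 0 and 1.
    * ``toggle``: 2-node mutual repression (A=!B, B=!A); fixed points
      ``01`` and ``10`` plus the 2-cycle {00, 11}.
    * ``negation_ring3``: 3-ring of negations A=!C, B=!A, C=!B; synchronous
      update gives two cycles: a 2-cycle {000,111} reached only from itself
      and a 6-cycle through the remaining states.
    * ``constant2``: both nodes decay to 0; single fixed point 00, basin 4.
    * ``copy_chain3``: A=A, B=A, C=B; fixed points 000 and 111.
    """
    catalog: dict[str, Fixture] = {}

    catalog["identity1"] = Fixture(
        _net({"A": "A"}),
        expected={(0,): 1, (1,): 1})

    catalog["toggle"] = Fixture(
        _net({"A": "!B", "B": "!A"}),
        # states: bit0=A, bit1=B; 01 means A=1,B=0 -> int 1
        expected={(1,): 1, (2,): 1, (0, 3): 2})

    catalog["negation_ring3"] = Fixture(
        _net({"A": "!C", "B": "!A", "C": "!B"}),
        # 000->111->000 (2-cycle, basin 2); remaining six states form
        # the 6-cycle 1->5->4->6->2->3->1 (ints, bit0=A bit1=B bit2=C)
        expected={(0, 7): 2, (1, 5, 4, 6, 2, 3): 6})

    catalog["constant2"] = Fixture(
        _net({"A": "0", "B": "0"}),
        expected={(0,): 4})

    catalog["copy_chain3"] = Fixture(
        _net({"A": "A", "B": "A", "C": "B"}),
        expected={(0,): 4, (7,): 4})

    return catalog
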