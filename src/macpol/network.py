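"""Boolean network model: parsing, validation, serialization, clamping.

Rule files use the BoolNet-style plain-text dialect::

    targets, factors
    NODE, <expression>

with one rule per line, ``&``/``|``/``!`` operators and parentheses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

from .expr import (
    Expr,
    ExprError,
    expr_to_str,
    expr_variables,
    normalize_name,
    parse_expr,
)

__all__ = [
    "BooleanNetwork",
    "ClampSet",
    "NetworkError",
    "RuleParseError",
    "parse_rules",
    "serialize_rules",
    "load_rules",
    "load_macrophage_model",
    "apply_clamps",
    "reduce_low_degree_nodes",
    "MACROPHAGE_MODEL_RESOURCE",
]

MACROPHAGE_MODEL_RESOURCE = "macrophage_tme.txt"


class NetworkError(ValueError):
    """Structural problem with a Boolean network."""


class RuleParseError(NetworkError):
    """Raised when a rule file cannot be parsed."""


@dataclass(frozen=True)
class ClampSet:
    """A named set of permanent node assignments (0/1)."""

    assignments: dict[str, int]
    label: str = ""

    def __post_init__(self):
        for node, value in self.assignments.items():
            if value not in (0, 1):
                raise NetworkError(
                    f"clamp value for {node} must be 0 or 1, got {value!r}")

    def merge(self, other: "ClampSet", label: str | None = None) -> "ClampSet":
        """Union of two clamp sets; conflicting assignments are an error."""
        merged = dict(self.assignments)
        for node, value in other.assignments.items():
            if merged.get(node, value) != value:
                raise NetworkError(
                    f"conflicting clamp for {node}: "
                    f"{merged[node]} vs {value}")
            merged[node] = value
        if label is None:
            label = "+".join(x for x in (self.label, other.label) if x)
        return ClampSet(merged, label)


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered collection of named nodes with Boolean update rules.

    ``node_names`` fixes the bit order of integer state encodings: bit ``i``
    of a state holds the value of ``node_names[i]``.
    """

    node_names: tuple[str, ...]
    functions: dict[str, Expr]
    clamps: dict[str, int] = field(default_factory=dict)
    metadata: str = ""

    def __post_init__(self):
        names = self.node_names
        if len(names) < 1:
            raise NetworkError("network must have at least one node")
        if len(set(names)) != len(names):
            raise NetworkError("duplicate node names")
        missing = set(names) - set(self.functions)
        if missing:
            raise NetworkError(f"nodes without update rule: {sorted(missing)}")
        extra = set(self.functions) - set(names)
        if extra:
            raise NetworkError(f"rules for undeclared nodes: {sorted(extra)}")
        for name in names:
            for ref in expr_variables(self.functions[name]):
                if ref not in set(names):
                    raise NetworkError(
                        f"rule for {name} references undeclared node {ref}")
        for node in self.clamps:
            if node not in set(names):
                raise NetworkError(f"clamp on undeclared node {node}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_names if n not in self.clamps)

    @property
    def free_node_count(self) -> int:
        return self.n_nodes - len(self.clamps)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def regulators(self, target: str) -> set[str]:
        """Distinct nodes referenced by ``target``'s update rule."""
        return expr_variables(self.functions[target])

    def edges(self) -> set[tuple[str, str]]:
        """All distinct (regulator, target) pairs; self-loops included."""
        out = set()
        for target in self.node_names:
            for reg in self.regulators(target):
                out.add((reg, target))
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def degree(self, node: str) -> int:
        """Total degree: in-edges plus out-edges over distinct pairs."""
        es = self.edges()
        return sum(1 for e in es if e[0] == node or e[1] == node)


def parse_rules(text: str, *, normalize_names: bool = False,
                metadata: str = "") -> BooleanNetwork:
    """Parse rule-file content into a validated :class:`BooleanNetwork`.

    The first non-comment line must be the ``targets, factors`` header.
    Lines starting with ``#`` are comments.
    """
    lines = text.splitlines()
    header_seen = False
    entries: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            norm = "".join(line.lower().split())
            if norm != "targets,factors":
                raise RuleParseError(
                    f"line {lineno}: expected 'targets, factors' header, "
                    f"got {line!r}")
            header_seen = True
            continue
        if "," not in line:
            raise RuleParseError(f"line {lineno}: expected 'NODE, expression'")
        target, expr_text = line.split(",", 1)
        entries.append((lineno, target.strip(), expr_text.strip()))
    if not header_seen or not entries:
        raise RuleParseError("empty rule file")

    names: list[str] = []
    functions: dict[str, Expr] = {}
    rename: dict[str, str] = {}
    for lineno, target, _ in entries:
        name = normalize_name(target) if normalize_names else target
        if name in functions:
            raise RuleParseError(f"line {lineno}: duplicate target {name}")
        rename[target] = name
        names.append(name)
        functions[name] = ("const", 0)  # placeholder until second pass

    def rename_vars(expr: Expr) -> Expr:
        op = expr[0]
        if op == "var":
            return ("var", normalize_name(expr[1]) if normalize_names else expr[1])
        if op == "const":
            return expr
        return (op, *(rename_vars(sub) for sub in expr[1:]))

    declared = set(names)
    for lineno, target, expr_text in entries:
        try:
            expr = rename_vars(parse_expr(expr_text))
        except ExprError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
        for ref in expr_variables(expr):
            if ref not in declared:
                raise RuleParseError(
                    f"line {lineno}: rule for {rename[target]} references "
                    f"undeclared node {ref}")
        functions[rename[target]] = expr

    return BooleanNetwork(tuple(names), functions, metadata=metadata)


def serialize_rules(net: BooleanNetwork) -> str:
    """Render a network in the ``targets, factors`` dialect.

    Clamped nodes are emitted with their constant replacement so that a
    serialize/parse round trip preserves the dynamics.
    """
    lines = ["targets, factors"]
    for name in net.node_names:
        expr = net.functions[name]
        if name in net.clamps:
            expr = ("const", net.clamps[name])
        lines.append(f"{name}, {expr_to_str(expr)}")
    return "\n".join(lines) + "\n"


def load_rules(path, **kwargs) -> BooleanNetwork:
    """Read a rule file from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_rules(fh.read(), **kwargs)


def load_macrophage_model() -> BooleanNetwork:
    """Load the bundled 29-node macrophage polarization network."""
    try:
        ref = importlib.resources.files("macpol.models") / MACROPHAGE_MODEL_RESOURCE
        text = ref.read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise NetworkError(
            f"packaged model {MACROPHAGE_MODEL_RESOURCE} missing") from exc
    net = parse_rules(text, normalize_names=True,
                      metadata="bundled macrophage tumor-microenvironment model")
    return net


def apply_clamps(net: BooleanNetwork, clamps: ClampSet) -> BooleanNetwork:
    """Return a copy of ``net`` with clamped nodes replaced by constants.

    Existing clamps are kept; re-clamping a node to a different value is an
    error (a clamp is a permanent experimental intervention).
    """
    merged = dict(net.clamps)
    for node, value in clamps.assignments.items():
        if node not in net.node_names:
            raise NetworkError(f"cannot clamp unknown node {node}")
        if merged.get(node, value) != value:
            raise NetworkError(
                f"conflicting clamp for {node}: {merged[node]} vs {value}")
        merged[node] = value
    functions = dict(net.functions)
    for node, value in merged.items():
        functions[node] = ("const", value)
    return replace(net, functions=functions, clamps=merged)


def reduce_low_degree_nodes(net: BooleanNetwork) -> BooleanNetwork:
    """Drop nodes with total degree (in + out, distinct pairs) below two.

    Applied once, not iterated.  If a surviving rule still references a
    removed node the reduction is refused, because silently rewiring the
    logic would change the dynamics.
    """
    doomed = {n for n in net.node_names if net.degree(n) < 2}
    if not doomed:
        return net
    keep = tuple(n for n in net.node_names if n not in doomed)
    if not keep:
        raise NetworkError("reduction would remove every node")
    orphans = []
    for name in keep:
        bad = expr_variables(net.functions[name]) & doomed
        if bad:
            orphans.append(f"{name} references {sorted(bad)}")
    if orphans:
        raise NetworkError(
            "reduction would orphan references: " + "; ".join(orphans))
    functions = {n: net.functions[n] for n in keep}
    clamps = {n: v for n, v in net.clamps.items() if n in keep}
    return BooleanNetwork(keep, functions, clamps, net.metadata)
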