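"""Boolean expression trees for update rules.

Expressions are immutable nested tuples:

    ("var", name)        node reference
    ("const", 0 | 1)     constant
    ("not", sub)
    ("and", a, b, ...)   n-ary conjunction
    ("or", a, b, ...)    n-ary disjunction

The concrete syntax uses ``&``, ``|``, ``!`` and parentheses with the
precedence NOT > AND > OR.  Node names match ``[A-Za-z_][A-Za-z0-9_]*``.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable

Expr = tuple

__all__ = [
    "Expr",
    "ExprError",
    "parse_expr",
    "expr_to_str",
    "expr_variables",
    "eval_expr",
    "compile_expr",
    "normalize_name",
]


class ExprError(ValueError):
    """Raised on malformed Boolean expressions."""


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])"
                       r"|(?P<op>[&|!()]))")

# ASCII fallbacks for Greek letters that occur in published rule files.
_GREEK = {
    "α": "A", "β": "B", "γ": "G", "δ": "D", "κ": "K",
    "Α": "A", "Β": "B", "Γ": "G", "Δ": "D", "Κ": "K",
}


def normalize_name(raw: str) -> str:
    """Map a published node name onto an ASCII identifier.

    Greek letters are transliterated, hyphens/spaces/slashes dropped and the
    result upper-cased, e.g. ``HIF1-α`` -> ``HIF1A``, ``NFκB`` -> ``NFKB``.
    """
    out = []
    for ch in raw.strip():
        if ch in _GREEK:
            out.append(_GREEK[ch])
        elif ch.isalnum() or ch == "_":
            out.append(ch.upper())
        # hyphen, space, slash, dot: dropped
    name = "".join(out)
    if not name or name[0].isdigit():
        raise ExprError(f"cannot normalize node name {raw!r}")
    return name


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExprError(f"unexpected character {text[pos]!r} in expression "
                            f"{text!r}")
        if m.group("name"):
            tokens.append(("name", m.group("name")))
        elif m.group("const"):
            tokens.append(("const", m.group("const")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


def parse_expr(text: str) -> Expr:
    """Parse ``text`` into an expression tree.

    Precedence: ``!`` binds tighter than ``&``, which binds tighter than
    ``|``; parentheses override.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ExprError("empty expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        terms = [parse_and()]
        while peek() == ("op", "|"):
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", *terms)

    def parse_and() -> Expr:
        factors = [parse_unary()]
        while peek() == ("op", "&"):
            take()
            factors.append(parse_unary())
        return factors[0] if len(factors) == 1 else ("and", *factors)

    def parse_unary() -> Expr:
        kind, val = peek()
        if (kind, val) == ("op", "!"):
            take()
            return ("not", parse_unary())
        if (kind, val) == ("op", "("):
            take()
            inner = parse_or()
            if peek() != ("op", ")"):
                raise ExprError(f"unbalanced parenthesis in {text!r}")
            take()
            return inner
        if kind == "name":
            take()
            return ("var", val)
        if kind == "const":
            take()
            return ("const", int(val))
        raise ExprError(f"unexpected token {val!r} in {text!r}")

    result = parse_or()
    if pos != len(tokens):
        raise ExprError(f"trailing tokens after expression in {text!r}")
    return result


def expr_to_str(expr: Expr) -> str:
    """Serialize an expression tree back to rule-file syntax."""
    op = expr[0]
    if op == "var":
        return expr[1]
    if op == "const":
        return str(expr[1])
    if op == "not":
        sub = expr[1]
        body = expr_to_str(sub)
        if sub[0] in ("and", "or"):
            body = f"({body})"
        return f"!{body}"
    if op == "and":
        parts = []
        for sub in expr[1:]:
            body = expr_to_str(sub)
            if sub[0] == "or":
                body = f"({body})"
            parts.append(body)
        return " & ".join(parts)
    if op == "or":
        return " | ".join(expr_to_str(sub) for sub in expr[1:])
    raise ExprError(f"unknown expression node {op!r}")


def expr_variables(expr: Expr) -> set[str]:
    """Set of node names referenced by ``expr``."""
    op = expr[0]
    if op == "var":
        return {expr[1]}
    if op == "const":
        return set()
    out: set[str] = set()
    for sub in expr[1:]:
        out |= expr_variables(sub)
    return out


def eval_expr(expr: Expr, env):
    """Evaluate ``expr`` with ``env`` mapping names to bools or bool arrays.

    Uses ``&``/``|``/``~`` so it is transparent to numpy boolean arrays;
    scalar values should be numpy bools (or Python bools are fine because
    constants are handled explicitly and ``~`` is never applied to ints).
    """
    op = expr[0]
    if op == "var":
        return env[expr[1]]
    if op == "const":
        return bool(expr[1])
    if op == "not":
        val = eval_expr(expr[1], env)
        if val is True or val is False:
            return not val
        return ~val
    if op == "and":
        acc = eval_expr(expr[1], env)
        for sub in expr[2:]:
            nxt = eval_expr(sub, env)
            acc = (acc and nxt) if isinstance(acc, bool) and isinstance(nxt, bool) else acc & nxt
        return acc
    if op == "or":
        acc = eval_expr(expr[1], env)
        for sub in expr[2:]:
            nxt = eval_expr(sub, env)
            acc = (acc or nxt) if isinstance(acc, bool) and isinstance(nxt, bool) else acc | nxt
        return acc
    raise ExprError(f"unknown expression node {op!r}")


def compile_expr(expr: Expr, index: dict[str, int]) -> Callable:
    """Compile ``expr`` to ``f(env)`` where ``env`` is a sequence of numpy
    boolean arrays indexed by ``index[name]``.

    Constants are emitted as ``True``/``False`` and rely on numpy
    broadcasting; a pure-constant function returns a scalar bool, callers
    must broadcast.
    """

    def fold(e: Expr) -> Expr:
        """Constant-fold so `~` is never applied to a Python bool."""
        op = e[0]
        if op in ("var", "const"):
            return e
        subs = [fold(s) for s in e[1:]]
        if op == "not":
            if subs[0][0] == "const":
                return ("const", 1 - subs[0][1])
            return ("not", subs[0])
        keep = []
        for s in subs:
            if s[0] == "const":
                if op == "and" and s[1] == 0:
                    return ("const", 0)
                if op == "or" and s[1] == 1:
                    return ("const", 1)
                continue  # neutral element, drop
            keep.append(s)
        if not keep:
            return ("const", 1 if op == "and" else 0)
        if len(keep) == 1:
            return keep[0]
        return (op, *keep)

    def emit(e: Expr) -> str:
        op = e[0]
        if op == "var":
            return f"env[{index[e[1]]}]"
        if op == "const":
            return "True" if e[1] else "False"
        if op == "not":
            return f"~({emit(e[1])})"
        if op == "and":
            return "(" + " & ".join(emit(s) for s in e[1:]) + ")"
        if op == "or":
            return "(" + " | ".join(emit(s) for s in e[1:]) + ")"
        raise ExprError(f"unknown expression node {op!r}")

    src = f"lambda env: {emit(fold(expr))}"
    return eval(src, {})  # noqa: S307 - source built from validated AST
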