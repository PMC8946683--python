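"""Reading and writing models in a BoolNet-style ``.bnet`` dialect.

One line per node, ``target, factors``, with ``&``/``|``/``!`` and
parentheses; an input node is declared by the self-referential line
``target, target``.  A comment header records node kinds, display
symbols and edge signs so that a round trip preserves the full model:

    # kind: <name> <input|internal|output> [display symbol...]
    # edge: <source> <target> <+|->

When the header is absent, edge signs are inferred from the (monotone)
rules' discrete derivatives and node kinds fall back to: self-rule =>
input, no outgoing edge => output.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable

from .logic import (BooleanModel, Expr, ModelValidationError, NodeSpec,
                    SignedEdge, Var, parse_expression)

__all__ = ["read_bnet", "loads_bnet", "write_bnet", "dumps_bnet"]


def _infer_sign(expr: Expr, var: str) -> int:
    """Sign of a monotone rule's dependence on ``var`` (exhaustive contexts)."""
    regs = sorted(expr.variables())
    others = [r for r in regs if r != var]
    pos = neg = False
    for bits in itertools.product((0, 1), repeat=len(others)):
        env = dict(zip(others, bits))
        env[var] = 1
        hi = expr.evaluate(env)
        env[var] = 0
        lo = expr.evaluate(env)
        if hi > lo:
            pos = True
        elif hi < lo:
            neg = True
    if pos and neg:
        raise ModelValidationError(f"rule not monotone in {var}: {expr}")
    if not pos and not neg:
        raise ModelValidationError(f"rule does not depend on {var}: {expr}")
    return 1 if pos else -1


def loads_bnet(text: str, name: str = "model") -> BooleanModel:
    kinds: dict[str, str] = {}
    displays: dict[str, str] = {}
    signs: dict[tuple[str, str], int] = {}
    raw_rules: list[tuple[str, str]] = []

    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("kind:"):
                parts = body[len("kind:"):].split(None, 2)
                if len(parts) >= 2:
                    kinds[parts[0]] = parts[1]
                    if len(parts) == 3:
                        displays[parts[0]] = parts[2]
            elif body.startswith("edge:"):
                parts = body[len("edge:"):].split()
                if len(parts) == 3 and parts[2] in ("+", "-"):
                    signs[(parts[0], parts[1])] = 1 if parts[2] == "+" else -1
            continue
        if stripped.lower().replace(" ", "").startswith("targets,factors"):
            continue
        if "," not in stripped:
            raise ModelValidationError(f"malformed bnet line: {line!r}")
        target, factors = stripped.split(",", 1)
        raw_rules.append((target.strip(), factors.strip()))

    order = [t for t, _ in raw_rules]
    if len(set(order)) != len(order):
        raise ModelValidationError("duplicate targets in bnet file")

    rules: dict[str, Expr] = {}
    inputs: set[str] = set()
    for target, factors in raw_rules:
        expr = parse_expression(factors)
        # "A, A" declares an input -- unless the header says A is a real
        # node, in which case it is a genuine self-activation rule
        if expr == Var(target) and kinds.get(target, "input") == "input":
            inputs.add(target)
        else:
            rules[target] = expr

    edges: set[SignedEdge] = set()
    for target, expr in rules.items():
        for var in sorted(expr.variables()):
            sign = signs.get((var, target))
            if sign is None:
                sign = _infer_sign(expr, var)
            edges.add(SignedEdge(var, target, sign))

    has_out = {e.source for e in edges}
    nodes = []
    for n in order:
        kind = kinds.get(n)
        if kind is None:
            kind = "input" if n in inputs else ("internal" if n in has_out else "output")
        nodes.append(NodeSpec(n, kind, displays.get(n)))
    return BooleanModel(nodes, edges, rules, name=name)


def read_bnet(path: str | Path) -> BooleanModel:
    path = Path(path)
    return loads_bnet(path.read_text(), name=path.stem)


def dumps_bnet(model: BooleanModel, header_comments: Iterable[str] = ()) -> str:
    lines = [f"# {c}" for c in header_comments]
    for n in model.nodes:
        disp = f" {n.display_symbol}" if n.display_symbol else ""
        lines.append(f"# kind: {n.name} {n.kind}{disp}")
    for e in sorted(model.edges, key=lambda e: (e.source, e.target)):
        lines.append(f"# edge: {e.source} {e.target} {'+' if e.sign > 0 else '-'}")
    lines.append("targets, factors")
    for n in model.nodes:
        if n.kind == "input":
            lines.append(f"{n.name}, {n.name}")
        else:
            lines.append(f"{n.name}, {model.rules[n.name].to_bnet()}")
    return "\n".join(lines) + "\n"


def write_bnet(model: BooleanModel, path: str | Path,
               header_comments: Iterable[str] = ()) -> None:
    Path(path).write_text(dumps_bnet(model, header_comments))
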