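"""Core types for logical regulatory models.

A Boolean regulatory model is a signed directed graph over named nodes
together with one monotone Boolean rule per non-input node.  Nodes hold
values 0 (inactive/OFF) or 1 (active/ON).  Activating regulators enter a
rule positively, inhibiting regulators negatively; the sign annotation on
each edge is therefore checkable against the rule's discrete derivative.

Rules are kept as explicit expression trees (AND/OR/NOT over regulator
names) rather than truth tables, so that edge consistency, monotonicity
and circuit-functionality analysis can work symbolically; truth tables
are derived on demand for small in-degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Expr", "Var", "Const", "Not", "And", "Or", "parse_expression",
    "NodeSpec", "SignedEdge", "LogicalRule", "BooleanModel",
    "Perturbation", "Phenotype", "PHENOTYPE_LABELS",
    "ModelValidationError",
]

MONOTONICITY_EXHAUSTIVE_MAX_INDEGREE = 12


class ModelValidationError(ValueError):
    """A model violates a structural invariant (edges vs rules, signs, ...)."""


# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean expression trees."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, env: Mapping[str, int]) -> int:
        """Two-valued evaluation; every variable must be bound."""
        raise NotImplementedError

    def evaluate3(self, env: Mapping[str, int | None]) -> int | None:
        """Kleene three-valued evaluation; unbound/None variables stay unknown.

        Used by the fixed-point search to prune partial assignments.
        """
        raise NotImplementedError

    def to_python(self, index: Mapping[str, int]) -> str:
        """Render as a python expression over a state sequence ``s``."""
        raise NotImplementedError

    def to_bnet(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_bnet()

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def variables(self):
        return frozenset((self.name,))

    def evaluate(self, env):
        return env[self.name]

    def evaluate3(self, env):
        return env.get(self.name)

    def to_python(self, index):
        return f"s[{index[self.name]}]"

    def to_bnet(self):
        return self.name

    def _key(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Const(Expr):
    value: int

    def variables(self):
        return frozenset()

    def evaluate(self, env):
        return self.value

    def evaluate3(self, env):
        return self.value

    def to_python(self, index):
        return str(self.value)

    def to_bnet(self):
        return str(self.value)

    def _key(self):
        return self.value


@dataclass(frozen=True, eq=False)
class Not(Expr):
    operand: Expr

    def variables(self):
        return self.operand.variables()

    def evaluate(self, env):
        return 1 - self.operand.evaluate(env)

    def evaluate3(self, env):
        v = self.operand.evaluate3(env)
        return None if v is None else 1 - v

    def to_python(self, index):
        return f"(1-{self.operand.to_python(index)})"

    def to_bnet(self):
        inner = self.operand.to_bnet()
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"

    def _key(self):
        return self.operand


@dataclass(frozen=True, eq=False)
class And(Expr):
    operands: tuple[Expr, ...]

    def __init__(self, *operands: Expr):
        flat: list[Expr] = []
        for o in operands:  # canonical n-ary form: A & (B & C) == A & B & C
            flat.extend(o.operands if isinstance(o, And) else (o,))
        object.__setattr__(self, "operands", tuple(flat))

    def variables(self):
        return frozenset().union(*(o.variables() for o in self.operands))

    def evaluate(self, env):
        for o in self.operands:
            if not o.evaluate(env):
                return 0
        return 1

    def evaluate3(self, env):
        unknown = False
        for o in self.operands:
            v = o.evaluate3(env)
            if v == 0:
                return 0
            if v is None:
                unknown = True
        return None if unknown else 1

    def to_python(self, index):
        return "(" + " and ".join(o.to_python(index) for o in self.operands) + ")"

    def to_bnet(self):
        parts = []
        for o in self.operands:
            s = o.to_bnet()
            if isinstance(o, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)

    def _key(self):
        return self.operands


@dataclass(frozen=True, eq=False)
class Or(Expr):
    operands: tuple[Expr, ...]

    def __init__(self, *operands: Expr):
        flat: list[Expr] = []
        for o in operands:  # canonical n-ary form: A | (B | C) == A | B | C
            flat.extend(o.operands if isinstance(o, Or) else (o,))
        object.__setattr__(self, "operands", tuple(flat))

    def variables(self):
        return frozenset().union(*(o.variables() for o in self.operands))

    def evaluate(self, env):
        for o in self.operands:
            if o.evaluate(env):
                return 1
        return 0

    def evaluate3(self, env):
        unknown = False
        for o in self.operands:
            v = o.evaluate3(env)
            if v == 1:
                return 1
            if v is None:
                unknown = True
        return None if unknown else 0

    def to_python(self, index):
        return "(" + " or ".join(o.to_python(index) for o in self.operands) + ")"

    def to_bnet(self):
        return " | ".join(o.to_bnet() for o in self.operands)

    def _key(self):
        return self.operands


# --- parser: &, |, !, parentheses, 0/1 constants, identifiers -------------

_IDENT_CHARS = set("abcdefghijklmnopqrstuvwxyz"
                   "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_-")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "&|!()":
            tokens.append(c)
            i += 1
        elif c in _IDENT_CHARS:
            j = i
            while j < len(text) and text[j] in _IDENT_CHARS:
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise ModelValidationError(f"unexpected character {c!r} in rule {text!r}")
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse a BoolNet-style rule expression (``&``, ``|``, ``!``, parens).

    ``|`` binds loosest, then ``&``, then ``!``.  Bare ``0``/``1`` are
    constants, anything else alphanumeric (plus ``_``/``-``) a variable.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        if pos >= len(tokens):
            raise ModelValidationError(f"unexpected end of rule {text!r}")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ModelValidationError(f"expected {expected!r}, got {tok!r} in {text!r}")
        pos += 1
        return tok

    def parse_or() -> Expr:
        terms = [parse_and()]
        while peek() == "|":
            take("|")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def parse_and() -> Expr:
        terms = [parse_not()]
        while peek() == "&":
            take("&")
            terms.append(parse_not())
        return terms[0] if len(terms) == 1 else And(*terms)

    def parse_not() -> Expr:
        if peek() == "!":
            take("!")
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> Expr:
        tok = take()
        if tok == "(":
            e = parse_or()
            take(")")
            return e
        if tok in ("0", "1"):
            return Const(int(tok))
        if tok in ("&", "|", "!", ")"):
            raise ModelValidationError(f"misplaced {tok!r} in rule {text!r}")
        return Var(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise ModelValidationError(f"trailing tokens in rule {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Nodes, edges, rules, model
# ---------------------------------------------------------------------------

NODE_KINDS = ("input", "internal", "output")


@dataclass(frozen=True)
class NodeSpec:
    """A molecular species (gene, protein, ncRNA) or a readout node."""

    name: str
    kind: str = "internal"
    display_symbol: str | None = None

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ModelValidationError(f"unknown node kind {self.kind!r}")

    @property
    def label(self) -> str:
        return self.display_symbol or self.name


@dataclass(frozen=True)
class SignedEdge:
    """Directed regulatory interaction: sign +1 activation, -1 inhibition."""

    source: str
    target: str
    sign: int

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ModelValidationError(f"edge sign must be +1/-1, got {self.sign}")


@dataclass(frozen=True)
class LogicalRule:
    target: str
    expression: Expr

    def variables(self) -> frozenset[str]:
        return self.expression.variables()


@dataclass(frozen=True)
class Perturbation:
    """KO/E1 clamps: node name -> 0 (loss of function) or 1 (gain of function).

    An empty clamp map is the wild type.  Clamped nodes are never updated.
    """

    clamps: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_dict(cls, clamps: Mapping[str, int] | None) -> "Perturbation":
        if not clamps:
            return cls(())
        for name, v in clamps.items():
            if v not in (0, 1):
                raise ModelValidationError(f"clamp value for {name} must be 0/1")
        return cls(tuple(sorted(clamps.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.clamps)

    def __bool__(self) -> bool:
        return bool(self.clamps)

    def __contains__(self, name: str) -> bool:
        return any(n == name for n, _ in self.clamps)


WILD_TYPE = Perturbation(())

PHENOTYPE_LABELS = ("Proliferation", "Senescence", "Apoptosis", "None", "Mixed")


@dataclass(frozen=True)
class Phenotype:
    """Cell-fate readout of an attractor, derived from the output nodes.

    The label is the unique ON output node's name ("None" when all
    outputs are OFF, "Mixed" for cyclic attractors whose states disagree
    or for states with several outputs ON — the latter also sets
    ``flagged``).  For the checkpoint model the labels are the canonical
    PHENOTYPE_LABELS.
    """

    label: str
    flagged: bool = False  # True when >1 output was ON in one state

    def __post_init__(self):
        if not self.label:
            raise ModelValidationError("phenotype label must be non-empty")

    def __str__(self):
        return self.label


class BooleanModel:
    """A signed regulatory graph with one monotone logical rule per node.

    Input nodes carry no rule and are held constant during dynamics; output
    nodes have no outgoing edges and define the phenotype readout.
    """

    def __init__(self, nodes: Sequence[NodeSpec], edges: Iterable[SignedEdge],
                 rules: Mapping[str, Expr | str], name: str = "model",
                 validate: bool = True):
        self.name = name
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.edges: frozenset[SignedEdge] = frozenset(edges)
        self.rules: dict[str, Expr] = {
            t: (parse_expression(e) if isinstance(e, str) else e)
            for t, e in rules.items()
        }
        self.index: dict[str, int] = {n.name: i for i, n in enumerate(self.nodes)}
        if validate:
            self.validate()
        self._compiled: dict[str, object] = {}

    # -- basic structure ----------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def input_nodes(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "input")

    @property
    def output_nodes(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "output")

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index[name]]

    def regulators(self, name: str) -> frozenset[str]:
        rule = self.rules.get(name)
        return rule.variables() if rule is not None else frozenset()

    def targets_of(self, name: str) -> tuple[str, ...]:
        return tuple(e.target for e in self.edges if e.source == name)

    def edge_sign(self, source: str, target: str) -> int:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.sign
        raise KeyError(f"no edge {source} -> {target}")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate node names")
        name_set = set(names)
        seen_pairs = set()
        for e in self.edges:
            if e.source not in name_set or e.target not in name_set:
                raise ModelValidationError(f"edge {e.source}->{e.target} uses undeclared node")
            if (e.source, e.target) in seen_pairs:
                raise ModelValidationError(f"duplicate edge {e.source}->{e.target}")
            seen_pairs.add((e.source, e.target))
        for n in self.nodes:
            if n.kind == "input":
                if n.name in self.rules:
                    raise ModelValidationError(f"input node {n.name} must not carry a rule")
            else:
                if n.name not in self.rules:
                    raise ModelValidationError(f"non-input node {n.name} has no rule")
            if n.kind == "output" and self.targets_of(n.name):
                raise ModelValidationError(f"output node {n.name} has outgoing edges")
        # rule variable sets must exactly reconstruct the edge set
        in_edges: dict[str, set[str]] = {n: set() for n in name_set}
        for e in self.edges:
            in_edges[e.target].add(e.source)
        for target, expr in self.rules.items():
            if target not in name_set:
                raise ModelValidationError(f"rule for undeclared node {target}")
            vars_ = expr.variables()
            missing = vars_ - name_set
            if missing:
                raise ModelValidationError(
                    f"rule for {target} references undeclared {sorted(missing)}")
            if vars_ != in_edges[target]:
                raise ModelValidationError(
                    f"rule/edge mismatch for {target}: rule uses {sorted(vars_)}, "
                    f"edges give {sorted(in_edges[target])}")
        self.check_monotonicity()

    def check_monotonicity(self) -> None:
        """Every rule must be monotone with the declared edge signs.

        Exhaustive over regulator contexts; only attempted for in-degree
        up to MONOTONICITY_EXHAUSTIVE_MAX_INDEGREE.
        """
        for target, expr in self.rules.items():
            regs = sorted(expr.variables())
            if len(regs) > MONOTONICITY_EXHAUSTIVE_MAX_INDEGREE:
                continue
            signs = {r: self.edge_sign(r, target) for r in regs}
            for bits in itertools.product((0, 1), repeat=len(regs)):
                env = dict(zip(regs, bits))
                for r in regs:
                    lo = dict(env, **{r: 0})
                    hi = dict(env, **{r: 1})
                    delta = expr.evaluate(hi) - expr.evaluate(lo)
                    if delta * signs[r] < 0:
                        raise ModelValidationError(
                            f"rule for {target} is not monotone in {r} "
                            f"(edge sign {signs[r]:+d}, context {env})")

    # -- evaluation ---------------------------------------------------------

    def compiled_rule(self, name: str):
        """Rule compiled to a fast closure over a state sequence."""
        fn = self._compiled.get(name)
        if fn is None:
            expr = self.rules[name]
            fn = eval("lambda s: 1 if %s else 0" % expr.to_python(self.index))
            self._compiled[name] = fn
        return fn

    def evaluate_rule(self, name: str, state: Sequence[int]) -> int:
        """Truth value of ``name``'s rule under ``state`` (declared node order)."""
        if name not in self.index:
            raise KeyError(f"unknown node {name!r}")
        if name not in self.rules:
            raise ModelValidationError(f"node {name} is an input; it has no rule")
        if len(state) != len(self.nodes):
            raise ModelValidationError("state length does not match node count")
        return self.compiled_rule(name)(state)

    # -- perturbation -------------------------------------------------------

    def apply_perturbation(self, p: Perturbation) -> "BooleanModel":
        """Return a copy with clamped nodes' rules replaced by constants.

        A clamped input node becomes a constant-rule internal node for the
        purposes of dynamics; the original model is unmodified.  Applying
        the same perturbation twice is idempotent.
        """
        if not p:
            return self
        clamps = p.as_dict()
        unknown = set(clamps) - set(self.index)
        if unknown:
            raise KeyError(f"cannot clamp unknown node(s) {sorted(unknown)}")
        rules = dict(self.rules)
        for name, value in clamps.items():
            rules[name] = Const(value)
        nodes = []
        for n in self.nodes:
            if n.name in clamps and n.kind == "input":
                nodes.append(NodeSpec(n.name, "internal", n.display_symbol))
            else:
                nodes.append(n)
        m = BooleanModel(nodes, self.edges, rules,
                         name=self.name, validate=False)
        m.clamped = frozenset(clamps)
        return m

    # -- phenotype ----------------------------------------------------------

    def state_phenotype_label(self, state: Sequence[int]) -> tuple[str, bool]:
        on = [o for o in self.output_nodes if state[self.index[o]]]
        if len(on) == 0:
            return "None", False
        if len(on) == 1:
            return on[0], False
        return "Mixed", True

    def classify_attractor(self, states: Iterable[Sequence[int]]) -> Phenotype:
        """Phenotype of an attractor from its output-node values.

        Fixed points yield the unique ON output ("None" when all OFF);
        cyclic attractors whose member states disagree yield "Mixed".
        A state with more than one output ON is reported Mixed and flagged.
        """
        states = list(states)
        if not states:
            raise ValueError("attractor must be non-empty")
        labels = set()
        flagged = False
        for s in states:
            lab, flag = self.state_phenotype_label(s)
            flagged = flagged or flag
            labels.add(lab)
        if flagged or len(labels) > 1:
            return Phenotype("Mixed", flagged=flagged)
        return Phenotype(labels.pop())

    # -- misc ---------------------------------------------------------------

    def state_from_dict(self, values: Mapping[str, int],
                        default: int = 0) -> tuple[int, ...]:
        return tuple(int(values.get(n.name, default)) for n in self.nodes)

    def state_to_dict(self, state: Sequence[int]) -> dict[str, int]:
        return {n.name: int(v) for n, v in zip(self.nodes, state)}

    def __repr__(self):
        return (f"<BooleanModel {self.name!r}: {len(self.nodes)} nodes, "
                f"{len(self.edges)} edges>")
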