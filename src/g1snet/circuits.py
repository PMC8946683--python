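"""Signed feedback circuits and their functionality.

A circuit (feedback loop) is an elementary cycle of the signed regulatory
graph; its sign is the product of its edge signs.  Positive circuits are
the structural prerequisite for multistability, negative ones for
oscillations.  A circuit is *functional* (operative) when some network
state makes every circuit edge's discrete derivative nonzero, i.e. the
loop actively transmits along all of its edges simultaneously and thus
shapes the dynamics; a state certifying this is a witness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from .logic import BooleanModel, Perturbation, SignedEdge, WILD_TYPE

__all__ = ["Circuit", "enumerate_circuits", "edge_derivative",
           "is_functional", "perturbation_screen"]

CONTEXT_BUDGET = 2 ** 20


@dataclass(frozen=True)
class Circuit:
    """Elementary cycle of signed edges, in canonical rotation."""

    edges: tuple[SignedEdge, ...]

    @staticmethod
    def from_nodes(model: BooleanModel, nodes: Sequence[str]) -> "Circuit":
        edges = []
        k = len(nodes)
        for i, src in enumerate(nodes):
            tgt = nodes[(i + 1) % k]
            edges.append(SignedEdge(src, tgt, model.edge_sign(src, tgt)))
        return Circuit(Circuit._canonical(tuple(edges)))

    @staticmethod
    def _canonical(edges: tuple[SignedEdge, ...]) -> tuple[SignedEdge, ...]:
        # rotate so the lexicographically smallest source comes first;
        # the sign is invariant under rotation
        start = min(range(len(edges)), key=lambda i: edges[i].source)
        return edges[start:] + edges[:start]

    def __post_init__(self):
        object.__setattr__(self, "edges", Circuit._canonical(self.edges))
        nodes = [e.source for e in self.edges]
        if len(set(nodes)) != len(nodes):
            raise ValueError("circuit must be a simple cycle")
        for e, nxt in zip(self.edges, self.edges[1:] + self.edges[:1]):
            if e.target != nxt.source:
                raise ValueError("edges do not form a cycle")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(e.source for e in self.edges)

    @property
    def sign(self) -> int:
        s = 1
        for e in self.edges:
            s *= e.sign
        return s

    def __len__(self) -> int:
        return len(self.edges)

    def __repr__(self):
        return ("<Circuit %s sign=%+d>" % ("/".join(self.nodes), self.sign))


def enumerate_circuits(model: BooleanModel, max_length: int = 0) -> set[Circuit]:
    """All elementary cycles of length <= max_length (0 = unbounded).

    Johnson-style enumeration on the regulatory digraph.  Self-loops are
    circuits of length 1.  Input nodes cannot belong to a circuit (they
    have no incoming edges).
    """
    if max_length < 0:
        raise ValueError("max_length must be >= 0")
    G = nx.DiGraph()
    G.add_nodes_from(model.node_names)
    for e in model.edges:
        G.add_edge(e.source, e.target)
    bound = max_length if max_length > 0 else None
    out = set()
    for cycle in nx.simple_cycles(G, length_bound=bound):
        out.add(Circuit.from_nodes(model, cycle))
    return out


def edge_derivative(model: BooleanModel, edge: SignedEdge,
                    state: Sequence[int]) -> int:
    """Discrete Jacobian entry: f_target(x[source:=1]) - f_target(x[source:=0]).

    For monotone rules the derivative, when nonzero, equals the edge sign.
    """
    i = model.index[edge.source]
    rule = model.compiled_rule(edge.target)
    hi = list(state)
    hi[i] = 1
    lo = list(state)
    lo[i] = 0
    return rule(tuple(hi)) - rule(tuple(lo))


def is_functional(model: BooleanModel, circuit: Circuit,
                  p: Perturbation = WILD_TYPE,
                  max_witnesses: int | None = 1,
                  ) -> tuple[bool, list[tuple[int, ...]]]:
    """Does some state make every circuit edge's derivative nonzero?

    The search runs over the joint context of the circuit: the union of
    the regulators of the circuit's targets (minus the respective edge
    source, whose value the derivative quantifies over).  Nodes outside
    that context cannot change any derivative, so the search is exact
    without visiting the full state space; it proceeds by backtracking
    over context assignments, checking each edge's derivative as soon as
    its local context is complete.  Clamping any circuit node makes the
    circuit non-functional (its rule becomes constant).  Returned
    witnesses set all non-context nodes to 0.
    """
    perturbed = model.apply_perturbation(p)
    clamped = set(p.as_dict())
    if any(n in clamped for n in circuit.nodes):
        return False, []

    # local context per edge; edges checked as soon as theirs is assigned
    edge_ctx = [sorted(set(perturbed.regulators(e.target)) - {e.source})
                for e in circuit.edges]
    context_order: list[str] = []
    seen: set[str] = set()
    for ctx in edge_ctx:  # grouping by edge lets checks fire early
        for v in ctx:
            if v not in seen:
                seen.add(v)
                context_order.append(v)
    var_pos = {v: i for i, v in enumerate(context_order)}
    ready_at: dict[int, list[int]] = {}
    for k, ctx in enumerate(edge_ctx):
        depth = max((var_pos[v] + 1 for v in ctx), default=0)
        ready_at.setdefault(depth, []).append(k)

    base = [0] * len(model.nodes)
    for name, v in p.as_dict().items():
        base[model.index[name]] = v

    witnesses: list[tuple[int, ...]] = []

    def derivative_ok(k: int, assign: dict[str, int]) -> bool:
        e = circuit.edges[k]
        state = list(base)
        for nm, b in assign.items():
            state[model.index[nm]] = b
        return edge_derivative(perturbed, e, tuple(state)) != 0

    def search(depth: int, assign: dict[str, int]) -> bool:
        for k in ready_at.get(depth, ()):
            if not derivative_ok(k, assign):
                return False
        if depth == len(context_order):
            state = list(base)
            for nm, b in assign.items():
                state[model.index[nm]] = b
            witnesses.append(tuple(state))
            return max_witnesses is not None and len(witnesses) >= max_witnesses
        var = context_order[depth]
        for b in (0, 1):
            assign[var] = b
            if search(depth + 1, assign):
                del assign[var]
                return True
            del assign[var]
        return False

    search(0, {})
    return bool(witnesses), witnesses


def perturbation_screen(circuit_nodes: Sequence[str],
                        analyse: Callable[[Perturbation], set[str]],
                        ) -> list[tuple[tuple[str, ...], set[str]]]:
    """KO/E1 screen over a circuit's nodes.

    For each of the 2^k assignments of KO (clamp 0) / E1 (clamp 1) to the
    circuit's nodes, ``analyse`` runs the attractor analysis under that
    perturbation and returns the reachable phenotype labels.  Rows are
    ordered by the number of E1 clamps, then by position: for a 3-node
    circuit KO/KO/KO, E1/KO/KO, KO/E1/KO, KO/KO/E1, E1/E1/KO, E1/KO/E1,
    KO/E1/E1, E1/E1/E1.
    """
    rows = []
    k = len(circuit_nodes)
    ordered = sorted(itertools.product((0, 1), repeat=k),
                     key=lambda bits: (sum(bits),
                                       tuple(-b for b in bits)))
    for bits in ordered:
        labels = tuple("E1" if b else "KO" for b in bits)
        p = Perturbation.from_dict(dict(zip(circuit_nodes, bits)))
        rows.append((labels, analyse(p)))
    return rows
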