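"""Seeded random Boolean networks and brute-force oracles.

These fixtures let every dynamics and circuit operation be tested
exhaustively at small n: a generated model's full 2^n asynchronous STG is
enumerable, so fixed points, attractors and absorption probabilities have
an independent ground truth.  The default ``and_not`` rule template (ON
iff some activator is ON and no inhibitor is) mirrors the rule family
used by the checkpoint model, so the engine is exercised on the same
rule shapes the analysis uses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .dynamics import Attractor, _Dynamics, make_rng
from .logic import (And, BooleanModel, Expr, Not, NodeSpec, Or, Perturbation,
                    SignedEdge, Var, WILD_TYPE)

__all__ = ["RandomNetworkConfig", "generate", "brute_force_attractors",
           "brute_force_fixed_points", "full_stg"]

BRUTE_FORCE_MAX_NODES = 14
RULE_TEMPLATES = ("and_not", "nested_canalyzing", "random_monotone")


@dataclass(frozen=True)
class RandomNetworkConfig:
    n_nodes: int
    max_in_degree: int = 3
    activation_fraction: float = 0.6
    rule_template: str = "and_not"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (1 <= self.max_in_degree <= self.n_nodes):
            raise ValueError("need 1 <= max_in_degree <= n_nodes")
        if not (0.0 <= self.activation_fraction <= 1.0):
            raise ValueError("activation_fraction must lie in [0, 1]")
        if self.rule_template not in RULE_TEMPLATES:
            raise ValueError(f"unknown rule template {self.rule_template!r}")


def _literal(name: str, sign: int) -> Expr:
    return Var(name) if sign > 0 else Not(Var(name))


def _and_not_rule(regs: list[tuple[str, int]]) -> Expr:
    acts = [Var(n) for n, s in regs if s > 0]
    inhs = [Var(n) for n, s in regs if s < 0]
    act = acts[0] if len(acts) == 1 else (Or(*acts) if acts else None)
    inh = inhs[0] if len(inhs) == 1 else (Or(*inhs) if inhs else None)
    if act is None:
        return Not(inh)
    if inh is None:
        return act
    return And(act, Not(inh))


def _nested_canalyzing_rule(regs: list[tuple[str, int]], rng) -> Expr:
    order = list(regs)
    rng.shuffle(order)
    expr = _literal(*order[-1])
    for name, sign in reversed(order[:-1]):
        lit = _literal(name, sign)
        expr = And(lit, expr) if rng.random() < 0.5 else Or(lit, expr)
    return expr


def _random_monotone_rule(regs: list[tuple[str, int]], rng) -> Expr:
    k = len(regs)
    n_clauses = int(rng.integers(1, k + 1))
    clauses: list[list[tuple[str, int]]] = []
    for _ in range(n_clauses):
        size = int(rng.integers(1, k + 1))
        idx = rng.choice(k, size=size, replace=False)
        clauses.append([regs[i] for i in sorted(idx)])
    covered = {n for cl in clauses for n, _ in cl}
    for name, sign in regs:  # every regulator must appear in the rule
        if name not in covered:
            cl = clauses[int(rng.integers(0, len(clauses)))]
            if name not in {n for n, _ in cl}:
                cl.append((name, sign))
    terms = []
    for cl in clauses:
        lits = [_literal(n, s) for n, s in cl]
        terms.append(lits[0] if len(lits) == 1 else And(*lits))
    return terms[0] if len(terms) == 1 else Or(*terms)


def generate(config: RandomNetworkConfig) -> BooleanModel:
    """Draw a valid model reproducibly from the config's seed.

    The same config yields a byte-identical ``.bnet`` serialization.
    """
    rng = make_rng(config.seed)
    n = config.n_nodes
    names = [f"n{i}" for i in range(n)]
    nodes = [NodeSpec(name, "internal") for name in names]
    edges: set[SignedEdge] = set()
    rules: dict[str, Expr] = {}
    for target in names:
        k = int(rng.integers(1, config.max_in_degree + 1))
        sources = [names[i] for i in sorted(rng.choice(n, size=k, replace=False))]
        regs = [(s, 1 if rng.random() < config.activation_fraction else -1)
                for s in sources]
        if config.rule_template == "and_not":
            expr = _and_not_rule(regs)
        elif config.rule_template == "nested_canalyzing":
            expr = _nested_canalyzing_rule(regs, rng)
        else:
            expr = _random_monotone_rule(regs, rng)
        rules[target] = expr
        for s, sign in regs:
            edges.add(SignedEdge(s, target, sign))
    return BooleanModel(nodes, edges, rules,
                        name=f"random_{config.rule_template}_s{config.seed}")


# ---------------------------------------------------------------------------
# brute-force oracles (exhaustive over the full 2^n state space)
# ---------------------------------------------------------------------------

def _guard(model: BooleanModel):
    if len(model.nodes) > BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_MAX_NODES} nodes, "
            f"model has {len(model.nodes)}")


def full_stg(model: BooleanModel, p: Perturbation = WILD_TYPE) -> nx.DiGraph:
    """The asynchronous STG over all 2^n states (clamped nodes held fixed)."""
    _guard(model)
    dyn = _Dynamics(model, p)
    clamps = p.as_dict()
    fixed = {model.index[k]: v for k, v in clamps.items()}
    G = nx.DiGraph()
    n = len(model.nodes)
    for bits in itertools.product((0, 1), repeat=n):
        if any(bits[i] != v for i, v in fixed.items()):
            continue
        G.add_node(bits)
        for t in dyn.successors(bits):
            G.add_edge(bits, t)
    return G


def brute_force_fixed_points(model: BooleanModel,
                             p: Perturbation = WILD_TYPE) -> set[tuple[int, ...]]:
    G = full_stg(model, p)
    return {s for s in G.nodes if G.out_degree(s) == 0}


def brute_force_attractors(model: BooleanModel,
                           p: Perturbation = WILD_TYPE) -> set[Attractor]:
    """Attractors from the FULL 2^n STG by terminal-SCC analysis."""
    G = full_stg(model, p)
    cond = nx.condensation(G)
    out = set()
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = frozenset(cond.nodes[comp_id]["members"])
            kind = "fixed_point" if len(members) == 1 else "cyclic"
            out.add(Attractor(members, kind, model.classify_attractor(members)))
    return out
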