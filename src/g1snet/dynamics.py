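"""Asynchronous dynamics of Boolean regulatory models.

Under the asynchronous update scheme exactly one unstable node (a node
whose rule value differs from its current value) flips per transition, so
a state can have several successors and trajectories are non-deterministic.
The reachable behaviour is summarised by the state transition graph (STG);
its terminal strongly connected components are the attractors: fixed
points (single state, no successors) or cyclic attractors (>= 2 states).

Reachability probabilities are computed two ways and cross-checked:

* Monte Carlo random walks that draw the next transition uniformly among
  the enabled ones (the "exact exit probabilities" scheme: every enabled
  transition is equally likely at each step), and
* an exact linear solve for the absorption probabilities of the induced
  uniform-transition Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .logic import BooleanModel, Perturbation, Phenotype, WILD_TYPE

__all__ = [
    "Attractor", "PhenotypeDistribution", "StateBudgetExceeded",
    "async_successors", "unstable_nodes", "enumerate_fixed_points",
    "build_stg", "find_attractors", "exact_absorption",
    "monte_carlo_phenotypes", "make_rng",
]

DEFAULT_MAX_STATES = 2_000_000
DEFAULT_MAX_STEPS = 10_000

State = tuple[int, ...]


class StateBudgetExceeded(RuntimeError):
    """STG exploration hit the state budget; use sampling instead."""


def make_rng(seed: int) -> np.random.Generator:
    """Counter-based generator (Philox) for cross-platform reproducibility."""
    return np.random.Generator(np.random.Philox(key=seed))


# ---------------------------------------------------------------------------
# prepared dynamics context
# ---------------------------------------------------------------------------

class _Dynamics:
    """Model + perturbation compiled for fast successor computation."""

    def __init__(self, model: BooleanModel, p: Perturbation = WILD_TYPE):
        self.model = model
        self.perturbation = p
        self.perturbed = model.apply_perturbation(p)
        clamped = set(p.as_dict())
        # inputs are frozen parameters of a run; clamped nodes never update
        self.updatable: list[int] = [
            i for i, n in enumerate(model.nodes)
            if n.kind != "input" and n.name not in clamped
        ]
        pm = self.perturbed
        self.rule_fns = {i: pm.compiled_rule(model.nodes[i].name)
                         for i in self.updatable}
        self._succ_cache: dict[State, tuple[State, ...]] = {}
        self._bit_fns: dict[int, object] | None = None

    # -- integer-encoded fast path (bit i of the int = node i) -------------

    def encode(self, state: Sequence[int]) -> int:
        return sum(int(b) << i for i, b in enumerate(state))

    def decode(self, code: int) -> State:
        return tuple((code >> i) & 1 for i in range(len(self.model.nodes)))

    def bit_fns(self):
        if self._bit_fns is None:
            fns = {}
            ix = self.model.index
            for i in self.updatable:
                expr = self.perturbed.rules[self.model.nodes[i].name]
                code = (expr.to_python(ix)
                        .replace("s[", "((s>>").replace("]", ")&1)"))
                fns[i] = eval("lambda s: 1 if %s else 0" % code)
            self._bit_fns = fns
        return self._bit_fns

    def force_clamps(self, state: Sequence[int]) -> State:
        s = list(int(v) for v in state)
        for name, v in self.perturbation.as_dict().items():
            s[self.model.index[name]] = v
        return tuple(s)

    def successors(self, state: State) -> tuple[State, ...]:
        cached = self._succ_cache.get(state)
        if cached is None:
            out = []
            for i in self.updatable:
                if self.rule_fns[i](state) != state[i]:
                    nxt = list(state)
                    nxt[i] = 1 - nxt[i]
                    out.append(tuple(nxt))
            cached = tuple(out)
            self._succ_cache[state] = cached
        return cached


def unstable_nodes(model: BooleanModel, state: Sequence[int],
                   p: Perturbation = WILD_TYPE) -> list[str]:
    """Names of unclamped non-input nodes whose rule disagrees with the state."""
    dyn = _Dynamics(model, p)
    state = tuple(int(v) for v in state)
    return [model.nodes[i].name for i in dyn.updatable
            if dyn.rule_fns[i](state) != state[i]]


def async_successors(model: BooleanModel, state: Sequence[int],
                     p: Perturbation = WILD_TYPE) -> set[State]:
    """One successor per unstable node, each flipping exactly that node.

    Empty iff ``state`` is a fixed point of the (perturbed) dynamics.
    """
    if len(state) != len(model.nodes):
        raise ValueError("state dimension does not match model")
    dyn = _Dynamics(model, p)
    return set(dyn.successors(tuple(int(v) for v in state)))


# ---------------------------------------------------------------------------
# fixed points: branch-and-prune with three-valued constraint propagation
# ---------------------------------------------------------------------------

def enumerate_fixed_points(model: BooleanModel, p: Perturbation = WILD_TYPE,
                           input_values: Mapping[str, int] | None = None,
                           ) -> set[State]:
    """All states where every unclamped non-input node satisfies x_v = f_v(x).

    Sound and complete without enumerating 2^n states: a partial assignment
    is propagated through the rules with Kleene three-valued evaluation
    (a rule that is already decided forces its target's value at a fixed
    point), and contradictions prune the branch.  Input nodes take the
    value given in ``input_values``; unspecified inputs are branched over.
    """
    perturbed = model.apply_perturbation(p)
    clamps = p.as_dict()
    input_values = dict(input_values or {})
    n = len(model.nodes)
    names = model.node_names

    constrained: list[int] = []  # indices whose rule must equal their value
    init: list[int | None] = [None] * n
    for i, node in enumerate(model.nodes):
        if node.name in clamps:
            init[i] = clamps[node.name]
        elif node.kind == "input":
            if node.name in input_values:
                init[i] = int(input_values[node.name])
        else:
            constrained.append(i)
            if node.name in input_values:
                init[i] = int(input_values[node.name])

    rules = {i: perturbed.rules[names[i]] for i in constrained}
    results: set[State] = set()

    def propagate(assign: list[int | None]) -> bool:
        changed = True
        while changed:
            changed = False
            env = {names[i]: assign[i] for i in range(n)}
            for i in constrained:
                val = rules[i].evaluate3(env)
                if val is None:
                    continue
                if assign[i] is None:
                    assign[i] = val
                    env[names[i]] = val
                    changed = True
                elif assign[i] != val:
                    return False
        return True

    def search(assign: list[int | None]) -> None:
        assign = list(assign)
        if not propagate(assign):
            return
        try:
            j = assign.index(None)
        except ValueError:
            results.add(tuple(assign))  # fully assigned and consistent
            return
        for v in (0, 1):
            branch = list(assign)
            branch[j] = v
            search(branch)

    search(init)
    return results


# ---------------------------------------------------------------------------
# state transition graph and attractors
# ---------------------------------------------------------------------------

def build_stg(model: BooleanModel, root: Sequence[int],
              p: Perturbation = WILD_TYPE,
              max_states: int = DEFAULT_MAX_STATES) -> nx.DiGraph:
    """Breadth-first closure of the asynchronous successors from ``root``.

    Returns a DiGraph whose nodes are state tuples; ``G.graph['root']``
    holds the root.  Raises StateBudgetExceeded past ``max_states``.
    """
    if len(root) != len(model.nodes):
        raise ValueError("root dimension does not match model")
    dyn = _Dynamics(model, p)
    root_t = dyn.force_clamps(root)
    G = nx.DiGraph(root=root_t, model=model.name)
    G.add_node(root_t)
    frontier = [root_t]
    while frontier:
        nxt_frontier = []
        for s in frontier:
            for t in dyn.successors(s):
                if t not in G:
                    if G.number_of_nodes() >= max_states:
                        raise StateBudgetExceeded(
                            f"STG exceeded {max_states} states; "
                            "use Monte Carlo sampling for this scenario")
                    G.add_node(t)
                    nxt_frontier.append(t)
                G.add_edge(s, t)
        frontier = nxt_frontier
    return G


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the asynchronous STG, tagged with its phenotype."""

    states: frozenset[State]
    kind: str  # "fixed_point" | "cyclic"
    phenotype: Phenotype

    def __post_init__(self):
        if self.kind not in ("fixed_point", "cyclic"):
            raise ValueError(f"bad attractor kind {self.kind!r}")
        if not self.states:
            raise ValueError("attractor must be non-empty")

    @property
    def is_fixed_point(self) -> bool:
        return self.kind == "fixed_point"

    @property
    def representative(self) -> State:
        return min(self.states)

    def __repr__(self):
        return (f"<Attractor {self.kind} |S|={len(self.states)} "
                f"{self.phenotype}>")


def find_attractors(stg: nx.DiGraph, model: BooleanModel) -> set[Attractor]:
    """Terminal SCCs of a complete STG, classified by kind and phenotype."""
    cond = nx.condensation(stg)
    attractors = set()
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = frozenset(cond.nodes[comp_id]["members"])
            kind = "fixed_point" if len(members) == 1 else "cyclic"
            if kind == "fixed_point":
                (s,) = members
                if stg.out_degree(s) > 0:  # self-loop-free async STG: cannot happen
                    kind = "cyclic"
            attractors.add(Attractor(members, kind,
                                     model.classify_attractor(members)))
    return attractors


# ---------------------------------------------------------------------------
# reachability probabilities
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeDistribution:
    """Probabilities of reaching each attractor from a given root."""

    probabilities: dict[Attractor, float]
    n_runs: int
    seed: int | None
    method: str  # "monte_carlo" | "exact"

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def by_phenotype(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for att, prob in self.probabilities.items():
            out[att.phenotype.label] = out.get(att.phenotype.label, 0.0) + prob
        return out

    def __getitem__(self, phenotype_label: str) -> float:
        return self.by_phenotype().get(phenotype_label, 0.0)


def exact_absorption(stg: nx.DiGraph, model: BooleanModel,
                     root: State | None = None) -> PhenotypeDistribution:
    """Absorption probabilities of the uniform-transition Markov chain.

    Each enabled transition of a state is taken with equal probability;
    terminal SCCs are the absorbing classes.  Solved exactly with a sparse
    linear system over the transient states.
    """
    root = root if root is not None else stg.graph["root"]
    attractors = sorted(find_attractors(stg, model),
                        key=lambda a: a.representative)
    state_to_att: dict[State, int] = {}
    for k, att in enumerate(attractors):
        for s in att.states:
            state_to_att[s] = k

    if root in state_to_att:
        probs = {att: (1.0 if k == state_to_att[root] else 0.0)
                 for k, att in enumerate(attractors)}
        return PhenotypeDistribution(probs, 0, None, "exact")

    transient = [s for s in stg.nodes if s not in state_to_att]
    t_index = {s: i for i, s in enumerate(transient)}
    nt, na = len(transient), len(attractors)
    Q = sp.lil_matrix((nt, nt))
    R = np.zeros((nt, na))
    for s in transient:
        succs = list(stg.successors(s))
        w = 1.0 / len(succs)
        i = t_index[s]
        for t in succs:
            if t in state_to_att:
                R[i, state_to_att[t]] += w
            else:
                Q[i, t_index[t]] += w
    A = sp.identity(nt, format="csc") - Q.tocsc()
    H = spla.spsolve(A, R)  # (nt, na) absorption probabilities
    H = np.atleast_2d(H)
    if H.shape != (nt, na):
        H = H.reshape(nt, na)
    row = H[t_index[root]]
    total = row.sum()
    assert abs(total - 1.0) < 1e-6, "absorbing chain must conserve probability"
    row = row / total
    probs = {att: float(row[k]) for k, att in enumerate(attractors)}
    return PhenotypeDistribution(probs, 0, None, "exact")


def monte_carlo_phenotypes(model: BooleanModel, root: Sequence[int],
                           p: Perturbation = WILD_TYPE,
                           n_runs: int = 100_000, seed: int = 0,
                           max_steps: int = DEFAULT_MAX_STEPS,
                           ) -> PhenotypeDistribution:
    """Uniform-transition random walks from ``root`` absorbed at attractors.

    Each walk draws the next state uniformly among the enabled asynchronous
    transitions and stops at the first fixed point.  A walk that is still
    moving after ``max_steps`` is routed to cycle detection: if it sits in
    a cyclic terminal SCC the walk counts for that attractor, otherwise the
    run aborts (the reachable graph should contain no such trap).
    Bit-reproducible for a given seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    dyn = _Dynamics(model, p)
    root_c = dyn.encode(dyn.force_clamps(root))
    fns = dyn.bit_fns()
    upd = dyn.updatable
    masks = {i: 1 << i for i in upd}
    rng = make_rng(seed)

    counts: dict[int, int] = {}            # fixed point -> hits
    cyclic_counts: dict[frozenset, int] = {}
    cyclic_member: dict[int, frozenset] = {}
    succ_cache: dict[int, tuple[int, ...]] = {}

    BLOCK = 1 << 14
    buf = rng.random(BLOCK)
    cursor = 0

    for _ in range(n_runs):
        s = root_c
        for _step in range(max_steps):
            succs = succ_cache.get(s)
            if succs is None:
                succs = tuple(s ^ masks[i] for i in upd
                              if fns[i](s) != (s >> i) & 1)
                succ_cache[s] = succs
            k = len(succs)
            if k == 0:
                counts[s] = counts.get(s, 0) + 1
                break
            if cursor >= BLOCK:
                buf = rng.random(BLOCK)
                cursor = 0
            s = succs[int(buf[cursor] * k)]
            cursor += 1
        else:
            cyc = cyclic_member.get(s)
            if cyc is None:
                closure = build_stg(model, dyn.decode(s), p)
                terminal = find_attractors(closure, model)
                st = dyn.decode(s)
                hit = next((a for a in terminal if st in a.states), None)
                if hit is None or hit.kind != "cyclic":
                    raise RuntimeError(
                        f"walk not absorbed after {max_steps} steps and not "
                        "inside a cyclic attractor")
                cyc = frozenset(dyn.encode(x) for x in hit.states)
                for c in cyc:
                    cyclic_member[c] = cyc
            cyclic_counts[cyc] = cyclic_counts.get(cyc, 0) + 1

    probs: dict[Attractor, float] = {}
    for s, c in sorted(counts.items()):
        st = dyn.decode(s)
        att = Attractor(frozenset((st,)), "fixed_point",
                        model.classify_attractor([st]))
        probs[att] = c / n_runs
    for states, c in cyclic_counts.items():
        sts = frozenset(dyn.decode(x) for x in states)
        att = Attractor(sts, "cyclic", model.classify_attractor(sts))
        probs[att] = c / n_runs
    return PhenotypeDistribution(probs, n_runs, seed, "monte_carlo")
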