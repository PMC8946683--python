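"""Tabular and graphical reports over the checkpoint analyses.

Everything returns a pandas DataFrame; probabilities are kept as
fractions together with n_runs and seed so the Monte Carlo error stays
interpretable — percent formatting belongs to rendering, not data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .circuits import enumerate_circuits, is_functional, perturbation_screen
from .dynamics import exact_absorption, build_stg
from .model import NsclcModelBundle, NOVEL_CIRCUITS, INPUT_NODE

__all__ = ["fixed_point_table", "probability_report", "probability_chart",
           "circuit_report", "screen_report", "write_stg_edgelist",
           "write_stg_dot"]


def fixed_point_table(bundle: NsclcModelBundle,
                      scenarios: Sequence[str] | None = None) -> pd.DataFrame:
    """One row per (scenario, fixed point): phenotype plus every node value.

    The machine-readable twin of a stable-state matrix figure: scenarios
    down the side, molecules across the top.
    """
    names = list(scenarios) if scenarios else list(bundle.scenarios)
    m = bundle.model
    rows = []
    for name in names:
        scn = bundle.scenarios[name]
        for k, fp in enumerate(bundle.fixed_points(name)):
            row = {"scenario": name, "input": scn.input_value,
                   "fixed_point": k,
                   "phenotype": m.classify_attractor([fp]).label}
            row.update(m.state_to_dict(fp))
            rows.append(row)
    return pd.DataFrame(rows)


def probability_report(bundle: NsclcModelBundle,
                       scenarios: Sequence[str],
                       n_runs: int = 100_000, seed: int = 0,
                       exact: bool = False,
                       max_states: int = 500_000) -> pd.DataFrame:
    """Phenotype probabilities per scenario (Monte Carlo, optionally exact).

    The exact estimator solves the absorption linear system on the full
    reachable STG and is only attempted when that graph fits the state
    budget; scenarios whose reachable graph overflows report Monte Carlo
    only.
    """
    rows = []
    for name in scenarios:
        dist = bundle.monte_carlo(name, n_runs=n_runs, seed=seed)
        for pheno, prob in sorted(dist.by_phenotype().items()):
            rows.append({"scenario": name, "phenotype": pheno,
                         "probability": prob, "method": "monte_carlo",
                         "n_runs": n_runs, "seed": seed})
        if exact:
            scn = bundle.scenarios[name]
            try:
                stg = build_stg(bundle.model, bundle.root_state(name),
                                scn.perturbation, max_states=max_states)
            except Exception:
                continue
            dist = exact_absorption(stg, bundle.model)
            for pheno, prob in sorted(dist.by_phenotype().items()):
                rows.append({"scenario": name, "phenotype": pheno,
                             "probability": prob, "method": "exact",
                             "n_runs": 0, "seed": seed})
    return pd.DataFrame(rows)


def probability_chart(report: pd.DataFrame, path: str | Path) -> None:
    """Stacked phenotype-probability bars, one bar per scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mc = report[report["method"] == "monte_carlo"]
    pivot = mc.pivot_table(index="scenario", columns="phenotype",
                           values="probability", fill_value=0.0, sort=False)
    palette = {"Proliferation": "#4daf4a", "Senescence": "#377eb8",
               "Apoptosis": "#e41a1c", "None": "#bbbbbb", "Mixed": "#984ea3"}
    colors = [palette.get(c, "#777777") for c in pivot.columns]
    ax = pivot.plot(kind="bar", stacked=True, color=colors, figsize=(9, 4.5))
    ax.set_ylabel("reachability probability")
    ax.set_ylim(0, 1)
    ax.legend(title=None, fontsize=8)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)


def circuit_report(bundle: NsclcModelBundle, max_length: int = 0,
                   functional_only: bool = False) -> pd.DataFrame:
    """Inventory of elementary circuits with sign and functionality."""
    m = bundle.model
    rows = []
    for c in sorted(enumerate_circuits(m, max_length),
                    key=lambda c: (len(c), c.nodes)):
        func, wit = is_functional(m, c)
        if functional_only and not func:
            continue
        rows.append({"nodes": "/".join(c.nodes), "length": len(c),
                     "sign": "+" if c.sign > 0 else "-",
                     "functional": func,
                     "novel": tuple(sorted(c.nodes)) in
                              {tuple(sorted(n)) for n in NOVEL_CIRCUITS}})
    return pd.DataFrame(rows)


def screen_report(bundle: NsclcModelBundle) -> pd.DataFrame:
    """The 24-row KO/E1 screen over the three novel positive circuits."""
    from .dynamics import enumerate_fixed_points

    m = bundle.model
    rows = []
    # present rows in the conventional miRNA/factor/lncRNA order, not the
    # canonical rotation the Circuit object stores
    for nodes in NOVEL_CIRCUITS:

        def analyse(p):
            fps = enumerate_fixed_points(m, p, {INPUT_NODE: 1})
            return {m.classify_attractor([fp]).label for fp in fps}

        for labels, phenos in perturbation_screen(nodes, analyse):
            rows.append({"circuit": "/".join(nodes),
                         "perturbation": "/".join(labels),
                         "phenotypes": " and ".join(sorted(phenos))})
    return pd.DataFrame(rows)


def write_stg_edgelist(stg: nx.DiGraph, path: str | Path) -> None:
    """Plain-text STG: one '<state> <state>' pair of 0/1 strings per line."""
    with open(path, "w") as fh:
        root = stg.graph.get("root")
        if root is not None:
            fh.write("# root %s\n" % "".join(map(str, root)))
        for s, t in stg.edges:
            fh.write("%s %s\n" % ("".join(map(str, s)), "".join(map(str, t))))


def write_stg_dot(stg: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph STG {\n  node [shape=box, fontname=monospace];\n")
        for s, t in stg.edges:
            fh.write('  "%s" -> "%s";\n'
                     % ("".join(map(str, s)), "".join(map(str, t))))
        fh.write("}\n")
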