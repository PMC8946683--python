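"""The NSCLC G1/S-checkpoint Boolean model: miR-34a versus ANRIL/UFC1.

The network captures how a non-small-cell lung cancer cell decides, at
the G1/S checkpoint, between continued proliferation, p21-mediated
senescence and caspase-mediated apoptosis, and how that decision is
steered by the tumour-suppressor microRNA miR-34a and the two oncogenic
long non-coding RNAs ANRIL and UFC1 that sponge it.

Wiring (single input DNA_Damage; three read-out nodes):

* DNA damage activates ATM, which inactivates Mdm2 and thereby
  stabilises p53; ATM and p53 both induce miR-34a.
* p53 signalling is split into an arrest form p53-A (Ser-15/20, drives
  p21 and Wip1) and a killer form p53-K (Ser-46, drives Bax ->
  caspase-3); the two forms are mutually exclusive and their
  interconversion is governed by Wip1 and p53-INP1.
* miR-34a directly represses its validated targets Myc, HDAC1, Sirt-1,
  E2F1, Cdc25A, BCL2 and the CDK4/6-cyclin D and CDK2-cyclin E
  complexes.
* The sponges: E2F1 induces UFC1 and (with Myc) ANRIL; both lncRNAs
  repress miR-34a and feed EZH2, which silences PTEN (activating AKT),
  KLF2 (an upstream activator of p21) and miR-34a itself.  This closes
  the three positive circuits miR-34a/E2F1/ANRIL, miR-34a/E2F1/UFC1 and
  miR-34a/Myc/ANRIL.

With no damage the model has a single proliferative fixed point (cycle
promoters, Myc, ANRIL and UFC1 ON; miR-34a OFF).  Under sustained
damage it is bistable between a senescent fixed point (p53-A, p21,
miR-34a ON) and an apoptotic one (p53-K, Bax, caspase-3, miR-34a ON);
the asynchronous race between the slow miR-34a -> p21 arm and the fast
p53-K -> caspase-3 arm sets the phenotype probabilities.

The rule set is a reconstruction: node inventory and interactions
follow the published wiring, and the handful of logical choices the
wiring leaves open were fixed against the published fixed points,
perturbation phenotypes and Monte Carlo probabilities (the calibration
battery in :func:`calibration_report`).  See docs/methods.md for every
such decision and its biological grounding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .circuits import Circuit, enumerate_circuits, is_functional
from .dynamics import (build_stg, enumerate_fixed_points, find_attractors,
                       monte_carlo_phenotypes, PhenotypeDistribution)
from .io import loads_bnet, dumps_bnet
from .logic import (BooleanModel, NodeSpec, Perturbation, SignedEdge,
                    parse_expression, WILD_TYPE)

__all__ = ["NODES", "RULES", "NOVEL_CIRCUITS", "Scenario", "NsclcModelBundle",
           "build_nsclc_model", "load_packaged_model", "calibration_report"]

#: node name, kind, display symbol (the field-standard label)
NODES: tuple[tuple[str, str, str], ...] = (
    ("DNA_Damage", "input", "DNA Damage"),
    ("ATM", "internal", "ATM"),
    ("p53", "internal", "p53"),
    ("Mdm2", "internal", "Mdm2"),
    ("Wip1", "internal", "Wip1"),
    ("p53_A", "internal", "p53-A"),
    ("p53_K", "internal", "p53-K"),
    ("p53_INP1", "internal", "p53-INP1"),
    ("p21", "internal", "p21"),
    ("Bax", "internal", "Bax"),
    ("Casp3", "internal", "Caspase3"),
    ("BCL2", "internal", "BCL2"),
    ("miR34a", "internal", "miR-34a"),
    ("ANRIL", "internal", "ANRIL"),
    ("UFC1", "internal", "UFC1"),
    ("EZH2", "internal", "EZH2"),
    ("PTEN", "internal", "PTEN"),
    ("AKT", "internal", "AKT"),
    ("KLF2", "internal", "KLF2"),
    ("Myc", "internal", "Myc"),
    ("HDAC1", "internal", "HDAC1"),
    ("Sirt1", "internal", "Sirt-1"),
    ("E2F1", "internal", "E2F1"),
    ("Cdc25A", "internal", "Cdc25A"),
    ("CDK46_CycD", "internal", "CDK46/CycD"),
    ("CDK2_CycE", "internal", "CDK2/CycE"),
    ("RB", "internal", "RB"),
    ("Proliferation", "output", "Proliferation"),
    ("Senescence", "output", "Senescence"),
    ("Apoptosis", "output", "Apoptosis"),
)

RULES: dict[str, str] = {
    "ATM": "DNA_Damage & (E2F1 | !(Wip1 & HDAC1))",
    "p53": "ATM & !Mdm2",
    "Mdm2": "(p53 | AKT) & !ATM",
    "Wip1": "p53 & p53_A",
    "p53_A": "p53 & !p53_K & !p53_INP1 & !E2F1",
    "p53_K": "p53 & !p53_A & !p21",
    "p53_INP1": "p53_A & !Wip1",
    "p21": "(p53_A | KLF2) & !Myc & !HDAC1 & !Casp3",
    "Bax": "p53_K & !BCL2",
    "Casp3": "Bax & !p21",
    "BCL2": "!miR34a & !p53",
    "miR34a": "(ATM & p53 & !Casp3) | ((ATM | p53) & !ANRIL & !UFC1 & !EZH2)",
    "ANRIL": "E2F1 | Myc",
    "UFC1": "E2F1",
    "EZH2": "ANRIL | UFC1 | !p53",
    "PTEN": "p53 | !EZH2",
    "AKT": "!PTEN",
    "KLF2": "!EZH2",
    "Myc": "(E2F1 | AKT) & !miR34a & !p21 & !p53",
    "HDAC1": "Myc | !miR34a",
    "Sirt1": "E2F1 & !miR34a",
    "E2F1": "!miR34a & !Casp3 & ((Myc & !RB) | (ATM & !Sirt1))",
    "Cdc25A": "(E2F1 | Myc) & !miR34a & !ATM",
    "CDK46_CycD": "Myc & !miR34a & !p21",
    "CDK2_CycE": "E2F1 & Cdc25A & !miR34a & !p21",
    "RB": "!CDK46_CycD & !CDK2_CycE",
    "Proliferation": "CDK46_CycD & CDK2_CycE & Cdc25A & !p21 & !Casp3",
    "Senescence": "p21 & !Casp3",
    "Apoptosis": "Casp3",
}

#: the three lncRNA/miRNA positive circuits the analysis centres on
NOVEL_CIRCUITS: tuple[tuple[str, str, str], ...] = (
    ("miR34a", "E2F1", "ANRIL"),
    ("miR34a", "E2F1", "UFC1"),
    ("miR34a", "Myc", "ANRIL"),
)

INPUT_NODE = "DNA_Damage"
PHENOTYPE_OUTPUTS = ("Proliferation", "Senescence", "Apoptosis")


@dataclass(frozen=True)
class Scenario:
    """A named in-silico experiment: clamp map + input value + expectation.

    ``expected_phenotypes`` is the set of phenotypes of the reachable
    attractors reported for the experiment; ``expected_probabilities``
    carries the published Monte Carlo fractions where the study printed
    them (plain fractions, not percentages).
    """

    name: str
    clamps: tuple[tuple[str, int], ...]
    input_value: int
    expected_phenotypes: frozenset[str]
    expected_probabilities: tuple[tuple[str, float], ...] | None = None
    note: str = ""

    @property
    def perturbation(self) -> Perturbation:
        return Perturbation(self.clamps)

    def clamp_dict(self) -> dict[str, int]:
        return dict(self.clamps)


def _scn(name, clamps, input_value, phenos, probs=None, note=""):
    return Scenario(name, tuple(sorted(clamps.items())), input_value,
                    frozenset(phenos),
                    tuple(sorted(probs.items())) if probs else None, note)


def _build_scenarios() -> dict[str, Scenario]:
    s: list[Scenario] = [
        _scn("WT_no_damage", {}, 0, {"Proliferation"},
             note="unstressed wild type: single proliferative fixed point"),
        _scn("WT_damage", {}, 1, {"Senescence", "Apoptosis"},
             probs={"Apoptosis": 0.80, "Senescence": 0.20},
             note="wild type under sustained DNA damage: bistable"),
        # lncRNA loss of function (damage on)
        _scn("UFC1_KO", {"UFC1": 0}, 1, {"Senescence", "Apoptosis"},
             note="miR-34a ON in every fixed point"),
        _scn("ANRIL_KO", {"ANRIL": 0}, 1, {"Senescence", "Apoptosis"},
             note="miR-34a ON in every fixed point"),
        _scn("ANRIL_KO_UFC1_KO", {"ANRIL": 0, "UFC1": 0}, 1,
             {"Senescence", "Apoptosis"},
             note="double sponge knockdown: increased miR-34a expression"),
        # lncRNA gain of function (no damage: proliferative escape)
        _scn("UFC1_E1", {"UFC1": 1}, 0, {"Proliferation"},
             note="sponge overexpression keeps miR-34a OFF"),
        _scn("ANRIL_E1", {"ANRIL": 1}, 0, {"Proliferation"},
             note="sponge overexpression keeps miR-34a OFF"),
        # miR-34a rescue of the sponge knockdowns (damage on)
        _scn("UFC1_KO_miR34a_E1", {"UFC1": 0, "miR34a": 1}, 1,
             {"Senescence", "Apoptosis"},
             probs={"Senescence": 0.60, "Apoptosis": 0.40}),
        _scn("ANRIL_KO_miR34a_E1", {"ANRIL": 0, "miR34a": 1}, 1,
             {"Senescence", "Apoptosis"},
             probs={"Senescence": 0.60, "Apoptosis": 0.40}),
        # miR-34a perturbations
        _scn("miR34a_KO", {"miR34a": 0}, 1, {"Apoptosis"},
             note="senescence abrogated, apoptosis only"),
        _scn("miR34a_E1", {"miR34a": 1}, 1, {"Senescence", "Apoptosis"},
             note="lncRNAs OFF in every fixed point"),
        _scn("UFC1_KO_miR34a_KO", {"UFC1": 0, "miR34a": 0}, 1, {"Apoptosis"}),
        _scn("ANRIL_KO_miR34a_KO", {"ANRIL": 0, "miR34a": 0}, 1, {"Apoptosis"}),
        # Myc perturbations
        _scn("Myc_KO", {"Myc": 0}, 1, {"Senescence", "Apoptosis"},
             note="lncRNAs OFF in every fixed point"),
        _scn("Myc_E1", {"Myc": 1}, 1, {"Apoptosis"},
             note="miR-34a OFF, apoptosis only"),
    ]
    # circuit-perturbation screen: 8 KO/E1 triples per novel circuit;
    # senescence survives only when miR-34a is forced ON and neither the
    # E2F1 hub nor the screened lncRNA path blocks the p21 arm
    for nodes in NOVEL_CIRCUITS:
        for bits in sorted(itertools.product((0, 1), repeat=3),
                           key=lambda b: (sum(b), tuple(-x for x in b))):
            labels = "_".join(f"{n}_{'E1' if b else 'KO'}"
                              for n, b in zip(nodes, bits))
            mir, partner, lnc = bits
            if mir == 1 and partner == 0:
                expected = {"Senescence", "Apoptosis"}
            else:
                expected = {"Apoptosis"}
            s.append(_scn(labels, dict(zip(nodes, bits)), 1, expected,
                          note="circuit screen: %s" % "/".join(nodes)))
    out = {}
    for scn in s:
        if scn.name in out:
            continue  # the three circuits share some triples (same clamps)
        out[scn.name] = scn
    return out


@dataclass
class NsclcModelBundle:
    """Model + scenario catalogue + the three novel circuits."""

    model: BooleanModel
    scenarios: dict[str, Scenario]
    novel_circuits: tuple[Circuit, ...]

    # -- scenario plumbing --------------------------------------------------

    def scenario(self, name: str) -> tuple[int, Perturbation]:
        """Input value and perturbation for a named experiment."""
        try:
            scn = self.scenarios[name]
        except KeyError:
            raise KeyError(f"unknown scenario {name!r}; known: "
                           f"{sorted(self.scenarios)}") from None
        return scn.input_value, scn.perturbation

    def proliferative_state(self) -> tuple[int, ...]:
        """The unique damage-OFF wild-type fixed point."""
        fps = enumerate_fixed_points(self.model,
                                     input_values={INPUT_NODE: 0})
        assert len(fps) == 1, "expected a unique unstressed fixed point"
        return next(iter(fps))

    def root_state(self, name: str) -> tuple[int, ...]:
        """Initial state for a scenario's dynamics.

        Damage-ON scenarios start from the proliferative fixed point with
        DNA_Damage switched to 1 (a cycling cell suffering genotoxic
        stress); damage-OFF scenarios start from the all-zero state.
        Clamps are forced in either case.
        """
        scn = self.scenarios[name]
        if scn.input_value:
            base = list(self.proliferative_state())
        else:
            base = [0] * len(self.model.nodes)
        base[self.model.index[INPUT_NODE]] = scn.input_value
        for node, v in scn.clamps:
            base[self.model.index[node]] = v
        return tuple(base)

    def fixed_points(self, name: str) -> list[tuple[int, ...]]:
        scn = self.scenarios[name]
        return sorted(enumerate_fixed_points(
            self.model, scn.perturbation,
            {INPUT_NODE: scn.input_value}))

    def reachable_attractors(self, name: str, max_states: int = 500_000):
        scn = self.scenarios[name]
        stg = build_stg(self.model, self.root_state(name), scn.perturbation,
                        max_states=max_states)
        return find_attractors(stg, self.model)

    def monte_carlo(self, name: str, n_runs: int = 100_000,
                    seed: int = 0) -> PhenotypeDistribution:
        scn = self.scenarios[name]
        return monte_carlo_phenotypes(self.model, self.root_state(name),
                                      scn.perturbation, n_runs=n_runs,
                                      seed=seed)

    def fixed_point_phenotypes(self, name: str) -> set[str]:
        return {self.model.classify_attractor([fp]).label
                for fp in self.fixed_points(name)}


def build_nsclc_model() -> NsclcModelBundle:
    """Construct the checkpoint model from its authoritative rule set."""
    nodes = [NodeSpec(n, k, d) for n, k, d in NODES]
    edges: set[SignedEdge] = set()
    from .io import _infer_sign
    for target, rule in RULES.items():
        expr = parse_expression(rule)
        for var in sorted(expr.variables()):
            edges.add(SignedEdge(var, target, _infer_sign(expr, var)))
    model = BooleanModel(nodes, edges, RULES, name="nsclc_g1s")
    circuits = tuple(Circuit.from_nodes(model, nodes_)
                     for nodes_ in NOVEL_CIRCUITS)
    return NsclcModelBundle(model, _build_scenarios(), circuits)


def load_packaged_model() -> BooleanModel:
    """The same model, parsed from the shipped ``nsclc_g1s.bnet`` file."""
    text = (resources.files("g1snet") / "data" / "nsclc_g1s.bnet").read_text()
    return loads_bnet(text, name="nsclc_g1s")


# ---------------------------------------------------------------------------
# calibration battery
# ---------------------------------------------------------------------------

def calibration_report(bundle: NsclcModelBundle | None = None) -> dict[str, bool]:
    """Machine-checkable assertions pinning the model to the study's results.

    Covers the wild-type attractor structure, every perturbation
    phenotype (including the 24-row circuit screen), the miR-34a/lncRNA
    expression patterns at the fixed points, and the existence and
    functionality of the three novel positive circuits.
    """
    bundle = bundle or build_nsclc_model()
    m = bundle.model
    ix = m.index
    report: dict[str, bool] = {}

    fp0 = bundle.fixed_points("WT_no_damage")
    fp1 = bundle.fixed_points("WT_damage")
    prolif = fp0[0] if fp0 else None
    report["wt_three_fixed_points"] = len(fp0) + len(fp1) == 3
    report["wt_no_damage_proliferative"] = (
        len(fp0) == 1 and
        bundle.fixed_point_phenotypes("WT_no_damage") == {"Proliferation"})
    report["wt_proliferative_promoters_on"] = bool(prolif) and all(
        prolif[ix[n]] for n in ("CDK46_CycD", "CDK2_CycE", "Cdc25A",
                                "Myc", "ANRIL", "UFC1", "Proliferation")
    ) and not prolif[ix["miR34a"]]
    report["wt_damage_bistable_sen_apo"] = (
        bundle.fixed_point_phenotypes("WT_damage") ==
        {"Senescence", "Apoptosis"} and len(fp1) == 2)
    report["wt_damage_miR34a_on"] = all(s[ix["miR34a"]] for s in fp1)

    def _mir_on(name):
        fps = bundle.fixed_points(name)
        return bool(fps) and all(s[ix["miR34a"]] for s in fps)

    def _mir_off(name):
        fps = bundle.fixed_points(name)
        return bool(fps) and not any(s[ix["miR34a"]] for s in fps)

    def _lnc_off(name):
        fps = bundle.fixed_points(name)
        return bool(fps) and not any(
            s[ix["ANRIL"]] or s[ix["UFC1"]] for s in fps)

    for name, scn in bundle.scenarios.items():
        report[f"phenotypes::{name}"] = (
            bundle.fixed_point_phenotypes(name) == set(scn.expected_phenotypes))
    report["sponge_KO_miR34a_on"] = all(
        _mir_on(n) for n in ("UFC1_KO", "ANRIL_KO", "ANRIL_KO_UFC1_KO"))
    report["sponge_E1_miR34a_off"] = all(
        _mir_off(n) for n in ("UFC1_E1", "ANRIL_E1"))
    report["myc_E1_miR34a_off"] = _mir_off("Myc_E1")
    report["myc_KO_lncRNAs_off"] = _lnc_off("Myc_KO")
    report["miR34a_E1_lncRNAs_off"] = _lnc_off("miR34a_E1")

    report["novel_circuits_positive"] = all(
        c.sign == +1 for c in bundle.novel_circuits)
    report["novel_circuits_functional"] = all(
        is_functional(m, c)[0] for c in bundle.novel_circuits)

    # output mutual exclusivity over every scenario fixed point
    exclusive = True
    for name in bundle.scenarios:
        for fp in bundle.fixed_points(name):
            if sum(fp[ix[o]] for o in PHENOTYPE_OUTPUTS) > 1:
                exclusive = False
    report["outputs_mutually_exclusive"] = exclusive
    return report


def packaged_bnet_text() -> str:
    """Serialize the authoritative model to the shipped .bnet dialect."""
    bundle = build_nsclc_model()
    header = [
        "nsclc_g1s: Boolean model of the NSCLC G1/S checkpoint",
        "miR-34a vs the lncRNA sponges ANRIL and UFC1; single input DNA_Damage",
        "generated from g1snet.model.RULES -- edit there, not here",
    ]
    return dumps_bnet(bundle.model, header_comments=header)
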