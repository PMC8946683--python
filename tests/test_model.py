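"""The NSCLC G1/S checkpoint model: structure, scenarios, calibration."""

import pytest

from g1snet.circuits import enumerate_circuits, is_functional
from g1snet.dynamics import async_successors, monte_carlo_phenotypes
from g1snet.logic import Perturbation
from g1snet.model import (NOVEL_CIRCUITS, build_nsclc_model,
                          calibration_report, load_packaged_model)


# --- structure ---------------------------------------------------------------

def test_single_input_and_three_outputs(bundle):
    m = bundle.model
    assert m.input_nodes == ("DNA_Damage",)
    assert m.output_nodes == ("Proliferation", "Senescence", "Apoptosis")
    for out in m.output_nodes:
        assert not m.targets_of(out)


def test_node_and_edge_inventory(bundle):
    m = bundle.model
    assert len(m.nodes) == 30
    assert len(m.edges) == 83
    # every miR-34a target named in the wiring is repressed
    for target in ("Myc", "HDAC1", "Sirt1", "E2F1", "Cdc25A", "BCL2",
                   "CDK46_CycD", "CDK2_CycE"):
        assert m.edge_sign("miR34a", target) == -1
    # the sponges repress miR-34a; E2F1 and Myc drive the sponges
    assert m.edge_sign("ANRIL", "miR34a") == -1
    assert m.edge_sign("UFC1", "miR34a") == -1
    assert m.edge_sign("E2F1", "UFC1") == +1
    assert m.edge_sign("E2F1", "ANRIL") == +1
    assert m.edge_sign("Myc", "ANRIL") == +1
    assert m.edge_sign("EZH2", "miR34a") == -1
    assert m.edge_sign("EZH2", "PTEN") == -1
    assert m.edge_sign("EZH2", "KLF2") == -1


def test_packaged_bnet_equals_code_model(bundle):
    m2 = load_packaged_model()
    m = bundle.model
    assert m2.node_names == m.node_names
    assert m2.edges == m.edges
    assert m2.rules == m.rules


# --- scenario catalogue ------------------------------------------------------

def test_scenario_lookup():
    b = build_nsclc_model()
    value, p = b.scenario("UFC1_KO_miR34a_E1")
    assert value == 1 and p.as_dict() == {"UFC1": 0, "miR34a": 1}
    value, p = b.scenario("WT_no_damage")
    assert value == 0 and not p
    value, p = b.scenario("ANRIL_KO_UFC1_KO")
    assert value == 1 and p.as_dict() == {"ANRIL": 0, "UFC1": 0}
    with pytest.raises(KeyError):
        b.scenario("no_such_experiment")


def test_scenario_catalogue_covers_the_screen(bundle):
    screen_names = [n for n in bundle.scenarios
                    if bundle.scenarios[n].note.startswith("circuit screen")]
    assert len(screen_names) == 24


def test_root_state_applies_damage_and_clamps(bundle):
    ix = bundle.model.index
    root = bundle.root_state("UFC1_KO_miR34a_E1")
    assert root[ix["DNA_Damage"]] == 1
    assert root[ix["UFC1"]] == 0 and root[ix["miR34a"]] == 1
    # remaining coordinates come from the proliferative state
    assert root[ix["Myc"]] == 1 and root[ix["CDK46_CycD"]] == 1


# --- dynamics anchors --------------------------------------------------------

def test_proliferative_state_content(bundle):
    ix = bundle.model.index
    fp = bundle.proliferative_state()
    for name in ("CDK46_CycD", "CDK2_CycE", "Cdc25A", "Myc", "ANRIL",
                 "UFC1", "Proliferation"):
        assert fp[ix[name]] == 1, name
    for name in ("miR34a", "p53", "p21", "Casp3", "Senescence", "Apoptosis"):
        assert fp[ix[name]] == 0, name


def test_damage_destabilizes_the_proliferative_state(bundle):
    root = list(bundle.proliferative_state())
    root[bundle.model.index["DNA_Damage"]] = 1
    succs = async_successors(bundle.model, tuple(root))
    assert succs  # ATM becomes updatable
    flipped = {i for s in succs
               for i in range(len(s)) if s[i] != root[i]}
    assert bundle.model.index["ATM"] in flipped


def test_apoptosis_rule_holds_at_the_apoptotic_fixed_point(bundle):
    apo = [fp for fp in bundle.fixed_points("WT_damage")
           if bundle.model.classify_attractor([fp]).label == "Apoptosis"]
    assert len(apo) == 1
    assert bundle.model.evaluate_rule("Apoptosis", apo[0]) == 1
    assert apo[0][bundle.model.index["p53_K"]] == 1


def test_monte_carlo_absorbs_exactly_into_the_enumerated_fixed_points(bundle):
    """Sampled reachability agrees with complete enumeration: under damage
    the walks end in precisely the two DDR fixed points."""
    dist = bundle.monte_carlo("WT_damage", n_runs=3000, seed=2)
    absorbed = {next(iter(a.states)) for a in dist.probabilities}
    assert absorbed == set(bundle.fixed_points("WT_damage"))


# --- calibration battery -----------------------------------------------------

def test_calibration_battery_is_green(bundle):
    report = calibration_report(bundle)
    failed = sorted(k for k, ok in report.items() if not ok)
    assert not failed, f"calibration constraints violated: {failed}"


def test_novel_circuits_are_positive_and_functional(bundle):
    m = bundle.model
    short = {c.nodes: c for c in enumerate_circuits(m, 3)}
    for nodes in NOVEL_CIRCUITS:
        from g1snet.circuits import Circuit
        c = Circuit.from_nodes(m, nodes)
        assert c in enumerate_circuits(m, 3)
        assert c.sign == +1
        func, wit = is_functional(m, c)
        assert func and wit
    # interaction signs follow the documented evidence:
    # miRNA represses the TF, the TF activates the lncRNA, the lncRNA
    # sponges the miRNA
    for mir, tf, lnc in NOVEL_CIRCUITS:
        assert m.edge_sign(mir, tf) == -1
        assert m.edge_sign(tf, lnc) == +1
        assert m.edge_sign(lnc, mir) == -1


def test_clamping_a_circuit_node_silences_the_circuit(bundle):
    from g1snet.circuits import Circuit
    c = Circuit.from_nodes(bundle.model, NOVEL_CIRCUITS[0])
    for node in NOVEL_CIRCUITS[0]:
        for v in (0, 1):
            func, _ = is_functional(bundle.model, c,
                                    Perturbation.from_dict({node: v}))
            assert not func
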