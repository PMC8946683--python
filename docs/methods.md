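# Methods

This note documents the modelling formalism, the checkpoint model's
construction and calibration, the numerical choices in the dynamics and
circuit engines, the synthetic fixtures the tests rely on, and the known
limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Formalism

A model is a signed directed graph over named nodes with one Boolean
rule per non-input node. Node values are 0 (inactive) / 1 (active).
Every rule is **monotone** with respect to its declared edge signs:
flipping an activator from 0 to 1 can never decrease the rule value,
flipping an inhibitor can never increase it. The validator enforces
this exhaustively over regulator contexts (in-degrees here are ≤ 7;
the check is skipped above in-degree 12), together with exact
rule/edge consistency: the variables of a node's rule are precisely the
sources of its incoming edges.

Dynamics are **fully asynchronous**: a state's successors are obtained
by flipping exactly one *unstable* node (one whose rule value disagrees
with its current value); input nodes are frozen parameters of a run and
clamped nodes are never updated. Attractors are the terminal strongly
connected components of the state transition graph (STG): fixed points
(single state, no outgoing transition) or cyclic attractors (≥ 2
states). A fixed point of the asynchronous scheme satisfies x = F(x)
and is therefore identical to the synchronous fixed point — the test
suite asserts this scheme-independence on random fixtures.

Perturbations follow knockout/overexpression semantics: KO clamps a
node to 0, E1 clamps it to 1, replacing its rule by a constant. The
model is strictly Boolean; no multi-valued variables, priority classes
or stochastic rule noise (see Limitations).

### Reachability probabilities

Non-deterministic asynchronous dynamics induce a Markov chain once a
tie-breaking distribution is fixed. We use the **uniform-transition
convention**: at each state every enabled transition is taken with
equal probability. Two estimators are implemented:

* **Monte Carlo**: seeded random walks from a root state, absorbed at
  the first fixed point (walks exceeding the step budget are routed to
  cycle detection; a walk that is neither absorbed nor inside a cyclic
  attractor is a hard error). The RNG is counter-based (Philox) so
  runs are bit-reproducible across platforms for a given seed.
* **Exact absorption**: the absorption probabilities of the uniform
  chain into each terminal SCC, from a sparse linear solve over the
  transient states of the full reachable STG.

The two are cross-checked against each other (within three binomial
standard errors) on fixtures whose reachable STG is small enough to
build. For the full checkpoint model the reachable damage-ON state
space exceeds 10^7 states, so the STG builder's state budget
(default 2 × 10^6) deliberately refuses it and all reported checkpoint
probabilities are Monte Carlo estimates with n = 100,000 (binomial
standard error ≤ 0.16 percentage points). The uniform convention is
isolated in one place so alternative weightings remain pluggable.

### Circuit functionality

The sign of a feedback circuit is the product of its edge signs;
positive circuits are the structural prerequisite for multistability,
negative ones for sustained oscillations. A circuit is **functional**
(operative) when a single state makes the discrete derivative
`f_v(x[u:=1]) − f_v(x[u:=0])` nonzero for *every* circuit edge u→v
simultaneously; for monotone rules a nonzero derivative always equals
the edge sign (asserted as a property test). Functionality is decided
exactly by backtracking over the circuit's joint regulator context
(the union of the targets' regulators minus the respective edge
source); nodes outside the context cannot affect any derivative, so
the search never visits the full state space. Witness states returned
by the search set all non-context nodes to 0. Clamping any circuit
node makes its rule constant and hence the circuit non-functional.
Elementary circuits are enumerated with Johnson-style enumeration
(networkx `simple_cycles`), self-loops counting as length-1 circuits;
"at most three elements" means at most three nodes.

## 2. The checkpoint model

### Inventory

30 nodes, 83 signed interactions, one input (`DNA_Damage`), three
read-out nodes (`Proliferation`, `Senescence`, `Apoptosis`). The
inventory covers the DNA-damage-response core (ATM, p53, Mdm2, Wip1,
the two p53 phospho-forms p53-A and p53-K, p53-INP1), the effector
layer (p21, Bax, caspase-3, BCL2), the miR-34a/sponge layer (miR-34a,
ANRIL, UFC1, EZH2, PTEN, AKT, KLF2), and the cell-cycle arm (Myc,
HDAC1, Sirt-1, E2F1, Cdc25A, CDK4/6–cyclin D, CDK2–cyclin E, RB).
Narrative phospho-site and focus details (Ser-15/20/46, serine-1981,
53BP1, ROS) are absorbed into the semantics of ATM/p53-A/p53-K rather
than modelled as nodes, and DNA damage remains a pure input with a
single outgoing edge (into ATM).

### Rule construction

The published wiring fixes the interaction skeleton but not the full
logic. Rules follow the simplest monotone template — ON iff (some
activator ON) and (no inhibitor ON) — except where the observed
attractor repertoire forces a sharper gate. Every deviation, with its
biological grounding:

* **ATM** `= DNA_Damage & (E2F1 | !(Wip1 & HDAC1))` — Wip1 (the
  phosphatase closing the p53/Wip1/ATM negative loop) and HDAC1 only
  silence ATM jointly, and E2F1-driven replication stress overrides
  both (the E2F1/ATM positive circuit). This keeps ATM active in the
  damage fixed points, where exactly one of Wip1/HDAC1 is present.
* **p53 forms.** `p53_A = p53 & !p53_K & !p53_INP1 & !E2F1` and
  `p53_K = p53 & !p53_A & !p21`: mutual exclusion is the positive
  p53-A/p53-K circuit; p53-INP1 (induced by p53-A, suppressed by Wip1)
  converts arrest-p53 to killer-p53; E2F1 biases the p53 response away
  from arrest (E2F1 promotes the apoptotic p53 program), and p21
  feeds back to block the killer form once the arrest program is
  committed — without this gate the model has a spurious hybrid fixed
  point with p53-K and p21 jointly ON.
* **Wip1** `= p53 & p53_A` — p53-dependent transcription requiring the
  arrest form, closing p53 → Wip1 ⊣ ATM.
* **p21** `= (p53_A | KLF2) & !Myc & !HDAC1 & !Casp3` — the
  senescence–apoptosis switch: p21 needs an activator (arrest-p53 or
  KLF2) and release from its three repressors; caspase-3 cleavage of
  p21 and p21's block of the killer form realise the p21/caspase-3
  mutual-inhibition circuit.
* **miR-34a** `= (ATM & p53 & !Casp3) | ((ATM | p53) & !ANRIL & !UFC1
  & !EZH2)` — the central sponge logic. A single inducer is silenced
  by any sponge; the joint ATM·p53 damage burst saturates the sponges
  and fires miR-34a anyway (this is what breaks the proliferative
  lock-in under damage), but the burst requires an intact cell
  (!Casp3) and the burst's drivers decay at the fixed points, so
  forced sponges (ANRIL/UFC1/Myc E1) end with miR-34a OFF, as
  observed.
* **Sponge arm.** `ANRIL = E2F1 | Myc`, `UFC1 = E2F1`,
  `EZH2 = ANRIL | UFC1 | !p53` (p53 represses EZH2; basal EZH2 keeps
  PTEN/KLF2 silenced in unstressed cells), `PTEN = p53 | !EZH2`,
  `AKT = !PTEN`, `KLF2 = !EZH2` — exactly the ANRIL→EZH2⊣KLF2 and
  UFC1→EZH2⊣PTEN axes, with PTEN's p53-dependence.
* **Cell-cycle arm.** `Myc = (E2F1 | AKT) & !miR34a & !p21 & !p53`
  (AKT stabilises Myc; p53 represses it), `HDAC1 = Myc | !miR34a`,
  `Sirt1 = E2F1 & !miR34a`,
  `E2F1 = !miR34a & !Casp3 & ((Myc & !RB) | (ATM & !Sirt1))`,
  `Cdc25A = (E2F1 | Myc) & !miR34a & !ATM` (checkpoint-mediated
  Cdc25A degradation), cyclin complexes driven by Myc/E2F1 and blocked
  by miR-34a and p21, `RB = !CDK46_CycD & !CDK2_CycE`.
* **Outputs.** Proliferation requires all three cycle promoters with
  neither p21 nor caspase-3; Senescence is p21 without caspase-3;
  Apoptosis is caspase-3. These definitions make the three read-outs
  mutually exclusive in every reachable attractor (asserted during
  analysis).

### Calibration

The free logical choices above were fixed against a battery of 52
machine-checkable constraints (`g1snet.model.calibration_report`),
all of which hold for the shipped rule set:

* exactly three wild-type fixed points — one proliferative
  (damage OFF: CDK4/6–CycD, CDK2–CycE, Cdc25A, Myc, ANRIL, UFC1,
  Proliferation ON; miR-34a OFF) and a senescence/apoptosis pair
  (damage ON; miR-34a ON, sponges OFF);
* sponge knockdowns (single or double) leave miR-34a ON in every fixed
  point; sponge overexpression keeps it OFF with proliferation intact;
* any miR-34a knockout abolishes senescence (apoptosis-only fixed
  points); Myc E1 yields apoptosis-only with miR-34a OFF; Myc KO and
  miR-34a E1 yield both damage phenotypes with both lncRNAs OFF;
* the 24-row KO/E1 screen over the three lncRNA/miRNA circuits:
  senescence survives exactly in the rows where miR-34a is forced ON
  and the E2F1 (or Myc) hub is knocked out;
* the three circuits miR-34a/E2F1/ANRIL, miR-34a/E2F1/UFC1 and
  miR-34a/Myc/ANRIL exist, are positive, and are functional.

With the rules frozen, the Monte Carlo probabilities are *outputs*:
damaged wild type ≈ 78/22 apoptosis/senescence against the published
80/20, and the two rescue experiments (sponge KO + miR-34a E1) ≈ 60/40
senescence/apoptosis as published (UFC1 ≈ 59.6, ANRIL ≈ 60.9 per cent
senescence at n = 10^5). The residual 1–2-point gaps are the accuracy
limit of the reconstruction: the original study's exact rule file was
not available, and no further rule variant we examined closed the gap
without violating a calibration constraint. The acceptance test for
the wild-type split is intentionally strict (three binomial standard
errors) and documents this residual rather than hiding it.

### Circuit inventory

The reconstruction has 18 circuits of ≤ 3 nodes, 16 of them
functional. Fourteen coincide with the study's short-circuit list;
the study's p53/Mdm2 and p53/miR-34a/HDAC1 loops exist structurally
here but are not functional (their edges' derivative contexts are
mutually exclusive under our gating of p53 by ATM), while two loops of
the p53-form switch (Wip1/p53-INP1/p53-A and p21/p53-K/p53-A) are
functional here but unlisted there. The *total* functional-circuit
count is much larger than the published 28 (several hundred, dominated
by long cycles through the densely connected cell-cycle arm) — an
expected artefact of rule-set differences, since functionality of long
circuits is extremely sensitive to gating; the short-circuit
inventory, which the analysis actually interprets, is the calibrated
quantity.

### Scenario roots

Damage-ON experiments start from the proliferative fixed point with
`DNA_Damage` switched to 1 and clamps forced — a cycling cell hit by
genotoxic stress. Damage-OFF experiments start from the all-zero state
and relax. Both conventions live in one place
(`NsclcModelBundle.root_state`).

## 3. Synthetic fixtures

`g1snet.random_nets` draws random Boolean networks with configurable
size, in-degree bound, activation fraction and rule template
(`and_not` mirrors the checkpoint model's dominant rule family;
`nested_canalyzing` and `random_monotone` diversify rule shapes). All
generated rules are monotone and sign-consistent by construction, and
generation is reproducible: one seed, one byte-identical `.bnet`.
Because real regulatory networks are neither Erdős–Rényi-ish nor
sign-balanced, these fixtures validate *engine correctness* (oracle
equivalence against exhaustive 2^n computations at n ≤ 14), not
biological realism; passing them says nothing about any particular
biological network beyond the algorithms being exact.

## 4. Numerical and engineering choices

* Fixed-point enumeration is branch-and-prune with Kleene three-valued
  rule evaluation — sound and complete, never 2^n enumeration.
* STG construction is breadth-first with a hard state budget
  (default 2 × 10^6); overflow raises, signalling that the scenario
  needs sampling instead.
* Monte Carlo defaults: 100,000 walks, step cap 10,000, Philox RNG;
  successor tuples are ordered by declared node index, and successor
  sets are memoised per (model, perturbation) context.
* The exact absorption solve uses scipy sparse LU on I − Q; a finite
  absorbing chain cannot be singular and conservation of probability
  is asserted to 10^-6.
* The functionality search is exact backtracking; contexts here are
  ≤ ~20 nodes and the full 6,000-circuit inventory of the checkpoint
  model is analysed in about a second.
* Serialization keeps node kinds, display labels and edge signs in a
  comment header so a round trip is lossless; `target, target` lines
  declare inputs unless the header marks the node internal.

## 5. Limitations

* The rule set is a calibrated reconstruction, not a transcription of
  the original model file; node/edge counts (30/83) differ from the
  published inventory (32/94), absolute probabilities carry 1–2-point
  deviations, and the total functional-circuit count is not
  comparable.
* The uniform-transition convention is an assumption; biological
  transition propensities are neither uniform nor memoryless.
* Boolean abstraction: no graded expression levels, no kinetics, no
  cell-to-cell variability beyond update non-determinism.
* The sponge mechanism is a logical summary (any sponge silences a
  single inducer; the damage burst overrides) — stoichiometric
  titration of miRNA by lncRNA copies is outside the formalism.
* Under Myc overexpression the model keeps ANRIL ON but cannot keep
  UFC1 ON in the apoptotic fixed point, because UFC1's only documented
  activator (E2F1) is off there; the published observation that both
  lncRNAs stay up under Myc E1 is reproduced only for ANRIL.
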