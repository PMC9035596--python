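# Methods

## Model formalism

A Boolean network is an ordered list of nodes x_1..x_n, each with an update
rule f_i over the node set. Under the synchronous scheme used throughout,
all nodes update simultaneously, so every state has exactly one successor
and the 2^n-state space is a functional graph: each component contains one
attractor (a steady state of period 1 or a cycle of period τ) and every
state flows into exactly one attractor, which makes basin sizes well
defined without tie-breaking. The asynchronous scheme (one node at a time)
is used only as a robustness check: fixed points are invariant under any
update scheme (every node already holds its rule's value), whereas
synchronous cycles may or may not survive — `verify_async` explores the
asynchronous transition graph from the cycle states and reports whether
they sit in a terminal strongly-connected component.

Input nodes are nodes with the self-copy rule i(t+1) = i(t); they stand for
extrinsic signals. Because inputs never change along a trajectory, the
state space splits exactly into 2^|inputs| invariant subspaces, one per
input assignment. A micro-environment is an input assignment held fixed
(the rule replaced by a constant); a mutant is the same clamping operation
applied to an internal node (knock-out → 0, over-expression → 1).

## The macrophage model: a labelled reconstruction

The bundled 29-node network (`data/macrophage_reconstruction.bnet`)
describes macrophage polarization: nine extrinsic cytokine inputs (IFNG_e,
GMCSF_e, LPS_e, IL4_e, IC_e, IL1B_e, IL10_e, NECA_e, EGFR_e), receptor
nodes, the STAT1/3/5/6 and SOCS1/3 signaling layer (with the IL-10
dependent STAT3 pathway kept separate as STAT3_s, displayed "STAT3*"), the
transcription factors NF-κB, PPARγ and HIF1α, and four output cytokines
(IL12_out, IL6_out, IL10_out, VEGF_out).

The complete truth tables of the published model this package re-implements
live in that study's supplementary material and deposited repository, which
are not redistributed here. The shipped rule set is therefore a
**reconstruction**: the rules were chosen to satisfy, simultaneously, the
constraints the published text states. Specifically:

* inventory and interfaces — 29 nodes, 52 interactions between distinct
  nodes, inputs = the `_e` cytokines, STAT3* as a separate IL-10-dependent
  node;
* named circuits — STAT3 induces SOCS3 which inhibits IL6R (the negative
  feedback that generates the cyclic attractors); SOCS1 inhibits STAT1,
  STAT5 and STAT6;
* environment definitions — pro-M1 = IFNG+GMCSF+LPS, pro-M2a = IL4,
  pro-M2b = LPS+IC+IL1B, pro-M2c = IL10, pro-M2d = IC+IL4+IL10,
  mixed = LPS+IFNG+IL4;
* marker semantics — M1 produces IL-12; M2a = IL-10 + STAT6; M2b = IL-10 +
  IL-6; M2c = IL-10 + STAT3*; M2d = VEGF + IL-10 without IL-12; il6 = IL-6
  only; M0 = no cytokines;
* reported behavior — the per-environment cell-type menus, the stability
  of pro-M2a/pro-M2c, the absence of direct M1↔M2a transitions in the
  mixed environment, STAT1-knock-out losing IL-12/M1, PPARγ-knock-out
  reducing IL-10 producers, STAT6-over-expression enriching M2, steady
  il6 states requiring EGFR ligand, the basin ordering
  M0 > M2 > M2a > M1, and cycle periods drawn from {1, 2, 3, 6}.

Where the text under-determines a rule the reconstruction takes the
standard immunology reading: SOCS1 is driven by IL-10/STAT3* signaling and
by simultaneous (contradictory) STAT1+STAT6 activity, and sustains itself
only while both an IL-4 signal and an opposing IFN-γ/LPS signal persist —
this implements the published observation that naive M0 states arise in
environments whose contradictory signals silence each other through SOCS
proteins; IL-12 requires STAT1 and NF-κB jointly (IFN-γ + TLR/IL-1
co-stimulation); VEGF/HIF1α requires adenosine (NECA) plus NF-κB, or
IC + IL-4 + IL-10 co-signaling; PPARγ is STAT6-driven; IL-4/STAT6
suppresses IL-6 production; EGFR signaling activates STAT3 and NF-κB
directly, which is what makes EGFR-containing environments the only ones
with *steady* IL-6-producing attractors (elsewhere IL-6 production rides
the oscillating IL6R→STAT3→SOCS3⊣IL6R loop).

The tests assert exactly the reconstructed behaviors listed above — they
are properties of this rule set, verified by this package. Quantities that
depend on the original truth tables (absolute attractor counts, the
printed transition percentages, Derrida values) are *recomputed* from the
reconstruction by `scripts/acceptance.py` and reported as this model's
numbers; they are not expected to equal the published ones, and no test or
constant in the package encodes the published values. Known qualitative
divergences of the reconstruction: pro-M1 lacks the published minor
M0/il6/il6* attractors (it recovers dominant steady M1 plus cyclic M1*);
pro-M2b recovers M2 and M2b* but no steady M2b; pro-M2d recovers only
steady M2d; and the mixed environment's M0 attractor absorbs rather than
exchanges flux (perturbed M1/M2a states fall into M0, but M0 itself is
stable to single flips).

## Attractor enumeration

`find_attractors_exhaustive` decomposes on the input nodes. For each of
the 2^|inputs| assignments it builds the synchronous successor table over
the 2^m internal states (m = n − |inputs|) with vectorized rule evaluation
on bit arrays, then finds the cycles by pointer jumping: iterating
f ← f[f] ⌈log2(2^m)⌉+1 times sends every state to a state on its own cycle,
after which cycles are walked explicitly, canonically rotated to start at
their smallest state index, and basins obtained with one `bincount`. The
decomposition is exact — inputs are constant along trajectories — and the
union over assignments is asserted (in tests) to equal the flat brute-force
census whenever both are feasible. For the 29-node macrophage model the
full census (512 assignments × 2^20 states) takes under a minute on one
CPU. `brute_force_attractors` (guard n ≤ 20) is kept deliberately naive as
the independent oracle.

The asynchronous check is bounded: breadth-first exploration from the
cycle states with a frontier cap (default 10^6 states). If the cap is hit
the verdict is computed on the partial graph and labelled `bounded`;
exhaustive verdicts are labelled `exact`. Fixed points short-circuit to
stable by the scheme-invariance theorem.

## Labeling

Per attractor, each node is reduced to active (1 in every cycle state),
inactive (0 in every cycle state) or oscillating. Label rules are
conjunctions of required-active and required-inactive markers, tried in
priority order (M2d > M2b > M2a > M2c > M2 > M1 > il6 > M0-fallback), so
subtype rules fire before the generic M2 rule. An oscillating marker
satisfies required-active and violates required-inactive — cyclic
attractors thus carry the same base vocabulary, with the cyclic flag
rendered as a `*` suffix. Downstream "change of cell type" statistics
compare base labels (M1 → M1* is not a type change); the starred-level
percentage is reported alongside.

## Perturbation analysis

Transient perturbations flip 1 (single) or 2 (double, unordered pairs) of
the 29 nodes in one attractor state for one time step and let the dynamics
relax; the target attractor is resolved in O(1) against the precomputed
basin map of the environment. A flipped clamped input is restored by its
constant rule after one step, so input pulses are transient by
construction. The perturbation universe is every environment × every
attractor × every cycle state × every node (or pair), unweighted by basin
size. Summary percentages are computed both over the six named
environments and over all 512 input combinations; the all-combinations
figures are the headline numbers reported by the acceptance script. For
the M1↔M2 statistic, M1-family = {M1} and M2-family = {M2, M2a, M2b, M2c,
M2d}; M0 and il6 belong to neither.

The Derrida map draws, for each initial Hamming distance h, random (state,
h-flip mask) pairs, advances both states one synchronous step, and averages
the image distance. When the exact pair space 2^n·C(n,h) is small (≤ 2^22)
the average is computed exhaustively instead; each point records its
method, sample count and seed. Macrophage defaults: h = 1..29, 5000
samples per h.

Mutant reports clamp each mutated node across wild type and mutants, then
compare labeled attractor counts and basin fractions per environment. The
reference panel is STAT1-KO, PPARγ-KO, STAT6-OE and NF-κB-KO; the NF-κB
mutant is included although single-node NF-κB models are known not to
reproduce its experimental phenotype — the discordance is a property of
this level of abstraction and is reported, not corrected.

## Synthetic networks

`random_kauffman` draws N-K networks: each non-input node receives k
distinct regulators chosen uniformly and a random truth table whose
entries are 1 with probability `bias`; planted inputs are self-copies; the
expression is materialized as a DNF over the drawn table. One
`numpy.random.default_rng(seed)` generator drives everything, so networks
are bit-reproducible from the spec. These networks share the structural
assumptions of the analysis (binary states, fixed regulators, constant
inputs) but none of the biology: passing the oracle-equivalence and
conservation suites on them validates the *engine*, not the macrophage
model, which is why the fixture behaviors are tested separately. Default
test family: n = 6..12, k ∈ {1,2,3}, bias ∈ {0.25, 0.5, 0.75}, 0–3 inputs.

## Numerical and interface choices

* State encoding: node 0 (file order) is the least-significant bit;
  attractor cycles are canonically rotated to start at their minimal state
  index; reports list nodes in file order.
* The rule dialect is the `targets, factors` text format with `&`, `|`,
  `!`, parentheses and the constants 0/1; names are case-sensitive,
  whitespace is ignored, `#` starts a comment; richer constructs are
  rejected with an error naming the line. Writer and parser round-trip to
  function-identical networks (property-tested).
* Interaction signs come from an exhaustive monotonicity test of each rule
  in each regulator; non-monotone regulation is reported as `dual`, not an
  error. The "52 interactions" count excludes self-loops (the nine input
  self-copies and the SOCS1 self-sustain term).
* Fixture integrity is pinned by sha256 checksums verified at load.
* CSV outputs carry `#`-prefixed metadata headers (tool version, source,
  seed); identical configurations produce identical files.

## Limitations

The model is qualitative: Boolean states cannot express graded cytokine
levels or timescale separation, synchronous updating can create cycles
that asynchronous dynamics dissolve (and does so here for the period-2
toggles), and basin sizes weight all initial states equally. The
reconstruction shares the published model's scope — no TNF-α/TGF-β
extensions, no multi-valued logic, no SBML-qual import, no stochastic or
ODE dynamics — and, being rebuilt from textual constraints rather than
transcribed truth tables, its quantitative outputs (attractor counts,
percentages, Derrida values) characterize the reconstruction itself.
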