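# boolmac

Boolean-network analysis of macrophage differentiation, heterogeneity and
plasticity.

Macrophages polarize into a spectrum of functional programs — the
pro-inflammatory M1 type, the alternatively activated M2a–M2d subtypes, and
intermediate M2-like and IL-6-producing states — depending on the cytokines
in their micro-environment. `boolmac` models this decision process as a
Boolean regulatory network: each molecular player (cytokine, receptor, STAT
or SOCS protein, transcription factor) is a binary node x_i ∈ {0, 1} updated
synchronously by a logical rule,

    x_i(t+1) = f_i(x(t)),

so the network state x(t) evolves deterministically until it reaches an
**attractor**: a steady state (x(t+1) = x(t)) or a cycle
(x(t+τ) = x(t), τ > 1). Attractors are read as cell types through marker
rules on the output cytokines and signaling pathways; basins of attraction
measure how favored each type is; clamping input nodes models polarizing
micro-environments, clamping internal nodes models knock-out /
over-expression mutants; and one-step bit flips probe the stability and
plasticity of each cell type.

The package is aimed at systems-biology work on cell-fate logic: it bundles

* a Boolean network engine — `targets, factors` rule-file dialect,
  synchronous and asynchronous updating, signed interaction graphs;
* exhaustive attractor enumeration with exact basin sizes, scaled to
  ~30-node networks by decomposing the state space over the self-copying
  input nodes (2^|inputs| clamped subspaces of 2^(n−|inputs|) states, each
  swept with vectorized successor tables and pointer jumping);
* oscillation-aware cell-type labeling (a marker that oscillates along a
  cycle counts as present; cyclic attractors carry a `*` suffix);
* mutant reports, exhaustive single/double transient-perturbation
  transition tables with per-node transition rates, and Derrida curves;
* a 29-node macrophage polarization model (nine extrinsic cytokine inputs,
  STAT/SOCS signaling, NF-κB/PPARγ/HIF1α, four output cytokines) with its
  six polarizing environments and label rules. The shipped rule set is a
  reconstruction built from published structural and behavioral
  constraints — see `docs/methods.md` for its provenance and scope;
* a random N-K (Kauffman) network generator, so every analysis stage is
  testable against a brute-force oracle without external data.

## Worked example

Which cell types does a contradictory environment support? Fix the inputs
to the *mixed* environment (LPS + IFN-γ + IL-4, signals that drive both M1
and M2a polarization) and enumerate all 2^20 states of the remaining nodes:

```python
import boolmac as bm

net   = bm.load_macrophage_network()          # 29 nodes, 52 interactions
rules = bm.macrophage_label_rules()
envs  = {e.name: e for e in bm.macrophage_environments()}

aset = bm.attractors_by_environment(net, envs["mixed"])
df   = bm.label_set(aset, rules, net)
print(df.groupby("label")["basin_size"].sum().sort_values(ascending=False))
```

```
label
M0     913408
M1      62208
M2a     61440
M1*     11520
Name: basin_size, dtype: int64
```

The mixed environment is tristable plus one oscillation: most of the
1,048,576 initial states (87%) end in a naive M0 state in which mutual
SOCS1-mediated inhibition silences both the IFN-γ and the IL-4 pathway;
the rest commit to M1 (IL-12 producing; 6%), to M2a (IL-10/STAT6; 6%), or
to a cyclic M1\* attractor whose IL-6/STAT3/SOCS3 negative-feedback loop
oscillates (period 2, 1%). Transient-perturbation analysis
(`bm.transition_table`) shows every cell-type change in this environment
passes through M0 — there is no direct M1 ↔ M2a conversion.

The same pipeline is available from the shell:

```bash
boolmac environments --env mixed --out mixed.csv
boolmac perturb --order single --out perturb/
boolmac derrida --samples 10000 --seed 0 --out derrida.csv
boolmac full-analysis --out analysis/     # census + mutants + perturbations
```

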