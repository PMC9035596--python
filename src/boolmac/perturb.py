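"""Mutants, transient bitflip perturbations, and the Derrida curve.

Three perturbation regimes:

* **Mutants** clamp a node to 0 (knock-out) or 1 (over-expression) for the
  whole simulation and compare the labeled attractor landscape with the wild
  type.
* **Transient perturbations** flip one or two nodes of an attractor state for
  a single time step, relax, and record which attractor the trajectory falls
  into.  Aggregated over every environment / attractor / cycle state / node
  (or node pair) this yields the cell-type transition statistics and the
  per-node transition rates.
* The **Derrida map** measures one-step divergence: pairs of states at
  Hamming distance *h* are advanced one synchronous step and the expected
  distance of the images is recorded, probing how sensitive the dynamics are
  to state noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attractors import (AttractorSet, SubspaceCensus, environment_census,
                         make_bit_cache)
from .environments import Environment
from .labeling import LabelRule, label_attractor, summarize_activity
from .network import BooleanNetwork

KNOCKOUT = "knockout"
OVEREXPRESSION = "overexpression"

M1_FAMILY = frozenset({"M1"})
M2_FAMILY = frozenset({"M2", "M2a", "M2b", "M2c", "M2d"})


@dataclass(frozen=True)
class MutationSpec:
    """A permanent clamp: knock-out fixes the node to 0, over-expression to 1."""

    node: str
    kind: str

    def __post_init__(self):
        if self.kind not in (KNOCKOUT, OVEREXPRESSION):
            raise ValueError(f"unknown mutation kind {self.kind!r}")

    @property
    def value(self) -> int:
        return 0 if self.kind == KNOCKOUT else 1

    @property
    def name(self) -> str:
        suffix = "KO" if self.kind == KNOCKOUT else "OE"
        return f"{self.node}_{suffix}"


def apply_mutation(network: BooleanNetwork, spec: MutationSpec) -> BooleanNetwork:
    """Clamp the mutated node; the mutation is recorded in the metadata."""
    network.index_of(spec.node)
    mutated = network.fix_nodes({spec.node: spec.value})
    muts = list(mutated.metadata.get("mutations", []))
    muts.append((spec.node, spec.kind))
    mutated.metadata["mutations"] = muts
    return mutated


def mutant_report(network: BooleanNetwork, specs: list[MutationSpec],
                  rules: list[LabelRule],
                  environments: list[Environment]) -> pd.DataFrame:
    """Labeled attractor counts and basin fractions, wild type vs mutants.

    One row per (variant, environment, base label) with attractor count,
    combined basin size and basin fraction, plus the change in basin fraction
    relative to the wild type in the same environment.
    """
    from .attractors import attractors_by_environment

    rows = []
    variants = [("wild_type", network)]
    variants += [(s.name, apply_mutation(network, s)) for s in specs]
    for vname, net in variants:
        for env in environments:
            aset = attractors_by_environment(net, env)
            for i, a in enumerate(aset):
                lab = label_attractor(summarize_activity(a, net), rules)
                rows.append({
                    "variant": vname,
                    "environment": env.name,
                    "base_label": lab.base,
                    "n_attractors": 1,
                    "basin_size": a.basin_size,
                    "total_states": aset.total_states,
                })
    df = (pd.DataFrame(rows)
          .groupby(["variant", "environment", "base_label"], as_index=False)
          .agg(n_attractors=("n_attractors", "sum"),
               basin_size=("basin_size", "sum"),
               total_states=("total_states", "first")))
    df["basin_fraction"] = df["basin_size"] / df["total_states"]
    wt = df[df["variant"] == "wild_type"][
        ["environment", "base_label", "basin_fraction"]
    ].rename(columns={"basin_fraction": "wt_basin_fraction"})
    df = df.merge(wt, on=["environment", "base_label"], how="left")
    df["wt_basin_fraction"] = df["wt_basin_fraction"].fillna(0.0)
    df["delta_basin_fraction"] = df["basin_fraction"] - df["wt_basin_fraction"]
    return df.drop(columns=["total_states"])


# ---------------------------------------------------------------------------
# transient perturbations
# ---------------------------------------------------------------------------

def transient_perturb(network: BooleanNetwork, attractor_set: AttractorSet,
                      attractor, state_index: int, nodes,
                      _state_map: dict | None = None) -> int:
    """Flip the named node(s) of one cycle state for one step and relax.

    Returns the index (within ``attractor_set``) of the attractor reached by
    iterating the synchronous dynamics from the perturbed state.  The scope of
    the source attractor (its input assignment, if any) stays clamped, so a
    flipped input is restored by its constant rule after one step.
    """
    nodes = list(nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate perturbed nodes")
    if not 0 <= state_index < attractor.period:
        raise ValueError(f"state_index {state_index} out of range")
    clamp = attractor.scope_dict
    net = network.fix_nodes(clamp) if clamp else network
    idx = attractor.states[state_index]
    for v in nodes:
        idx ^= 1 << net.index_of(v)
    state_map = _state_map if _state_map is not None \
        else attractor_set.state_to_attractor()
    for _ in range(attractor_set.total_states + 2):
        if idx in state_map:
            return state_map[idx]
        idx = net.step_sync_index(idx)
    raise RuntimeError("trajectory did not reach a known attractor")


@dataclass
class TransitionSummary:
    """Aggregate statistics of a transient-perturbation experiment."""

    order: str
    n_perturbations: int
    n_base_change: int
    n_starred_change: int
    n_m1_m2: int

    @property
    def pct_type_change(self) -> float:
        """Percent of perturbations changing the *base* cell type."""
        return 100.0 * self.n_base_change / max(self.n_perturbations, 1)

    @property
    def pct_type_change_starred(self) -> float:
        """Same, counting steady<->cyclic of one type as a change too."""
        return 100.0 * self.n_starred_change / max(self.n_perturbations, 1)

    @property
    def pct_m1_m2(self) -> float:
        """Percent of perturbations crossing between the M1 and M2 families."""
        return 100.0 * self.n_m1_m2 / max(self.n_perturbations, 1)

    def as_dict(self) -> dict:
        return {
            "order": self.order,
            "n_perturbations": self.n_perturbations,
            "n_base_change": self.n_base_change,
            "n_starred_change": self.n_starred_change,
            "n_m1_m2": self.n_m1_m2,
            "pct_type_change": self.pct_type_change,
            "pct_type_change_starred": self.pct_type_change_starred,
            "pct_m1_m2": self.pct_m1_m2,
        }


def _is_m1_m2(a: str, b: str) -> bool:
    return ((a in M1_FAMILY and b in M2_FAMILY)
            or (a in M2_FAMILY and b in M1_FAMILY))


class _RecordSink:
    """Column-wise accumulator for transition records."""

    def __init__(self, keep_records: bool):
        self.keep = keep_records
        self.cols = {k: [] for k in
                     ("environment", "source_attractor", "state_index",
                      "node1", "node2", "flip1", "flip2",
                      "target_attractor", "source_label", "target_label",
                      "source_base", "target_base")}
        self.n = 0
        self.n_base = 0
        self.n_star = 0
        self.n_m1m2 = 0
        self.node_counts: dict[tuple[str, str], list[int]] = {}

    def add(self, env_name, ai, si, nodes, flips, tgt,
            src_label, tgt_label):
        self.n += 1
        base_change = src_label.base != tgt_label.base
        if base_change:
            self.n_base += 1
        if str(src_label) != str(tgt_label):
            self.n_star += 1
        if _is_m1_m2(src_label.base, tgt_label.base):
            self.n_m1m2 += 1
        for v, f in zip(nodes, flips):
            cnt = self.node_counts.setdefault((v, f), [0, 0])
            cnt[0] += 1
            if base_change:
                cnt[1] += 1
        if self.keep:
            c = self.cols
            c["environment"].append(env_name)
            c["source_attractor"].append(ai)
            c["state_index"].append(si)
            c["node1"].append(nodes[0])
            c["node2"].append(nodes[1] if len(nodes) > 1 else "")
            c["flip1"].append(flips[0])
            c["flip2"].append(flips[1] if len(flips) > 1 else "")
            c["target_attractor"].append(tgt)
            c["source_label"].append(str(src_label))
            c["target_label"].append(str(tgt_label))
            c["source_base"].append(src_label.base)
            c["target_base"].append(tgt_label.base)

    def records(self) -> pd.DataFrame:
        return pd.DataFrame(self.cols)

    def summary(self, order: str) -> TransitionSummary:
        return TransitionSummary(order, self.n, self.n_base,
                                 self.n_star, self.n_m1m2)

    def node_rates(self) -> pd.DataFrame:
        rows = [{"node": v, "flip": f, "n_perturbations": c[0],
                 "n_type_change": c[1],
                 "pct_type_change": 100.0 * c[1] / max(c[0], 1)}
                for (v, f), c in sorted(self.node_counts.items())]
        return pd.DataFrame(rows)


def transition_table(network: BooleanNetwork,
                     environments: list[Environment],
                     rules: list[LabelRule],
                     order: str = "single",
                     keep_records: bool = True):
    """Exhaustive transient perturbation of every attractor state.

    For every environment, every attractor, every cycle state, and every node
    (``order="single"``) or unordered node pair (``order="double"``), flip the
    bits for one step, relax, and record the target attractor and the
    source/target cell-type labels.

    Returns ``(records, summary, node_rates)``; ``records`` is empty when
    ``keep_records`` is false (summary and node rates are always computed).
    Flipped clamped inputs are restored by their constant rule after one
    step, so input pulses are transient by construction.
    """
    if order not in ("single", "double"):
        raise ValueError(f"unknown perturbation order {order!r}")
    sink = _RecordSink(keep_records)
    inputs = network.input_nodes()
    bit_cache = None
    shared_free = None
    for env in environments:
        assignment = dict(env.assignment)
        for inp in inputs:
            assignment.setdefault(inp, 0)
        free_nodes = [v for v in network.nodes if v not in assignment]
        if free_nodes != shared_free:
            shared_free = free_nodes
            bit_cache = make_bit_cache(free_nodes)
        census = environment_census(network, assignment, bit_cache)
        _perturb_census(network, census, env.name, assignment, rules,
                        order, sink)
    return sink.records(), sink.summary(order), sink.node_rates()


def _perturb_census(network, census: SubspaceCensus, env_name, assignment,
                    rules, order, sink):
    free_nodes = census.free_nodes
    free_index = {v: j for j, v in enumerate(free_nodes)}
    free_pos = {v: network.index_of(v) for v in free_nodes}
    clamped = [v for v in network.nodes if v in assignment]
    labels = [label_attractor(summarize_activity(a, network), rules)
              for a in census.attractors]
    fixed_net = network.fix_nodes(assignment)
    attr_of = census.attr_of

    def internal_of_full(full_idx: int) -> int:
        out = 0
        for v, j in free_index.items():
            if (full_idx >> free_pos[v]) & 1:
                out |= 1 << j
        return out

    def resolve(full_idx: int, internal_idx: int, flipped) -> int:
        """Attractor reached from the perturbed state."""
        if all(v in free_index for v in flipped):
            for v in flipped:
                internal_idx ^= 1 << free_index[v]
            return int(attr_of[internal_idx])
        # a clamped input was flipped: advance one step (the constant rule
        # restores the input), then look the internal state up
        state = list(network.index_to_state(full_idx))
        for v in flipped:
            i = network.index_of(v)
            state[i] ^= 1
        env = {name: bool(b) for name, b in zip(network.nodes, state)}
        nxt = 0
        for v, j in free_index.items():
            if fixed_net.functions[v].evaluate(env):
                nxt |= 1 << j
        return int(attr_of[nxt])

    if order == "single":
        combos = [(v,) for v in network.nodes]
    else:
        combos = list(itertools.combinations(network.nodes, 2))

    for ai, (attr, src_label) in enumerate(zip(census.attractors, labels)):
        for si, full_idx in enumerate(attr.states):
            internal_idx = internal_of_full(full_idx)
            for combo in combos:
                flips = tuple(
                    "1->0" if (full_idx >> network.index_of(v)) & 1 else "0->1"
                    for v in combo)
                tgt = resolve(full_idx, internal_idx, combo)
                sink.add(env_name, ai, si, combo, flips, tgt,
                         src_label, labels[tgt])


def all_input_environments(network: BooleanNetwork) -> list[Environment]:
    """Every 0/1 combination of the network's inputs, as named environments."""
    inputs = network.input_nodes()
    envs = []
    for a in range(1 << len(inputs)):
        assignment = {inp: (a >> i) & 1 for i, inp in enumerate(inputs)}
        present = "+".join(k for k, v in assignment.items() if v) or "none"
        envs.append(Environment(f"combo:{present}", assignment))
    return envs


def node_transition_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-node, per-flip-direction percentage of type-changing perturbations.

    Computed from a records table (both nodes of a double perturbation are
    credited).  Matches the node-rate table returned by
    :func:`transition_table` when that was run with records kept.
    """
    rows = []
    counts: dict[tuple[str, str], list[int]] = {}
    for _, rec in records.iterrows():
        change = rec["source_base"] != rec["target_base"]
        for v, f in ((rec["node1"], rec["flip1"]), (rec["node2"], rec["flip2"])):
            if not v:
                continue
            c = counts.setdefault((v, f), [0, 0])
            c[0] += 1
            if change:
                c[1] += 1
    for (v, f), c in sorted(counts.items()):
        rows.append({"node": v, "flip": f, "n_perturbations": c[0],
                     "n_type_change": c[1],
                     "pct_type_change": 100.0 * c[1] / max(c[0], 1)})
    return pd.DataFrame(rows)


def label_flux(records: pd.DataFrame) -> pd.DataFrame:
    """Transition counts between base labels per environment (flux table)."""
    if records.empty:
        return pd.DataFrame(columns=["environment", "source_base",
                                     "target_base", "n"])
    return (records.groupby(["environment", "source_base", "target_base"])
            .size().rename("n").reset_index())


# ---------------------------------------------------------------------------
# Derrida map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerridaPoint:
    """Mean one-step image distance for initial Hamming distance ``h``."""

    initial_hamming: int
    mean_final_hamming: float
    n_samples: int
    seed: int | None
    method: str  # "exhaustive" | "sampled"


def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x.astype(np.uint64)).astype(np.int64)


def derrida_map(network: BooleanNetwork, max_h: int | None = None,
                samples: int = 10_000, seed: int = 0,
                exhaustive_limit: int = 1 << 22) -> list[DerridaPoint]:
    """One-step divergence curve of the synchronous dynamics.

    For each ``h`` in ``1..max_h`` draw random (state, h-bit mask) pairs,
    advance both states one synchronous step, and average the Hamming
    distance of the images.  When the full ``2^n * C(n, h)`` pair space is
    small enough the average is computed exhaustively instead (recorded in
    the point's ``method``).
    """
    n = network.n
    if max_h is None:
        max_h = n
    if not 1 <= max_h <= n:
        raise ValueError(f"max_h must be in 1..{n}")
    if samples < 1:
        raise ValueError("samples must be >= 1")
    rng = np.random.default_rng(seed)
    points = []
    succ_table = None
    if n <= 20:
        succ_table = network.successor_table()

    def batch_succ(states: np.ndarray) -> np.ndarray:
        if succ_table is not None:
            return succ_table[states]
        bits = {v: ((states >> i) & 1).astype(bool)
                for i, v in enumerate(network.nodes)}
        out_bits = network.step_batch(bits)
        out = np.zeros(len(states), dtype=np.int64)
        for i, v in enumerate(network.nodes):
            out |= out_bits[v].astype(np.int64) << i
        return out

    for h in range(1, max_h + 1):
        n_pairs_exact = None
        try:
            from math import comb
            n_pairs_exact = (1 << n) * comb(n, h)
        except OverflowError:  # pragma: no cover
            pass
        if n_pairs_exact is not None and n_pairs_exact <= exhaustive_limit:
            states = np.arange(1 << n, dtype=np.int64)
            base = batch_succ(states)
            total = 0
            count = 0
            for combo in itertools.combinations(range(n), h):
                mask = 0
                for b in combo:
                    mask |= 1 << b
                other = batch_succ(states ^ mask)
                total += int(_popcount(base ^ other).sum())
                count += len(states)
            points.append(DerridaPoint(h, total / count, count, None,
                                       "exhaustive"))
        else:
            states = rng.integers(0, 1 << n, size=samples, dtype=np.int64)
            order = np.argsort(rng.random((samples, n)), axis=1)[:, :h]
            masks = np.zeros(samples, dtype=np.int64)
            for col in range(h):
                masks |= np.int64(1) << order[:, col].astype(np.int64)
            d = _popcount(batch_succ(states) ^ batch_succ(states ^ masks))
            points.append(DerridaPoint(h, float(d.mean()), samples, seed,
                                       "sampled"))
    return points


def derrida_table(points: list[DerridaPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "initial_hamming": p.initial_hamming,
        "mean_final_hamming": p.mean_final_hamming,
        "n_samples": p.n_samples,
        "seed": p.seed,
        "method": p.method,
    } for p in points])
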