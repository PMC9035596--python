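"""Synchronous attractor enumeration with basins, and the asynchronous check.

Under synchronous updating every state has exactly one successor, so the state
space is a functional graph: each connected component contains exactly one
cycle (a steady state when the period is 1) and every state flows into one.
Attractors are found by building the successor table and pointer-jumping
(iterated ``succ[succ]``), which lands every state on its cycle in
``O(log |states|)`` gather passes.

Networks near n = 30 are enumerated by decomposing on the input nodes: inputs
are self-copying, so their values never change along a trajectory and the
state space splits exactly into ``2^|inputs|`` invariant subspaces of
``2^(n - |inputs|)`` states each.  The union of the per-assignment censuses is
the full census, and within-subspace basin counts are full-space basin counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .environments import Environment
from .network import BooleanNetwork

BRUTE_FORCE_MAX_N = 20


@dataclass(frozen=True)
class Attractor:
    """A synchronous attractor: an ordered state cycle with its basin.

    ``states`` are full-network integer state indices in successor order,
    canonically rotated so the smallest index comes first; ``period == 1``
    means a steady state.  ``basin_size`` counts the states that flow into the
    cycle within the enumeration scope, and ``scope`` records the input
    assignment (empty for a full-space census).
    """

    states: tuple[int, ...]
    basin_size: int
    scope: tuple[tuple[str, int], ...] = ()

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_steady_state(self) -> bool:
        return len(self.states) == 1

    @property
    def scope_dict(self) -> dict[str, int]:
        return dict(self.scope)


@dataclass
class AttractorSet:
    """All attractors of one network (or one environment-restricted network)."""

    attractors: list[Attractor]
    total_states: int
    n: int
    nodes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.attractors)

    def __iter__(self):
        return iter(self.attractors)

    def basin_sum(self) -> int:
        return sum(a.basin_size for a in self.attractors)

    def steady_states(self) -> list[Attractor]:
        return [a for a in self.attractors if a.is_steady_state]

    def cycles(self) -> list[Attractor]:
        return [a for a in self.attractors if not a.is_steady_state]

    def state_to_attractor(self) -> dict[int, int]:
        """Map from every attractor state index to its attractor's position."""
        out = {}
        for i, a in enumerate(self.attractors):
            for s in a.states:
                out[s] = i
        return out


@dataclass(frozen=True)
class AsyncReport:
    """Result of checking one synchronous attractor under asynchronous updates.

    Fixed points are update-scheme invariant (every node already holds its
    rule's value), so ``fixed_point_stable`` is true whenever the period is 1.
    For cycles, the asynchronous transition graph is explored from the cycle
    states; ``async_recurrent`` reports whether the cycle states sit in a
    terminal strongly-connected component (an asynchronous attractor), and
    ``method`` records whether the exploration was exhaustive or hit the
    frontier cap.
    """

    fixed_point_stable: bool
    async_recurrent: bool
    method: str  # "exact" | "bounded"
    n_states_explored: int


# ---------------------------------------------------------------------------
# cycle extraction from a successor table
# ---------------------------------------------------------------------------

def _attractors_from_succ(succ: np.ndarray):
    """Cycles, basin sizes and the basin map of a functional graph.

    Returns ``(cycles, basins, attr_of)``: each cycle is a list of state
    indices in successor order starting at the smallest index, and
    ``attr_of[s]`` is the cycle index every state ``s`` flows into.
    """
    size = len(succ)
    f = succ
    # succ^(2^t) for 2^t >= size lands every state on its cycle
    t = max(1, int(size - 1).bit_length())
    for _ in range(t):
        f = f[f]
    on_cycle = np.unique(f)
    cycle_id = np.full(size, -1, dtype=np.int64)
    cycles = []
    for s in on_cycle.tolist():
        if cycle_id[s] != -1:
            continue
        cyc = [s]
        cur = int(succ[s])
        while cur != s:
            cyc.append(cur)
            cur = int(succ[cur])
        # canonical rotation: smallest state index first
        k = cyc.index(min(cyc))
        cyc = cyc[k:] + cyc[:k]
        cid = len(cycles)
        for st in cyc:
            cycle_id[st] = cid
        cycles.append(cyc)
    attr_of = cycle_id[f]
    basins = np.bincount(attr_of, minlength=len(cycles))
    return cycles, basins, attr_of


def brute_force_attractors(network: BooleanNetwork) -> AttractorSet:
    """Independent oracle: full successor table over all ``2^n`` states.

    Guarded to ``n <= 20``; no input decomposition, no chunking — the slow,
    obviously-correct reference the fast path is tested against.
    """
    if network.n > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"brute force limited to n <= {BRUTE_FORCE_MAX_N}, got n={network.n}"
        )
    succ = network.successor_table()
    cycles, basins, _ = _attractors_from_succ(succ)
    attractors = [
        Attractor(tuple(c), int(b)) for c, b in zip(cycles, basins)
    ]
    attractors.sort(key=lambda a: a.states[0])
    return AttractorSet(
        attractors, 1 << network.n, network.n, list(network.nodes),
        {"method": "brute_force"},
    )


# ---------------------------------------------------------------------------
# input-decomposed enumeration
# ---------------------------------------------------------------------------

@dataclass
class SubspaceCensus:
    """Census of one clamped subspace, with the basin map kept around.

    ``attractors`` hold full-network state indices; ``attr_of[s]`` gives the
    attractor index of every *internal* state index ``s`` (bits in
    ``free_nodes`` order).  The perturbation analysis uses ``attr_of`` for
    O(1) resolution of bitflipped states.
    """

    attractors: list[Attractor]
    attr_of: np.ndarray
    succ: np.ndarray
    free_nodes: list[str]
    clamp: dict

    def internal_of_state(self, state) -> int:
        """Internal index of a full state's free-node bits."""
        idx = 0
        for j, v in enumerate(self.free_nodes):
            if state[j]:
                idx |= 1 << j
        return idx


def _subspace_census(network, free_nodes, clamp, bit_cache=None) -> SubspaceCensus:
    """Attractors of the subspace where ``clamp`` nodes are held constant.

    ``free_nodes`` are enumerated (first name = least-significant internal
    bit); clamped nodes evaluate as constants.  Attractor states are reported
    in the full-network encoding; basins are counts over the subspace.
    """
    m = len(free_nodes)
    size = 1 << m
    if bit_cache is None:
        idx = np.arange(size, dtype=np.int64)
        bit_cache = {v: ((idx >> j) & 1).astype(bool)
                     for j, v in enumerate(free_nodes)}
    env: dict = dict(bit_cache)
    for node, val in clamp.items():
        env[node] = bool(val)
    succ = np.zeros(size, dtype=np.int64)
    for j, v in enumerate(free_nodes):
        out = network.functions[v].evaluate(env)
        arr = np.asarray(out, dtype=bool)
        if arr.shape != (size,):
            arr = np.broadcast_to(arr, (size,))
        succ |= arr.astype(np.int64) << j
    cycles, basins, attr_of = _attractors_from_succ(succ)

    # embed internal indices into the full-network encoding
    free_pos = [network.index_of(v) for v in free_nodes]
    clamp_bits = 0
    for node, val in clamp.items():
        if val:
            clamp_bits |= 1 << network.index_of(node)

    def embed(internal_idx: int) -> int:
        full = clamp_bits
        for j, pos in enumerate(free_pos):
            if (internal_idx >> j) & 1:
                full |= 1 << pos
        return full

    scope = tuple(sorted((k, int(v)) for k, v in clamp.items()))
    built = []
    for cyc, basin in zip(cycles, basins):
        states = [embed(s) for s in cyc]
        k = states.index(min(states))
        states = states[k:] + states[:k]
        built.append((Attractor(tuple(states), int(basin), scope), len(built)))
    order = sorted(range(len(built)), key=lambda i: built[i][0].states[0])
    remap = np.zeros(len(built), dtype=np.int64)
    for new_i, old_i in enumerate(order):
        remap[old_i] = new_i
    attractors = [built[i][0] for i in order]
    return SubspaceCensus(attractors, remap[attr_of], succ,
                          list(free_nodes), dict(clamp))


def find_attractors_exhaustive(network: BooleanNetwork,
                               progress: bool = False) -> AttractorSet:
    """Full attractor census with basin sizes over the ``2^n`` state space.

    Decomposes on the self-copy input nodes (exact, because inputs are
    constant along every trajectory); within each of the ``2^|inputs|`` input
    assignments the successor table over the internal states is built
    vectorized and cycles found by pointer-jumping.  Identical to
    :func:`brute_force_attractors` whenever the latter is applicable.
    """
    inputs = network.input_nodes()
    if not inputs:
        if network.n > BRUTE_FORCE_MAX_N:
            raise ValueError(
                "network has no self-copy inputs to decompose on and is too "
                f"large for flat enumeration (n={network.n})"
            )
        aset = brute_force_attractors(network)
        aset.provenance = {"method": "exhaustive", "n_inputs": 0}
        return aset
    free_nodes = [v for v in network.nodes if v not in set(inputs)]
    m = len(free_nodes)
    if m > 24:
        raise ValueError(f"internal state space too large (2^{m})")
    idx = np.arange(1 << m, dtype=np.int64)
    bit_cache = {v: ((idx >> j) & 1).astype(bool) for j, v in enumerate(free_nodes)}
    attractors: list[Attractor] = []
    n_assign = 1 << len(inputs)
    for a in range(n_assign):
        clamp = {inp: (a >> i) & 1 for i, inp in enumerate(inputs)}
        sub = _subspace_census(network, free_nodes, clamp, bit_cache)
        attractors.extend(sub.attractors)
    attractors.sort(key=lambda x: x.states[0])
    return AttractorSet(
        attractors, 1 << network.n, network.n, list(network.nodes),
        {"method": "exhaustive", "n_inputs": len(inputs)},
    )


def attractors_by_environment(network: BooleanNetwork,
                              environment: Environment) -> AttractorSet:
    """Attractors of the input-fixed network for one micro-environment.

    Every input node should be assigned; unassigned inputs are treated as
    free (with a warning) by enumerating both of their values.  Basin sizes
    are counted over the ``2^(n - |assigned|)`` clamped subspace.
    """
    assignment = dict(environment.assignment)
    for node in assignment:
        network.index_of(node)
    inputs = set(network.input_nodes())
    unassigned = sorted(inputs - set(assignment))
    if environment.assignment and unassigned:
        warnings.warn(
            f"environment {environment.name!r} leaves inputs unassigned "
            f"(treated as free): {unassigned}"
        )
    if environment.free:
        aset = find_attractors_exhaustive(network)
        aset.provenance["environment"] = environment.name
        return aset
    fixed = network.fix_nodes(assignment)
    free_nodes = [v for v in network.nodes if v not in assignment]
    if len(free_nodes) > 24:
        raise ValueError(f"free state space too large (2^{len(free_nodes)})")
    attractors: list[Attractor] = []
    n_free_inputs = len(unassigned)
    enum_nodes = [v for v in free_nodes if v not in inputs]
    idx = np.arange(1 << len(enum_nodes), dtype=np.int64)
    bit_cache = {v: ((idx >> j) & 1).astype(bool)
                 for j, v in enumerate(enum_nodes)}
    for a in range(1 << n_free_inputs):
        clamp = dict(assignment)
        clamp.update({inp: (a >> i) & 1 for i, inp in enumerate(unassigned)})
        sub = _subspace_census(fixed, enum_nodes, clamp, bit_cache)
        attractors.extend(sub.attractors)
    attractors.sort(key=lambda x: x.states[0])
    return AttractorSet(
        attractors, 1 << len(free_nodes), network.n, list(network.nodes),
        {"method": "environment", "environment": environment.name,
         "assignment": {k: int(v) for k, v in assignment.items()}},
    )


def environment_census(network: BooleanNetwork, assignment: dict,
                       bit_cache=None) -> SubspaceCensus:
    """Census of one fully-specified input assignment, with the basin map.

    ``assignment`` must cover (at least) every self-copy input node; the
    remaining nodes are enumerated.  This is the workhorse the perturbation
    analysis builds on: ``attr_of`` resolves any internal state in O(1).
    """
    for node in assignment:
        network.index_of(node)
    free_nodes = [v for v in network.nodes if v not in assignment]
    if len(free_nodes) > 24:
        raise ValueError(f"free state space too large (2^{len(free_nodes)})")
    for inp in network.input_nodes():
        if inp not in assignment:
            raise ValueError(f"input node {inp!r} not assigned")
    return _subspace_census(network, free_nodes, dict(assignment), bit_cache)


def make_bit_cache(free_nodes) -> dict:
    """Precompute the per-node bit arrays shared by every input assignment."""
    idx = np.arange(1 << len(free_nodes), dtype=np.int64)
    return {v: ((idx >> j) & 1).astype(bool) for j, v in enumerate(free_nodes)}


# ---------------------------------------------------------------------------
# asynchronous verification
# ---------------------------------------------------------------------------

def verify_async(network: BooleanNetwork, attractor: Attractor,
                 cap: int = 1_000_000) -> AsyncReport:
    """Check one synchronous attractor under asynchronous (one node at a
    time) updating.

    Fixed points are reported stable by theorem.  For cycles the asynchronous
    transition graph is explored breadth-first from the cycle states up to
    ``cap`` states; the attractor is asynchronously recurrent when its states
    lie in a terminal strongly-connected component of the explored graph.
    When the cap is hit the verdict is computed on the partial graph and
    ``method`` is ``"bounded"``.
    """
    clamp = attractor.scope_dict
    net = network.fix_nodes(clamp) if clamp else network
    if attractor.period == 1:
        return AsyncReport(True, True, "exact", 1)

    g = nx.DiGraph()
    frontier = list(attractor.states)
    seen = set(frontier)
    exhaustive = True
    while frontier:
        nxt = []
        for s in frontier:
            state = net.index_to_state(s)
            for node in net.nodes:
                t = net.state_to_index(net.step_async(state, node))
                if t != s:
                    g.add_edge(s, t)
                if t not in seen:
                    if len(seen) >= cap:
                        exhaustive = False
                        continue
                    seen.add(t)
                    nxt.append(t)
        frontier = nxt
    g.add_nodes_from(attractor.states)
    comps = list(nx.strongly_connected_components(g))
    comp_of = {}
    for i, comp in enumerate(comps):
        for s in comp:
            comp_of[s] = i
    cyc_comps = {comp_of[s] for s in attractor.states}
    recurrent = False
    if len(cyc_comps) == 1:
        cid = cyc_comps.pop()
        comp = comps[cid]
        terminal = all(comp_of[t] == cid for s in comp for t in g.successors(s))
        recurrent = terminal and exhaustive
        if not exhaustive and terminal:
            # unexplored frontier may still leave the component
            recurrent = False
    return AsyncReport(
        fixed_point_stable=False,
        async_recurrent=recurrent,
        method="exact" if exhaustive else "bounded",
        n_states_explored=len(seen),
    )
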