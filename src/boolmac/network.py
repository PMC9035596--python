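"""Boolean network representation, state encoding, and update schemes.

A :class:`BooleanNetwork` is an ordered list of named nodes, each carrying a
Boolean update rule over the other nodes.  States are length-``n`` bit vectors
aligned to the node order; node 0 is the least-significant bit of the integer
encoding, so reports are deterministic and independent of the rule syntax.

Micro-environments and mutants are both "clamp a node" operations: the node's
rule is replaced by a constant, and the assignment is recorded in the network
metadata so downstream tables can report what was fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .expr import And, BoolExpr, Const, Not, Or, Var

ACTIVATION = "activation"
INHIBITION = "inhibition"
DUAL = "dual"


@dataclass(frozen=True)
class SignedEdge:
    """A regulatory interaction with its sign.

    The sign is decided by an exhaustive monotonicity test of the target's
    rule in the source argument: ``activation`` if flipping the source on can
    only switch the target on, ``inhibition`` if it can only switch it off,
    and ``dual`` if the effect depends on the context (non-monotone rule).
    """

    source: str
    target: str
    sign: str


class BooleanNetwork:
    """An ordered set of nodes with one Boolean update rule each.

    Parameters
    ----------
    nodes:
        Node names in canonical (file) order.  This order defines the bit
        order of the state encoding.
    functions:
        Mapping from node name to its update rule; every name referenced by a
        rule must be a declared node.
    metadata:
        Free-form provenance (display aliases, fixed-node bookkeeping, ...).
    """

    def __init__(self, nodes, functions, metadata=None):
        nodes = list(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        for name in nodes:
            if not name:
                raise ValueError("empty node name")
        missing = set(functions) - set(nodes)
        if missing:
            raise ValueError(f"functions for undeclared nodes: {sorted(missing)}")
        for node in nodes:
            if node not in functions:
                raise ValueError(f"node {node!r} has no update rule")
            for ref in functions[node].support():
                if ref not in set(nodes):
                    raise ValueError(
                        f"rule for {node!r} references undeclared node {ref!r}"
                    )
        self.nodes: list[str] = nodes
        self.functions: dict[str, BoolExpr] = dict(functions)
        self.metadata: dict = dict(metadata or {})
        self._index = {name: i for i, name in enumerate(nodes)}

    # -- basics -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def copy(self, metadata=None) -> "BooleanNetwork":
        md = dict(self.metadata)
        if metadata:
            md.update(metadata)
        return BooleanNetwork(self.nodes, self.functions, md)

    def __repr__(self):
        return f"BooleanNetwork(n={self.n}, nodes={self.nodes[:4]}...)"

    # -- state encoding ---------------------------------------------------
    def state_to_index(self, state) -> int:
        """Pack a bit vector into an integer; node 0 is the LSB."""
        idx = 0
        for i, b in enumerate(state):
            if b:
                idx |= 1 << i
        return idx

    def index_to_state(self, index: int) -> tuple[int, ...]:
        if not 0 <= index < (1 << self.n):
            raise ValueError(f"state index {index} out of range for n={self.n}")
        return tuple((index >> i) & 1 for i in range(self.n))

    def state_dict(self, state) -> dict[str, bool]:
        return {name: bool(b) for name, b in zip(self.nodes, state)}

    # -- stepping ---------------------------------------------------------
    def step_sync(self, state) -> tuple[int, ...]:
        """Synchronous update: every node evaluates its rule on `state`."""
        env = self.state_dict(state)
        return tuple(int(bool(self.functions[v].evaluate(env))) for v in self.nodes)

    def step_async(self, state, node: str) -> tuple[int, ...]:
        """Asynchronous update of a single node; all other bits preserved."""
        i = self.index_of(node)
        env = self.state_dict(state)
        out = list(int(b) for b in state)
        out[i] = int(bool(self.functions[node].evaluate(env)))
        return tuple(out)

    def step_sync_index(self, index: int) -> int:
        return self.state_to_index(self.step_sync(self.index_to_state(index)))

    def step_batch(self, bits: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Vectorized synchronous step on a batch of states.

        `bits` maps every node name to a boolean array (one entry per state in
        the batch); the returned dict holds the successor bits.
        """
        shape = next(iter(bits.values())).shape
        out = {}
        for v in self.nodes:
            val = np.asarray(self.functions[v].evaluate(bits), dtype=bool)
            if val.shape != shape:
                val = np.broadcast_to(val, shape).copy()
            out[v] = val
        return out

    # -- clamping ---------------------------------------------------------
    def fix_nodes(self, assignment: dict[str, int]) -> "BooleanNetwork":
        """Replace the rules of the assigned nodes by constants.

        Used both for micro-environments (fixing the input nodes) and for
        knock-out / over-expression mutants; the assignment is recorded under
        ``metadata['fixed']`` (merged with any earlier fixing).
        """
        for node in assignment:
            self.index_of(node)
        funcs = dict(self.functions)
        for node, value in assignment.items():
            funcs[node] = Const(bool(value))
        fixed = dict(self.metadata.get("fixed", {}))
        fixed.update({k: int(v) for k, v in assignment.items()})
        md = dict(self.metadata)
        md["fixed"] = fixed
        return BooleanNetwork(self.nodes, funcs, md)

    # -- structure --------------------------------------------------------
    def input_nodes(self) -> list[str]:
        """Nodes whose rule is the literal self-copy ``i(t+1) = i(t)``.

        These represent extrinsic signals: their value never changes along a
        trajectory, so the state space decomposes exactly by input assignment.
        Detection is semantic (truth-table equality with the identity on the
        node itself), so e.g. ``A, (A)`` also counts.
        """
        out = []
        for node in self.nodes:
            f = self.functions[node]
            sup = f.support()
            if sup == [node]:
                if (bool(f.evaluate({node: False})) is False
                        and bool(f.evaluate({node: True})) is True):
                    out.append(node)
        return out

    def interaction_graph(self) -> list[SignedEdge]:
        """One signed edge per (regulator, target) pair.

        The sign is computed by evaluating the target rule on every assignment
        of its support with the regulator toggled: monotone increasing =>
        activation, monotone decreasing => inhibition, both => dual.  A
        regulator that appears syntactically but never changes the output is
        reported as ``dual`` (vacuous dependence; does not occur in
        well-formed models).
        """
        edges = []
        for target in self.nodes:
            f = self.functions[target]
            sup = f.support()
            for source in sup:
                others = [s for s in sup if s != source]
                up = down = False
                for combo in itertools.product([False, True], repeat=len(others)):
                    env = dict(zip(others, combo))
                    env[source] = False
                    v0 = bool(f.evaluate(env))
                    env[source] = True
                    v1 = bool(f.evaluate(env))
                    if v1 and not v0:
                        up = True
                    elif v0 and not v1:
                        down = True
                if up and not down:
                    sign = ACTIVATION
                elif down and not up:
                    sign = INHIBITION
                else:
                    sign = DUAL
                edges.append(SignedEdge(source, target, sign))
        return edges

    # -- vectorized successor tables --------------------------------------
    def successor_table(self, max_n: int = 24) -> np.ndarray:
        """Synchronous successor index for every state, vectorized.

        Guarded to ``n <= max_n`` (default 24, i.e. 16M states); use the
        input-decomposed enumeration for larger networks with inputs.
        """
        if self.n > max_n:
            raise ValueError(f"n={self.n} exceeds the exhaustive guard ({max_n})")
        size = 1 << self.n
        idx = np.arange(size, dtype=np.int64)
        bits = {v: ((idx >> i) & 1).astype(bool) for i, v in enumerate(self.nodes)}
        succ = np.zeros(size, dtype=np.int64)
        for i, v in enumerate(self.nodes):
            out = self.functions[v].evaluate(bits)
            out = np.broadcast_to(np.asarray(out, dtype=bool), (size,))
            succ |= out.astype(np.int64) << i
        return succ


def constant(value) -> BoolExpr:
    return Const(bool(value))


def expr_from_truth_table(inputs: list[str], table) -> BoolExpr:
    """Build a DNF expression realizing `table` over `inputs`.

    ``table[i]`` is the output for the input assignment whose bits are the
    binary digits of ``i`` (inputs[0] = LSB).  Used by the random-network
    generator.
    """
    table = [bool(t) for t in table]
    if len(table) != 1 << len(inputs):
        raise ValueError("truth table length mismatch")
    if not any(table):
        return Const(False)
    if all(table):
        return Const(True)
    terms = []
    for i, out in enumerate(table):
        if not out:
            continue
        lits = []
        for j, name in enumerate(inputs):
            lit: BoolExpr = Var(name)
            if not (i >> j) & 1:
                lit = Not(lit)
            lits.append(lit)
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))
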