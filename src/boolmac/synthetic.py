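"""Random N-K (Kauffman) Boolean networks and hand-enumerable toy fixtures.

The generator emulates the statistical setting the analysis assumes: discrete
0/1 nodes, a fixed set of regulators per node, random truth tables with a
controllable bias, and optionally a planted set of self-copy input nodes
standing in for extrinsic signals.  Everything is reproducible from a single
integer seed threaded through one ``numpy`` generator — no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, expr_from_truth_table
from .expr import Var


@dataclass(frozen=True)
class KauffmanSpec:
    """Parameters of a random N-K network.

    n nodes; each non-input node draws ``k`` distinct regulators uniformly and
    a truth table whose entries are 1 with probability ``bias``; the first
    ``n_inputs`` nodes are planted self-copy inputs.
    """

    n: int
    k: int
    bias: float = 0.5
    n_inputs: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError("need 1 <= k <= n")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [0, 1]")
        if not 0 <= self.n_inputs < self.n:
            raise ValueError("need 0 <= n_inputs < n")


def random_kauffman(spec: KauffmanSpec) -> BooleanNetwork:
    """Draw a random network; identical specs yield identical networks."""
    rng = np.random.default_rng(spec.seed)
    names = [f"v{i:02d}" for i in range(spec.n)]
    funcs = {}
    for i, name in enumerate(names):
        if i < spec.n_inputs:
            funcs[name] = Var(name)
            continue
        regs = rng.choice(spec.n, size=spec.k, replace=False)
        table = rng.random(1 << spec.k) < spec.bias
        funcs[name] = expr_from_truth_table([names[r] for r in regs], table)
    return BooleanNetwork(
        names, funcs,
        {"generator": "random_kauffman",
         "spec": {"n": spec.n, "k": spec.k, "bias": spec.bias,
                  "n_inputs": spec.n_inputs, "seed": spec.seed}},
    )


# Hand-enumerated censuses: each entry lists (cycle states..., basin size)
# with states written as integer encodings (node 0 = LSB).
_TOY_RULES = {
    "identity_1": "targets, factors\nA, A\n",
    "negation_1": "targets, factors\nA, !A\n",
    "toggle": "targets, factors\nA, !B\nB, !A\n",
    "negation_ring_3": "targets, factors\nA, !C\nB, !A\nC, !B\n",
    "copy_chain_input": (
        "targets, factors\nI, I\nA, I\nB, A\nC, A & B\n"
    ),
}

_TOY_CENSUS = {
    # A, A: two fixed points, each its own basin
    "identity_1": [((0,), 1), ((1,), 1)],
    # A, !A: one period-2 cycle absorbing both states
    "negation_1": [((0, 1), 2)],
    # toggle: fixed points 01 (A=1,B=0 -> index 1) and 10 (index 2),
    # plus the period-2 cycle {00, 11} with basin 2
    "toggle": [((0, 3), 2), ((1,), 1), ((2,), 1)],
    # odd negation ring: two fixed-point-free cycles under synchronous update:
    # {000,111} (period 2) and the 6-cycle through the remaining states
    "negation_ring_3": [((0, 7), 2), ((1, 5, 4, 6, 2, 3), 6)],
    # planted input I (bit 0) with a copy chain A=I, B=A, C=A&B:
    # I=0 sinks to 0000 (basin 8), I=1 sinks to 1111 (basin 8)
    "copy_chain_input": [((0,), 8), ((15,), 8)],
}


def toy_fixtures() -> dict[str, dict]:
    """Small networks with their fully hand-enumerated attractor censuses.

    Each value holds ``network`` and ``census`` — a list of
    ``(cycle_states, basin_size)`` pairs with cycles in canonical rotation —
    so every stage of the pipeline can be tested without any external file.
    """
    from .bnet import parse_bnet

    out = {}
    for name, rules in _TOY_RULES.items():
        out[name] = {
            "network": parse_bnet(rules, {"fixture": name}),
            "census": [(tuple(states), basin)
                       for states, basin in _TOY_CENSUS[name]],
        }
    return out
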