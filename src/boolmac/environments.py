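"""Micro-environment definitions: named assignments of the input nodes.

An input node is an extrinsic signal (e.g. a cytokine in the medium) with the
self-copy rule ``i(t+1) = i(t)``.  Fixing the inputs to a 0/1 pattern models a
polarizing micro-environment; the special "free" environment fixes nothing and
lets the census range over every input combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Environment:
    """A named input assignment.

    ``assignment`` maps input-node names to 0/1; an empty assignment means the
    environment leaves every input free.
    """

    name: str
    assignment: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "assignment", {k: int(v) for k, v in self.assignment.items()}
        )

    @property
    def free(self) -> bool:
        return not self.assignment

    def present(self) -> list[str]:
        return [k for k, v in self.assignment.items() if v]
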