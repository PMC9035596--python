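"""Boolean expression trees for update rules.

Expressions are built from node-name literals, the constants 0/1, and the
connectives NOT / AND / OR.  They evaluate either on a scalar assignment
(``dict`` of node -> bool) or elementwise on numpy boolean arrays, which is
what the vectorized state-space sweeps use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


class BoolExpr:
    """Base class of the expression AST."""

    def evaluate(self, env):
        raise NotImplementedError

    def support(self) -> list[str]:
        """Node names appearing in the expression, in first-appearance order."""
        seen: dict[str, None] = {}
        for name in self._names():
            seen.setdefault(name, None)
        return list(seen)

    def _names(self) -> Iterator[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_text()!r})"


@dataclass(frozen=True)
class Const(BoolExpr):
    value: bool

    def evaluate(self, env):
        return self.value

    def _names(self):
        return iter(())

    def to_text(self):
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str

    def evaluate(self, env):
        return env[self.name]

    def _names(self):
        yield self.name

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Not(BoolExpr):
    arg: BoolExpr

    def evaluate(self, env):
        v = self.arg.evaluate(env)
        if hasattr(v, "dtype"):
            return ~v
        return not v

    def _names(self):
        yield from self.arg._names()

    def to_text(self):
        inner = self.arg.to_text()
        if isinstance(self.arg, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]

    def evaluate(self, env):
        out = self.args[0].evaluate(env)
        for a in self.args[1:]:
            out = out & a.evaluate(env)
        return out

    def _names(self):
        for a in self.args:
            yield from a._names()

    def to_text(self):
        parts = []
        for a in self.args:
            t = a.to_text()
            if isinstance(a, Or):
                t = f"({t})"
            parts.append(t)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]

    def evaluate(self, env):
        out = self.args[0].evaluate(env)
        for a in self.args[1:]:
            out = out | a.evaluate(env)
        return out

    def _names(self):
        for a in self.args:
            yield from a._names()

    def to_text(self):
        return " | ".join(a.to_text() for a in self.args)
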