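"""Reader and writer for the BoolNet-style "targets, factors" rule dialect.

The canonical dialect accepted here:

.. code-block:: text

    targets, factors
    A, B & !C
    B, (A | C) & !B
    C, 1

Operators ``&`` (and), ``|`` (or), ``!`` (not), parentheses, and the constants
``0``/``1``.  Node identifiers match ``[A-Za-z_][A-Za-z0-9_]*`` or are purely
numeric constants; names are case-sensitive and whitespace is ignored.
Foreign constructs of richer BoolNet dialects (temporal operators,
probabilistic rule lists) are rejected with an error naming the line.
"""

from __future__ import annotations

import re

from .expr import And, BoolExpr, Const, Not, Or, Var
from .network import BooleanNetwork

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_]*)|([01])|([&|!()]))")


class BnetParseError(ValueError):
    """Raised on malformed rule files; the message names the offending line."""


def _tokenize(text: str, lineno: int) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if rest:
                raise BnetParseError(
                    f"line {lineno}: unexpected token near {rest[:20]!r}"
                )
            break
        tokens.append(m.group(1) or m.group(2) or m.group(3))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: or := and ('|' and)*; and := unary ('&' unary)*;
    unary := '!' unary | '(' or ')' | name | const."""

    def __init__(self, tokens: list[str], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg):
        raise BnetParseError(f"line {self.lineno}: {msg}")

    def parse(self) -> BoolExpr:
        if not self.tokens:
            self.fail("empty expression")
        e = self.parse_or()
        if self.peek() is not None:
            self.fail(f"trailing input at {self.peek()!r}")
        return e

    def parse_or(self) -> BoolExpr:
        args = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            args.append(self.parse_and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def parse_and(self) -> BoolExpr:
        args = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            args.append(self.parse_unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def parse_unary(self) -> BoolExpr:
        tok = self.take()
        if tok is None:
            self.fail("unexpected end of expression")
        if tok == "!":
            return Not(self.parse_unary())
        if tok == "(":
            e = self.parse_or()
            if self.take() != ")":
                self.fail("unbalanced parenthesis")
            return e
        if tok in ("0", "1"):
            return Const(tok == "1")
        if _NAME_RE.fullmatch(tok):
            return Var(tok)
        self.fail(f"unexpected token {tok!r}")


def parse_expression(text: str, lineno: int = 0) -> BoolExpr:
    return _Parser(_tokenize(text, lineno), lineno).parse()


def parse_bnet(text: str, metadata=None) -> BooleanNetwork:
    """Parse rule-file content into a :class:`BooleanNetwork`.

    Node order is file order; every node referenced by a rule must itself be
    declared as a target.  ``#`` starts a comment.
    """
    lines = text.splitlines()
    header_seen = False
    nodes: list[str] = []
    funcs: dict[str, BoolExpr] = {}
    rule_line: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
                header_seen = True
                continue
            raise BnetParseError(
                f"line {lineno}: expected 'targets, factors' header, got {line!r}"
            )
        if "," not in line:
            raise BnetParseError(f"line {lineno}: expected 'target, expression'")
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not _NAME_RE.fullmatch(target):
            raise BnetParseError(f"line {lineno}: invalid target name {target!r}")
        if target in funcs:
            raise BnetParseError(
                f"line {lineno}: duplicate target {target!r} "
                f"(first declared on line {rule_line[target]})"
            )
        nodes.append(target)
        funcs[target] = parse_expression(expr_text, lineno)
        rule_line[target] = lineno
    if not header_seen:
        raise BnetParseError("missing 'targets, factors' header")
    declared = set(nodes)
    for target in nodes:
        for ref in funcs[target].support():
            if ref not in declared:
                raise BnetParseError(
                    f"line {rule_line[target]}: rule for {target!r} references "
                    f"undeclared node {ref!r}"
                )
    return BooleanNetwork(nodes, funcs, metadata)


def write_bnet(network: BooleanNetwork) -> str:
    """Serialize a network; round-trips through :func:`parse_bnet`."""
    lines = ["targets, factors"]
    for node in network.nodes:
        lines.append(f"{node}, {network.functions[node].to_text()}")
    return "\n".join(lines) + "\n"


def read_bnet(path, metadata=None) -> BooleanNetwork:
    with open(path, encoding="utf-8") as fh:
        md = dict(metadata or {})
        md.setdefault("source", str(path))
        return parse_bnet(fh.read(), md)
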