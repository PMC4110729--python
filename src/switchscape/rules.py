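"""Reader/writer for BoolNet-style rule text ("targets, factors").

The interchange format used by Boolean-network tools: a header line
``targets, factors`` followed by one line per node, e.g. ::

    targets, factors
    A, !B & C
    B, A | !A

Operators ``!`` (not), ``&`` (and), ``|`` (or), parentheses, and the
constants ``0``/``1``.  On reading, a node's inputs are ordered by first
appearance in its factor expression (first appearance = most-significant
bit, matching the package's truth-table convention); the truth table is
obtained by evaluating the expression over all input combinations.  The
writer emits a full disjunctive normal form with factors in stored input
order, so write→read round-trips bit-exactly.
"""

from __future__ import annotations

import re

from .boolean_core import BooleanNetwork
from .errors import RuleParseError

__all__ = ["write_rules", "read_rules", "save_rules", "load_rules"]

_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.]*|[01]|[!&|()])")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise RuleParseError(f"unexpected character at: {expr[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over:  expr := term ('|' term)* ;
    term := fact ('&' fact)* ;  fact := '!' fact | '(' expr ')' | name | 0 | 1.

    Produces a closure ``f(env) -> 0|1`` and records variable order of
    first appearance.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0
        self.variables: list[str] = []

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        fn = self.expr()
        if self.peek() is not None:
            raise RuleParseError(f"trailing tokens: {self.tokens[self.pos:]}")
        return fn

    def expr(self):
        terms = [self.term()]
        while self.peek() == "|":
            self.take()
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        return lambda env, fs=tuple(terms): int(any(f(env) for f in fs))

    def term(self):
        facts = [self.fact()]
        while self.peek() == "&":
            self.take()
            facts.append(self.fact())
        if len(facts) == 1:
            return facts[0]
        return lambda env, fs=tuple(facts): int(all(f(env) for f in fs))

    def fact(self):
        tok = self.take()
        if tok is None:
            raise RuleParseError("unexpected end of expression")
        if tok == "!":
            inner = self.fact()
            return lambda env, f=inner: 1 - f(env)
        if tok == "(":
            inner = self.expr()
            if self.take() != ")":
                raise RuleParseError("unbalanced parentheses")
            return inner
        if tok in ("0", "1"):
            return lambda env, v=int(tok): v
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tok):
            if tok not in self.variables:
                self.variables.append(tok)
            return lambda env, name=tok: env[name]
        raise RuleParseError(f"unexpected token {tok!r}")


def read_rules(text: str) -> BooleanNetwork:
    """Parse rule text into a :class:`BooleanNetwork`."""
    lines = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise RuleParseError("empty rule text")
    if lines[0].lower().replace(" ", "") in ("targets,factors", "targets,functions"):
        lines = lines[1:]
    targets, exprs = [], []
    for ln in lines:
        if "," not in ln:
            raise RuleParseError(f"rule line without comma: {ln!r}")
        tgt, expr = ln.split(",", 1)
        targets.append(tgt.strip())
        exprs.append(expr.strip())
    if len(set(targets)) != len(targets):
        raise RuleParseError("duplicate target gene")
    index = {name: i for i, name in enumerate(targets)}

    inputs, tables = [], []
    for tgt, expr in zip(targets, exprs):
        parser = _Parser(_tokenize(expr))
        fn = parser.parse()
        for v in parser.variables:
            if v not in index:
                raise RuleParseError(f"rule for {tgt!r} uses undefined gene {v!r}")
        order = parser.variables  # first appearance = most-significant bit
        k = len(order)
        tt = []
        for row in range(1 << k):
            env = {v: (row >> (k - 1 - p)) & 1 for p, v in enumerate(order)}
            tt.append(fn(env))
        inputs.append(tuple(index[v] for v in order))
        tables.append(tuple(tt))
    return BooleanNetwork(
        node_names=tuple(targets), inputs=tuple(inputs), truth_tables=tuple(tables)
    )


def write_rules(net: BooleanNetwork) -> str:
    """Emit rule text; each function is written as a minterm DNF."""
    lines = ["targets, factors"]
    for i in range(net.n):
        name = net.node_names[i]
        inp = net.inputs[i]
        tt = net.truth_tables[i]
        ones = [t for t, v in enumerate(tt) if v]
        if not inp:
            expr = str(tt[0])
        elif not ones:
            # contradiction keeps the input list (and its order) recoverable
            expr = " & ".join(f"{net.node_names[j]} & !{net.node_names[j]}" for j in inp)
        else:
            k = len(inp)
            terms = []
            for t in ones:
                lits = []
                for p, j in enumerate(inp):
                    bit = (t >> (k - 1 - p)) & 1
                    lit = net.node_names[j]
                    lits.append(lit if bit else f"!{lit}")
                terms.append(" & ".join(lits) if len(lits) > 1 else lits[0])
            if len(terms) == 1:
                expr = terms[0]
            else:
                expr = " | ".join(f"({t})" if " & " in t else t for t in terms)
        lines.append(f"{name}, {expr}")
    return "\n".join(lines) + "\n"


def save_rules(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_rules(net))


def load_rules(path) -> BooleanNetwork:
    with open(path) as fh:
        return read_rules(fh.read())
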