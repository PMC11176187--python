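"""Boolean networks, the synchronous map, wiring diagrams, and rule-file I/O.

Rule files follow the plain-text dialect used by public model repositories:
one line per node, ``target, expression``, where the expression combines named
regulators with NOT/AND/OR (``!``, ``&``, ``|`` accepted), parentheses and the
constants 0/1.  An optional ``targets, factors`` header line is ignored.
Node order in state vectors equals file order and is stable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InputShapeError, RuleParseError
from .functions import (
    TruthTable,
    all_input_tuples,
    essential_variables,
    reduce_to_essential,
    to_expression,
)


@dataclass(frozen=True)
class BooleanNetwork:
    """n nodes, each with an ordered regulator list and a matching truth table."""

    names: tuple[str, ...]
    regulators: tuple[tuple[int, ...], ...]
    rules: tuple[TruthTable, ...]

    def __post_init__(self):
        n = len(self.names)
        if len(set(self.names)) != n:
            raise InputShapeError("node names must be unique")
        if len(self.regulators) != n or len(self.rules) != n:
            raise InputShapeError("regulators and rules must match the node count")
        for j, (regs, rule) in enumerate(zip(self.regulators, self.rules)):
            if rule.k != len(regs):
                raise InputShapeError(
                    f"node {self.names[j]}: rule arity {rule.k} != {len(regs)} regulators"
                )
            if any(not 0 <= i < n for i in regs):
                raise InputShapeError(f"node {self.names[j]}: regulator index out of range")

    @property
    def n(self) -> int:
        return len(self.names)

    def step(self, state) -> np.ndarray:
        """One synchronous update of a single binary state vector."""
        state = np.asarray(state, dtype=np.uint8)
        if state.shape != (self.n,):
            raise InputShapeError(f"state must have length {self.n}")
        out = np.empty(self.n, dtype=np.uint8)
        for j in range(self.n):
            out[j] = self.rules[j].evaluate(state[list(self.regulators[j])])
        return out

    def step_batch(self, X: np.ndarray) -> np.ndarray:
        """One synchronous update of a (n_samples, n) bit matrix."""
        X = np.asarray(X, dtype=np.uint8)
        if X.ndim != 2 or X.shape[1] != self.n:
            raise InputShapeError(f"expected (m, {self.n}) bit matrix, got {X.shape}")
        out = np.empty_like(X)
        for j in range(self.n):
            out[:, j] = self.rules[j].evaluate_batch(X[:, list(self.regulators[j])])
        return out

    def reduced_rules(self) -> tuple[tuple[tuple[int, ...], TruthTable], ...]:
        """Per node: (essential regulator node indices, essential-reduced rule)."""
        out = []
        for regs, rule in zip(self.regulators, self.rules):
            ess = sorted(essential_variables(rule))
            out.append((tuple(regs[i] for i in ess), reduce_to_essential(rule)))
        return tuple(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": list(self.names),
                "regulators": [list(r) for r in self.regulators],
                "rules": ["".join(map(str, t.outputs.tolist())) for t in self.rules],
            }
        )


def synchronous_step(net: BooleanNetwork, state) -> np.ndarray:
    return net.step(state)


@dataclass(frozen=True)
class WiringDiagram:
    """Essential-dependency digraph: edge i -> j iff f_j depends on x_i."""

    n: int
    edges: frozenset[tuple[int, int]]

    @property
    def in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for _, j in self.edges:
            deg[j] += 1
        return deg

    @property
    def out_degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, _ in self.edges:
            deg[i] += 1
        return deg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def to_edge_tsv(self, names=None) -> str:
        names = names or [str(i) for i in range(self.n)]
        lines = ["source\ttarget"]
        for i, j in sorted(self.edges):
            lines.append(f"{names[i]}\t{names[j]}")
        return "\n".join(lines) + "\n"


def wiring_diagram(net: BooleanNetwork) -> WiringDiagram:
    """Edges from essential dependencies only (listed-but-inert inputs drop)."""
    edges = set()
    for j, (regs, rule) in enumerate(zip(net.regulators, net.rules)):
        for i in essential_variables(rule):
            edges.add((regs[i], j))
    return WiringDiagram(net.n, frozenset(edges))


_IDENTITY = TruthTable(1, np.array([0, 1], dtype=np.uint8))


def external_parameters(net: BooleanNetwork) -> frozenset[int]:
    """Nodes whose reduced rule is the identity on themselves (f_i = x_i)."""
    ext = set()
    for j, (regs, red) in enumerate(net.reduced_rules()):
        if regs == (j,) and np.array_equal(red.outputs, _IDENTITY.outputs):
            ext.add(j)
    return frozenset(ext)


# ---------------------------------------------------------------------------
# rule-file parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|&+|\|+|!|[A-Za-z_][A-Za-z0-9_.]*|[01])")


def _tokenize(expr: str, line_no: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise RuleParseError(f"unexpected character {expr[pos]!r}", line_no)
            break
        tok = m.group(1)
        upper = tok.upper()
        if upper == "AND":
            tok = "&"
        elif upper == "OR":
            tok = "|"
        elif upper == "NOT":
            tok = "!"
        tokens.append(tok)
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; precedence NOT > AND > OR."""

    def __init__(self, tokens: list[str], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise RuleParseError(f"trailing token {self.peek()!r}", self.line_no)
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok is None:
            raise RuleParseError("unexpected end of expression", self.line_no)
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise RuleParseError("missing closing parenthesis", self.line_no)
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tok):
            return ("var", tok)
        raise RuleParseError(f"unexpected token {tok!r}", self.line_no)


def _ast_variables(node, seen, order):
    kind = node[0]
    if kind == "var":
        if node[1] not in seen:
            seen.add(node[1])
            order.append(node[1])
    elif kind == "not":
        _ast_variables(node[1], seen, order)
    elif kind in ("and", "or"):
        _ast_variables(node[1], seen, order)
        _ast_variables(node[2], seen, order)


def _ast_eval(node, env) -> int:
    kind = node[0]
    if kind == "var":
        return env[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return 1 - _ast_eval(node[1], env)
    if kind == "and":
        return _ast_eval(node[1], env) & _ast_eval(node[2], env)
    return _ast_eval(node[1], env) | _ast_eval(node[2], env)


def read_rules(text: str) -> BooleanNetwork:
    """Parse a rule file into a :class:`BooleanNetwork`.

    Errors carry line numbers; undeclared regulators and duplicate targets
    are rejected.
    """
    entries: list[tuple[str, object, list[str], int]] = []
    targets: dict[str, int] = {}
    first_content = True
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if first_content:
            first_content = False
            if line.lower().replace(" ", "") == "targets,factors":
                continue
        if "," not in line:
            raise RuleParseError("expected 'target, expression'", line_no)
        target, expr = line.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", target):
            raise RuleParseError(f"invalid target name {target!r}", line_no)
        if target in targets:
            raise RuleParseError(f"duplicate target {target!r}", line_no)
        ast = _Parser(_tokenize(expr, line_no), line_no).parse()
        seen: set[str] = set()
        order: list[str] = []
        _ast_variables(ast, seen, order)
        targets[target] = len(entries)
        entries.append((target, ast, order, line_no))

    names = tuple(e[0] for e in entries)
    regulators, rules = [], []
    for target, ast, order, line_no in entries:
        for name in order:
            if name not in targets:
                raise RuleParseError(
                    f"undeclared regulator {name!r} in rule for {target!r}", line_no
                )
        k = len(order)
        X = all_input_tuples(k)
        out = np.empty(1 << k, dtype=np.uint8)
        for idx, row in enumerate(X):
            env = dict(zip(order, (int(v) for v in row)))
            out[idx] = _ast_eval(ast, env)
        regulators.append(tuple(targets[name] for name in order))
        rules.append(TruthTable(k, out, tuple(order)))
    return BooleanNetwork(names, tuple(regulators), tuple(rules))


def write_rules(net: BooleanNetwork) -> str:
    """Serialize to the rule-file dialect (header + one minterm-DNF line/node).

    ``read_rules(write_rules(net))`` reproduces all truth tables bit-exactly,
    except that constant rules come back as 0-regulator rules (their inert
    listed inputs are not representable in an expression).
    """
    lines = ["targets, factors"]
    for j in range(net.n):
        regs = net.regulators[j]
        expr = to_expression(net.rules[j], tuple(net.names[i] for i in regs))
        lines.append(f"{net.names[j]}, {expr}")
    return "\n".join(lines) + "\n"
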