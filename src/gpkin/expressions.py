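"""Expression trees: the genotypes of the symbolic-regression search.

A tree is built from the fixed primitive sets used throughout the package:

* binary functions ``+  -  *  /  ^`` (real-valued power),
* unary functions ``sin  cos  ln  exp`` (angles in radians),
* terminal variables ``C0`` (initial apical concentration, uM) and ``t``
  (time, min),
* terminal constants (the search draws from {1, 5, 10, 100, 1000}; after
  Lamarckian refitting constants may hold arbitrary reals),
* named parameter slots (``b1``, ``b2``, ...) produced by :func:`parameterize`.

Evaluation is deliberately *unprotected*: division by zero, ``ln`` of a
non-positive number, a negative base raised to a non-integer power, or an
``exp`` overflow all yield non-finite values (``nan``/``inf``) that propagate
to the caller.  Models with singularities inside the experimental domain are
removed later by curation rather than silently patched during evaluation.
"""

from __future__ import annotations

import json
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import sympy as sp

from .exceptions import ArityError, ParseError, PruneError

__all__ = [
    "Node",
    "UNARY_FUNCTIONS",
    "BINARY_FUNCTIONS",
    "VARIABLES",
    "DEFAULT_CONSTANTS",
    "variable",
    "constant",
    "parameter",
    "func",
    "evaluate",
    "evaluate_exact",
    "is_finite_on",
    "param_names",
    "parameterize",
    "substitute",
    "prune",
    "conserved_fraction",
    "serialize",
    "parse",
    "to_sympy",
    "to_json",
    "from_json",
]

UNARY_FUNCTIONS = ("sin", "cos", "ln", "exp")
BINARY_FUNCTIONS = ("add", "sub", "mul", "div", "pow")
VARIABLES = ("C0", "t")
#: Constant pool of the search's terminal set.
DEFAULT_CONSTANTS = (1.0, 5.0, 10.0, 100.0, 1000.0)

_OP_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "^"}
_SYMBOL_OP = {v: k for k, v in _OP_SYMBOL.items()}


class Node:
    """A node of a rooted, ordered expression tree.

    ``kind`` is one of ``"func"``, ``"var"``, ``"const"``, ``"param"``.
    ``value`` holds the function name, variable name, constant value, or
    parameter name respectively.  Children are ordered; arity is fixed by
    the function name (unary or binary).
    """

    __slots__ = ("kind", "value", "children")

    def __init__(self, kind: str, value, children: tuple = ()):
        if kind == "func":
            arity = 1 if value in UNARY_FUNCTIONS else 2
            if value not in UNARY_FUNCTIONS and value not in BINARY_FUNCTIONS:
                raise ValueError(f"unknown function {value!r}")
            if len(children) != arity:
                raise ValueError(
                    f"{value} expects {arity} operand(s), got {len(children)}")
        elif kind == "var":
            if value not in VARIABLES:
                raise ValueError(f"unknown variable {value!r}")
            if children:
                raise ValueError("leaves take no children")
        elif kind == "const":
            value = float(value)
            if children:
                raise ValueError("leaves take no children")
        elif kind == "param":
            if children:
                raise ValueError("leaves take no children")
        else:
            raise ValueError(f"unknown node kind {kind!r}")
        self.kind = kind
        self.value = value
        self.children = tuple(children)

    # -- structure ---------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return self.kind != "func"

    def depth(self) -> int:
        """Number of levels; a lone leaf has depth 1."""
        if self.is_leaf:
            return 1
        return 1 + max(c.depth() for c in self.children)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def iter_paths(self) -> Iterator[tuple[tuple[int, ...], "Node"]]:
        """Depth-first (pre-order) iteration as ``(path, node)`` pairs.

        A path is the tuple of child indices from the root; the root's path
        is ``()``.
        """
        stack = [((), self)]
        while stack:
            path, node = stack.pop()
            yield path, node
            for i in range(len(node.children) - 1, -1, -1):
                stack.append((path + (i,), node.children[i]))

    def node_at(self, path: Sequence[int]) -> "Node":
        node = self
        for i in path:
            try:
                node = node.children[i]
            except IndexError:
                raise PruneError(f"no node at path {tuple(path)}") from None
        return node

    def replace_at(self, path: Sequence[int], new: "Node") -> "Node":
        """Return a copy of the tree with the subtree at ``path`` replaced."""
        if not path:
            return new
        i = path[0]
        children = list(self.children)
        children[i] = children[i].replace_at(path[1:], new)
        return Node(self.kind, self.value, tuple(children))

    def copy(self) -> "Node":
        return Node(self.kind, self.value,
                    tuple(c.copy() for c in self.children))

    # -- comparison --------------------------------------------------------

    def _key(self):
        return (self.kind, self.value, tuple(c._key() for c in self.children))

    def __eq__(self, other):
        return isinstance(other, Node) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __repr__(self):
        return f"Node({serialize(self)!r})"


def variable(name: str) -> Node:
    return Node("var", name)


def constant(value: float) -> Node:
    return Node("const", value)


def parameter(name: str) -> Node:
    return Node("param", name)


def func(name: str, *children: Node) -> Node:
    return Node("func", name, children)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _real_power(a, b):
    # Real-valued power: negative base with non-integer exponent -> nan
    # (numpy float semantics), 0^negative -> inf.  No complex arithmetic.
    return np.power(a, b)


_FUNC_IMPL: dict[str, Callable] = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": np.true_divide,
    "pow": _real_power,
    "sin": np.sin,
    "cos": np.cos,
    "ln": np.log,
    "exp": np.exp,
}


def compile_evaluator(tree: Node, names: Sequence[str] | None = None):
    """Compile a tree into ``fn(c0, t, beta_array) -> values``.

    ``beta_array`` is positional, aligned with ``names`` (default:
    :func:`param_names` order).  Semantics are identical to
    :func:`evaluate`; this exists because the search evaluates the same
    genotype thousands of times inside nonlinear fits.
    """
    if names is None:
        names = param_names(tree)
    index = {name: i for i, name in enumerate(names)}

    def build(n: Node):
        if n.kind == "const":
            v = n.value
            return lambda c0, t, b: v
        if n.kind == "var":
            if n.value == "C0":
                return lambda c0, t, b: c0
            return lambda c0, t, b: t
        if n.kind == "param":
            i = index[n.value]
            return lambda c0, t, b: b[i]
        impl = _FUNC_IMPL[n.value]
        args = [build(c) for c in n.children]
        if len(args) == 1:
            a, = args
            return lambda c0, t, b: impl(a(c0, t, b))
        a, b2 = args
        return lambda c0, t, b: impl(a(c0, t, b), b2(c0, t, b))

    body = build(tree)

    def fn(c0, t, beta=()):
        with np.errstate(all="ignore"):
            return body(c0, t, beta)

    return fn


def param_names(tree: Node) -> list[str]:
    """Parameter names in depth-first left-to-right order of first occurrence."""
    names: list[str] = []
    def walk(n: Node):
        if n.kind == "param":
            if n.value not in names:
                names.append(n.value)
        for c in n.children:
            walk(c)
    walk(tree)
    return names


def _beta_mapping(tree: Node, beta) -> Mapping[str, float]:
    names = param_names(tree)
    if beta is None:
        beta = {}
    if isinstance(beta, Mapping):
        missing = [n for n in names if n not in beta]
        if missing:
            raise ArityError(f"missing parameter values for {missing}")
        return beta
    beta = list(beta)
    if len(beta) != len(names):
        raise ArityError(
            f"expected {len(names)} parameter values, got {len(beta)}")
    return dict(zip(names, beta))


def evaluate(tree: Node, c0, t, beta=None):
    """Evaluate the tree at ``(c0, t)`` in float64.

    ``beta`` maps parameter names to values (or is a sequence aligned with
    :func:`param_names`).  Inputs broadcast like numpy arrays.  Non-finite
    intermediate or final values are returned as-is; nothing is masked or
    "protected".
    """
    mapping = _beta_mapping(tree, beta)
    c0 = np.asarray(c0, dtype=float)
    t = np.asarray(t, dtype=float)

    def ev(n: Node):
        if n.kind == "const":
            return n.value
        if n.kind == "var":
            return c0 if n.value == "C0" else t
        if n.kind == "param":
            return float(mapping[n.value])
        args = [ev(c) for c in n.children]
        with np.errstate(all="ignore"):
            return _FUNC_IMPL[n.value](*args)

    with np.errstate(all="ignore"):
        out = ev(tree)
    return np.asarray(out, dtype=float) + np.zeros(np.broadcast(c0, t).shape)


def is_finite_on(tree: Node, beta, c0_grid, t_grid) -> bool:
    """True iff the model is finite at every probed ``(c0, t)`` point."""
    c0g, tg = np.meshgrid(np.asarray(c0_grid, float),
                          np.asarray(t_grid, float), indexing="ij")
    vals = evaluate(tree, c0g.ravel(), tg.ravel(), beta)
    return bool(np.all(np.isfinite(vals)))


# ---------------------------------------------------------------------------
# sympy bridge and exact evaluation
# ---------------------------------------------------------------------------

_SP_FUNC = {
    "add": lambda a, b: sp.Add(a, b, evaluate=False),
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: sp.Mul(a, b, evaluate=False),
    "div": lambda a, b: a / b,
    "pow": lambda a, b: a ** b,
    "sin": sp.sin,
    "cos": sp.cos,
    "ln": sp.log,
    "exp": sp.exp,
}


def to_sympy(tree: Node, beta=None, exact_constants: bool = True):
    """Convert to a sympy expression.

    With ``exact_constants=True`` numeric leaves (and supplied parameter
    values) become exact rationals of their decimal representation, so the
    expression can be evaluated with arbitrary-precision argument reduction;
    this matters because trees may nest huge arguments inside ``sin``/``cos``
    where float64 reduction is meaningless.
    """
    mapping = dict(_beta_mapping(tree, beta)) if beta is not None else None

    def num(x: float):
        return sp.Rational(repr(float(x))) if exact_constants else sp.Float(x)

    def conv(n: Node):
        if n.kind == "const":
            return num(n.value)
        if n.kind == "var":
            return sp.Symbol(n.value)
        if n.kind == "param":
            if mapping is not None:
                return num(mapping[n.value])
            return sp.Symbol(n.value)
        return _SP_FUNC[n.value](*[conv(c) for c in n.children])

    return conv(tree)


def evaluate_exact(tree: Node, c0, t, beta=None, dps: int = 50) -> float:
    """Arbitrary-precision evaluation at a single point.

    Printed decimal constants are treated as exact, and trigonometric
    argument reduction is performed at ``dps`` digits, so the result is the
    mathematically defined value of the written expression even when
    arguments are far beyond float64's reduction range.
    """
    expr = to_sympy(tree, beta=beta, exact_constants=True)
    expr = expr.subs({sp.Symbol("C0"): sp.Rational(repr(float(c0))),
                      sp.Symbol("t"): sp.Rational(repr(float(t)))})
    return float(sp.N(expr, dps))


# ---------------------------------------------------------------------------
# Parameter lifting
# ---------------------------------------------------------------------------

def parameterize(tree: Node, prefix: str = "b") -> tuple[Node, list[float]]:
    """Lift every constant leaf into a distinct named parameter slot.

    Slots are numbered ``b1, b2, ...`` in depth-first left-to-right order;
    the returned vector holds the original constants in slot order.
    """
    beta0: list[float] = []

    def walk(n: Node) -> Node:
        if n.kind == "const":
            beta0.append(n.value)
            return Node("param", f"{prefix}{len(beta0)}")
        if n.is_leaf:
            return n
        return Node(n.kind, n.value, tuple(walk(c) for c in n.children))

    return walk(tree), beta0


def substitute(tree: Node, beta) -> Node:
    """Replace parameter slots by constants holding their ``beta`` values."""
    mapping = _beta_mapping(tree, beta)

    def walk(n: Node) -> Node:
        if n.kind == "param":
            return Node("const", float(mapping[n.value]))
        if n.is_leaf:
            return n
        return Node(n.kind, n.value, tuple(walk(c) for c in n.children))

    return walk(tree)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune(tree: Node, node_path: Sequence[int]) -> Node:
    """Remove the subtree at ``node_path``.

    For a binary parent the surviving operand replaces the parent; removing
    the operand of a unary parent (or the root) cannot leave a valid tree
    and raises :class:`PruneError`.
    """
    node_path = tuple(node_path)
    if not node_path:
        raise PruneError("cannot remove the root")
    tree.node_at(node_path)  # raises if absent
    parent_path, idx = node_path[:-1], node_path[-1]
    parent = tree.node_at(parent_path)
    if parent.kind != "func" or len(parent.children) != 2:
        raise PruneError(
            "removal target's parent is not a binary node; pruning would "
            "leave an arity-invalid tree")
    survivor = parent.children[1 - idx]
    return tree.replace_at(parent_path, survivor)


# ---------------------------------------------------------------------------
# Positional conservation
# ---------------------------------------------------------------------------

def _symbol(n: Node):
    if n.kind == "func":
        return ("func", n.value)
    if n.kind == "const":
        return ("const", n.value)
    return (n.kind, n.value)


def conserved_fraction(reference: Node, population_subset: Iterable[Node]) -> float:
    """Fraction of reference nodes whose symbol is conserved positionally.

    A reference node counts as conserved when every member of the subset has
    a node at the same tree position with an identical symbol (function name,
    variable, parameter name, or constant value).
    """
    members = list(population_subset)
    if not members:
        raise ValueError("population subset must be non-empty")

    def node_or_none(tree: Node, path):
        n = tree
        for i in path:
            if n.kind != "func" or i >= len(n.children):
                return None
            n = n.children[i]
        return n

    ref_nodes = list(reference.iter_paths())
    conserved = 0
    for path, rnode in ref_nodes:
        ok = True
        for m in members:
            other = node_or_none(m, path)
            if other is None or _symbol(other) != _symbol(rnode):
                ok = False
                break
        conserved += ok
    return conserved / len(ref_nodes)


# ---------------------------------------------------------------------------
# Serialization: canonical infix grammar
# ---------------------------------------------------------------------------
#
#   expr    := term | expr ('+'|'-') term          (left-assoc, via parens)
#   term    := factor | term ('*'|'/') factor
#   factor  := base '^' factor | base
#   base    := NUMBER | '-' NUMBER | 'C0' | 't' | IDENT
#            | FUNC '(' expr ')' | '(' expr ')'
#
# serialize() emits explicit parentheses around every binary operation, so
# parse(serialize(x)) rebuilds the identical structure.

def serialize(tree: Node) -> str:
    if tree.kind == "const":
        return repr(tree.value)
    if tree.kind in ("var", "param"):
        return str(tree.value)
    name = tree.value
    if name in UNARY_FUNCTIONS:
        return f"{name}({serialize(tree.children[0])})"
    a, b = tree.children
    return f"({serialize(a)} {_OP_SYMBOL[name]} {serialize(b)})"


_TOKEN_CHARS = set("+-*/^()")


def _tokenize(text: str):
    tokens = []  # (type, value, pos)
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _TOKEN_CHARS:
            tokens.append(("op", ch, i))
            i += 1
            continue
        if ch.isdigit() or ch == ".":
            j = i
            while j < n and (text[j].isdigit() or text[j] in ".eE" or
                             (text[j] in "+-" and j > i and text[j - 1] in "eE")):
                j += 1
            try:
                val = float(text[i:j])
            except ValueError:
                raise ParseError(f"bad number {text[i:j]!r}", i)
            tokens.append(("number", val, i))
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("ident", text[i:j], i))
            i = j
            continue
        raise ParseError(f"unexpected character {ch!r}", i)
    tokens.append(("end", None, n))
    return tokens


def parse(text: str) -> Node:
    """Parse the canonical infix grammar back into a tree."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos]

    def take(expect_type=None, expect_val=None):
        nonlocal pos
        typ, val, p = tokens[pos]
        if expect_type and typ != expect_type:
            raise ParseError(f"expected {expect_type}, found {val!r}", p)
        if expect_val is not None and val != expect_val:
            raise ParseError(f"expected {expect_val!r}, found {val!r}", p)
        pos += 1
        return typ, val, p

    def parse_expr() -> Node:
        node = parse_term()
        while peek()[0] == "op" and peek()[1] in "+-":
            _, op, _ = take()
            rhs = parse_term()
            node = func("add" if op == "+" else "sub", node, rhs)
        return node

    def parse_term() -> Node:
        node = parse_factor()
        while peek()[0] == "op" and peek()[1] in "*/":
            _, op, _ = take()
            rhs = parse_factor()
            node = func("mul" if op == "*" else "div", node, rhs)
        return node

    def parse_factor() -> Node:
        node = parse_base()
        if peek()[0] == "op" and peek()[1] == "^":
            take()
            rhs = parse_factor()  # right-assoc
            node = func("pow", node, rhs)
        return node

    def parse_base() -> Node:
        typ, val, p = peek()
        if typ == "number":
            take()
            return constant(val)
        if typ == "op" and val == "-":
            take()
            typ2, val2, p2 = peek()
            if typ2 != "number":
                raise ParseError("unary minus is only allowed before a "
                                 "numeric literal", p)
            take()
            return constant(-val2)
        if typ == "op" and val == "(":
            take()
            node = parse_expr()
            take("op", ")")
            return node
        if typ == "ident":
            take()
            if val in UNARY_FUNCTIONS:
                take("op", "(")
                arg = parse_expr()
                take("op", ")")
                return func(val, arg)
            if val in VARIABLES:
                return variable(val)
            return parameter(val)
        raise ParseError(f"unexpected token {val!r}", p)

    node = parse_expr()
    typ, val, p = peek()
    if typ != "end":
        raise ParseError(f"trailing input {val!r}", p)
    return node


# ---------------------------------------------------------------------------
# JSON provenance export
# ---------------------------------------------------------------------------

def to_json(tree: Node) -> str:
    def enc(n: Node):
        d = {"kind": n.kind, "value": n.value}
        if n.children:
            d["children"] = [enc(c) for c in n.children]
        return d
    return json.dumps(enc(tree))


def from_json(text: str) -> Node:
    def dec(d) -> Node:
        return Node(d["kind"], d["value"],
                    tuple(dec(c) for c in d.get("children", ())))
    return dec(json.loads(text))
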