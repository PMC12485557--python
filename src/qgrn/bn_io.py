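"""Reading, writing and compiling synchronous Boolean networks (BoolNet dialect).

A network is an ordered list of genes, each with one Boolean update rule.
Rules use the BoolNet text grammar: ``!`` (NOT), ``&`` (AND), ``|`` (OR),
parentheses and the constants ``0``/``1``.  Operator precedence is
``!`` > ``&`` > ``|``; whitespace is insignificant.

State encoding convention (used package-wide): a state string is written
gene1...geneN left to right, and its integer index treats gene1 as the MOST
significant bit, so the printed label ``"1011"`` of a 4-gene network is state
index 11.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BooleanExpression",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanNetwork",
    "NetworkFormatError",
    "UndeclaredGeneError",
    "parse_boolnet",
    "parse_expression",
    "write_boolnet",
    "rule_truth_table",
    "state_to_string",
    "string_to_state",
]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

#: BoolNet extensions we deliberately refuse instead of misparsing.
_RESERVED = {"all", "any", "maj", "sumgt", "sumlt", "timegt", "timelt", "timeis"}


class NetworkFormatError(ValueError):
    """Malformed BoolNet input (header, duplicate targets, bad syntax)."""


class UndeclaredGeneError(NetworkFormatError):
    """A rule references a gene that is not declared as a target."""

    def __init__(self, gene: str):
        super().__init__(f"rule references undeclared gene {gene!r}")
        self.gene = gene


# --------------------------------------------------------------------------
# Expression AST


class BooleanExpression:
    """Base class for Boolean rule expressions."""

    def variables(self) -> set[str]:
        """Names of all genes referenced by this expression."""
        out: set[str] = set()
        self._collect(out)
        return out

    def _collect(self, out: set[str]) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def evaluate(self, env: dict[str, np.ndarray | int]) -> np.ndarray | int:
        raise NotImplementedError

    def unparse(self, parent_prec: int = 0) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self.unparse()


@dataclass(frozen=True)
class Var(BooleanExpression):
    name: str

    def _collect(self, out: set[str]) -> None:
        out.add(self.name)

    def evaluate(self, env):
        return env[self.name]

    def unparse(self, parent_prec: int = 0) -> str:
        return self.name


@dataclass(frozen=True)
class Const(BooleanExpression):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError("Boolean constants must be 0 or 1")

    def _collect(self, out: set[str]) -> None:
        pass

    def evaluate(self, env):
        return self.value

    def unparse(self, parent_prec: int = 0) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Not(BooleanExpression):
    child: BooleanExpression

    def _collect(self, out: set[str]) -> None:
        self.child._collect(out)

    def evaluate(self, env):
        return 1 - self.child.evaluate(env)

    def unparse(self, parent_prec: int = 0) -> str:
        return "!" + self.child.unparse(3)


@dataclass(frozen=True)
class And(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    def _collect(self, out: set[str]) -> None:
        for c in self.children:
            c._collect(out)

    def evaluate(self, env):
        result = self.children[0].evaluate(env)
        for c in self.children[1:]:
            result = result * c.evaluate(env)
        return result

    def unparse(self, parent_prec: int = 0) -> str:
        text = " & ".join(c.unparse(2) for c in self.children)
        return f"({text})" if parent_prec > 2 else text


@dataclass(frozen=True)
class Or(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    def _collect(self, out: set[str]) -> None:
        for c in self.children:
            c._collect(out)

    def evaluate(self, env):
        result = self.children[0].evaluate(env)
        for c in self.children[1:]:
            v = c.evaluate(env)
            result = result + v - result * v
        return result

    def unparse(self, parent_prec: int = 0) -> str:
        text = " | ".join(c.unparse(1) for c in self.children)
        return f"({text})" if parent_prec > 1 else text


# --------------------------------------------------------------------------
# Network container


@dataclass
class BooleanNetwork:
    """A synchronous Boolean network: ordered genes + one rule per gene."""

    genes: list[str]
    rules: list[BooleanExpression]
    comment: str = ""

    def __post_init__(self):
        if len(self.genes) != len(self.rules) or not self.genes:
            raise NetworkFormatError("need one rule per gene and at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise NetworkFormatError("duplicate gene names")
        for g in self.genes:
            if not _NAME_RE.fullmatch(g):
                raise NetworkFormatError(f"invalid gene name {g!r}")
        declared = set(self.genes)
        for rule in self.rules:
            for v in rule.variables():
                if v not in declared:
                    raise UndeclaredGeneError(v)

    @property
    def n(self) -> int:
        return len(self.genes)

    def gene_index(self, name: str) -> int:
        return self.genes.index(name)


# --------------------------------------------------------------------------
# Parsing


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "!&|()":
            yield (ch, ch)
            i += 1
        elif ch in "01":
            yield ("const", ch)
            i += 1
        else:
            m = _NAME_RE.match(text, i)
            if not m:
                raise NetworkFormatError(f"unexpected character {ch!r} in rule {text!r}")
            name = m.group(0)
            if name.lower() in _RESERVED:
                raise NetworkFormatError(
                    f"unsupported BoolNet extension {name!r}; only plain "
                    "Boolean rules (!, &, |, 0, 1) are accepted"
                )
            yield ("name", name)
            i = m.end()


class _Parser:
    """Recursive-descent parser for the rule grammar: or > and > not > atom."""

    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.text = text

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, kind: str | None = None) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise NetworkFormatError(f"unexpected end of rule {self.text!r}")
        if kind is not None and tok[0] != kind:
            raise NetworkFormatError(
                f"expected {kind!r} but found {tok[1]!r} in rule {self.text!r}"
            )
        self.pos += 1
        return tok

    def parse(self) -> BooleanExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            raise NetworkFormatError(
                f"trailing input {self.peek()[1]!r} in rule {self.text!r}"
            )
        return expr

    def parse_or(self) -> BooleanExpression:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek()[0] == "|":
            self.take("|")
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> BooleanExpression:
        factors = [self.parse_not()]
        while self.peek() is not None and self.peek()[0] == "&":
            self.take("&")
            factors.append(self.parse_not())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_not(self) -> BooleanExpression:
        if self.peek() is not None and self.peek()[0] == "!":
            self.take("!")
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> BooleanExpression:
        tok = self.take()
        kind, value = tok
        if kind == "name":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        if kind == "(":
            expr = self.parse_or()
            self.take(")")
            return expr
        raise NetworkFormatError(f"unexpected token {value!r} in rule {self.text!r}")


def parse_expression(text: str) -> BooleanExpression:
    """Parse a single rule expression (no header, no target)."""
    return _Parser(text).parse()


def parse_boolnet(text: str) -> BooleanNetwork:
    """Parse a BoolNet-formatted network description.

    Expects a ``targets, factors`` header, then one ``gene, expression`` line
    per gene; ``#`` starts a comment.  The rule order defines the gene order
    (and hence the bit order of state indices).

    Raises
    ------
    NetworkFormatError
        Missing header, duplicate target, or malformed rule.
    UndeclaredGeneError
        A rule references a gene with no rule line of its own.
    """
    lines: list[str] = []
    comments: list[str] = []
    for raw in text.splitlines():
        stripped = raw.split("#", 1)[0].strip()
        if raw.strip().startswith("#"):
            comments.append(raw.strip().lstrip("#").strip())
        if stripped:
            lines.append(stripped)
    if not lines:
        raise NetworkFormatError("empty BoolNet input")
    header = [p.strip().lower() for p in lines[0].split(",")]
    if header[:2] != ["targets", "factors"]:
        raise NetworkFormatError(
            f"missing 'targets, factors' header (found {lines[0]!r})"
        )
    genes: list[str] = []
    rules: list[BooleanExpression] = []
    for line in lines[1:]:
        if "," not in line:
            raise NetworkFormatError(f"rule line without comma: {line!r}")
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not _NAME_RE.fullmatch(target):
            raise NetworkFormatError(f"invalid target gene name {target!r}")
        if target in genes:
            raise NetworkFormatError(f"duplicate target gene {target!r}")
        if "," in expr_text:
            raise NetworkFormatError(
                f"unsupported rule format (extra comma) in line {line!r}; "
                "probabilistic BoolNet rules are not supported"
            )
        genes.append(target)
        rules.append(parse_expression(expr_text))
    return BooleanNetwork(genes, rules, comment="\n".join(comments))


def write_boolnet(net: BooleanNetwork) -> str:
    """Serialize a network to BoolNet text; inverse of :func:`parse_boolnet`."""
    out = []
    for line in net.comment.splitlines():
        out.append(f"# {line}" if line else "#")
    out.append("targets, factors")
    for gene, rule in zip(net.genes, net.rules):
        out.append(f"{gene}, {rule.unparse()}")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Truth-table compilation


def state_bits(n: int, states: np.ndarray | None = None) -> np.ndarray:
    """Bit matrix of shape (len(states), n), gene 0 in the MSB column."""
    if states is None:
        states = np.arange(1 << n)
    states = np.asarray(states)
    shifts = np.arange(n - 1, -1, -1)
    return (states[:, None] >> shifts[None, :]) & 1


def state_to_string(state: int, n: int) -> str:
    return format(state, f"0{n}b")


def string_to_state(bits: str) -> int:
    return int(bits, 2)


def rule_truth_table(net: BooleanNetwork, gene_index: int) -> np.ndarray:
    """Truth table (length 2**n, dtype uint8) of one gene's update rule.

    Entry ``s`` is the rule evaluated on the bit assignment encoded by state
    index ``s`` (gene 0 = MSB).
    """
    if not 0 <= gene_index < net.n:
        raise IndexError(f"gene index {gene_index} out of range for n={net.n}")
    bits = state_bits(net.n)
    env = {g: bits[:, i] for i, g in enumerate(net.genes)}
    table = net.rules[gene_index].evaluate(env)
    if np.isscalar(table):
        table = np.full(1 << net.n, table)
    return np.asarray(table, dtype=np.uint8)
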