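"""Packaged example networks and seeded synthetic-network generators.

Everything a test or benchmark needs is generated programmatically or
shipped as a small BoolNet text file:

* ``giacomantonio_fixture`` — the 5-gene Boolean model of mammalian
  cortical area development (Fgf8, Emx2, Pax6, Coup_tfi, Sp8): two
  fixed-point attractors with basins 4 and 28 of the 32 states.
* ``fourgene_fixture`` — a SYNTHETIC 4-gene network constructed so its
  attractor set is exactly the five fixed points 0000, 1011, 0011, 1111
  and 1101; a stand-in mirroring the published 4-agent demonstration
  case, whose original rules are not redistributed here.
* ``random_network`` — seeded random k-regulator networks for the
  randomized property suites.
* ``make_chain_network`` — the pathological worst case: a state space that
  is one long chain (saturating binary counter), where uniform sampling
  after T_t steps hits the single attractor with probability (T_t+1)/2**n.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .bn_io import (
    And,
    BooleanExpression,
    BooleanNetwork,
    Const,
    Not,
    Or,
    Var,
    parse_boolnet,
)
from .classical import EXHAUSTIVE_GUARD

__all__ = [
    "random_network",
    "make_chain_network",
    "fourgene_fixture",
    "giacomantonio_fixture",
    "network_from_truth_tables",
]


def _load_packaged(name: str) -> BooleanNetwork:
    text = resources.files("qgrn.data").joinpath(name).read_text(encoding="utf-8")
    return parse_boolnet(text)


def giacomantonio_fixture() -> BooleanNetwork:
    """The 5-gene cortical-area-development network (two attractors,
    basins 4 and 28 of 32)."""
    return _load_packaged("giacomantonio.bn")


def fourgene_fixture() -> BooleanNetwork:
    """SYNTHETIC 4-gene network whose attractors are exactly the fixed
    points 0000, 1011, 0011, 1111, 1101 (a constructed stand-in)."""
    return _load_packaged("fourgene_synthetic.bn")


def _minterm_expression(
    genes: list[str], table: np.ndarray, support: list[int]
) -> BooleanExpression:
    """Sum-of-minterms expression over the support genes for a truth table
    indexed MSB-first by the support assignment."""
    k = len(support)
    ones = np.nonzero(table)[0]
    if len(ones) == 0:
        return Const(0)
    if len(ones) == 1 << k:
        return Const(1)
    terms: list[BooleanExpression] = []
    for s in ones:
        lits: list[BooleanExpression] = []
        for j in range(k):
            v: BooleanExpression = Var(genes[support[j]])
            if not (int(s) >> (k - 1 - j)) & 1:
                v = Not(v)
            lits.append(v)
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def network_from_truth_tables(
    genes: list[str], supports: list[list[int]], tables: list[np.ndarray]
) -> BooleanNetwork:
    """Build a network whose gene i implements ``tables[i]`` over the genes
    in ``supports[i]`` (sum-of-minterms rules)."""
    rules = [
        _minterm_expression(genes, t, sup) for t, sup in zip(tables, supports)
    ]
    return BooleanNetwork(list(genes), rules)


def random_network(
    n: int, k: int, seed: int, bias: float = 0.5
) -> BooleanNetwork:
    """Seeded random network: every gene gets k distinct regulators chosen
    uniformly and an independent random truth table with P(1) = ``bias``.
    Deterministic in its arguments."""
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if n > EXHAUSTIVE_GUARD:
        raise ValueError(f"n={n} exceeds the exhaustive guard")
    rng = np.random.default_rng(seed)
    genes = [f"g{i+1}" for i in range(n)]
    supports = [sorted(rng.choice(n, size=k, replace=False).tolist()) for _ in range(n)]
    tables = [(rng.random(1 << k) < bias).astype(np.uint8) for _ in range(n)]
    return network_from_truth_tables(genes, supports, tables)


def _xor(a: BooleanExpression, b: BooleanExpression) -> BooleanExpression:
    return Or((And((a, Not(b))), And((Not(a), b))))


def make_chain_network(n: int) -> BooleanNetwork:
    """Saturating binary counter: state s maps to s+1, the all-ones state
    is the unique (fixed-point) attractor, and the state transition graph
    is a single chain of length 2**n, so the transient time is 2**n - 1.

    Bit i flips exactly when all lower-order bits are 1 and the state is
    not yet all-ones: bit_i' = bit_i XOR (AND lower) & !(AND all).
    """
    if n > EXHAUSTIVE_GUARD:
        raise ValueError(f"n={n} exceeds the exhaustive guard")
    genes = [f"b{i+1}" for i in range(n)]  # b1 is the most significant bit
    all_ones: BooleanExpression = (
        Var(genes[0]) if n == 1 else And(tuple(Var(g) for g in genes))
    )
    rules: list[BooleanExpression] = []
    for i in range(n):
        lower = [Var(genes[j]) for j in range(i + 1, n)]
        if lower:
            carry: BooleanExpression = lower[0] if len(lower) == 1 else And(tuple(lower))
            flip: BooleanExpression = And((carry, Not(all_ones)))
        else:
            flip = Not(all_ones)
        rules.append(_xor(Var(genes[i]), flip))
    return BooleanNetwork(genes, rules)
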