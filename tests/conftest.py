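"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute every feature family with explicit
per-position loops and no code shared with the package, so they can
arbitrate the vectorised implementations.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from cytosel import ALPHABET, PropertyGroupTable, ProteinRecord


@pytest.fixture(scope="session")
def table() -> PropertyGroupTable:
    return PropertyGroupTable.default()


@pytest.fixture(scope="session")
def random_records() -> list[ProteinRecord]:
    """200 random sequences of lengths 1-100 (includes L=1 edge cases)."""
    rng = random.Random(20240917)
    records = []
    for i in range(200):
        length = rng.randint(1, 100)
        seq = "".join(rng.choice(ALPHABET) for _ in range(length))
        records.append(ProteinRecord(id=f"r{i}", sequence=seq))
    return records


# ---------------------------------------------------------------------------
# brute-force oracles (explicit loops, independent of cytosel internals)

def oracle_composition(seq: str) -> list[float]:
    out = []
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        count = 0
        for ch in seq:
            if ch == aa:
                count += 1
        out.append(count / len(seq))
    return out


def _oracle_groups(table: PropertyGroupTable):
    """(property, [set, set, set]) pairs read straight off the table."""
    return [
        (prop, [set(res) for _, res in groups]) for prop, groups in table.properties
    ]


def oracle_content(seq: str, table: PropertyGroupTable) -> list[float]:
    out = []
    for _, groups in _oracle_groups(table):
        for members in groups:
            count = 0
            for ch in seq:
                if ch in members:
                    count += 1
            out.append(count / len(seq))
    return out


def oracle_transition(seq: str, table: PropertyGroupTable) -> list[float]:
    out = []
    for _, groups in _oracle_groups(table):
        for a, b in ((0, 1), (0, 2), (1, 2)):
            count = 0
            for i in range(len(seq) - 1):
                x, y = seq[i], seq[i + 1]
                if (x in groups[a] and y in groups[b]) or (
                    x in groups[b] and y in groups[a]
                ):
                    count += 1
            out.append(count / len(seq))
    return out


def oracle_distribution(seq: str, table: PropertyGroupTable) -> list[float]:
    out = []
    length = len(seq)
    for _, groups in _oracle_groups(table):
        for members in groups:
            positions = []
            for i, ch in enumerate(seq):
                if ch in members:
                    positions.append(i + 1)
            n_g = len(positions)
            if n_g == 0:
                out.extend([0.0] * 5)
                continue
            ks = [1]
            for q in (0.25, 0.5, 0.75, 1.0):
                ks.append(math.ceil(q * n_g))
            for k in ks:
                out.append(positions[k - 1] / length)
    return out


def oracle_full(seq: str, table: PropertyGroupTable) -> list[float]:
    return (
        oracle_composition(seq)
        + oracle_content(seq, table)
        + oracle_transition(seq, table)
        + oracle_distribution(seq, table)
    )
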