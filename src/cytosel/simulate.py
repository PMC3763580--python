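"""Synthetic labelled protein sequences with class-dependent group bias.

Negatives are i.i.d. uniform over the 20-letter alphabet; positives put
an extra ``bias`` share of probability mass on a designated residue set
(default: the secondary-structure helix group EALMQKRH), so the two
classes differ in residue-group usage and the CTD feature families can
separate them. The generator targets feature-space separability only —
it makes no attempt to mimic real protein statistics (motifs, domains,
length distributions of actual families).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHABET, ProteinRecord

#: Default biased residue set: the helix group of the secondary-structure
#: property — the anchor membership of the default property-group table.
HELIX_SET = "EALMQKRH"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic two-class sequence generator."""

    n_pos: int = 50
    n_neg: int = 2000
    length_range: tuple[int, int] = (50, 200)
    bias: float = 0.5
    biased_set: str = HELIX_SET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= lo <= hi")
        if not (0.0 <= self.bias <= 1.0):
            raise ValueError("bias must lie in [0, 1]")
        if not self.biased_set or any(c not in ALPHABET for c in self.biased_set):
            raise ValueError("biased_set must be a nonempty subset of the alphabet")


def generate(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], list[ProteinRecord], dict[str, str]]:
    """Draw positive and negative records plus an id -> label table.

    Residue probabilities: negatives uniform 1/20 each; positives
    ``bias/|biased_set| + (1-bias)/20`` for biased residues and
    ``(1-bias)/20`` otherwise. Lengths are uniform over ``length_range``.
    Deterministic per seed (byte-identical output).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range

    uniform = np.full(20, 1.0 / 20)
    biased = uniform * (1.0 - config.bias)
    for c in config.biased_set:
        biased[ALPHABET.index(c)] += config.bias / len(config.biased_set)
    alphabet = np.array(list(ALPHABET))

    def draw(n: int, probs: np.ndarray, prefix: str) -> list[ProteinRecord]:
        records = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=probs))
            records.append(ProteinRecord(id=f"{prefix}{i + 1:05d}", sequence=seq))
        return records

    positives = draw(config.n_pos, biased, "pos")
    negatives = draw(config.n_neg, uniform, "neg")
    labels = {r.id: "1" for r in positives}
    labels.update({r.id: "0" for r in negatives})
    return positives, negatives, labels
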