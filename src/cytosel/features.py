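"""CTD feature extraction for protein sequences.

Four feature families over the 20-letter alphabet and 8 physicochemical
properties, each property partitioning the alphabet into 3 groups:

* **composition** (20D): per-residue frequency n_i / L.
* **content** (24D): per property and group, the fraction of residues in
  that group (8 x 3).
* **transition** (24D): bivalent frequency — per property and unordered
  group pair, the number of adjacent residue pairs whose members fall in
  the two groups (either order), divided by L (8 x 3 pairs).
* **distribution** (120D): per property, group and chain fraction
  q in {first, 25%, 50%, 75%, 100%}, the 1-based position of the k-th
  occurrence of a group residue divided by L, with k = 1 for "first" and
  k = ceil(q * n_g) otherwise (8 x 3 x 5).

The 120D distribution block is the core representation; the full 188D
vector is composition + content + transition + distribution in that order.
All features lie in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .seqio import ALPHABET, ALPHABET_SET, ProteinRecord

#: Chain-fraction labels for the distribution block, in order.
DISTRIBUTION_POINTS = ("first", "p25", "p50", "p75", "p100")
_QUANTILES = (0.25, 0.50, 0.75, 1.00)

#: Valid feature-set names (with CLI-style aliases).
FEATURE_SETS = {
    "composition20": "composition20",
    "content24": "content24",
    "transition24": "transition24",
    "distribution120": "distribution120",
    "full188": "full188",
    "20d": "composition20",
    "24d-content": "content24",
    "24d-transition": "transition24",
    "120d": "distribution120",
    "188d": "full188",
}


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered numeric features for one sequence."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.size:
            raise ValueError("names and values must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        if values.min(initial=0.0) < 0.0 or values.max(initial=0.0) > 1.0:
            raise ValueError("feature values must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _concat(parts: Sequence[FeatureVector]) -> FeatureVector:
    names = tuple(n for p in parts for n in p.names)
    values = np.concatenate([p.values for p in parts])
    return FeatureVector(names, values)


class PropertyGroupTable:
    """3-way partitions of the amino-acid alphabet for 8 properties.

    Property order and group order are fixed by the config file, so
    feature indices are stable across calls. Each property's groups must
    partition the full alphabet.
    """

    def __init__(self, properties: Sequence[tuple[str, Sequence[tuple[str, str]]]]):
        self.properties: list[tuple[str, list[tuple[str, str]]]] = []
        for prop_name, groups in properties:
            groups = [(g, residues.upper()) for g, residues in groups]
            if len(groups) != 3:
                raise ValueError(f"property {prop_name!r} must have exactly 3 groups")
            combined = "".join(res for _, res in groups)
            if len(combined) != len(set(combined)):
                raise ValueError(f"property {prop_name!r}: groups overlap")
            if set(combined) != ALPHABET_SET:
                raise ValueError(
                    f"property {prop_name!r}: groups do not cover the 20-letter alphabet"
                )
            self.properties.append((prop_name, groups))
        # residue -> group index (0/1/2), one lookup row per property
        self._index = {}
        for prop_name, groups in self.properties:
            lut = np.empty(len(ALPHABET), dtype=np.int64)
            for gi, (_, residues) in enumerate(groups):
                for res in residues:
                    lut[ALPHABET.index(res)] = gi
            self._index[prop_name] = lut

    @property
    def property_names(self) -> list[str]:
        return [name for name, _ in self.properties]

    def group_names(self, prop: str) -> list[str]:
        for name, groups in self.properties:
            if name == prop:
                return [g for g, _ in groups]
        raise KeyError(prop)

    def group_indices(self, prop: str, encoded: np.ndarray) -> np.ndarray:
        """Map alphabet-encoded residues (0..19) to group indices 0..2."""
        return self._index[prop][encoded]

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "PropertyGroupTable":
        """Load from YAML; ``None`` loads the packaged default table."""
        if path is None:
            text = (
                resources.files("cytosel").joinpath("data/property_groups.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        props = [
            (entry["name"], list(entry["groups"].items()))
            for entry in raw["properties"]
        ]
        return cls(props)

    @classmethod
    def default(cls) -> "PropertyGroupTable":
        return cls.from_yaml(None)


_ENCODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i


def _encode(record: ProteinRecord | str) -> np.ndarray:
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if not seq:
        raise ValueError("empty sequence")
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)})
        raise ValueError(f"sequence contains non-standard residue(s) {bad!r}")
    return codes


def composition(record: ProteinRecord | str) -> FeatureVector:
    """20D amino-acid frequencies n_i / L, in fixed alphabet order."""
    codes = _encode(record)
    counts = np.bincount(codes, minlength=20)
    names = tuple(f"comp_{aa}" for aa in ALPHABET)
    return FeatureVector(names, counts / codes.size)


def content(record: ProteinRecord | str, table: PropertyGroupTable) -> FeatureVector:
    """24D group-content fractions: per property, the share of residues in
    each of its 3 groups (the triple sums to 1)."""
    codes = _encode(record)
    names: list[str] = []
    values: list[float] = []
    for prop, groups in table.properties:
        gidx = table.group_indices(prop, codes)
        counts = np.bincount(gidx, minlength=3)
        for (gname, _), c in zip(groups, counts):
            names.append(f"cont_{prop}_{gname}")
            values.append(c / codes.size)
    return FeatureVector(tuple(names), np.array(values))


def transition(record: ProteinRecord | str, table: PropertyGroupTable) -> FeatureVector:
    """24D bivalent frequencies: per property and unordered group pair, the
    count of adjacent residue pairs crossing the two groups, divided by L.

    A single-residue sequence has no adjacent pairs; all values are 0 then.
    """
    codes = _encode(record)
    length = codes.size
    if length == 1:
        warnings.warn("single-residue sequence has no adjacent pairs; "
                      "all transition features are 0", stacklevel=2)
    names: list[str] = []
    values: list[float] = []
    for prop, groups in table.properties:
        gidx = table.group_indices(prop, codes)
        left, right = gidx[:-1], gidx[1:]
        for a, b in ((0, 1), (0, 2), (1, 2)):
            count = int(np.sum(((left == a) & (right == b)) | ((left == b) & (right == a))))
            names.append(f"trans_{prop}_{groups[a][0]}_{groups[b][0]}")
            values.append(count / length)
    return FeatureVector(tuple(names), np.array(values))


def distribution(record: ProteinRecord | str, table: PropertyGroupTable) -> FeatureVector:
    """120D distribution features: normalized chain positions of the first,
    25%, 50%, 75% and 100% occurrences of each property group.

    For a group with n_g occurrences at 1-based positions p_1 < ... < p_{n_g},
    the five values are p_1/L and p_k/L with k = ceil(q * n_g) for
    q in {0.25, 0.5, 0.75, 1.0}. A group absent from the sequence
    contributes five zeros.
    """
    codes = _encode(record)
    length = codes.size
    names: list[str] = []
    values: list[float] = []
    for prop, groups in table.properties:
        gidx = table.group_indices(prop, codes)
        for gi, (gname, _) in enumerate(groups):
            positions = np.flatnonzero(gidx == gi) + 1  # 1-based
            n_g = positions.size
            if n_g == 0:
                block = [0.0] * 5
            else:
                ks = [1] + [math.ceil(q * n_g) for q in _QUANTILES]
                block = [positions[k - 1] / length for k in ks]
            for point, val in zip(DISTRIBUTION_POINTS, block):
                names.append(f"dist_{prop}_{gname}_{point}")
                values.append(val)
    return FeatureVector(tuple(names), np.array(values))


def full_188(record: ProteinRecord | str, table: PropertyGroupTable) -> FeatureVector:
    """188D vector: composition (20) + content (24) + transition (24) +
    distribution (120), in that order."""
    return _concat(
        [
            composition(record),
            content(record, table),
            transition(record, table),
            distribution(record, table),
        ]
    )


def extract(
    records: Iterable[ProteinRecord],
    table: PropertyGroupTable | None = None,
    feature_set: str = "distribution120",
) -> pd.DataFrame:
    """Feature matrix for a batch of records: one row per record, indexed by
    record id, with stable feature-name columns.

    ``feature_set`` is one of composition20, content24, transition24,
    distribution120, full188 (or the aliases 20d, 24d-content,
    24d-transition, 120d, 188d).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature_set {feature_set!r}; choose from {sorted(set(FEATURE_SETS.values()))}"
        )
    canonical = FEATURE_SETS[feature_set]
    if table is None:
        table = PropertyGroupTable.default()

    def one(rec: ProteinRecord) -> FeatureVector:
        if canonical == "composition20":
            return composition(rec)
        if canonical == "content24":
            return content(rec, table)
        if canonical == "transition24":
            return transition(rec, table)
        if canonical == "distribution120":
            return distribution(rec, table)
        return full_188(rec, table)

    records = list(records)
    if not records:
        raise ValueError("no records to extract features from")
    vectors = [one(r) for r in records]
    frame = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        index=pd.Index([r.id for r in records], name="id"),
        columns=list(vectors[0].names),
    )
    return frame
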