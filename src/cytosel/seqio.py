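"""Protein FASTA I/O, sequence validation, and dataset-curation rules.

Sequences are strings over the 20-letter amino-acid alphabet. Curation
follows the longest-per-family selection used to build non-redundant
negative sets: one representative (the longest sequence) per protein
family, with families belonging to the positive class excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The canonical 20-letter amino-acid alphabet, in fixed (alphabetical) order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence ``S = R_1 R_2 ... R_L``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        """Number of residues L."""
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyAnnotation:
    """Maps a record id to its protein-family id."""

    record_id: str
    family_id: str


def _clean_sequence(record_id: str, raw: str, strict: bool) -> str:
    seq = "".join(raw.split()).upper()
    bad = [c for c in seq if c not in ALPHABET_SET]
    if bad:
        if strict:
            raise ValueError(
                f"record {record_id!r} contains non-standard residue(s) "
                f"{sorted(set(bad))!r}; use strict=False to drop them"
            )
        warnings.warn(
            f"record {record_id!r}: dropped {len(bad)} non-standard residue(s) "
            f"{sorted(set(bad))!r}",
            stacklevel=3,
        )
        seq = "".join(c for c in seq if c in ALPHABET_SET)
    return seq


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    The header token before the first whitespace becomes the record id and
    sequences are upper-cased. In strict mode any character outside the
    20-letter alphabet raises; in lenient mode it is dropped with a warning
    (the length L shrinks accordingly).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(entry.id, str(entry.seq), strict)
        if not seq:
            raise ValueError(f"record {entry.id!r} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as plain FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (``id<TAB>value``) into an ordered dict.

    Lines starting with ``#`` are comments; a first line whose id column is
    a recognised header word (``id``, ``record_id``, ``name``) is skipped.
    """
    mapping: dict[str, str] = {}
    first = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            key, value = parts[0].strip(), parts[1].strip()
            if first and key.lower() in {"id", "record_id", "name"}:
                first = False
                continue
            first = False
            if key in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id {key!r}")
            mapping[key] = value
    return mapping


def write_table(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}\t{value}\n")


def select_longest_per_family(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, str],
    excluded_families: Iterable[str] = (),
) -> list[ProteinRecord]:
    """Pick one representative per protein family: the longest member.

    ``annotations`` maps record id -> family id; families listed in
    ``excluded_families`` contribute nothing (this is how negative
    candidates drawn from positive families are rejected). Length ties are
    broken by lexicographically smallest id, so the selection is
    deterministic regardless of input order. Output preserves the order in
    which families first appear in ``records``.
    """
    excluded = set(excluded_families)
    missing = [r.id for r in records if r.id not in annotations]
    if missing:
        raise ValueError(f"records without family annotation: {missing}")

    best: dict[str, ProteinRecord] = {}
    family_order: list[str] = []
    for rec in records:
        family = annotations[rec.id]
        if family in excluded:
            continue
        if family not in best:
            best[family] = rec
            family_order.append(family)
        else:
            cur = best[family]
            if (-rec.length, rec.id) < (-cur.length, cur.id):
                best[family] = rec
    return [best[f] for f in family_order]
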