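"""Sequence data model and FASTA I/O.

Records are grouped by role — ``ingroup`` (the target taxon, e.g. *Ephedra*
ITS2 sequences), ``outgroup`` (non-target comparison sequences) or ``query``
(sequences to be screened for a signature). Residues are normalized on
ingest: uppercase, RNA ``U`` mapped to ``T``, alignment gaps (``-``/``.``)
stripped; only the 15 IUPAC nucleotide symbols are accepted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import normalize, reverse_complement  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "SequenceRecord",
    "SequenceSet",
    "FastaParseError",
    "DuplicateIdError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]


class Group(str, Enum):
    INGROUP = "ingroup"
    OUTGROUP = "outgroup"
    QUERY = "query"


class FastaParseError(ValueError):
    pass


class DuplicateIdError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled nucleotide sequence.

    ``residues`` must already be normalized IUPAC (use
    :func:`nucsig.alphabet.normalize` for raw input); construction validates.
    """

    id: str
    residues: str
    group: Group = Group.QUERY
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(
            self, "residues", normalize(self.residues, context=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, residues=reverse_complement(self.residues))


@dataclass
class SequenceSet:
    """An ordered, role-homogeneous collection of records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    group: Group = Group.QUERY

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        seen: set[str] = set()
        for rec in self.records:
            if rec.group != self.group:
                raise ValueError(
                    f"record {rec.id!r} has group {rec.group.value!r}, "
                    f"set is {self.group.value!r}"
                )
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        group: Union[Group, str] = Group.QUERY,
        prefix: str = "seq",
    ) -> "SequenceSet":
        group = Group(group)
        recs = [
            SequenceRecord(id=f"{prefix}{i + 1}", residues=s, group=group)
            for i, s in enumerate(sequences)
        ]
        return cls(records=recs, group=group)


def _open_text(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path], group: Union[Group, str] = Group.QUERY) -> SequenceSet:
    """Read a (plain or gzipped) FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes the record id, the
    remainder the taxon. Residues are normalized on ingest. Errors: sequence
    data before the first header (parse error naming the line), duplicate
    ids, non-IUPAC symbols. An empty file yields an empty set with a warning.
    """
    path = Path(path)
    group = Group(group)
    with _open_text(path) as fh:
        # SimpleFastaParser silently skips leading junk; report it instead.
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    records = []
    from io import StringIO

    with StringIO("\n".join(lines)) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FastaParseError(f"{path}: empty FASTA header")
            rec_id = parts[0]
            taxon = parts[1].strip() if len(parts) > 1 else ""
            records.append(
                SequenceRecord(id=rec_id, residues=seq, group=group, taxon=taxon)
            )
    if not records:
        logger.warning("%s: no FASTA records found; returning an empty set", path)
    return SequenceSet(records=records, group=group)


def write_fasta(seq_set: SequenceSet, path: Union[str, Path]) -> Path:
    """Write a set as standard FASTA (60-column wrapping, header ``id taxon``)."""
    path = Path(path)
    bio_records = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.taxon)
        for r in seq_set
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(bio_records, fh, "fasta")
    return path
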