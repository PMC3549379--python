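"""Sequence and annotation I/O plus the core record types.

Coordinates are 0-based, half-open ``[start, start + L)`` everywhere inside
the package; 1-based positions appear only in human-readable messages and
reports.  Only the plain A/C/G/T alphabet is accepted: the scoring matrix
defines no scores for ambiguity codes, and resolving them silently would
shift every calibrated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One promoter-region sequence: an id and its A/C/G/T residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        for pos, base in enumerate(residues):
            if base not in _VALID:
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {base!r} "
                    f"at position {pos + 1}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def windows(self, length: int) -> list[str]:
        """All length-``length`` subsequences, one per start offset."""
        n = len(self.residues)
        if length < 1 or length > n:
            raise ValueError(
                f"sequence {self.id!r}: window length {length} "
                f"outside [1, {n}]"
            )
        return [self.residues[i : i + length] for i in range(n - length + 1)]


@dataclass(frozen=True)
class PromoterSet:
    """Ordered set of homologous promoter sequences."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if len(records) < 2:
            raise ValueError("a promoter set needs at least 2 sequences")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        object.__setattr__(self, "records", records)

    @property
    def k(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def by_id(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(f"unknown sequence id {seq_id!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """Ground-truth site location: sequence id, 0-based start, length."""

    seq_id: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"annotation for {self.seq_id!r}: start {self.start} < 0"
            )
        if self.length < 1:
            raise ValueError("site length must be >= 1")


def read_fasta(path: str | Path) -> PromoterSet:
    """Read a FASTA file into a :class:`PromoterSet`.

    Entry order is preserved and residues are uppercased; lowercase letters
    in inputs are treated purely as case markup.  Empty files, duplicate ids
    and non-ACGT residues are rejected with a message naming the offender.
    """
    path = Path(path)
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return PromoterSet(tuple(records))


def write_fasta(promoters: PromoterSet, path: str | Path) -> None:
    bio = [
        SeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in promoters.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_annotations(
    path: str | Path,
    length: int,
    promoters: PromoterSet | None = None,
) -> list[SiteAnnotation]:
    """Read a 2+ column TSV (id, 0-based start) of true site locations.

    When ``promoters`` is supplied each start is checked against the window
    range ``[0, N - length]`` of its sequence; ids absent from the set are an
    error at that point.
    """
    annots: list[SiteAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected id<TAB>start")
        seq_id, start = fields[0], int(fields[1])
        ann = SiteAnnotation(seq_id=seq_id, start=start, length=length)
        if promoters is not None:
            rec = promoters.by_id(seq_id)
            hi = len(rec) - length
            if not 0 <= ann.start <= hi:
                raise ValueError(
                    f"annotation for {seq_id!r}: start {start} "
                    f"outside [0, {hi}]"
                )
        annots.append(ann)
    return annots


def write_annotations(annots: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annots:
            fh.write(f"{ann.seq_id}\t{ann.start}\n")
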