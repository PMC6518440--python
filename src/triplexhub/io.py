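"""Sequence and interval I/O with one coordinate convention throughout.

All genomic intervals are 0-based half-open (BED convention).  DNA records
always denote the forward strand of a duplex; the reverse strand is derived
on demand and never stored.  Ambiguous bases are rejected by default,
mirroring the removal of peaks containing N from the analysis; with
``mask_ambiguous=True`` they are replaced by :data:`MASK_CHAR`, a character
that can never satisfy any Hoogsteen pairing rule.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MASK_CHAR",
    "NucleicSequence",
    "GenomicRegion",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "extract_region_sequence",
    "reverse_complement",
]

#: Placeholder for hard-masked ambiguous bases; never pairs with anything.
MASK_CHAR = "X"

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGT" + MASK_CHAR, "TGCA" + MASK_CHAR)

Kind = Literal["DNA", "RNA"]


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


class BedParseError(ValueError):
    """Malformed BED input."""


@dataclass(frozen=True)
class NucleicSequence:
    """A validated single-stranded nucleic acid sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    residues : str
        Upper-case residues over {A,C,G,T} (DNA) or {A,C,G,U} (RNA),
        plus :data:`MASK_CHAR` for hard-masked positions.
    kind : {"DNA", "RNA"}
        DNA sequences represent the forward strand of a duplex.
    """

    id: str
    residues: str
    kind: Kind

    def __post_init__(self) -> None:
        if self.kind not in ("DNA", "RNA"):
            raise SequenceValidationError(f"unknown sequence kind {self.kind!r}")
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r} is empty")
        alphabet = _DNA_ALPHABET if self.kind == "DNA" else _RNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet and ch != MASK_CHAR:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: disallowed character {ch!r} "
                    f"at position {pos} for kind {self.kind}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleicSequence":
        if self.kind != "DNA":
            raise SequenceValidationError("reverse_complement is defined for DNA only")
        rc = self.residues.translate(_DNA_COMPLEMENT)[::-1]
        return NucleicSequence(id=self.id, residues=rc, kind="DNA")


def reverse_complement(residues: str) -> str:
    """Reverse complement of a forward-strand DNA string (mask-aware)."""
    return residues.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval; length = end - start."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise BedParseError(f"region start {self.start} < 0")
        if self.end <= self.start:
            raise BedParseError(
                f"region {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


def _normalize_residues(raw: str, kind: Kind, record_id: str, mask_ambiguous: bool) -> str:
    seq = raw.upper()
    # T<->U normalisation to the declared kind.
    seq = seq.replace("U", "T") if kind == "DNA" else seq.replace("T", "U")
    alphabet = _DNA_ALPHABET if kind == "DNA" else _RNA_ALPHABET
    bad = [i for i, ch in enumerate(seq) if ch not in alphabet]
    if bad:
        if not mask_ambiguous:
            raise SequenceValidationError(
                f"sequence {record_id!r}: disallowed character {seq[bad[0]]!r} "
                f"at position {bad[0]} (strict ambiguity policy; "
                f"use mask_ambiguous=True to hard-mask)"
            )
        chars = list(seq)
        for i in bad:
            chars[i] = MASK_CHAR
        seq = "".join(chars)
    return seq


def read_fasta(path: str | Path, kind: Kind, mask_ambiguous: bool = False) -> list[NucleicSequence]:
    """Read a FASTA file into validated :class:`NucleicSequence` records.

    Residues are case-folded to upper; T/U are normalised to the declared
    kind.  Ambiguous characters raise :class:`SequenceValidationError`
    (strict default) or are hard-masked.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, line in enumerate(text.splitlines()) if line.strip()
        )
        raise FastaParseError(f"{path}: line {first_bad}: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        residues = _normalize_residues(str(rec.seq), kind, rec.id, mask_ambiguous)
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(NucleicSequence(id=rec.id, residues=residues, kind=kind))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: Iterable[NucleicSequence], width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED (>=3 tab-separated columns) as 0-based half-open regions.

    Column 4, when present, is retained as the region name; further
    columns are ignored.  Track/browser/comment lines are skipped.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            try:
                regions.append(GenomicRegion(chrom=chrom, start=start, end=end, name=name))
            except BedParseError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def write_bed(path: str | Path, regions: Iterable[GenomicRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def extract_region_sequence(
    genome: list[NucleicSequence] | dict[str, NucleicSequence],
    region: GenomicRegion,
) -> NucleicSequence:
    """Forward-strand subsequence of ``region`` from a genome record set."""
    if not isinstance(genome, dict):
        genome = {s.id: s for s in genome}
    try:
        chrom_seq = genome[region.chrom]
    except KeyError:
        raise LookupError(f"chromosome {region.chrom!r} not present in genome") from None
    if region.end > len(chrom_seq):
        raise LookupError(
            f"region {region.chrom}:{region.start}-{region.end} extends beyond "
            f"chromosome length {len(chrom_seq)}"
        )
    return NucleicSequence(
        id=region.label,
        residues=chrom_seq.residues[region.start : region.end],
        kind=chrom_seq.kind,
    )
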