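"""Strand-aware purine composition of DNA regions.

Triplexes engage only the purines of the duplex, so unlike GC content the
relevant composition measure is strand-specific: if one strand is purine
rich the other is automatically purine poor.  Two region-level measures are
provided:

* **GA content** — the maximum over both strands of the purine (G/A)
  fraction; by construction always >= 50% on clean sequence.
* **Poly-purine content** — per strand, the summed length of maximal purine
  runs of at least ``min_run`` (default 10) divided by the region length;
  the reported value is the maximum over strands and ranges over the full
  0-100%.

Runs on the reverse strand correspond to C/T stretches of the forward
string and are reported in forward-strand coordinates.  Masked characters
count as non-purines on both strands and break runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import NucleicSequence

__all__ = [
    "PurineRun",
    "CompositionProfile",
    "strand_purine_fraction",
    "ga_content",
    "purine_runs",
    "polypurine_content",
    "composition_profile",
]

_PLUS_RUN = re.compile(r"[GA]+")
_MINUS_RUN = re.compile(r"[CT]+")   # C/T forward = G/A on the reverse strand


@dataclass(frozen=True)
class PurineRun:
    """Maximal purine run on one strand, in forward 0-based half-open coords."""

    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CompositionProfile:
    """Purine composition summary of one DNA region."""

    ga_content: float
    ga_strand: str
    polypurine_content: float
    polyga_strand: str
    runs: tuple[PurineRun, ...]
    gc_content: float


def _check_dna(dna: NucleicSequence) -> None:
    if dna.kind != "DNA":
        raise ValueError("composition measures are defined for DNA")
    if len(dna) == 0:
        raise ValueError("sequence must be non-empty")


def strand_purine_fraction(dna: NucleicSequence, strand: str) -> float:
    """Percentage of G/A on one strand of the duplex.

    The reverse strand is evaluated on the reverse complement, i.e. its
    purines sit where the forward string has C/T.
    """
    _check_dna(dna)
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    s = dna.residues
    n_pur = (s.count("G") + s.count("A")) if strand == "+" else \
        (s.count("C") + s.count("T"))
    return 100.0 * n_pur / len(s)


def ga_content(dna: NucleicSequence) -> float:
    """Maximum purine percentage over the two strands (>= 50% on clean DNA)."""
    return max(strand_purine_fraction(dna, "+"),
               strand_purine_fraction(dna, "-"))


def purine_runs(dna: NucleicSequence, min_run: int = 10) -> list[PurineRun]:
    """All maximal purine runs of length >= min_run on either strand."""
    _check_dna(dna)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    runs = []
    for strand, pattern in (("+", _PLUS_RUN), ("-", _MINUS_RUN)):
        for m in pattern.finditer(dna.residues):
            if m.end() - m.start() >= min_run:
                runs.append(PurineRun(strand=strand, start=m.start(), end=m.end()))
    runs.sort(key=lambda r: (r.start, r.strand))
    return runs


def polypurine_content(dna: NucleicSequence, min_run: int = 10) -> float:
    """Max over strands of the summed run lengths >= min_run, as a percentage."""
    runs = purine_runs(dna, min_run=min_run)
    per_strand = {"+": 0, "-": 0}
    for r in runs:
        per_strand[r.strand] += r.length
    return 100.0 * max(per_strand.values()) / len(dna)


def composition_profile(dna: NucleicSequence, min_run: int = 10) -> CompositionProfile:
    """Full composition summary (argmax strands resolved '+' first on ties)."""
    plus = strand_purine_fraction(dna, "+")
    minus = strand_purine_fraction(dna, "-")
    runs = purine_runs(dna, min_run=min_run)
    per_strand = {"+": 0, "-": 0}
    for r in runs:
        per_strand[r.strand] += r.length
    polyga_strand = "+" if per_strand["+"] >= per_strand["-"] else "-"
    gc = 100.0 * (dna.residues.count("G") + dna.residues.count("C")) / len(dna)
    return CompositionProfile(
        ga_content=max(plus, minus),
        ga_strand="+" if plus >= minus else "-",
        polypurine_content=100.0 * per_strand[polyga_strand] / len(dna),
        polyga_strand=polyga_strand,
        runs=tuple(runs),
        gc_content=gc,
    )
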