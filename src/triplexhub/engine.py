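"""Enumeration and counting of RNA-DNA triplex windows under Hoogsteen rules.

A triplex window is a same-length pairing of an RNA interval (the
triplex-forming-oligonucleotide side) with a DNA interval whose purine-rich
strand accommodates the third strand in the duplex major groove.  Three
canonical motif families are supported, each validated window-wide (motifs
are never mixed within one window):

========  ===================  =========================
motif     orientations         valid RNA.DNA-purine triples
========  ===================  =========================
TC        parallel only        C.G, U.A
GA        antiparallel only    G.G, A.A
GT        both                 G.G, U.A
========  ===================  =========================

Equivalently: DNA guanine binds RNA guanine in both orientations, DNA
adenine binds RNA uracil in both orientations, DNA guanine binds RNA
cytosine in the parallel orientation only, and the A.A pairing occurs in
the antiparallel orientation only.

Counting follows the overlap-allowed "Total (abs)" semantics: every
distinct (RNA interval, DNA interval, strand, orientation) of length >=
``min_length`` with at most ``floor(max_error_rate/100 * length)``
rule-violating positions is counted, including all sub-windows of a longer
perfect window.  A single 11-nt perfect alignment at ``min_length=10``
therefore contributes 3 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from ._kernels import _scan_pair
from .io import MASK_CHAR, NucleicSequence, reverse_complement

__all__ = [
    "EngineParams",
    "TriplexWindow",
    "pairing_valid",
    "enumerate_triplexes",
    "count_triplexes",
]

Orientation = Literal["parallel", "antiparallel"]
Motif = Literal["TC", "GA", "GT"]

_MOTIFS: tuple[Motif, ...] = ("TC", "GA", "GT")
_ORIENTATIONS: tuple[Orientation, ...] = ("parallel", "antiparallel")

# Base codes: A=0, C=1, G=2, T/U=3, mask=4 (never pairs).
_CODE = np.full(256, 4, dtype=np.uint8)
for _ch, _c in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("U", 3)):
    _CODE[ord(_ch)] = _c

# Valid (rna_code, purine_strand_code) pairs per (motif, orientation).
_RULES: dict[tuple[Motif, Orientation], frozenset[tuple[str, str]]] = {
    ("TC", "parallel"): frozenset({("C", "G"), ("U", "A")}),
    ("GA", "antiparallel"): frozenset({("G", "G"), ("A", "A")}),
    ("GT", "parallel"): frozenset({("G", "G"), ("U", "A")}),
    ("GT", "antiparallel"): frozenset({("G", "G"), ("U", "A")}),
}


def _rule_table(motif: Motif, orientation: Orientation) -> np.ndarray:
    table = np.zeros((5, 5), dtype=np.bool_)
    for rna_ch, dna_ch in _RULES.get((motif, orientation), ()):
        table[_CODE[ord(rna_ch)], _CODE[ord(dna_ch)]] = True
    return table


_TABLES = {key: _rule_table(*key) for key in
           [(m, o) for m in _MOTIFS for o in _ORIENTATIONS]}


def pairing_valid(rna_base: str, dna_purine_base: str,
                  orientation: Orientation, motif: Motif) -> bool:
    """Whether one Hoogsteen triple is valid.

    ``dna_purine_base`` is the base on the purine-tract strand of the
    duplex (A or G); pyrimidines on that strand never accept a third
    strand.  Total function: invalid combinations return False.
    """
    rna_base = rna_base.upper()
    dna_purine_base = dna_purine_base.upper()
    return (rna_base, dna_purine_base) in _RULES.get((motif, orientation), frozenset())


@dataclass(frozen=True)
class EngineParams:
    """Search thresholds for triplex window enumeration.

    ``min_length`` and ``max_error_rate`` mirror the canonical
    Triplexator-style ``-l 10 -e 10`` settings.  ``max_consecutive_errors``
    and ``min_guanine_rate`` are additional constraints of the original
    tool family and default to off.
    """

    min_length: int = 10
    max_error_rate: float = 10.0
    motifs: tuple[Motif, ...] = _MOTIFS
    orientations: tuple[Orientation, ...] = _ORIENTATIONS
    require_terminal_match: bool = True
    scan_both_dna_strands: bool = True
    max_consecutive_errors: int | None = None
    min_guanine_rate: float | None = None

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if not (0 <= self.max_error_rate < 100):
            raise ValueError("max_error_rate must be in [0, 100)")
        bad = set(self.motifs) - set(_MOTIFS)
        if bad or not self.motifs:
            raise ValueError(f"motifs must be a non-empty subset of {_MOTIFS}")
        bad = set(self.orientations) - set(_ORIENTATIONS)
        if bad or not self.orientations:
            raise ValueError(
                f"orientations must be a non-empty subset of {_ORIENTATIONS}")


@dataclass(frozen=True, order=True)
class TriplexWindow:
    """One qualifying RNA-window/DNA-window pairing.

    Coordinates are 0-based half-open; DNA coordinates always refer to the
    forward strand, ``dna_strand`` says which strand carries the purine
    tract.  ``motifs`` lists every motif family that validates the window;
    ``n_errors`` is the minimum mismatch count over those motifs.
    """

    rna_start: int
    rna_end: int
    dna_start: int
    dna_end: int
    dna_strand: str
    orientation: str
    motifs: tuple[str, ...] = field(compare=False)
    n_errors: int = field(compare=False)

    @property
    def length(self) -> int:
        return self.rna_end - self.rna_start


def _encode(residues: str) -> np.ndarray:
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _check_inputs(rna: NucleicSequence, dna: NucleicSequence) -> None:
    if not isinstance(rna, NucleicSequence) or not isinstance(dna, NucleicSequence):
        raise TypeError("rna and dna must be NucleicSequence instances")
    if rna.kind != "RNA":
        raise TypeError(f"first argument must be RNA, got kind={rna.kind}")
    if dna.kind != "DNA":
        raise TypeError(f"second argument must be DNA, got kind={dna.kind}")
    if len(rna) == 0 or len(dna) == 0:
        raise ValueError("sequences must be non-empty")


def _window_passes_extras(rna: str, purine: str, motif: Motif,
                          orientation: Orientation,
                          params: EngineParams) -> bool:
    """Optional post-filters (consecutive errors, guanine rate)."""
    if params.min_guanine_rate is not None:
        g_rate = 100.0 * rna.count("G") / len(rna)
        if g_rate < params.min_guanine_rate - 1e-9:
            return False
    if params.max_consecutive_errors is not None:
        aligned = purine if orientation == "parallel" else purine[::-1]
        run = longest = 0
        for rb, db in zip(rna, aligned):
            if pairing_valid(rb, db, orientation, motif):
                run = 0
            else:
                run += 1
                longest = max(longest, run)
        if longest > params.max_consecutive_errors:
            return False
    return True


def enumerate_triplexes(rna: NucleicSequence, dna: NucleicSequence,
                        params: EngineParams | None = None) -> list[TriplexWindow]:
    """All qualifying triplex windows between one RNA and one DNA duplex.

    Windows found by several motifs are reported once with all validating
    motifs recorded.  No low-complexity masking is applied.  Output is
    sorted and deterministic.
    """
    params = params or EngineParams()
    _check_inputs(rna, dna)

    R = _encode(rna.residues)
    dna_len = len(dna)
    strands = [("+", _encode(dna.residues))]
    if params.scan_both_dna_strands:
        strands.append(("-", _encode(reverse_complement(dna.residues))))

    extras = (params.max_consecutive_errors is not None
              or params.min_guanine_rate is not None)

    # (rna_iv, dna_iv, strand, orientation) -> [motifs, min errors]
    found: dict[tuple, list] = {}
    for strand, P in strands:
        for orientation in params.orientations:
            anti = orientation == "antiparallel"
            for motif in params.motifs:
                if (motif, orientation) not in _RULES:
                    continue
                flat = _scan_pair(R, P, _TABLES[(motif, orientation)], anti,
                                  params.min_length,
                                  float(params.max_error_rate),
                                  params.require_terminal_match)
                for w in range(0, len(flat), 4):
                    rs, ps, L, ne = flat[w], flat[w + 1], flat[w + 2], flat[w + 3]
                    if strand == "+":
                        ds, de = ps, ps + L
                    else:
                        ds, de = dna_len - ps - L, dna_len - ps
                    if extras:
                        p_seq = dna.residues[ds:de] if strand == "+" else \
                            reverse_complement(dna.residues[ds:de])
                        if not _window_passes_extras(
                                rna.residues[rs:rs + L], p_seq, motif,
                                orientation, params):
                            continue
                    key = (rs, rs + L, ds, de, strand, orientation)
                    entry = found.get(key)
                    if entry is None:
                        found[key] = [{motif}, ne]
                    else:
                        entry[0].add(motif)
                        if ne < entry[1]:
                            entry[1] = ne
    windows = [
        TriplexWindow(rna_start=k[0], rna_end=k[1], dna_start=k[2],
                      dna_end=k[3], dna_strand=k[4], orientation=k[5],
                      motifs=tuple(sorted(v[0])), n_errors=v[1])
        for k, v in found.items()
    ]
    windows.sort()
    return windows


def count_triplexes(rna: NucleicSequence, dna: NucleicSequence,
                    params: EngineParams | None = None) -> int:
    """N_tpx: cardinality of the deduplicated qualifying-window set."""
    return len(enumerate_triplexes(rna, dna, params))
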