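"""Independent brute-force oracles for triplex window enumeration.

Two implementations, both testing every (RNA interval, DNA interval,
strand, orientation, motif) combination directly against the pairing rule
table, sharing no code with the engine's diagonal run-scanning:

* :func:`naive_windows` — plain nested loops; transparent but slow.
* :func:`exhaustive_windows` — the same exhaustive window test vectorised
  with per-length prefix-sum matrices, fast enough for thousands of pairs.
"""

from __future__ import annotations

import math

import numpy as np

from triplexhub.engine import EngineParams, pairing_valid
from triplexhub.io import reverse_complement

_CODE = {ch: i for i, ch in enumerate("ACG")} | {"T": 3, "U": 3}

_RULE_COMBOS = [
    ("TC", "parallel"),
    ("GT", "parallel"),
    ("GA", "antiparallel"),
    ("GT", "antiparallel"),
]


def _allowed(err_rate: float, L: int) -> int:
    return math.floor(err_rate * L / 100 + 1e-9)


def naive_windows(rna: str, dna: str, params: EngineParams) -> dict:
    """{(rs, re, ds, de, strand, orientation): set of motifs} by full loops."""
    n, p = len(rna), len(dna)
    strands = [("+", dna)]
    if params.scan_both_dna_strands:
        strands.append(("-", reverse_complement(dna)))
    found: dict[tuple, set] = {}
    for strand, P in strands:
        for motif, orientation in _RULE_COMBOS:
            if motif not in params.motifs or orientation not in params.orientations:
                continue
            for L in range(params.min_length, min(n, p) + 1):
                allowed = _allowed(params.max_error_rate, L)
                for a in range(n - L + 1):
                    for b in range(p - L + 1):
                        errs = 0
                        ends_ok = True
                        for k in range(L):
                            db = P[b + k] if orientation == "parallel" \
                                else P[b + L - 1 - k]
                            if not pairing_valid(rna[a + k], db, orientation, motif):
                                errs += 1
                                if k in (0, L - 1):
                                    ends_ok = False
                        if errs > allowed:
                            continue
                        if params.require_terminal_match and not ends_ok:
                            continue
                        ds, de = (b, b + L) if strand == "+" else (p - b - L, p - b)
                        found.setdefault(
                            (a, a + L, ds, de, strand, orientation),
                            set()).add(motif)
    return found


def _code(seq: str) -> np.ndarray:
    return np.array([_CODE.get(ch, 4) for ch in seq], dtype=np.int64)


def _valid_table(motif: str, orientation: str) -> np.ndarray:
    table = np.zeros((5, 5), dtype=bool)
    for rb in "ACGU":
        for db in "AG":
            if pairing_valid(rb, db, orientation, motif):
                table[_CODE[rb], _CODE[db]] = True
    return table


def exhaustive_windows(rna: str, dna: str, params: EngineParams) -> dict:
    """Same exhaustive per-window test, vectorised per window length."""
    n, p = len(rna), len(dna)
    R = _code(rna)
    strands = [("+", dna)]
    if params.scan_both_dna_strands:
        strands.append(("-", reverse_complement(dna)))
    found: dict[tuple, set] = {}
    for strand, Pstr in strands:
        Pa = _code(Pstr)
        for motif, orientation in _RULE_COMBOS:
            if motif not in params.motifs or orientation not in params.orientations:
                continue
            table = _valid_table(motif, orientation)
            if orientation == "parallel":
                mism = ~table[R[:, None], Pa[None, :]]
            else:
                # reverse the purine strand: window (a, b, L) antiparallel on
                # Pa equals window (a, p - b - L, L) parallel on Pa reversed
                mism = ~table[R[:, None], Pa[::-1][None, :]]
            D = np.zeros((n + 1, p + 1), dtype=np.int64)
            for i in range(n):
                D[i + 1, 1:] = D[i, :-1] + mism[i, :]
            for L in range(params.min_length, min(n, p) + 1):
                allowed = _allowed(params.max_error_rate, L)
                errs = D[L:, L:] - D[:n - L + 1, :p - L + 1]
                ok = errs <= allowed
                if params.require_terminal_match:
                    ok &= ~mism[:n - L + 1, :p - L + 1]
                    ok &= ~mism[L - 1:, L - 1:]
                for a, q in np.argwhere(ok):
                    b = q if orientation == "parallel" else p - q - L
                    ds, de = (b, b + L) if strand == "+" else (p - b - L, p - b)
                    found.setdefault(
                        (int(a), int(a) + L, int(ds), int(de), strand, orientation),
                        set()).add(motif)
    return found


def windows_as_dict(windows) -> dict:
    """Engine output in the oracle's comparison form."""
    return {
        (w.rna_start, w.rna_end, w.dna_start, w.dna_end, w.dna_strand,
         w.orientation): set(w.motifs)
        for w in windows
    }
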