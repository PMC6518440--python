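"""Exact dinucleotide-preserving shuffling of transcripts.

Control RNAs for the significance contrasts must hold sequence composition
fixed: the shuffled sequence keeps the exact 16-entry dinucleotide count
vector (hence also mononucleotide counts and terminal residues) of the
original.  This is the Altschul-Erickson scheme: the sequence is a walk on
the dinucleotide transition multigraph, and a uniform random Eulerian path
with the same start/end vertices is sampled by drawing a random "last-edge"
in-tree toward the terminal vertex and permuting the remaining out-edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import NucleicSequence

__all__ = ["ShuffleResult", "dinucleotide_shuffle", "dinucleotide_counts"]


@dataclass(frozen=True)
class ShuffleResult:
    original_id: str
    shuffled: NucleicSequence
    seed: int


def dinucleotide_counts(residues: str) -> Counter:
    """The 16-entry (fewer if alphabet smaller) dinucleotide count vector."""
    return Counter(residues[i:i + 2] for i in range(len(residues) - 1))


def dinucleotide_shuffle(seq: NucleicSequence, seed: int) -> ShuffleResult:
    """Uniform random sequence with the exact dinucleotide counts of ``seq``.

    Deterministic given ``seed``; the first and last residue are invariant.
    Sequences whose dinucleotide counts admit a single arrangement (e.g.
    homopolymers, "GAGAGA") are returned unchanged.
    """
    s = seq.residues
    if len(s) < 2:
        raise ValueError("dinucleotide shuffling needs length >= 2")
    rng = np.random.default_rng(seed)

    # Out-edge multiset per vertex.
    edges: dict[str, list[str]] = {}
    for i in range(len(s) - 1):
        edges.setdefault(s[i], []).append(s[i + 1])
    start, end = s[0], s[-1]
    vertices = sorted(edges)

    # Draw a random last-edge per non-terminal vertex until the last edges
    # form an in-tree toward `end` (Altschul-Erickson condition).  With at
    # most 4 vertices this terminates after a handful of attempts.
    while True:
        last_edge = {}
        for v in vertices:
            if v == end:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            cur, hops = v, 0
            while cur != end:
                if cur not in last_edge or hops > len(vertices):
                    ok = False
                    break
                cur = last_edge[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break

    # Permute remaining out-edges, appending each vertex's last edge.
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        perm = [pool[i] for i in rng.permutation(len(pool))]
        if v in last_edge:
            perm.append(last_edge[v])
        ordered[v] = perm

    # Walk the Eulerian path.
    out = [start]
    ptr = {v: 0 for v in vertices}
    cur = start
    for _ in range(len(s) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)

    assert dinucleotide_counts(shuffled) == dinucleotide_counts(s)
    return ShuffleResult(
        original_id=seq.id,
        shuffled=NucleicSequence(id=f"{seq.id}_shuf{seed}", residues=shuffled,
                                 kind=seq.kind),
        seed=seed,
    )
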