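"""Synthetic genomes, planted purine tracts and transcript panels.

The generator emulates the study conditions the screen assumes: a neutral
i.i.d. background genome, planted purine-rich low-complexity tracts (the
positive class), length-matched control regions sampled away from the
plants, and a transcript panel of controlled length and GC content.

Uniform i.i.d. transcripts essentially never contain the >= 10-nt
single-motif runs that drive triplex window blow-up at desk scale, while
real transcripts do; the panel generator therefore injects a configurable
number of single-base runs per transcript (default: one poly-U, one poly-C
and one poly-G run of length 12).  Mixed-alphabet runs would mismatch a
pure planted tract at ~50% of positions and never reach the 10% error
threshold, so the defaults use singleton alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (GenomicRegion, NucleicSequence, reverse_complement,
                 write_bed, write_fasta)
from .shuffle import dinucleotide_shuffle

__all__ = [
    "LcrSpec",
    "RnaRunSpec",
    "PlantedRegion",
    "FixtureConfig",
    "FixtureTruth",
    "generate_genome",
    "plant_lcrs",
    "sample_control_regions",
    "generate_rna_panel",
    "make_fixture",
]

_PURINES = frozenset("GA")
_RUN_ALPHABETS = (frozenset("CU"), frozenset("GU"), frozenset("GA"))


@dataclass(frozen=True)
class LcrSpec:
    """One planted low-complexity purine tract.

    ``unit`` is repeated along the tract; each position deviates to a
    uniform random base with probability ``1 - purity``.
    """

    unit: str
    tract_length: int
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not self.unit or set(self.unit) - _PURINES:
            raise ValueError("unit must be a non-empty purine (G/A) string")
        if self.tract_length < 10:
            raise ValueError("tract_length must be >= 10")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class RnaRunSpec:
    """Run injection into panel transcripts: `count` runs drawn from `alphabet`."""

    alphabet: frozenset
    run_length: int
    count: int

    def __post_init__(self) -> None:
        alpha = frozenset(self.alphabet)
        if not any(alpha <= allowed for allowed in _RUN_ALPHABETS):
            raise ValueError(
                "run alphabet must be a subset of {C,U}, {G,U} or {G,A}")
        if self.run_length < 10:
            raise ValueError("run_length must be >= 10")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class PlantedRegion:
    """Truth record for one planted region."""

    region: GenomicRegion
    tract: GenomicRegion
    strand: str
    spec: LcrSpec


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _iid_bases(rng: np.random.Generator, length: int, gc: float,
               alphabet: str = "ACGT") -> str:
    # alphabet order A, C, G, T/U
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(alphabet.encode(), dtype="S1")
    return rng.choice(bases, size=length, p=probs).tobytes().decode("ascii")


def generate_genome(length: int, gc: float, seed: int,
                    chrom: str = "chr1") -> NucleicSequence:
    """i.i.d. genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    return NucleicSequence(id=chrom,
                           residues=_iid_bases(_rng(seed), length, gc),
                           kind="DNA")


def _place_nonoverlapping(rng: np.random.Generator, genome_length: int,
                          lengths: Sequence[int],
                          exclude: Sequence[tuple[int, int]],
                          max_tries: int = 10_000) -> list[int]:
    """Uniform non-overlapping placements avoiding `exclude`; raises on failure."""
    taken = [tuple(iv) for iv in exclude]
    starts = []
    for L in lengths:
        if L > genome_length:
            raise ValueError(f"region length {L} exceeds genome length")
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - L + 1))
            if all(s + L <= a or s >= b for a, b in taken):
                starts.append(s)
                taken.append((s, s + L))
                break
        else:
            raise RuntimeError(
                "placement error: could not place a region without overlap")
    return starts


def _build_tract(rng: np.random.Generator, spec: LcrSpec) -> str:
    unit = spec.unit
    chars = [unit[i % len(unit)] for i in range(spec.tract_length)]
    if spec.purity < 1:
        corrupt = rng.random(spec.tract_length) > spec.purity
        bases = "ACGT"
        for i in np.flatnonzero(corrupt):
            chars[i] = bases[rng.integers(4)]
    return "".join(chars)


def plant_lcrs(genome: NucleicSequence, n: int,
               spec: LcrSpec | Sequence[LcrSpec],
               region_length: int, seed: int,
               ) -> tuple[NucleicSequence, list[PlantedRegion]]:
    """Plant ``n`` non-overlapping purine-tract regions into a genome.

    Each planted region of ``region_length`` contains one tract built from
    ``spec`` (a single spec, or a list cycled across regions) at a random
    offset, on a randomly chosen strand.  Returns the modified genome and
    the truth records.
    """
    specs = [spec] if isinstance(spec, LcrSpec) else list(spec)
    if n == 0:
        return genome, []
    for sp in specs:
        if sp.tract_length > region_length:
            raise ValueError("tract_length must be <= region_length")
    if n * region_length > len(genome) // 2:
        raise ValueError("planted regions would cover more than half the genome")
    rng = _rng(seed)
    starts = _place_nonoverlapping(rng, len(genome), [region_length] * n, [])
    residues = list(genome.residues)
    planted = []
    for i, s in enumerate(starts):
        sp = specs[i % len(specs)]
        tract = _build_tract(rng, sp)
        offset = int(rng.integers(0, region_length - sp.tract_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = tract if strand == "+" else reverse_complement(tract)
        t0 = s + offset
        residues[t0:t0 + sp.tract_length] = insert
        planted.append(PlantedRegion(
            region=GenomicRegion(genome.id, s, s + region_length,
                                 name=f"planted_{i:04d}"),
            tract=GenomicRegion(genome.id, t0, t0 + sp.tract_length,
                                name=f"planted_{i:04d}_tract"),
            strand=strand, spec=sp))
    new_genome = NucleicSequence(id=genome.id, residues="".join(residues),
                                 kind="DNA")
    return new_genome, planted


def sample_control_regions(genome: NucleicSequence, lengths: Sequence[int],
                           exclude: Sequence[GenomicRegion],
                           seed: int) -> list[GenomicRegion]:
    """Length-matched control regions sampled uniformly away from `exclude`."""
    rng = _rng(seed)
    excl = [(r.start, r.end) for r in exclude]
    starts = _place_nonoverlapping(rng, len(genome), lengths, excl)
    return [GenomicRegion(genome.id, s, s + L, name=f"control_{i:04d}")
            for i, (s, L) in enumerate(zip(starts, lengths))]


def generate_rna_panel(n: int, length: int, gc: float,
                       run_spec: RnaRunSpec | Sequence[RnaRunSpec] | None,
                       seed: int) -> list[NucleicSequence]:
    """Transcript panel of controlled length/GC with optional injected runs.

    Runs are placed at random non-overlapping positions; each run position
    is drawn uniformly from the run alphabet.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = ([] if run_spec is None
             else [run_spec] if isinstance(run_spec, RnaRunSpec)
             else list(run_spec))
    total_run = sum(sp.run_length * sp.count for sp in specs)
    if total_run > length:
        raise ValueError("injected runs cannot fit in the transcript length")
    rng = _rng(seed)
    panel = []
    for i in range(n):
        residues = list(_iid_bases(rng, length, gc, alphabet="ACGU"))
        run_lengths = [sp.run_length for sp in specs for _ in range(sp.count)]
        alphabets = [sorted(sp.alphabet) for sp in specs for _ in range(sp.count)]
        placements = _place_nonoverlapping(rng, length, run_lengths, [])
        for s, L, alpha in zip(placements, run_lengths, alphabets):
            for k in range(L):
                residues[s + k] = alpha[rng.integers(len(alpha))]
        panel.append(NucleicSequence(id=f"rna_{i:04d}",
                                     residues="".join(residues), kind="RNA"))
    return panel


@dataclass(frozen=True)
class FixtureConfig:
    """Desk-scale defaults: 500 kb genome, 50 planted + 50 background
    regions of 500 bp, pure 100-bp tracts alternating poly-A/poly-G, and a
    20-transcript panel (1000 nt, GC 0.5) with poly-U/C/G runs of 12."""

    genome_length: int = 500_000
    genome_gc: float = 0.5
    n_planted: int = 50
    n_background: int = 50
    region_length: int = 500
    lcr_specs: tuple[LcrSpec, ...] = (
        LcrSpec(unit="A", tract_length=100, purity=1.0),
        LcrSpec(unit="G", tract_length=100, purity=1.0),
    )
    n_rnas: int = 20
    rna_length: int = 1000
    rna_gc: float = 0.5
    run_specs: tuple[RnaRunSpec, ...] = (
        RnaRunSpec(alphabet=frozenset("U"), run_length=12, count=1),
        RnaRunSpec(alphabet=frozenset("C"), run_length=12, count=1),
        RnaRunSpec(alphabet=frozenset("G"), run_length=12, count=1),
    )
    n_shuffled: int = 0


@dataclass(frozen=True)
class FixtureTruth:
    """A complete generated dataset plus its ground truth."""

    genome: NucleicSequence
    planted: tuple[PlantedRegion, ...]
    background: tuple[GenomicRegion, ...]
    panel: tuple[NucleicSequence, ...]
    shuffled_panel: tuple[NucleicSequence, ...]
    expected_positive: tuple[str, ...]


def make_fixture(config: FixtureConfig | None = None, seed: int = 0,
                 out_dir: str | Path | None = None) -> FixtureTruth:
    """Compose genome + plants + controls + panel into one dataset.

    When ``out_dir`` is given, writes genome.fasta, planted.bed,
    background.bed, panel.fasta (plus shuffled_panel.fasta when requested),
    truth.tsv and config.tsv.
    """
    config = config or FixtureConfig()
    base = generate_genome(config.genome_length, config.genome_gc,
                           seed=[seed, 0])
    genome, planted = plant_lcrs(base, config.n_planted,
                                 list(config.lcr_specs),
                                 config.region_length, seed=[seed, 1])
    background = sample_control_regions(
        genome, [config.region_length] * config.n_background,
        [p.region for p in planted], seed=[seed, 2])
    panel = generate_rna_panel(config.n_rnas, config.rna_length,
                               config.rna_gc, list(config.run_specs),
                               seed=[seed, 3])
    shuffled = []
    for k in range(config.n_shuffled):
        src = panel[k % len(panel)]
        shuffled.append(dinucleotide_shuffle(src, seed=1_000_003 * k + 7).shuffled)

    # Sanity property of the construction: plants raise poly-purine content.
    truth = FixtureTruth(
        genome=genome,
        planted=tuple(planted),
        background=tuple(background),
        panel=tuple(panel),
        shuffled_panel=tuple(shuffled),
        expected_positive=tuple(p.region.name for p in planted),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fasta", [genome])
        write_bed(out / "planted.bed", [p.region for p in planted])
        write_bed(out / "background.bed", list(background))
        write_fasta(out / "panel.fasta", panel)
        if shuffled:
            write_fasta(out / "shuffled_panel.fasta", shuffled)
        with open(out / "truth.tsv", "w") as fh:
            fh.write("name\tchrom\tstart\tend\tclass\tstrand\tunit\t"
                     "tract_start\ttract_end\tpurity\n")
            for p in planted:
                fh.write(f"{p.region.name}\t{p.region.chrom}\t{p.region.start}"
                         f"\t{p.region.end}\tplanted\t{p.strand}\t{p.spec.unit}"
                         f"\t{p.tract.start}\t{p.tract.end}\t{p.spec.purity}\n")
            for r in background:
                fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}"
                         f"\tbackground\t.\t.\t.\t.\t.\n")
        with open(out / "config.tsv", "w") as fh:
            fh.write("key\tvalue\n")
            for key, value in vars(config).items():
                fh.write(f"{key}\t{value}\n")
    return truth
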