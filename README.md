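# triplexhub

RNA–DNA triplex target site (TTS) discovery: enumerate candidate triple
helices between transcripts and genomic regions under Hoogsteen
base-pairing rules, score each pair's window count against a
length-calibrated Poisson null, and classify regions that are significant
for more than 90% of a transcript panel as **universal TTSs** — loci whose
long purine-rich tracts can accept third strands from many different RNAs.

Intended for regulatory-genomics analyses of chromatin-associated RNAs
(e.g. lncRNA ChOP-seq / Capture-seq peak sets), and for simulation studies
of the purine-tract confounder in triplex prediction.

## Model

A triplex window pairs an RNA interval with a same-length DNA interval
whose purine-rich strand hosts the third strand. Motif families (validated
window-wide): TC (parallel; C·G, U·A), GA (antiparallel; G·G, A·A), GT
(both orientations; G·G, U·A). A window qualifies at length
L ≥ l (default 10) with at most ⌊e/100 · L⌋ rule violations (default
e = 10%); counting is overlap-allowed, so N_tpx — the count for one
RNA/DNA pair — includes every qualifying sub-window.

Significance of an observed N_tpx uses a Poisson null whose mean is linear
in the sequence lengths,

    λ(L_RNA, L_DNA) = θ₀ + θ₁·L_RNA + θ₂·L_DNA ,

with shipped reference coefficients θ₀ = −0.688, θ₁ = 5.37×10⁻⁴,
θ₂ = 6.03×10⁻⁴ (refittable from engine simulations over a length grid);
p = P(X ≥ N_tpx | X ~ Pois(λ)), Bonferroni-adjusted per RNA, significant
at adjusted p < 0.01. A region significant for > 90% of the panel is a
universal TTS. Composition measures (strand-maximised GA content and
poly-purine content from purine runs ≥ 10 nt) profile what the universal
calls are made of. See `docs/methods.md` for the full account.

## Worked example

```python
from triplexhub import (NucleicSequence, EngineParams, enumerate_triplexes,
                        CalibrationModel, expected_lambda, triplex_pvalue)

rna = NucleicSequence("rna", "GAGAGAGAGAG", "RNA")
dna = NucleicSequence("dna", "GAGAGAGAGAG", "DNA")
for w in enumerate_triplexes(rna, dna, EngineParams()):
    print(w.rna_start, w.rna_end, w.dna_start, w.dna_end,
          w.dna_strand, w.orientation, w.motifs, w.n_errors)

model = CalibrationModel.default()
lam = expected_lambda(model, 1000, 1000)
print(lam, triplex_pvalue(3, lam))
```

prints

```
0 10 1 11 + antiparallel ('GA',) 0
0 11 0 11 + antiparallel ('GA',) 0
1 11 0 10 + antiparallel ('GA',) 0
0.45200000000000007 0.011008894413416535
```

i.e. the perfect 11-mer GA-repeat alignment counts N_tpx = 3 (the full
antiparallel GA-motif window plus its two length-10 sub-windows), and for
a 1000-nt RNA against a 1000-bp region the null expects λ = 0.452 windows,
so observing 3 has p ≈ 0.011.

A full screen, from the built-in synthetic benchmark:

```python
from triplexhub import make_fixture, TriplexScreen, extract_region_sequence

truth = make_fixture(seed=0)                      # 500 kb genome, 50 planted
gmap = {truth.genome.id: truth.genome}            # purine tracts, 50 controls,
regions = [(p.region, extract_region_sequence(gmap, p.region))  # 20 RNAs
           for p in truth.planted]
regions += [(r, extract_region_sequence(gmap, r)) for r in truth.background]
res = TriplexScreen(rnas=list(truth.panel), regions=regions).fit()
print(res.summary())
```

```
Triplex screen summary
======================
RNAs: 20   regions: 100   pairs: 2000
engine: min_length=10 max_error_rate=10.0%
calibration: theta=(-0.688, 0.000537, 0.000603) [reference]
alpha=0.01 (Bonferroni, family=per-rna)
significant pairs: 1050 (52.5%)
universal TTSs (> 90% of panel): 51 of 100 (51.0%)
```

All 50 planted purine-tract regions and 1 of 50 background regions are
called universal: the planted tracts bind (nearly) the whole panel, the
composition-matched background does not.

The same operations are available from the shell:

```bash
triplexhub simulate --seed 0 --out-dir fixture/
triplexhub classify --rna-panel fixture/panel.fasta \
    --regions fixture/planted.bed --genome fixture/genome.fasta \
    --out-dir results/
triplexhub scan --rna rna.fasta --dna regions.fasta --out counts.tsv
triplexhub calibrate --reps 10 --seed 1 --out model.tsv
triplexhub composition --dna regions.fasta --out composition.tsv
triplexhub shuffle --rna transcript.fasta --n-per-seq 153 --seed 1 --out controls.fasta
```

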