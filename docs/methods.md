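# Methods

## The problem

Long non-coding RNAs can contact chromatin directly by laying a third
strand into the major groove of duplex DNA, hydrogen-bonding (Hoogsteen or
reverse-Hoogsteen) to the purines of one strand. Pulldown assays
(ChOP-seq, Capture-seq) map where a given RNA binds, but sequence-based
prediction of such triplex target sites (TTSs) is dominated by a
confounder: long purine-rich low-complexity tracts accept third strands
from *many* different RNAs. `triplexhub` implements the analysis that
makes this explicit — enumerate candidate triplexes between an RNA panel
and a region set, score each pair's window count against a
length-calibrated Poisson null, and flag regions significant for more
than 90% of the panel as **universal TTSs**.

## Window enumeration model

A window pairs an RNA interval with a same-length DNA interval. The DNA
base that accepts the third strand is always a purine on one strand of
the duplex; both strands are scanned (coordinates are always reported on
the forward strand, with `dna_strand` naming the purine-tract strand).
Three motif families are evaluated window-wide, never mixed within a
window:

| motif | orientation(s)   | valid RNA·DNA-purine triples |
|-------|------------------|------------------------------|
| TC    | parallel         | C·G, U·A                     |
| GA    | antiparallel     | G·G, A·A                     |
| GT    | both             | G·G, U·A                     |

A window of length L ≥ `min_length` (default 10) qualifies if at most
`floor(max_error_rate/100 · L)` positions (default rate 10%) violate the
rules of at least one enabled motif, and — by default — its first and
last aligned positions are error-free (`require_terminal_match`; this
prevents error-padded inflation of counts at tract boundaries and is
configurable because different search tools differ here). Counting is
overlap-allowed ("Total (abs)" semantics): every qualifying
(RNA interval, DNA interval, strand, orientation) is counted once,
including all sub-windows of a longer window, with motifs merged on
duplicates (the recorded `n_errors` is the minimum over validating
motifs). A perfect 11-mer alignment at `min_length=10` therefore counts
3. Optional constraints of the original tool family
(`max_consecutive_errors`, `min_guanine_rate`) default to off.

The implementation scans (anti)diagonals of the pairing matrix with a
compiled (numba) kernel that enumerates windows from mismatch-run
structure; its contract is exact equality with a brute-force
every-window oracle, which the test suite enforces on tens of thousands
of random pairs. Enumeration cost is linear in the matrix size plus the
number of emitted windows, so adversarial inputs (e.g. kilobase poly-U
against poly-A) are quadratic in output and should be counted, not
enumerated, with care.

## Statistical model

The null expectation for the window count of a random RNA/DNA pair is
modelled linearly in the two lengths:

λ(L_RNA, L_DNA) = θ₀ + θ₁·L_RNA + θ₂·L_DNA

The shipped reference calibration (θ₀ = −0.688, θ₁ = 5.37×10⁻⁴,
θ₂ = 6.03×10⁻⁴, adjusted R² = 0.87) was estimated at genome scale
against Triplexator-style counts and is the default scoring model, so
that identical counts always score identically regardless of which
engine produced them. Refitting against the bundled engine is an explicit user
action: `simulate_lambda_grid` draws uniform-composition random
sequences over a length grid (reference grid: L_RNA ∈ {500, 1000, 1500,
2000} × L_DNA ∈ {200, 400, …, 2000}, 100 sequences per side, cell mean
over all pairs) and `fit_lambda_model` performs OLS of cell means on the
two lengths. The re-implemented engine's counting need not match the
original tool's exactly, so refit coefficients are checked only for the
qualitative properties that matter (positive slopes, means increasing
with length); the reference θ values are not asserted as reproducible.

Significance of an observed count n is the exact Poisson upper tail
P(X ≥ n | X ~ Pois(λ)), 1 at n = 0. The linear model can predict λ ≤ 0
for short inputs (e.g. (500, 200) → −0.2989); predictions below the
floor (default 10⁻³) are clamped to it, with a warning when the raw
value is ≤ 0, since at such lengths any observed window becomes
significant — a conservative-in-the-other-direction behaviour that is
deliberately surfaced rather than hidden. Tails that underflow to
exactly 0 for very large counts are accepted downstream. Bonferroni
adjustment multiplies by the family size, by default the number of
regions tested per RNA (each transcript's scan is one family); a
`global` family (all RNA×region tests) is available because the choice
is genuinely open. A pair is significant when adjusted p < α (default
0.01, strict); a region is a universal TTS when its significant fraction
of the panel strictly exceeds `universal_fraction` (default 0.9).

The Poisson null matches means, not dispersion: overlap-allowed counting
makes windows arrive in bursts (one length-12 perfect run contributes 6
windows), so the null is over-dispersed relative to Poisson and the
nominal type-I rate is not exact. The test suite records the empirical
null fraction below 0.01 as a diagnostic rather than asserting exact
calibration.

## Composition measures

GA content is the maximum over the two strands of the purine (G/A)
fraction — on clean sequence always ≥ 50%, since a purine on one strand
is a pyrimidine on the other. Poly-purine content sums, per strand,
maximal purine runs of ≥ `min_run` (default 10, matching the engine's
minimum window) and takes the strand maximum of that sum over the region
length; it spans the full 0–100%. Runs from different strands are never
mixed. Hard-masked characters (ambiguity masking uses `X`, which no
pairing rule accepts) count as non-purines on both strands and break
runs; masked sequence can therefore drop GA content below 50%.

## Dinucleotide shuffling

Control RNAs preserve the exact dinucleotide count vector of the source
transcript (hence mononucleotide counts and both terminal residues),
via uniform Eulerian-path sampling on the dinucleotide transition
multigraph (Altschul–Erickson: random last-edge in-tree toward the
terminal vertex, rejection-sampled, then random permutation of remaining
out-edges). Exact count preservation — rather than Markov resampling —
is required because the downstream significance contrast depends on
composition being held fixed.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions end to end: an i.i.d.
background genome (default 500 kb, GC 0.5), 50 planted 500-bp regions
each containing one pure 100-bp purine tract (units alternating poly-A
and poly-G, strand randomised), 50 length-matched control regions
sampled away from the plants, and a 20-transcript panel (1000 nt,
GC 0.5). Uniform i.i.d. transcripts essentially never contain the ≥10-nt
single-motif runs that drive window blow-up, while real transcripts do,
so each panel transcript gets three injected length-12 runs: poly-U
(binds poly-A tracts via U·A), poly-C (binds poly-G via C·G, parallel)
and poly-G (binds poly-G via G·G, both orientations). Singleton run
alphabets are deliberate: a mixed C/U run mismatches a pure tract at
roughly half its positions and can never pass a 10% error threshold.

The background is neutral i.i.d. sequence — no repeat structure,
chromatin, expression or secondary-structure effects. Passing the
planted-recovery test therefore shows the pipeline separates purine-tract
regions from composition-matched noise under its own model assumptions;
it does not certify performance on real genomes, where low-complexity
structure is pervasive and peak length distributions differ.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere (BED convention); DNA
  records always store the forward strand.
- Allowed errors use `floor(rate/100 · L)` with a 10⁻⁹ guard against
  float representation of the rate.
- Window sets are dicts keyed by interval identity; output is sorted, so
  iteration order can never affect counts or downstream tables.
- All generators accept explicit seeds (numpy `SeedSequence`-derived
  streams per grid cell / fixture component) and are bit-reproducible.
- Whether identical interval pairs validated in both orientations should
  be deduplicated further (the poly-U/poly-A case) is not decidable from
  the counting example alone; they are counted separately here, which the
  oracle and the closed-form blow-up test both encode.
- Problem sizes in the test suite (reduced 4×10 calibration grid at 10
  sequences per side; the 500 kb / 100-region / 20-transcript fixture)
  are the package's desk-scale defaults, chosen so a full run completes
  in minutes on one CPU while still exercising every code path at
  realistic lengths.

## Known limitations

- The engine reproduces the documented thresholds of the original search
  tool but not its undocumented internals (q-gram indexing, binary
  outputs, exact defaults of the consecutive-error and guanine-rate
  filters); counts can therefore differ from Triplexator's on the same
  input, which is why refitting the calibration is supported.
- RNA secondary structure, chromatin accessibility and expression are
  out of model.
- Genome-scale published fractions (e.g. 56.3% significant ChOP-seq
  peaks, 16.3%/0.6%/40% universal) require the real human-genome inputs
  and are not reproduced at desk scale.
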