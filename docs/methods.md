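# Methods

## Replicon model and roles

A *replicon* is one nucleotide sequence over {A, C, G, T, N}; lowercase and
IUPAC ambiguity codes other than N are normalized on input (ambiguity → N)
so that k-mer arithmetic works on a 4-letter alphabet. GC content is
computed over non-N bases only, which keeps gap-filled MAG sequences from
being biased toward their filler composition. Four roles are assigned:
CHROMOSOME, CHROMID, OTHER (plasmid-like or unclassifiable), and UNASSIGNED
(complete-genome mode only, for assemblies with a single replicon, which the
screen cannot address).

## Genomic signatures

For word size k ∈ {2, 4}, frequencies f\*(w) are sliding-window counts over
windows containing only ACGT, accumulated from the sequence **and its
reverse complement** before normalizing (strand symmetrization), so a
replicon's signature does not depend on the deposited strand:
`distance(s, reverse_complement(s)) == 0` exactly. Windows overlapping N
are dropped, not imputed — imputation would bias ratios on gappy MAG
sequences. The relative abundance of w = x₁…x_k is

ρ(w) = f\*(w) / (f\*(x₁)·…·f\*(x_k)),

the zero-order (mononucleotide-product) normalization; words whose
mononucleotide product is zero get ρ = 0 and are excluded from the
signature's informative-word count. The distance between signatures is the
mean absolute difference over all 4^k words times a scale factor.

**Scale convention.** The working thresholds (dinucleotide ≤ 0.4,
tetranucleotide < 1.6) are only meaningful relative to a scale, and no
single convention is universal; this package multiplies the mean absolute
difference by a configurable factor, default ×10, and always reports
thresholds together with the configured scale. On that scale, same-genome
replicon pairs of ≥ 100 kb typically sit well below 1 (sampling noise decays
as ~L^(-1/2)), while compositionally foreign pairs sit higher; the
dinucleotide ≤ 0.4 pre-screen is therefore informative for replicons of
roughly ≥ 50–100 kb and is disabled by default.

Comparison directions follow the screening conventions: strict `<` for the
tetranucleotide cutoff, `≤` for the dinucleotide pre-screen, and `≤` for
the GC band (60.0% vs 61.0% passes a 1.0 pp band; 61.01% fails). The GC
band is absolute percentage points, not a relative 1%.

## Marker categories and scanning

Four categories drive the rules: REP (plasmid replication initiators), PAR
(partitioning proteins), CORE (bacterial core genes), DNAA (the chromosomal
replication initiator DnaA and homologs). The database is *consumed, not
built*: model files come with a manifest TSV (`marker_id <tab> category`),
because category identity is not encoded in HMM format and is never guessed
from a marker's name. DNAA models are not counted as CORE.

Two scanner backends implement one contract:

* **hmm** — HMMER3 profiles searched with pyhmmer; a hit must pass the
  full-sequence E-value threshold (default 1e-5, conventional hmmsearch
  practice) or, when a model carries gathering cutoffs, those per-model
  cutoffs instead.
* **motif** — each "model" is a literal amino-acid motif; a hit is an exact
  substring match reported with e_value 0. This backend makes the whole
  pipeline testable without model files.

Counting is presence/absence over *distinct* markers: five proteins hitting
the same core model contribute n_core = 1, because the screening rules ask
whether a category is represented, not how often.

Gene calling likewise has two backends: `prodigal` (external, meta mode)
and a built-in naive ORF finder (both strands, three frames; an ORF runs
from the first ATG after an in-frame stop to the next stop and must encode
≥ 30 aa). The naive backend exists so the pipeline is exercisable with no
external processes and is what the synthetic benchmark uses; it
deliberately over-calls ORFs relative to a real gene caller, which is
harmless here because classification only consumes marker hits.

## Decision procedures

**Complete-genome screen.** Assemblies with < 2 replicons → UNASSIGNED.
Longest replicon → CHROMOSOME; a length tie is broken by DnaA presence,
then lexicographic id, with a logged warning. Each secondary replicon is
CHROMID iff |ΔGC| ≤ 1.0 pp ∧ (optional dinucleotide pre-screen) ∧ the
marker rule; otherwise OTHER, with the failed condition recorded as
evidence.

**MAG pipeline.** Step 1 retains sequences with ≥ 1 predicted gene and
≥ 1 marker hit of any category (the retention criterion is configuration,
exposed as such). Steps 2–3 cluster retained sequences around every
DnaA-bearing center: members must be strictly shorter than the center
(equal length excluded), within the GC band, and pass the candidate marker
rule. Step 4 filters members by tetranucleotide distance to their center.
Calls: centers → CHROMOSOME (a DnaA-bearing sequence is never called a
chromid, even when it would qualify as a member of another cluster);
members passing in ≥ 1 cluster → CHROMID (one call, all supporting centers
in the evidence; the reported center is the smallest-distance one);
everything else → OTHER. A sequence may sit in many clusters — with
groupings removed this is expected, not an error.

**Marker rules.** strict = REP ∧ PAR ∧ CORE; relaxed = (REP ∨ PAR) ∧ CORE.
Complete-genome mode defaults to strict (all three systems observable in a
closed genome); MAG mode defaults to relaxed, tolerating incomplete MAGs
while preserving the essentiality requirement (core genes). Both are
selectable everywhere.

Because the tetranucleotide threshold acts only at step 4, threshold sweeps
(`metrics.threshold_sweep`) compute steps 1–3 once and re-apply the final
filter per grid value; `math.inf` is an accepted sentinel at which every
cluster member passes.

## Evaluation

Positive class = CHROMID; UNASSIGNED and OTHER are negative predictions.
Rates are Acc = (TP+TN)/(P+N), precision = TP/(TP+FP), TPR = TP/(TP+FN),
FPR = FP/(FP+TN), reported as percentages rounded **half-up to two
decimals** (e.g. 144/156 = 92.3077 → 92.31). Undefined denominators yield a
flagged NaN with a warning rather than an exception. ROC AUC over a sweep
is trapezoidal, with the curve anchored at (0,0) and (100,100); it is a
convenience diagnostic, not a calibrated quantity.

## Synthetic benchmark

`synthetic.generate_assembly` draws each replicon from an order-0 or
order-1 Markov model. The order-1 model multiplies a base-composition
vector by a fixed strand-symmetric dinucleotide bias (CG strongly depleted,
AA/TT enriched, TA depleted, GG/CC enriched — the qualitative shape of real
bacterial genomes) and bisects the composition knob until the chain's
stationary GC hits the target. Chromids reuse the chromosome's model family
with the GC target nudged by the chromid offset — compositional kinship is
a *signature* property in this design, not merely a GC property — while
plasmids get a model offset by several pp of GC. Sequential sampling runs
through a small numba kernel, keeping megabase simulation cheap.

Default study conditions: 500 kb chromosome at 60% GC carrying planted
DnaA + two core genes; one 150 kb chromid at +0.3 pp GC carrying
Rep + Par + core; one 40 kb plasmid at +5 pp GC carrying Rep + Par but no
core gene. Offsets were chosen to land clearly inside (0.3 ≪ 1.0 pp) and
clearly outside (5.0 ≫ 1.0 pp) the screening band relative to the ~0.1 pp
sampling noise of these lengths; `plasmid_markers` switches the plasmid
failure mode between composition divergence ("rep_par", default), marker
withholding ("none"), and a deliberately confusable full marker set
("full"). Planted genes are valid ORFs (ATG, ≥ 30 sense codons, stop) on
random strands at non-overlapping positions, each encoding one literal
motif from the toy marker database, so both gene backends and both scanner
backends recover them. Per-assembly seeds are base_seed + index:
replicates are independent but individually regenerable.

The benchmark suite runs 50 assemblies (150 pooled sequences, ~35 Mb) —
large enough for stable rate estimates at the single-percent level while
keeping a full run in tens of seconds.

**What passing does and does not show.** The generator produces uniform
background composition, unrealistically clean marker presence/absence, no
mobile elements, rearrangements, contamination, fragmentation, or
sequencing error, and no hard cases near the decision boundaries. Perfect
recall/FPR on it validates the *mechanics* of the rules — thresholds,
clustering, distance filter, bookkeeping — not real-world accuracy; on real
data the binding failure modes are missing markers in incomplete MAGs and
borderline compositional divergence, which the evidence log is designed to
make auditable.

## Numerical choices and degenerate inputs

* Signature arithmetic is vectorized float64; the distance is validated
  against an independent brute-force word-enumeration oracle to 1e-12.
* All-N or too-short sequences raise typed errors at the signature layer
  and are reportable (GC = missing) at the pipeline layer.
* Percentage rounding uses decimal half-up, matching the reporting style
  of the reproduced confusion-matrix rates.
* Determinism: fixed seed ⇒ byte-identical FASTA, result TSV, and metric
  output; scanning and clustering iterate in deterministic input order, and
  classification is invariant to input permutation.

## Known limitations

* The relative-abundance normalization is zero-order only; higher-order
  Markov normalizations are out of scope.
* The naive ORF finder reports the longest ORF per stop-to-stop segment;
  nested or overlapping genes in the same frame are not separated.
* The dinucleotide pre-screen threshold (0.4) and the tetranucleotide
  cutoff (1.6) are convention-bound to the ×10 scale; users supplying their
  own conventions must adjust scale and thresholds together.
* Megaplasmid sub-classification and taxonomy assignment are out of scope;
  OTHER aggregates everything non-chromid.
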