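# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind each analysis stage. Defaults printed here are the
package defaults; all are configurable.

## Size-class profiling

Reads are collapsed to unique (sequence, count) records after dropping
N-containing reads; sequences are held internally in the RNA alphabet
(T→U) and written back in the input dialect. Read relative abundance (RRA)
at each length is the fraction of the library's retained reads of that
length; the miRNA class is lengths 21–24 nt and the piRNA class 26–29 nt
(length 25 and ≥ 30 belong to neither). The RRA and RPM denominator is the
library total *after* N-filtering but *before* the 18–25-nt discovery
filter: size-class profiles must see the full length distribution, while
precursor discovery consumes only the plausibly Dicer-sized subset. Because
the original study's cross-library normalization for absolute abundance is
not fully specified, only within-library relative measures are claimed.

## Pre-miRNA discovery

The discovery model assumes a Dicer-processed locus produces a dominant
mature read stack, a minor star stack with 2-nt 3′ overhangs against the
mature on the precursor stem, and little else.

*Mapping.* Exact-match anchoring on both strands through an 18-mer seed
index with full-length verification. No mismatches are tolerated —
mismatch mapping would blur downstream sibling-species SNP analysis. Reads
with more than `max_genomic_hits` (15) genomic hits are discarded as
repeat-derived. Anchors are only folded when their collapsed stack has ≥ 3
reads and at least half the mature RPM gate; both are pure efficiency
gates below the candidate-level abundance filter, which is applied
afterwards to the full ±2-nt 5′ neighborhood.

*Excision and folding.* Three windows per anchor — [start−150, end+150),
[start−150, end+30), [start−30, end+150), clipped to the contig — cover
mature-on-5′-arm, mature-on-3′-arm and centered layouts. Windows are
folded with the thermodynamic backend (ViennaRNA MFE) when its Python
binding is importable, else with the built-in Nussinov base-pair
maximization (pairs AU/UA/GC/CG/GU/UG, minimum loop 3, deterministic
traceback preferring the outermost compatible pair then the leftmost
bifurcation). The backends share one contract — (dot-bracket, partner
table, paired fraction) — and everything downstream reads only that.
Base-pair maximization is exact and is verified against exhaustive
enumeration for short sequences, but on a ~320-nt window it is
combinatorially underdetermined: random RNA admits many co-optimal
near-complete pairings, of which the planted stem is only one. The
thermodynamic backend resolves that degeneracy, which is why it is
preferred for discovery; the DP remains the reference implementation of
the folding contract and the default of `fold()`.

*Duplex calling.* The star spans the partners of mature[0..len−3]
extended by 2 nt at its own 3′ end, realizing 2-nt 3′ overhangs on both
duplex ends. Unpaired mature termini resolve to the nearest paired
position toward the loop. A candidate is rejected when the mature is
entirely unpaired, its partners fall on both sides (it crosses the arms),
or its unpaired loop-facing tail exceeds 4 nt.

*Signature score.* score = log2((consistent+1)/(inconsistent+1)) + 2·[a
read starts exactly at the star 5′ end], with consistent = reads entirely
inside the precursor whose 5′ ends lie within ±2 nt of the mature or star
5′ end, inconsistent = all other window-overlapping reads. This is a
transparent log-odds surrogate for the probabilistic read-signature models
of the miRDeep family, chosen so results are deterministic and exactly
testable; the acceptance threshold (score ≥ 1) is configurable. Star
support is a bonus, not a hard gate.

*Filters.* Precursor (window) ≥ 56 nt; mature ≥ 10 RPM in ≥ 1 library
(interpreted per-library, not pooled); mature region ≥ 60% paired;
signature ≥ 1; contaminant filter (below). Overlapping candidates merge at
the level of their mature/star duplex spans — not their whole 320-nt
windows, so genuinely distinct precursors a few hundred nt apart (cluster
members) survive as separate records — with the highest signature score,
then highest mature RPM, winning.

*Contaminant filter.* Local Smith–Waterman alignment (match +1, mismatch
−1, gap −2, both orientations) of the precursor against a tRNA/rRNA
database; a candidate fails at ≥ 80% precursor coverage and ≥ 90% identity
over the aligned span. Coverage is measured on the precursor, so a short
tRNA can only fail a candidate whose excision window it dominates;
abundant long-rRNA fragments are the main discovery-time target of this
filter.

## Conservation

Ungapped sliding comparison over every offset, no reverse complement
(mature miRNAs are orientation-fixed); a hit needs ≥ 20 aligned nt with
≤ 2 mismatches, the best hit per reference maximizing overlap then
minimizing mismatches. Conserved = hit in ≥ 1 species other than the
query's own. Family labels parse miRBase-style names (species prefix
dropped, -5p/-3p dropped, trailing paralog letters after the family number
dropped); novel queries get serial names in discovery order, which is
reproducible but does not reconstruct any published numbering. SNP tables
list mismatch positions inside the best overlap of counterpart pairs.

## Expression

Counts: a read contributes to a miRNA's library count when its 5′ end is
within ±2 nt of the mature 5′ end and its length within ±2 nt of the
mature length. The differential test scales replicates to the mean library
size, sums them per group, and compares the group sums conditionally on
their total: the sum of n i.i.d. NB(μ, φ) draws is NB(nμ, φ/n), and the
two-sided p aggregates all conditional outcomes no more probable than the
observed one. The common dispersion is pooled method of moments,
φ = Σ(var−mean)/Σmean², floored at 0.01 — the pooled form is close to
unbiased at 3 replicates, where per-miRNA moment estimates are extremely
noisy, and it keeps the empirical type-I error at the nominal 0.05 level
in the package's own null simulations. This test deliberately re-implements
the exact-test idea rather than calling an external package, and it is
validated against a permutation oracle in the test suite; it does not
reproduce TMM normalization or tagwise (per-miRNA) dispersion shrinkage.
Raw p-values are used by default, matching the P < 0.05 convention of the
study design this follows; Benjamini–Hochberg correction is available but
off. log2 fold changes use mean RPM with a 0.5 pseudocount.

Stage handling: two stages merge into one group when fewer than 5 miRNAs
are differentially expressed between them (strict inequality). Categories:
*unique:<stage>* requires significance *and* a higher mean in that stage
against every other group — "differentially expressed in one stage" is
read as up-regulated there; *broad* requires no significant pairwise
contrast and mean RPM above `broad_rpm_min` (default 50; the alternative
convention of 100 is a config switch); everything else is *other*. The
three labels partition the set, and classification is invariant to library
order and to common depth rescaling.

## Clusters

Single sweep per (contig, strand) over start-sorted precursors, chaining
while next.start − current.end ≤ 3000 (inclusive; overlap counts as gap 0
with a warning), emitting maximal runs of ≥ 2. Gaps are measured between
precursor boundaries, not mature positions or midpoints. Co-expression is
the median pairwise Pearson r of log2(mean stage RPM + 0.5) profiles;
members constant across stages contribute r = 0 rather than NaN.

## Degradome

Tags must be exactly 20 nt (the fragment length fixed by MmeI digestion in
PARE chemistry); mapping is exact and sense-only, counting each tag at its
5′ position in every matching transcript. The complementarity penalty
follows the position-weighted convention standard in cleavage-site
pipelines: mismatch 1, G:U wobble 0.5, Watson–Crick 0, doubled over miRNA
positions 2–13; sites score ≤ 7 by default, searched over the whole
transcript (cleavage is not restricted to 3′ UTRs). The cleavage position
is the transcript base pairing miRNA position 10. Duplexes are ungapped —
target-site bulges are a known limitation. Categories on occupied sites:
4 = single read; 0 = unique transcript maximum; 1 = shared maximum;
2 = above the median of occupied positions; 3 = at or below it. The
empirical p-value is add-one corrected over dinucleotide-preserving miRNA
shuffles (random Eulerian walks on the dinucleotide multigraph; a
homopolymer shuffles to itself, making the null powerless by construction,
which is the correct degenerate behavior): a shuffle succeeds when it
reaches the observed score at a site of the same transcript whose category
is at least as good. Final calls: category ≤ 2 and p < 0.05 (strict).
Multi-library runs report targets shared by all libraries versus
library-private ones, keyed by (miRNA, transcript, cleavage position).

## Synthetic data

The generator emulates the features the pipeline's decisions rest on, at
desk scale.

*Genome and hairpins.* An i.i.d. uniform-ACGT genome (a neutral null for
false-positive testing) with non-overlapping planted precursors: stem =
mature + 4–10 extension bp, loop 8–15 nt, mature 21–23 nt on a random arm
and strand, precursor length ≥ 64 nt. The mature/star duplex is fully
paired with exact 2-nt 3′ overhangs; 2–3 G:U wobble pairs are planted
inside the duplex so the locus is not a perfect inverted repeat — on a
perfect palindrome every duplex read would exact-match both strands and
discovery would emit a mirror-image twin of each locus, an artifact real
genomes avoid for the same reason. Up to 2 mismatches are injected into
the stem *outside* the duplex. Features keep ≥ 350 nt clearance so one
locus's stack cannot fall inside a neighboring locus's excision window
(where the signature score would count it as inconsistent evidence);
0.35–3-kb gaps still arise freely, exercising the cluster scanner.

*Abundances.* Each stage's miRNA-class read budget, (1 − piRNA fraction −
degradation fraction) × 10⁶ RPM minus the contaminant allocation and
divided by (1 + star fraction), is split among expressed hairpins
proportionally to log-uniform weights — in real libraries the miRNA-class
reads *are* dominated by miRNA loci, so planted loci must own the class
budget for the size-class fractions, the RPM gates, and the signature
formula to cohere. ~10% of hairpins sit at a fixed 3 RPM (unambiguously
below the 10-RPM gate even after Poisson sampling); ~20% are stage
specific (full weight in one stage, 1/8 elsewhere).

*Reads.* Mature stacks are Poisson at RPM × depth/10⁶ with 5′-end jitter
−1/0/+1 at 0.1/0.8/0.1 (stressing the ±2-nt signature window without
defeating it); star stacks ride at 5% of mature; 26–29-nt piRNA-class
reads are drawn at random genomic positions and strands at the configured
per-stage fraction (positionally random — no ping-pong signature, since
only size-class behavior is analysed); embedded 350–500-nt rRNA-like
contaminants expose two fixed ~200-RPM fragment stacks each, exercising
the contaminant filter inside discovery. No adapter, quality, or
sequencing-error realism beyond the 5′ jitter is attempted. Default stages
are egg, L1, L2, early pupa, late pupa, adult × 3 replicates with a piRNA
fraction gradient 0.40 → 0.25.

*Sibling species and PARE.* Each mature receives one random substitution
with probability `snp_rate`; positions and alleles are recorded. PARE
simulation emits exactly-20-nt tags from planted cleavage positions
(default 80% signal) plus uniform-position degradation tags.

What passing on this generator does **not** show about real data: folding
of real precursors is harder (bulged duplexes, multiloops), real piRNA
populations are clustered and strand-biased, real libraries carry adapter
and quality artifacts and isomiR complexity beyond ±1-nt jitter, and
mapping real reads to fragmented assemblies raises multi-mapping rates.
The planted-truth checks validate the pipeline's logic and thresholds, not
the biology of any particular dataset.

## Problem sizes

The reference validation study, rerun by `scripts/acceptance.py` and the
acceptance test module, uses: a 100-kb genome with 20 planted hairpins and
one 10⁶-read library (plus a hairpin-free null genome of the same depth)
for discovery; 1000 random sequences of length ≤ 20 against the exhaustive
folding oracle; a 2000-miRNA 3-vs-3 null and a 150-hairpin, 5-stage × 3
replicate planted design for the expression stage; 200 random precursors
for the cluster oracle; 1000 random profiles, 10 planted miRNA targets on
20 1-kb transcripts, and 100-shuffle p-values for the degradome; and
10⁶-read egg/adult libraries for the size-class gradient. These sizes make
every stochastic check comfortably stable across seeds.

## Numerical conventions

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3
exports. On the minus strand the 5′ end is the highest coordinate. Ties in
locus merging break by signature score, then mature RPM, then position.
The exact-NB p-value normalizes the conditional distribution explicitly
and treats outcomes within a 1e-12 relative tolerance of the observed
probability as ties. All generator randomness flows from a single integer
seed through named numpy SeedSequence channels, so every artifact is
byte-reproducible and independent stages cannot perturb each other's
streams.
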