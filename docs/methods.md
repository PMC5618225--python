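# Methods

This note documents the models, algorithms and parameter choices behind
`mdsrna`, what the synthetic data does and does not emulate, and the known
limits of each stage.

## The reconstruction problem

M satellite dsRNAs are short (1.3–2.5 kb) linear molecules sequenced at
very high depth after purification. Two things make naive assembly
insufficient. First, k-mers at the physical termini are supported by few
read placements, so multiplicity pruning clips the ends of the de Bruijn
contig. Second, the classically accepted ends (the 5′-GAAAAA motif and the
3′-terminal stem-loop region) are not necessarily the physical ends:
isotypes carry 0–230 nt of "extra" terminal sequence. The pipeline
therefore follows assembly with an iterative, maximally conservative
terminal-extension step and verifies the final sequence by mapping all
reads back.

## Read QC

Reads are trimmed of terminal poly-N (interior Ns kept), then discarded if
shorter than 50 nt, if ≥ 5 % of bases are N, or if the read-quality
statistic is below phred 28. The quality statistic is the arithmetic
**mean** over retained bases by default; whether the original filtering
used mean or minimum is not documented anywhere we know of, so it is a
config knob (`quality_statistic: mean|min`). Boundary semantics are fixed
and tested: exactly 50 nt passes, exactly 5 % N fails, mean exactly 28
passes. Each discarded read is attributed to exactly one cause in the
fixed order trim → length → N fraction → quality, making the QC report
deterministic, and filtering is idempotent.

## Micro-assembly

A single-k de Bruijn assembler (default k = 31, odd so no k-mer is its own
reverse complement). K-mers are strand-canonical because dsRNA libraries
sequence both strands evenly. Multiplicity < 2 is pruned — at ≤ 0.5 %
substitution error and ~100× depth, error k-mers are overwhelmingly
singletons. Contigs are maximal non-branching paths, reported in canonical
orientation and sorted by length then lexicographically (tie-breaks favour
determinism over any optimality claim). Before path extraction, one round
of tip removal drops dead-end unitigs shorter than 2k whose mean coverage
is below 25 % of the junction neighbour's. Contigs shorter than 300 nt are
removed. A multi-k mode (`k_list`-style sweeping) was considered and
rejected: at these genome sizes and depths, single-k assembly plus
terminal extension recovers the molecule, and a second k adds runtime
without changing outcomes in our experiments.

A-homopolymer caveat: a pure poly(A) run of ≥ k nt collapses the graph
(identical k-mers), breaking the contig. Real central A-rich regions are
impure enough (the generator default is 90 % purity) that k-mers remain
unique; a genuinely pure run longer than k − 1 is not resolvable by this
assembler and must be recovered by the extension/mapping stages.

## Terminal extension

Each round, an exact-substring index over all reads and their reverse
complements retrieves every read whose terminal overlap with the current
contig is **100 % identical** over at least `min_overlap` bases and which
overhangs the end by ≥ 1 nt; contained reads are excluded. Overhang columns
are stacked and the contig grows base-by-base while column support ≥
`min_support` and majority fraction ≥ `consensus_fraction`; an exact
top-count tie halts extension for that end (ties are never auto-resolved —
terminal bases are the product of this pipeline, so conservatism beats
completeness). Both ends are extended each round; iteration stops when a
full round adds nothing, or at `max_rounds` (reported as non-converged).

Parameter choices: `min_overlap = 31` matches the assembly k and makes a
spurious exact 31-mer overlap (4⁻³¹) negligible; `min_support = 3` and
`consensus_fraction = 0.8` are this package's choices — the original
procedure's thresholds are not public — and are exposed in config and
echoed to the run log. Reads are processed in id-sorted order, so the
result is a deterministic function of config and input set, and running on
reverse-complemented input yields the reverse-complemented result.

## Map-back consensus

Reads are placed by exact seed (first `seed_length` = 31 bases, with
fallback seeds at offsets 31, 62, … so a single error cannot kill every
seed of a ≥ 62-nt read) followed by ungapped verification allowing ≤ 3
mismatches; the placement with fewest mismatches wins, plus strand
preferred on ties. Gapped alignment is deliberately out of scope: the
simulator plants substitution errors only, and at these depths indel
support would be adjudicated by the extension stage anyway. Reads shorter
than the seed are counted unmapped (the QC length filter keeps them out of
the pipeline proper). The curated consensus changes a base only where
depth > 0, agreement ≥ `consensus_fraction`, and the majority differs from
the reference; zero-coverage positions are reported.

## Anchored coordinates

The G of the 5′-GAAAAA occurrence chosen as anchor is position 1; upstream
positions are (−)1, (−)2 … outward; positions past the legacy 3′ end (the
classically accepted terminus, supplied by the user as a motif such as
CCTAGC for the K2 genome — only that one is published) are (+)1, (+)2 …
There is no position 0, and the mapping to 0-based indices is bijective
given (anchor, legacy end); both directions are fuzz-tested. When several
GAAAAA occur, the default policy picks the occurrence nearest upstream of
the ORF start (`anchor_policy: orf_proximal`); `first` is available
because the original convention is ambiguous on this point. Internally all
intervals are 0-based half-open; signed labels exist only at the reporting
boundary (GFF3 `paper_coord` attributes).

## Poly(A) runs

A central poly(A) run is a maximal window that begins and ends on A, has
A-fraction ≥ `purity` (default 0.9) and length ≥ `min_run` (default 12),
and lies ≥ 50 nt from each terminus (so terminal homopolymers are not
mislabelled "central"). For each candidate start the longest qualifying
window is taken via prefix sums; overlaps are resolved longest-first with
ties to the leftmost. The defaults were chosen so that the documented
two-run layouts are separated rather than merged.

## Preprotoxin ORF

The longest forward ORF (ATG…stop, ≥ 60 codons) starting in the 5′ third
of the genome. Kex2 endopeptidase sites are all dibasic (K|R)R pairs with
cleavage after the R — both KR and RR are accepted because the published
annotations mark sites without stating the rule; KK is not a Kex2 site.
N-glycosylation sequons are N-X-[S/T] with X ≠ P. Signal-peptide cleavage
is **not** predicted (no algorithm to reproduce); a user-supplied cleavage
position is accepted and echoed into the report. A C-terminal K/R is noted
as a candidate Kex1 trimming substrate, not modelled.

## Hairpin (3′TRE) scan

All hairpins in the 3′-terminal window (default 120 nt) with stem ≥
`min_stem` (default 4) and loop ≥ 3 are enumerated; each is scored with a
nearest-neighbour stack sum (standard Watson–Crick RNA parameters at
37 °C, kcal/mol → kJ/mol) plus a linear loop penalty (5.6 kcal/mol at loop
4, +0.3 per extra nt); G·U wobble pairs are optional with a flat stack
value. The minimum-ΔG hairpin below 0 is reported. This is a deliberately
reduced model: it has no terminal mismatches, special loop tables,
bulges or multibranch terms, so its ΔG values are **not comparable** with
full secondary-structure predictors and published ΔG figures; only ordinal
properties are asserted (GC stems below AT stems, energy strictly
decreasing with added stacks, all reported values ≤ 0).

## Isotype comparison and variants

The previously-known (shorter) reference is located inside the query by
semi-global alignment (query end gaps free), performed by Biopython's
PairwiseAligner with match 1, mismatch −1, gap open −4 (first gap base)
and extend −1 — the original analysis names only an MSA program with no
parameters, so these are package defaults, exposed in config. Unaligned
query prefix/suffix become the 5′/3′ extras; aligned columns yield the
core identity (terminal gaps excluded, so extras cannot dilute it) and
the variant catalogue (SNV labels in the published `689C > T` style;
`pos ins/del` for indels; labels round-trip through a parser). Core
identity < 0.8 yields a "not the same virus type" status instead of a
partition. SNVs inside the reference ORF get codon-level consequences
(`228T > I` or `synonymous`); everything else is `noncoding`. Alignment
scores are validated in the test suite against an independent affine-gap
DP, itself validated by exhaustive alignment enumeration on tiny inputs.

## Repeated-motif discovery

Every in-region k-mer (default k = 24) is a candidate centroid. Candidate
hit windows are pre-screened with an exact-block pigeonhole index
(max_mismatch + 1 blocks: any window within Hamming ≤ 4 of the centroid
shares one exact block), then verified by Hamming distance. Per genome,
maximal non-overlapping hits are kept left-to-right and labelled A, B, C …
5′→3′. Candidate families are scored first (hit count, then total
matches) and accepted best-first with position claiming, so a shifted
look-alike window cannot pre-empt the true family; families must span ≥ 2
genomes. The original motif was evidently found by inspection — this
greedy clustering is the package's own, deterministic formalisation.

## Synthetic data: what it emulates, and what it does not

The generator plants, at recorded coordinates: a 5′-extra segment, the
GAAAAA anchor, a short leader, a stop-free ORF with planted KR and N-X-S
motifs, 1–2 impure poly(A) runs (impurities interior, so the interval is
crisply recoverable), 24-nt motif copies with a per-copy mismatch budget,
a GC-rich perfect-stem TRE hairpin placed near the legacy 3′ terminus, and
a 3′-extra segment. Three guards keep truth recoverable rather than
ambiguous: no GAAAAA look-alike between the anchor and the ORF start, no
ATG upstream of the planted start codon (either would *legitimately* move
the annotation), and non-A bases flanking each poly(A) run.

Reads are drawn from both strands evenly with i.i.d. substitution errors
and two-level constant phred qualities (sufficient to exercise a
mean-quality filter; no learned error profile). Fragment starts range one
read-length upstream of the 5′ end and are clipped to the molecule, so
terminal fragments truncate at the physical ends — as fragmentation of a
linear molecule produces — which is what keeps terminal bases covered and
recoverable at the simulated depths. Not emulated: indels, adapter
contamination, platform-specific quality profiles, coverage bias. Paired
simulation exists (`simulate_paired_reads`, insert 300 ± 30) but is
cosmetic: the extension algorithm consumes reads individually.
Consequently, passing tests demonstrate correctness of the algorithms
under substitution-error short-read conditions; they do not certify
behaviour under indel-heavy or biased real libraries.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: genomes of
1300–2400 nt at 100× coverage (about 1300–2400 reads per library), 20
genomes per recovery experiment, 100 seeds for motif sensitivity /
specificity, 10⁴ cases for coordinate and alignment fuzzing. These sizes
were chosen so the full suite completes in about a minute while every
claim is still exercised end-to-end. All randomness flows through
explicit integer seeds; identical spec + seed yields byte-identical
FASTA/FASTQ.

## Known limitations

- No scaffolding, bubble popping beyond tip removal, or repeat
  resolution: an exact interior repeat ≥ k breaks the contig (documented
  and tested); the extension stage usually heals it at these genome sizes.
- Ungapped mapping only; indels in reads are not placed.
- Hairpin ΔG is model-specific (ordinal use only).
- VBS/IRE elements are not discovered (no defining rule available);
  rRNA/host identity searches run only against user-supplied FASTA
  databases, so results depend on the database given.
- Deposited-sequence checks (`mdsrna.accessions`) require network access
  to NCBI; the sequences are not bundled.
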