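# Methods

This note documents the models and procedures implemented in `pollenmir`,
the parameter defaults and why they were chosen, what the synthetic data
emulate (and do not), and the numerical conventions.

## Read preprocessing

Reads are kept when their mean phred quality is at least `min_qual`
(default 20) and they contain at most `max_n` (default 0) ambiguous
bases. The exact quality criterion of the original analysis is not
published; mean-phred ≥ 20 is a standard, declared default.

The 3′ adaptor is located by semi-global alignment of the adaptor prefix
against the read: unit mismatch cost, gap cost 2, minimum overlap 6 nt,
and at most 20 % errors per aligned adaptor base. Among feasible
alignments the lowest error rate wins, ties broken towards longer adaptor
overlap and then earlier start. An exact-string fast path handles
error-free reads (the overwhelming majority); the dynamic program is the
fallback. Inserts shorter than 18 nt are rejected; the upper bound of
30 nt is enforced at collapsing. The trimmer is property-tested against an
independent per-start global-alignment oracle.

## Exact mapping

Tags are 18–30 nt, so mapping is exact full-length string matching on
both strands: an 18-mer hash seed index with full-length verification.
`N` never matches. Percentages are read-weighted (each read contributes,
not each unique tag), matching the accounting convention of published
library statistics tables. The mapper is property-tested against a
quadratic brute-force scan, including strand-symmetry under genome
reverse complementation.

## Annotation cascade

Each mapped tag receives exactly one class, the first match in:
structural ncRNA (strand-blind) → known miRNA hairpin (sense) → exon
sense → exon antisense → intron sense → intron antisense → repeat
(strand-blind) → unannotated. Overlap means ≥ 1 shared base at any of the
tag's hits. Design choices where the published order is ambiguous:

* known-hairpin overlap outranks exon overlap so hairpins residing inside
  genes are not lost to the mRNA filter;
* ncRNA and repeat overlap are strand-blind because degraded structural
  RNA and repeat siRNAs occur on both strands; exon/intron classes are
  strand-aware because sense and antisense reads are reported separately.

Known miRNAs are quantified by locating each tag inside the reference
precursor: a tag counts to the mature when its 5′ end is within ±2 nt of
the annotated mature 5′ end and its length within ±2 nt (isomiR
allowance — the original tolerance is unstated); other precursor tags
count to the hairpin only. The candidate pool for novel prediction is
the sum of known-miRNA, repeat-associated and unannotated reads.

## Folding model

Hairpins are detected with a Nussinov-style dynamic program maximizing
total pair weight (G-C = 3, A-U = 2, G-U = 1; minimum loop 3). This is a
deliberately self-contained substitute for a free-energy model: all the
downstream hairpin criteria consume is which mature bases pair with the
opposite arm, for which hydrogen-bond-weighted pairing is an adequate and
exactly testable ranking. The optimum is exact for nested structures and
the traceback is deterministic (ties pair the smaller 5′ index). The
contract (dot-bracket + score) admits a thermodynamic backend without
touching callers. Correctness is tested against exhaustive enumeration of
all nested structures on short sequences.

`evaluate_hairpin` folds windows extending 40, 80 and `window` (default
150) nt beyond the tag on each side and keeps the best accepted
arrangement. Shorter extents are tried because maximum-weight folding of
a long window can bury a clean stem in spurious long-range pairings; a
real hairpin is accepted in at least one extent. Acceptance requires the
mature fully on one arm, ≥ 16 mature bases paired against the opposite
arm, ≤ 4 unpaired, bulge asymmetry ≤ 2 nt within the duplex, and no
mature/loop overlap. The star is placed by the canonical 2-nt 3′ overhang
geometry using the *median duplex register* (the median of p+q over all
mature pairs): partner estimates q(p) = r − p are robust to register
slippage of a few terminal pairs across internal loops.

## Novel miRNA filter stack

F1 single genome locus; F2 total reads ≥ 5 (the source text states both
"fewer than five eliminated" and "greater than five" kept — the boundary
count of exactly 5 is retained, configurable); F3 no opposite-strand read
coverage over the locus; F4 hairpin acceptance; F5 no similarity to the
repeat library — implemented as an edlib infix edit-distance search at
≤ 20 % of query length in either orientation, a conservative reading of
"≥ 80 % identity over ≥ 80 % of length" (the original BLAST cutoffs are
unstated); F6 mature 20–24 nt; F7 expressed in ≥ 2 libraries or star
detected among tags (±2 nt tolerance); F8 ≥ 1 predicted target. Every
filter decision is recorded per candidate. Survivors are deduplicated by
precursor locus (a mature and its star nominate the same hairpin; the
more abundant tag wins) and numbered miR-N1, miR-N2, … in genomic order.

## Expression

TPM = 1e6 × count / clean 18–30-nt reads of the library. Enrichment
combines ratio > 2 and Z-score > 2. Sample scope: ratio against the mean
of the other five libraries; z on the six-sample profile with the
population (n) standard deviation. Group scope (pollen = UNM/BCP/TCP vs
sporophyte): ratio of group means; z of the group's most extreme member.
sd = 0 ⇒ z = 0 (flat profiles are never enriched); values equal up to
floating round-off count as flat. A consequence of this standard form is
that a profile with one elevated sample over a flat background has
z = √5 ≈ 2.236 regardless of the fold change — the z cutoff only bites
when the background itself varies.

Clustering is Lloyd K-means on log2(TPM + 1) (pseudocount 1), 10 restarts
with a fixed seed; defaults k = 18 for known and k = 8 for novel miRNAs,
clamped to the number of profiles in small runs. PCA operates on the
samples-by-miRNAs log2 matrix with per-miRNA mean-centering only (no
unit-variance scaling), via SVD; explained-variance fractions are
eigenvalue shares, and a miRNA's score contribution to a component is its
loading scaled by the component standard deviation, so contributions are
on the log2-TPM scale and the |contribution| > 2 reporting cutoff is
meaningful there.

## Target prediction

The miRNA is aligned antiparallel to every transcript window of its
length ±1 (≤ 1 single-base bulge). Penalties: mismatch 1.0, G:U 0.5,
bulge 2.0; ×2 over miRNA positions 2–13; acceptance at ≤ 3.0. These
constants emulate the miRU/psRNATarget convention and are configurable —
none are published in the source analysis. The predicted cleavage site is
the bond opposite miRNA nucleotides 10/11, reported as the transcript
coordinate of the first base of the downstream fragment (the base paired
to nucleotide 10), matching 5′-RACE read-out. The production scanner is a
numba kernel, cross-checked in tests against the pure-Python reference
scorer. Note that the full position-weighted score is not symmetric
between the two duplex strands (the core weighting is anchored at the
miRNA 5′ end, and complementing both bases of a G:U wobble gives A:C);
the physically symmetric property — invariance under swapping which
strand is called the miRNA, with uniform weights — is what the tests
assert.

Expression correlation is Pearson's r on log2(x + 1) profiles over the
six libraries; negative at r ≤ −0.5, positive at r ≥ 0.5, zero-variance
profiles flagged and classed uncorrelated.

## GO abundance

One-sided hypergeometric upper-tail p per term with ≥ 1 query hit,
Benjamini–Hochberg adjustment across tested terms, significance at
FDR < 0.01. Term sets are flat (no propagation up the GO graph); the
background universe defaults to all genes in the annotation table.

## Synthetic data

The generator plants, at known non-overlapping coordinates in an 80-kb
toy genome: known miRNA hairpins (in the hairpin reference), novel
hairpins (absent from it, ~1/4 on the minus strand), rRNA/tRNA/snRNA/
snoRNA loci, 30 genes with 3 exons and 2 introns, annotated repeats
including a perfect inverted-repeat MITE, and one *unannotated* MITE copy
diverged ~8 % from the consensus — single-locus, hairpin-folding, and
removable only by the repeat screen. Hairpin star arms carry two
substitutions relative to the perfect reverse complement so the mature
maps to a single locus (a perfect inverted repeat would self-match on the
minus strand); each drawn hairpin is validated by the pipeline's own
evaluation in random context and redrawn if the fold is not robust or if
the draw is, by chance, a repeat homolog under the F5 screen (planted
hairpins must pass every filter by construction — without this check a
random 21-mer occasionally sits within the edit-distance threshold of a
repeat-library sequence and is then *correctly* discarded by F5, breaking
the recovery bookkeeping rather than the pipeline). Every
planted miRNA has a target site embedded in a distinct exon: one known
miRNA gets a perfect-complement site, all others carry two non-pairing
substitutions facing miRNA positions 15/18 (penalty 2.0) so that novel
matures stay single-locus. Gene expression truth anti-correlates target
hosts with their miRNA (one positive-control pair), and the GO table
assigns a chromatin assembly/disassembly term to the novel-target host
genes against a 300-gene universe.

Expression classes are template profiles (constitutive; pollen- or
sporophyte-enriched with a dominant member; stage-specific with all mass
in one library) scaled by a random amplitude — scaling preserves both the
ratio and the z-score, so class labels provably satisfy the enrichment
definitions on the expected TPMs (asserted in tests). Six libraries are
simulated with Poisson read counts at TPM × depth for matures (stars at a
0.25 ratio), repeat-derived siRNAs whose 21/24-nt length mixture shifts
from 24-dominant (UNM, callus, root) to 21-dominant (TCP, leaf),
degradation fragments of transcripts, pre-mRNA and ncRNA (uniform
18–30-nt substrings, sources weighted by length), a small antisense and
noise fraction, short inserts, 2 % low-quality reads and a 0.003/base
substitution error model (at most one substitution per read — errors are
rare at these rates and only need to exercise the quality/trimming
fallbacks). Reads are insert + 3′ adaptor truncated to 36 nt, phred+33.

Default problem sizes — 80-kb genome, 12 known + 15 novel hairpins,
60,000 reads per library (40,000 in the test suite) — keep a full run at
well under a minute while giving every stage-specific miRNA ≥ 50 expected
reads and every star ≥ 10, so recovery statistics are stable across
seeds.

What passing on synthetic data does *not* show: real libraries have
sequencing-instrument error profiles, PCR duplicates, isomiR spectra,
overlapping/nested genome annotation, multi-mapping repeat families at
scale, and miRNA families with near-identical matures — none of which are
emulated. The pipeline's behaviour on such data is constrained only by
the unit contracts, not by the recovery results.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open everywhere internally; GFF3 output is
1-based inclusive. All randomness flows from explicit integer seeds
(numpy `default_rng`); reruns are byte-identical and verified via a
SHA-256 artifact manifest. Ties in folding tracebacks prefer the smaller
5′ index; K-means uses a fixed `random_state`. Division guards: empty
libraries report zero fractions; all-zero expression rows are never
enriched; zero-variance profiles yield z = 0 and "uncorrelated";
a constant expression matrix is a PCA error; an empty GO query returns an
empty result with a warning; infeasible feature packing and all-zero
expected TPMs raise named errors.
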