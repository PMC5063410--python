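# Methods

## Locus model and junction probes

A locus is one plus-strand sequence with ordered, non-overlapping exons in
0-based half-open coordinates (minus-strand input is reverse-complemented
at load time). Junctions are ordered exon pairs: forward junctions have
the donor strictly upstream of the acceptor; back-splice junctions have
the donor at or downstream of the acceptor. Self-circles (donor ==
acceptor) are enumerable but excluded from default reporting, since
single-exon circles are never observed in this assay; a flag includes
them.

A junction is detected through its *probe*: the last F bases of the donor
exon concatenated with the first F bases of the acceptor. F defaults to
10, giving a 20-mer that spans the splice (or circularisation) point; it
is a configuration knob everywhere it is used. A read supports a junction
iff the probe matches at some offset of the read or its reverse
complement with Hamming distance ≤ `max_mismatch` (default 1). The
mismatch budget applies to the whole 2F-mer, the stricter of the two
possible readings (per flank vs per probe); it is configurable. Mismatch
counting is substitution-only; probes are required to be unique within a
probe set (an error otherwise), and reads tying between two probes at the
minimum distance are excluded as ambiguous and reported separately, so
counts are never double-booked and assigned + ambiguous + unassigned
always equals the input read count.

## Synthetic locus

The cloned construct the assays were designed against is not publicly
available, so the package ships a synthetic stand-in
(`synthetic_reference.synthetic_locus`): 950 nt of seeded uniform-random
sequence carrying five exons — exon 1 (60 nt), exon 2 (100 nt), exon 3
(40 nt), the unannotated intron-3 exon "3*" (40 nt), and exon 4 (36 nt).
The generator regenerates deterministically until no assay primer occurs
in the sequence and all junction probes are unique, the well-posedness the
real construct satisfies. Exon sizes were chosen once so that on 2×150
amplicon reads every 5′ junction (donor exon 1) falls in mate 1 and every
3′ junction (donor exon 2) falls in mate 2 with ≥18 nt of anchorable
sequence on each side, and so that the exon 2+3 circle (140 nt) is shorter
than one read. Exon 3*'s placement inside intron 3 is configurable in the
layout table; its coordinates are not known from the source data.

## Read simulator

The simulator is the ground-truth instrument for every pipeline test; its
defaults are the study conditions and are not tuned per experiment.

**Bulk libraries.** Each read pair is a 2×150 slice of a tagged PCR
product: common forward tag + channel primer + spliced template +
reverse-complemented reverse primer + reverse tag, using the published
primer and tag sequences. Isoforms are drawn multinomially from a mixture;
the default mixture is the published junction composition of the
exon1→exon4 amplicon: 23.2% exon-1→3* skipping, 5.7% exon-1→4 skipping,
and the remaining 71.1% carrying the 1–2 junction, split 12.9% / 4.7% /
82.4% between 2–4, 2–3* and canonical 2–3 on the 3′ side. Substitution
errors are iid per base at 0.2% (the rate used for the single-cell
recovery experiment, adopted as the global default; typical for the
sequencing chemistry). Circular templates are rotated so the back-splice
donor leads, placing the back-splice junction inside mate 1's template
window.

**Single-cell libraries.** Per cell and isoform, molecule counts are drawn
from a Poisson (default means: 64 linear, 11 circular molecules per cell —
the study's absolute estimates; a fixed-count family exists for
deterministic tests). Each molecule receives a uniform random 8-nt UMI and
a uniform 3–30 read pairs. Read 2 carries the published architecture:
Clontech PCR Primer IIA, Nextera read-2 sequence, 4-nt channel filler
(TCGA linear / AGCT circular), the UMI, then the channel RT primer,
followed by template.

**Artifact classes.** RT chimeras (default rate 5%, the rate at which the
filter is validated) replace a pair's read 2 with the other channel's
architecture — exactly the discordant-primer signature the filter removes.
Rolling-circle reads model reverse-transcriptase strand displacement on
circles: each circular molecule emits extra read pairs (binomial in its
read count, default rate 10%) whose template is the tandem-duplicated
circle. With the default 140-nt circle a 92-nt template window shows the
back-splice once per traversal, so the artifact manifests as read-count
inflation of the circular channel rather than multi-junction reads; this
is the minimal form of the artifact that biases read-based but not
UMI-based quantification. PCR amplification is modeled as independent
duplication without lineage structure — sufficient to exercise UMI
collapse, though it does not reproduce jackpot amplification or
polymerase-error propagation seen in real libraries. Quality strings are
constant ('I'); no pipeline stage uses qualities.

What passing tests show, therefore, is that the pipelines invert this
generative model at realistic error rates — not that they are robust to
real-data features the generator omits (indels, quality-correlated errors,
primer synthesis errors, cross-cell index hopping).

## Bulk pipeline choices

*Demultiplexing* uses exact substring matching of the published primers
(grep semantics): one channel hit assigns the pair, hits in two channels
flag it chimeric-like, none leaves it unassigned.

*Clustering* is greedy and abundance-ordered: unique sequences sorted by
multiplicity (lexicographic tie-break), each unclustered seed absorbing
later sequences within the identity threshold (default 0.99, k-mer
prefilter k = 10). Identity is 1 − editdistance/max(length), computed with
edlib; the published tool's "matches over alignment length" is equivalent
up to the treatment of terminal gaps, and this form is deterministic and
cheap. Clusters need ≥5 reads to proceed.

*Anchoring* finds all maximal exact matches ≥18 bp between a cluster
representative and the locus, both orientations, by k-mer seeding and
maximal extension, implemented natively so it is testable per-operation.
The match-cluster length 25 maps to a minimum total anchored span of 25 bp
per representative. Consecutive anchors (in query order, within the
orientation carrying more anchored sequence) whose reference gap differs
from their query gap define a breakpoint; breakpoints snap to exon
boundaries within 3 bp (maximal matches can chance-extend a base or two
across a junction when flanking genomic bases coincide), and are reported
when supported by more than 1% of channel reads.

*Fractions* are computed over reads assigned to any probe of the channel,
matching per-amplicon denominators; the unassigned and ambiguous tallies
are carried in the output so any other denominator can be reconstructed.

## Single-cell pipeline choices

Chimera removal compares the channel of the forward primer on mate 1 with
the channel of the RT primer on mate 2 and drops disagreements before any
per-cell total is computed. Channel splitting uses the RT primer in read
2. The UMI is parsed by anchoring: locate the RT primer, take the 8
preceding bases — tolerant of upstream indels, undefined (and excluded
from UMI quantification, though still counted in raw reads) when the
primer is not found exactly.

"Perfectly matched" is interpreted as zero mismatches within the junction
probe window, not the whole read: at a 0.2% per-base error rate a 150-nt
read is error-free only ~74% of the time, which would make a ≥2-perfect
threshold needlessly lossy, while the 20-nt window is error-free ~96% of
the time. The window is the configurable probe itself. UMIs are compared
exactly — no 1-edit merging — so defaults reproduce the published
procedure; a Hamming-1 merge exists behind a flag. A molecule is a
distinct (cell, channel, junction, UMI) group with ≥2 perfect-match reads
(`min_perfect`, configurable).

Cell identity comes from per-cell demultiplexed files (manifest TSV) in
real data; the simulator carries cell ids in read names. Classification
labels a cell linear-dominant or circular-dominant when the channel holds
a majority (>0.5) of its molecules, low-expression below a 5-molecule
floor; neither threshold comes from the source study and both are recorded
in output metadata. The mutual-exclusivity statistic is a Fisher exact
test on expressing-vs-not contingency across cells; on independent
expression it is calibrated (no signal), which the tests verify across
repeated simulations.

The expected number of distinct UMIs among m molecules follows the
birthday formula 4^L(1 − (1 − 4^−L)^m); at L = 8 and the study's per-cell
counts, collisions cost well under one molecule per cell, so UMI-collapsed
means are compared directly against the simulated Poisson means.

## qPCR statistics

Fold changes use 2^−ΔΔCt with efficiency fixed at 2.0 (no standard-curve
correction). ΔΔCt is computed replicate-wise with replicates paired by
index; because "fold change of the mean ΔΔCt" and "mean of replicate
folds" differ under Jensen's inequality, both are reported.
Linear:circular ratios are per-replicate 2^−(Ct_linear − Ct_circle)
summarised by geometric mean (equivalently the mean ΔCt), so the
reference construct's normalised ratio is exactly 1 by construction.
Box-plot summaries use type-7 (linear interpolation) quartiles — the
convention is recorded in the output — and whiskers are the most extreme
observations within 1.5×IQR of the quartiles.

## Problem sizes and numerical notes

The analysis scripts and acceptance checks use 100,000 bulk read pairs and
50 cells — the scales at which binomial/Poisson standard errors are small
enough to resolve the reported percentages — with breakpoint clustering
run on a 10,000-pair subsample (greedy clustering cost grows with the
number of unique error-bearing sequences, and breakpoints are
cluster-level calls that do not gain from deeper sampling). All randomness
flows through a single seed; simulator output is byte-reproducible for a
fixed seed. Degenerate inputs fail loudly: empty exon tables, empty
probe or primer sets, zero channel totals, unpaired qPCR replicates and
empty value sets all raise errors rather than returning silent zeros;
zero-molecule channels with nonzero reads report an infinite
overestimation ratio with a flag.

## Known limitations

* Indel-tolerant probe matching is off by default (substitution-only
  Hamming), so junctions adjacent to homopolymer indel errors can be
  undercounted.
* The breakpoint caller assumes representatives chain along one
  orientation; chimeric reads mixing orientations within one mate are not
  split.
* The generator does not simulate branching PCR lineages, quality decay,
  or cross-channel index hopping; conclusions about those failure modes
  cannot be drawn from these tests.
* The plasmid-control simulation uses fixed ±50 nt windows around the
  control exons rather than the real plasmid's full sequence.
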