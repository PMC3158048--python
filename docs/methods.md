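# Methods

`altsplice` analyses alternative mRNA isoform usage between two conditions
from short-read RNA-seq, the setting typified by an epithelial–mesenchymal
transition (EMT) time-zero/endpoint comparison: one sequencing library per
condition, single-end short reads (39 bp by default), and a reference
annotation from which alternative-isoform events are derived rather than
discovered de novo.

## Event model

Eight event types are derived from pairwise comparison of the annotated
transcripts of each gene: skipped exons (SE), retained introns (RI),
mutually exclusive exons (MXE), alternative 5′/3′ splice sites (A5SS/A3SS),
alternative first/last exons (AFE/ALE), and tandem 3′ UTRs. Every event
carries two disjoint *segment signatures* — sets of exon bodies, splice
junctions and UTR extensions that are unique to each isoform. For an SE
event, the inclusion signature is the alternative exon body plus its two
flanking junctions; the exclusion signature is the single skipping junction.
This uniform representation lets one read-counting rule serve all eight
types.

Classification precedence within a transcript pair is
RI > MXE > SE > A5SS/A3SS > AFE/ALE > TandemUTR; a lower-precedence
candidate that would re-claim a segment already assigned in the same pair is
suppressed. AFE/ALE require non-overlapping terminal exons; overlapping
terminal exons that share a splice site fall to A5SS/A3SS. All 5′/3′ and
upstream/downstream language is transcript-oriented, so minus-strand events
mirror genomic order. Duplicate events arising from different transcript
pairs are merged on (type, chrom, strand, sorted segment coordinates), which
is also the event-id key. Internally all coordinates are 0-based half-open;
GTF I/O converts to and from 1-based inclusive at the boundary (BED and SAM
interoperate without conversion).

## Ψ estimation

The percent-spliced-in value of an event is

  Ψ = d_inc / (d_inc + d_exc),

where each density d is supporting reads divided by the number of distinct
mappable read-start positions for that signature. A junction offers
`read_length − 2·min_overhang + 1` start positions (default 39 − 8 + 1 =
32); an exon body of length L offers `max(L − read_length + 1, 1)`. A read
supports a junction when two consecutive blocks end/start exactly at the
donor/acceptor with at least `min_overhang` (default 4) aligned bases on
both sides, and supports an exon-body segment when it is unspliced and lies
entirely within the segment. Whole-read containment (rather than
any-one-block containment) is deliberate: it makes the observable start
positions of a body segment exactly L − r + 1, so inclusion and exclusion
densities are estimates of the same per-position sampling rate and Ψ is
unbiased; crediting partial blocks of spliced reads to exon bodies inflates
body densities relative to the position model (we measured a ~0.07 absolute
Ψ bias for tandem UTRs at high depth before adopting containment).

Ψ is reported as undefined — not zero — when no read supports either
isoform, and undefined events are excluded from downstream testing. Tandem
3′ UTR events use the variant estimator Ψ = d(extension)/d(core), the
fraction of transcripts reading through to the distal site, clamped to
[0, 1]. Reads are treated as unstranded (typical for this library
protocol).

Gene expression is RPKM over the gene's constitutive exons (the per-base
intersection of its transcripts' exon footprints, merged): reads mapped
within constitutive exons / (kb of constitutive model) / (millions of
mapped reads).

## Differential tests

**Expression.** The Audic–Claverie exact test for counts x, y from
libraries of sizes N1, N2: under equal representation,
P(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) with r = N2/N1 (a negative
binomial law; the x+y+1 exponent normalizes the distribution). The reported
p doubles the smaller cumulative tail, capped at 1, computed in log space
(stable to counts of 10^6). Note the doubled-tail p is only approximately
exchange-symmetric: the pmf satisfies P(y|x) = P(x|y) at N1 = N2, but the
two orderings condition their tail sums on different observed counts.
Significance combines BH-adjusted p ≤ α (default 0.05) with an RPKM fold
change ≥ 3 (or ≤ 1/3); infinite fold changes (zero in one condition) are
capped at 2^15 for reporting.

**Splicing.** Each event is tested with a two-sided Fisher exact test on
the 2×2 table (inclusion reads, exclusion reads) × (condition 1, condition
2), followed by BH FDR over all tested events. With one library per
condition the sampling units are reads, which is anti-conservative for
biological inference — the test asks whether the read evidence could have
arisen from one isoform ratio, not whether cultures differ. ΔΨ is
Ψ(condition 2) − Ψ(condition 1); its sign gives the inclusion-direction
label. Event filters (defaults |ΔΨ| ≥ 0.10, FDR ≤ 0.05, both inclusive)
and the gene-level summary (fraction of tested genes with ≥ 1 passing
event) follow from there.

BH adjustment is implemented directly (step-up with order-invariant output
and shared values at ties) and cross-checked against statsmodels in the
test suite.

## Motif enrichment

For each regulated skipped exon the four flanking intronic regions of up to
250 nt are extracted, transcript-oriented, keyed (upstream_intron |
downstream_intron, I5 | I3) where I5 abuts the donor and I3 the acceptor of
its intron. When an intron is shorter than 500 nt the two regions truncate
at the midpoint (I5 takes the extra base of an odd-length intron) and never
overlap. Sequences are reported as RNA; minus-strand regions are
reverse-complemented.

Pentamer enrichment of a foreground (regulated, split by ΔΨ direction) over
a background of unchanged events (defaults FDR > 0.5 and |ΔΨ| < 0.05, both
isoforms detected) counts all overlapping 5-mer windows (step 1; windows
containing N are skipped). Per region class and pentamer, the hypergeometric
upper tail is taken with population = pooled fg+bg windows, successes =
pooled occurrences, draws = fg windows, observed = fg occurrences; BH FDR is
applied within each region class over the observed pentamers. Reporting
conventions: FDR < 0.1 to report, FDR < 0.05 to highlight. Pentamers are
annotated with splicing-factor motif families (RBFOX, ESRP, MBNL, CELF,
hnRNP F/H, PTB, hnRNP L, else Other) from a precedence-ordered pattern
table shipped as editable package data (`data/motif_families.tsv`).

CLIP-cluster association is a hypergeometric upper tail on the overlap of a
foreground event set with cluster-bearing events inside a stated universe;
an event bears a cluster when its span (introns + alternative exon, plus an
optional window) intersects a cluster interval.

## Signature analyses

Sample classification clusters samples on 1 − Pearson distance with average
(UPGMA) linkage (the distance follows the correlation matrices this kind of
analysis reports; the linkage is our choice). The dendrogram is cut into
two groups at the top split and misclassification is minimised over the two
label-to-cluster mappings. The randomized-clustering significance draws
|fg| event rows uniformly without replacement from the full panel, reclusters,
and reports p = (1 + #{draws with ≤ observed misclassifications}) /
(n_perm + 1) — the add-one estimator, which can never return 0 and is
(super-)uniform under a null foreground.

Coherence between two datasets is the fraction of shared events whose
inclusion change has the same sign (zero deltas excluded). Event-event
analysis on clinical-style panels computes pairwise-complete Pearson
correlations (pairs with < 3 shared observations are treated as missing),
clusters events on 1 − r, and attaches to each branch an ordinary bootstrap
probability — the fraction of sample-resampled dendrograms containing the
branch. This is a deliberate simplification of multiscale-bootstrap AU
support: plain bootstrap probabilities are biased toward 0.5 for deep
branches but require no extrapolation machinery. Dendrograms are exported
as newick with branch supports.

## Synthetic data

The generators emulate the target study design so every stage is testable
without external downloads: two conditions, Poisson read counts (a single
library per condition offers no replicate-based dispersion estimate; a
negative-binomial mode exists for robustness checks), uniform positional
coverage (no fragmentation bias — a known mismatch with real libraries),
39-bp single-end reads, planted per-event Ψ per condition, planted
expression fold changes, optional planted flank motifs, and planted
two-class Ψ panels. Every generator is a pure function of its arguments and
seed; regeneration is byte-identical.

The standard fixture is 90 genes — 10 events of each of the eight types
(one event gene each) plus 10 single-isoform genes — at 2×10^5 reads per
condition, which yields a median of roughly 800 informative reads per event
and Ψ sampling error ≈ 0.02–0.03. Gene expression is log-normal (σ = 0.5);
planted ΔΨ effects default to ±0.4 from a base Ψ uniform in (0.25, 0.75),
clamped into [0.02, 0.98]. Panels plant a class-mean difference of
`effect_dpsi` on a random half of events with randomized sign, Gaussian
noise, clamping to [0, 1] and optional missingness.

What passing these tests does *not* show about real data: alignment error,
positional bias, overdispersion across biological replicates, annotation
incompleteness and mappability artefacts are all outside the generative
model; the pipeline consumes aligned placements and an annotation as given.

## Numerical and design notes

- Tie-breaks: BH ties share the adjusted value; the top-ranked enriched
  pentamer is chosen by (FDR, then p). Event ids order catalogs
  deterministically.
- Degenerate inputs: constant sample vectors are an error naming the
  sample; constant event rows are dropped with notice; all-zero 2×2 tables
  and events with undefined Ψ are skipped; empty catalogs and empty filter
  results are valid.
- The permutation and bootstrap routines take explicit seeds and are
  bit-reproducible for a given seed.
- The package is a library: the importable API plus the `examples/`
  scripts are the interface, and the simulators are ordinary functions
  rather than a command-line tool.
- Test problem sizes (200-event Ψ grids at 10^4 reads, 2,000-event null
  panels, 100-replicate motif and classification recoveries, 999-draw
  permutations) were chosen so the full property suite completes in a few
  minutes on one core while leaving clear statistical margins.
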