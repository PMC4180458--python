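# Methods

## NSR primer design

The primer pool is the full lexicographic enumeration of DNA k-mers
(default k = 6; 1 <= k <= 12 is supported, bounded by the cost of holding
the enumeration in memory). Filtering removes every k-mer with a perfect
substring occurrence in the rRNA reference. Because the published
descriptions of the approach are ambiguous about orientation, the strand
convention is an explicit parameter:

- `sense` (default) — the k-mer itself occurs in an rRNA transcript;
- `antisense` — its reverse complement occurs;
- `both` — either.

`sense` is the default because the first-strand primer anneals to the RNA
template: a primer whose sequence appears in the rRNA *as written* is the
one complementary to rRNA's antisense context; in practice users should
record which mode they used (the output carries the mode and a checksum of
the reference). Retained order is the enumeration order, so oligo sheets
are reproducible byte-for-byte.

Reference handling: sequences are uppercased and U is converted to T on
ingest (rRNA references are often distributed in the RNA alphabet). IUPAC
ambiguity letters are tolerated but windows containing them can never be
matched — a primer cannot perfectly pair with an ambiguous base; characters
outside the IUPAC alphabet are an error naming the record. Records shorter
than k contribute nothing and produce a warning rather than an error.

Coverage statistics count *distinct* set members per target transcript and
the mean spacing between match start sites; overlapping occurrences are all
counted because each is an independent priming start site. The spacing
(density) is reported as absent when there are no occurrences.

Adapter-bearing oligos follow the two-adapter template (first strand
`adapter1 + N + revcomp(hexamer)`, second strand `adapter2 + N + hexamer`)
with the published default annealing sites `TCCGATCTCT` / `TCCGATCTGA`;
both adapters are configurable and validated as IUPAC DNA.

## Read classification and RPKM

Coordinates are 0-based half-open internally (SAM/BED interoperable) and
1-based closed in human-readable reports. Only primary alignments are
used. Each read receives exactly one category by fixed priority:
rRNA > sense-exonic mRNA > known ncRNA > antisense of coding exons >
intronic > intergenic. Overlap of >= 1 base (configurable) with the
relevant feature qualifies. rRNA and intron overlaps are strand-agnostic;
mRNA and ncRNA assignment requires the read strand to equal the transcript
strand, and "antisense" is defined only against coding (mRNA) exons.
Unannotated-transcript (TUF) loci are grouped with known ncRNAs for
classification. Reads on spike-in contigs are tallied separately and
excluded from the genomic breakdown, whose six fractions sum to 1.

Counting increments every transcript whose exons a read overlaps
(sense-only in stranded mode); no fractional assignment is made, which is
simple, reproducible and flagged in the documentation of the output. The
library size is *all* primary alignments of the sample — including rRNA
and spike-in reads — because rRNA content is conventionally reported as a
percentage of mapped reads, which implies it sits in the denominator.

RPKM = count / (exonic length in kb) / (library size in millions),
verified cell-wise in tests by exact inversion back to counts.

## Spike-in bias estimation

Observed spike-in RPKM is correlated with the ladder's reference
concentrations after log10 transformation with a pseudocount of 0.01 RPKM
(a 10^6-fold ladder makes linear Pearson degenerate — the top species
dominate the fit; linear scale remains available). Species with fewer
than `min_count` reads (default 5) in a sample are treated as below the
detection limit and excluded from that sample's correlations: at the
bottom of the ladder, log-scale Pearson measures shot noise rather than
priming bias. The detected-species count is reported alongside each
correlation. Pairwise sample-vs-sample correlations are computed over
species detected in both samples, and an all-transcript pairwise matrix
provides the replicate-agreement view. Zero-variance inputs yield an
explicit "undefined" (None) rather than NaN propagation.

## Differential calling and summaries

Calling is purely threshold-based to mirror how intermediate-size ncRNA
surveys are typically analysed (no dispersion model; replicates are rarely
available at this scale): a locus passes when max(RPKM_a, RPKM_b) >
`rpkm_min` (default 1) and the pseudocounted ratio clears `fc_min`
(default 2) in either direction. The RPKM gate applies to the *larger*
sample so that on/off loci — which the repressed/activated language
explicitly includes — are not silently dropped. The pseudocount
(default 0.01 RPKM) keeps on/off ratios finite; both knobs are exposed.
"Repressed" means higher in the mutant (the regulator normally represses
the locus), "activated" the reverse; swapping the two samples exactly
inverts every fold change and flips the labels.

One call is produced per transcript in the expression table; analyses of
ncRNA regulation should subset to the ncRNA universe before summarising,
because spike-in species and other very low-count transcripts near the
detection limit can produce extreme pseudocounted ratios that clear the
thresholds spuriously.

Per-chromosome enrichment uses a one-sided exact binomial test of the
observed passing-locus fraction against the chromosome's share of the
annotation universe (all annotated ncRNA loci, not all genes — the
comparison population the question is about). No multiplicity correction
is applied by default; Bonferroni is available.

Clustering is single-linkage chaining along each chromosome: passing loci
whose successive start coordinates lie within `max_gap` (default 10 kb)
merge, chains with >= `min_size` (default 3) members are reported, and by
default members must share a direction. No published criterion exists for
these clusters, so the defaults are recorded in every output header and
the result is deterministic and order-invariant.

Status shifts compare the passing direction of each locus between two
contrasts (e.g. untreated vs irradiated); a record exists only where the
directions differ, and the repressed-to-activated subset is separately
countable.

The 2^-ddCt calculator pairs replicate Ct series, computes
ddCt = (Ct_target,sample − Ct_ref,sample) − (Ct_target,control −
Ct_ref,control) per replicate, and reports fold = 2^−mean(ddCt) with the
SEM on the ddCt (cycle) scale, where error propagation is additive.

## Promoter motif scanning

Promoter windows span 2 kb upstream to 500 bp downstream of the TSS in
transcription orientation (reverse-complemented for minus-strand loci so
position 0 is always the most-upstream base); windows are clipped at
chromosome ends with a warning. Each annotation record contributes its own
TSS; collapsing multi-isoform genes to the most-upstream start is the
caller's responsibility since the toolkit's annotation model is
locus-level.

Patterns are IUPAC strings; `RRRCWWGYYY` (the p53-family half site)
expands to exactly 2^3 x 2^2 x 2^3 = 256 concrete 10-mers, and scanning is
verified in tests against that exhaustive expansion. Degenerate letters
are expanded on the pattern side only — an N in the genome matches
nothing (conservative). Both strands are scanned by default because
p53-family response elements are functional in either orientation. Hit
offsets locate the match's most-upstream base relative to the TSS,
negative upstream, matching the way such positions are conventionally
reported.

## Synthetic data generator

The generator emulates the study design the toolkit targets: two genotypes
(wild type, regulator-deficient mutant) by two treatments (untreated,
UV-irradiated), single-end 80-nt stranded reads, a genome at 36% GC (the
*C. elegans* genome-wide value) partitioned into six chromosomes, and a
92-species polyadenylated spike-in ladder spanning 250–2000 nt and a
10^6-fold concentration range. Default locus content: 2 rRNA loci, 30
multi-exon mRNAs, 200 single-exon ncRNAs, 12 TUF-sized loci, placed with
>= 2.2 kb inter-locus gaps so every promoter window is uncontested.

Expected counts per locus are a per-category read budget shared equally
across the category's loci, multiplied by a lognormal inter-locus factor
(sigma on the log10 scale, default 0.1). The factor is drawn once per
locus and shared across samples, so a locus's fold change between
conditions is perturbed only by Poisson counting noise — the natural
reading of expression noise that is a property of the locus, not of the
sample. Counts are Poisson draws around the expectation;
`count_model="exact"` rounds instead, giving byte-identical deterministic
fixtures (verified by checksum in tests). Planted differential loci
multiply (repressed) or divide (activated) the mutant's expectation by the
planted fold (default 2.5 at 20 loci, 10 of them arranged in three
same-direction clusters with 4-kb start-to-start spacing, scattered loci
biased toward chromosomes X and V to plant an enrichment signal). Ten
repressed loci switch to activated in the UV contrast, planting exactly
ten status shifts. Concrete motif instances are written into the upstream
gap of 40 of the first 100 ncRNA promoters.

Problem sizes are chosen so that the statistics, not the computation,
limit what the fixtures can show: 100,000 genomic reads per sample with
80% of the budget on the 200 ncRNA loci gives ~400 reads per locus, where
Poisson noise on a log10 ratio (~0.03) sits well inside the 2-fold
threshold's margin around the planted 2.5-fold signal — emulating the deep
real libraries, where called loci have ample counts, at desk scale. The
default read mix is therefore ncRNA-focused; the observed genomic category
mix of the original untreated wild-type worm sample is provided as
`N2_CATEGORY_MIX` for classification-style fixtures, and `exact_mix=True`
apportions category totals exactly (largest-remainder) for fixtures whose
fractions must be recovered exactly.

The spike ladder's expected counts are proportional to concentration x
length, scaled so the top species expects 1,500 reads; the most- and
least-concentrated species are assigned similar lengths so the expected
read counts span the configured dynamic range within a factor of ~2. An
optional priming-bias mode restricts read start positions to sites
matching a supplied hexamer set, for qualitative exploration of NSR
coverage unevenness.

What the fixtures deliberately do **not** model: sequencing errors and
quality-score structure, spliced (junction-spanning) reads, multi-mapping,
adapter contamination, replicate-level biological dispersion (no negative
binomial — there is no replicate information to calibrate one), positional
or GC priming bias by default, and any UV-response biology beyond the
planted direction switches. Passing tests therefore demonstrate correct
arithmetic, bookkeeping and recovery of signal under counting noise — not
robustness to alignment artefacts or real biological variance.

Every planted quantity is recorded in a `TruthLedger` (per-locus counts
per sample, per-category read totals, planted folds and directions,
cluster memberships, motif offsets and instances, spike expectations), and
an infeasible specification fails validation before any file is written.

## Numerical and formatting choices

- Fold-change pseudocount 0.01 RPKM; correlation pseudocount 0.01 RPKM;
  spike detection threshold 5 reads — all configurable.
- Percentages in reports are rounded half-up to two decimals, matching the
  conventional table style; correlations print to three decimals.
- Cluster and call outputs are sorted deterministically; every CLI run
  writes its resolved configuration as JSON, and reruns with identical
  inputs are byte-identical (no timestamps; one seed governs all
  randomness).
- Pearson correlation is reported as undefined (not NaN) for degenerate
  inputs; fewer than three common spike species is an error.

## Known limitations

- Filtering is exact-match only; near-match (1-mismatch) rRNA priming is
  out of scope, as are melting temperature and secondary-structure
  screens of the oligos.
- The genomic 939-hexamer worm NSR set cannot be regenerated without the
  original rRNA transcript set, which is distributed only as journal
  supplementary material; the filter is instead validated against
  brute-force substring-inventory oracles at the same sequence scale.
- Multi-overlap reads are counted once per overlapped transcript, which
  double-counts reads in overlapping annotation; the fixtures avoid
  overlapping loci, so real annotations deserve scrutiny here.
- The spike-in correlation's detection threshold trades a small survivor
  bias for robustness to shot noise; reported detected-species counts make
  the trade visible.
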