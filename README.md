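# nsrseq

A toolkit for **"not-so-random" (NSR) primed RNA-seq**: design
rRNA-depleting hexamer primer sets from any rRNA reference, quantify the
resulting libraries (read classification, RPKM), measure priming and
amplification bias against an external spike-in ladder, and run the
downstream non-coding-RNA analysis — threshold-based differential calling,
chromosomal enrichment, genomic clustering of differential loci,
condition-dependent status shifts, and degenerate p53-family binding-motif
scanning of promoters.

## Who this is for

Transcriptomics groups working in organisms where commercial rRNA-depletion
kits are unavailable or poorly matched (the approach was pioneered for
human and works particularly well in compact, GC-uniform genomes such as
*C. elegans*), and anyone who needs a transparent, scriptable
implementation of the NSR design plus the simple fold-change analyses that
typically accompany it.

## The method in brief

1. **Primer design.** Enumerate all 4^k DNA k-mers (k = 6 by default, a
   pool of 4,096 hexamers). Remove every k-mer with a *perfect* substring
   match to an rRNA reference — optionally in sense, antisense, or both
   orientations. The survivors are the NSR set; reverse transcription
   primed with this pool cannot initiate on rRNA templates, depleting rRNA
   without a subtraction step. Each surviving hexamer is emitted as a pair
   of synthesis-ready oligos:

   ```
   first strand :  5'-TCCGATCTCT N (reverse complement of hexamer)-3'
   second strand:  5'-TCCGATCTGA N (hexamer)-3'
   ```

2. **Quantification.** Primary alignments are classified into one genomic
   category each, by priority
   `rRNA > sense-exonic mRNA > known ncRNA > antisense-of-coding-exon >
   intronic > intergenic`, and counted per transcript. Expression is
   normalised as RPKM = count / (exonic kb x library millions).

3. **Bias QC.** Observed RPKM of a spiked-in reference ladder (e.g. the
   92-species ERCC mix spanning a 10^6-fold concentration range) is
   correlated (Pearson, log10 scale) with the known concentrations, per
   sample and pairwise between samples.

4. **Differential calling.** A locus is differential between wild type and
   mutant when max(RPKM_wt, RPKM_mut) > 1 and the pseudocounted fold
   change `(RPKM_mut + 0.01)/(RPKM_wt + 0.01)` is >= 2 (or <= 1/2).
   Summaries: exact binomial per-chromosome enrichment, single-linkage
   clustering of differential loci along chromosomes, and status shifts
   between treatment conditions. A 2^-ddCt calculator supports qPCR
   validation.

5. **Motif scanning.** Promoter windows (2 kb upstream to 500 bp
   downstream of each TSS, in transcription orientation) are scanned for
   degenerate IUPAC patterns, by default the p53-family half site
   `RRRCWWGYYY` (R = A/G, W = A/T, Y = C/T).

## Worked example

Everything is testable without downloads: the package ships a synthetic
study generator that emulates the two-genotype x two-treatment design with
planted signal and a ground-truth ledger.

```python
from nsrseq import (FixtureSpec, make_fixture, enumerate_kmers,
                    filter_against_reference, RnaReference,
                    count_reads, compute_rpkm, read_sam,
                    spikein_correlation, call_differential, find_clusters)

fx = make_fixture(FixtureSpec(seed=1), "demo_fixture")

ref = RnaReference.from_fasta(fx.rrna_fasta)
kept = filter_against_reference(enumerate_kmers(6), ref, mode="sense")
print(len(kept), kept.removed)          # 1760 2336

table = count_reads({s: read_sam(p) for s, p in fx.sam_by_sample.items()},
                    fx.annotation)
table.rpkm = compute_rpkm(table.counts, fx.annotation.exonic_lengths(),
                          table.library_size)
rep = spikein_correlation(table, fx.spikein)
print(round(rep.reference_r["N2"], 3))  # 0.993

calls = call_differential(table, "N2", "cep1", annotation=fx.annotation)
ncrna = {t.id for t in fx.annotation if t.biotype == "known_ncRNA"}
nc_calls = [c for c in calls if c.transcript_id in ncrna]
print(sum(c.passes for c in nc_calls))  # 20
print(len(find_clusters(nc_calls, max_gap=5000, min_size=3)))  # 3
```

The filter retains 1,760 of the 4,096 hexamers against this synthetic
rRNA reference (2,336 removed); the spike-in ladder correlates with its
reference concentrations at r = 0.993 under Poisson counting noise; all 20
planted >= 2.5-fold differential ncRNA loci are recovered with no false
positives, including the three planted genomic clusters.

The same steps are available from the shell:

```bash
nsrseq design --rrna rrna.fa -k 6 --mode sense -o primers.tsv
nsrseq quantify --aln N2=N2.sam --aln cep1=cep1.sam \
    --gff annotation.gff3 --spikein spikein.tsv -o quant/
nsrseq diff --rpkm quant/rpkm.tsv --a N2 --b cep1 --gff annotation.gff3 \
    -o calls.tsv
nsrseq clusters --calls calls.tsv --max-gap 10000 --min-size 3 -o clusters.bed
nsrseq motif --genome genome.fa --gff annotation.gff3 --genes activated.txt \
    --pattern RRRCWWGYYY -o hits.tsv
```

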