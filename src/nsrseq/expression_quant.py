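"""Read classification, RPKM quantification and spike-in QC.

Consumes primary read alignments (SAM or 6-column BED) plus a transcript
annotation (GFF3 or BED12), classifies each read into one genomic category
(rRNA, sense-exonic mRNA, known ncRNA, antisense of coding exons, intronic,
intergenic), counts reads per transcript, normalises to RPKM (reads per
kilobase of exon model per million mapped reads), and estimates priming /
amplification bias by correlating spike-in RPKM against the known
concentrations of an external ladder such as the ERCC 92-species mix.

All coordinates are 0-based half-open internally (SAM/BED interoperable);
human-readable reports are 1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "Annotation",
    "AlignmentRecord",
    "CategoryBreakdown",
    "ExpressionTable",
    "SpikeInReference",
    "SpikeInCorrelationReport",
    "read_sam",
    "read_bed_alignments",
    "classify_alignments",
    "count_reads",
    "compute_rpkm",
    "spikein_correlation",
    "CATEGORIES",
]

BIOTYPES = ("rRNA", "mRNA", "known_ncRNA", "TUF", "spike_in")
#: Genomic read categories in the order they are conventionally tabulated.
CATEGORIES = ("rRNA", "mRNA", "known_ncRNA", "antisense", "intergenic", "intronic")

# GFF3 feature types mapped onto the biotype vocabulary.  A `biotype=`
# attribute on the feature overrides the type-based guess.
_GFF_TYPE_TO_BIOTYPE = {
    "rRNA": "rRNA",
    "mRNA": "mRNA",
    "ncRNA": "known_ncRNA",
    "snoRNA": "known_ncRNA",
    "snRNA": "known_ncRNA",
    "lincRNA": "known_ncRNA",
    "lnc_RNA": "known_ncRNA",
    "tRNA": "known_ncRNA",
    "TUF": "TUF",
    "spike_in": "spike_in",
}


@dataclass(frozen=True)
class TranscriptModel:
    """An annotated locus: strand-aware span, exon chain and biotype."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript must have at least one exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: exons must be sorted and disjoint")
            prev_end = e
        if self.exonic_length <= 0:
            raise ValueError(f"{self.id}: zero exonic length")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )


class Annotation:
    """Indexed collection of TranscriptModel records."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self.transcripts[t.id] = t
        self._trees: dict | None = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    @property
    def chromosomes(self) -> set[str]:
        return {t.chrom for t in self}

    def exonic_lengths(self) -> pd.Series:
        return pd.Series(
            {t.id: t.exonic_length for t in self}, name="exonic_length", dtype=int
        )

    def subset(self, biotypes: Sequence[str]) -> "Annotation":
        wanted = set(biotypes)
        return Annotation(t for t in self if t.biotype in wanted)

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_gff3(cls, path: str | Path) -> "Annotation":
        """Load transcript-level features (with optional exon children).

        Feature types are mapped onto biotypes (mRNA/rRNA/ncRNA/...); a
        ``biotype=`` attribute wins over the type-based mapping.  Features
        without exon children are treated as single-exon.
        """
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        transcripts = []
        for ftype, biotype_guess in _GFF_TYPE_TO_BIOTYPE.items():
            for feat in db.features_of_type(ftype):
                biotype = feat.attributes.get("biotype", [biotype_guess])[0]
                exons = sorted(
                    (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
                )
                if not exons:
                    exons = [(feat.start - 1, feat.end)]
                transcripts.append(
                    TranscriptModel(
                        id=feat.id,
                        chrom=feat.seqid,
                        strand=feat.strand if feat.strand in "+-" else "+",
                        start=feat.start - 1,
                        end=feat.end,
                        exons=tuple(exons),
                        biotype=biotype,
                    )
                )
        return cls(transcripts)

    @classmethod
    def from_bed12(cls, path: str | Path, biotype: str = "known_ncRNA") -> "Annotation":
        """Load BED12 transcript models; BED carries no biotype, so one is
        assigned uniformly (default known_ncRNA)."""
        transcripts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, start, end, name, _score, strand = f[:6]
                start, end = int(start), int(end)
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                    exons = tuple(
                        (start + off, start + off + size)
                        for off, size in zip(offsets, sizes)
                    )
                else:
                    exons = ((start, end),)
                transcripts.append(
                    TranscriptModel(
                        id=name,
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        exons=exons,
                        biotype=biotype,
                    )
                )
        return cls(transcripts)

    # ------------------------------------------------------- interval index

    def interval_index(self) -> dict:
        """Per-chromosome interval trees for each feature class (cached)."""
        if self._trees is not None:
            return self._trees
        trees: dict = {
            key: {}
            for key in (
                "rRNA_exons",
                "mRNA_exons",
                "ncRNA_exons",
                "introns",
                "spike_exons",
                "exons_by_tid",
            )
        }
        for t in self:
            if t.biotype == "rRNA":
                key = "rRNA_exons"
            elif t.biotype == "mRNA":
                key = "mRNA_exons"
            elif t.biotype in ("known_ncRNA", "TUF"):
                key = "ncRNA_exons"
            else:  # spike_in
                key = "spike_exons"
            tree = trees[key].setdefault(t.chrom, IntervalTree())
            tid_tree = trees["exons_by_tid"].setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e, (t.id, t.strand))
                tid_tree.addi(s, e, (t.id, t.strand))
            if t.biotype != "spike_in":
                itree = trees["introns"].setdefault(t.chrom, IntervalTree())
                for s, e in t.introns:
                    itree.addi(s, e, (t.id, t.strand))
        self._trees = trees
        return trees


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal genomic alignment: placement, strand and primary flag."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: empty alignment span")


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream mapped alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            yield AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                start=aln.reference_start,
                end=aln.reference_end,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
            )


def read_bed_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignments from a 6-column BED table (all taken as primary)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            yield AlignmentRecord(name, chrom, strand, int(start), int(end))


@dataclass(frozen=True)
class CategoryBreakdown:
    """Proportions of classified genomic reads per category.

    Reads on spike-in contigs are tallied separately (``spike_in_reads``)
    and excluded from the genomic fractions, which sum to 1.
    """

    counts: dict[str, int]
    spike_in_reads: int = 0

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_classified
        return {c: self.counts.get(c, 0) / n for c in CATEGORIES}


def _overlap_hits(tree_by_chrom, chrom, start, end, min_overlap):
    tree = tree_by_chrom.get(chrom)
    if tree is None:
        return []
    return [
        iv
        for iv in tree.overlap(start, end)
        if min(iv.end, end) - max(iv.begin, start) >= min_overlap
    ]


def classify_alignments(
    alignments: Iterable[AlignmentRecord],
    annotation: Annotation,
    min_overlap: int = 1,
) -> CategoryBreakdown:
    """Assign each primary alignment to exactly one genomic category.

    Priority: rRNA > sense-exonic mRNA > known ncRNA (sense) > antisense of
    coding exons > intronic > intergenic.  rRNA and intron overlaps are
    strand-agnostic; mRNA/ncRNA require the read strand to equal the
    transcript strand.  A read overlapping a feature by at least
    ``min_overlap`` bases (default 1) counts for that feature.
    """
    trees = annotation.interval_index()
    known_chroms = annotation.chromosomes
    warned: set[str] = set()
    counts = {c: 0 for c in CATEGORIES}
    spike = 0
    n = 0
    for aln in alignments:
        if not aln.is_primary:
            continue
        n += 1
        chrom, s, e = aln.chrom, aln.start, aln.end
        if chrom not in known_chroms and chrom not in warned:
            logger.warning("chromosome %r absent from annotation; reads classified intergenic", chrom)
            warned.add(chrom)
        if _overlap_hits(trees["spike_exons"], chrom, s, e, min_overlap):
            spike += 1
            continue
        if _overlap_hits(trees["rRNA_exons"], chrom, s, e, min_overlap):
            counts["rRNA"] += 1
            continue
        mrna_hits = _overlap_hits(trees["mRNA_exons"], chrom, s, e, min_overlap)
        if any(iv.data[1] == aln.strand for iv in mrna_hits):
            counts["mRNA"] += 1
            continue
        ncrna_hits = _overlap_hits(trees["ncRNA_exons"], chrom, s, e, min_overlap)
        if any(iv.data[1] == aln.strand for iv in ncrna_hits):
            counts["known_ncRNA"] += 1
            continue
        if mrna_hits:  # exonic overlap on the wrong strand of a coding exon
            counts["antisense"] += 1
            continue
        if _overlap_hits(trees["introns"], chrom, s, e, min_overlap):
            counts["intronic"] += 1
            continue
        counts["intergenic"] += 1
    if n == 0:
        raise ValueError("empty alignment stream")
    return CategoryBreakdown(counts=counts, spike_in_reads=spike)


@dataclass
class ExpressionTable:
    """Per-transcript raw counts and RPKM across samples.

    ``counts`` and ``rpkm`` are transcript x sample DataFrames;
    ``library_size`` holds the per-million denominator for each sample
    (all classified primary alignments, rRNA and spike-ins included).
    """

    counts: pd.DataFrame
    library_size: pd.Series
    rpkm: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path, what: str = "rpkm") -> None:
        df = self.rpkm if what == "rpkm" else self.counts
        if df is None:
            raise ValueError("RPKM not computed yet")
        df.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path | None = None, rpkm_path: str | Path | None = None,
        library_size: Mapping[str, int] | None = None,
    ) -> "ExpressionTable":
        counts = (
            pd.read_csv(counts_path, sep="\t", index_col=0)
            if counts_path
            else None
        )
        rpkm = pd.read_csv(rpkm_path, sep="\t", index_col=0) if rpkm_path else None
        base = counts if counts is not None else rpkm
        if base is None:
            raise ValueError("need at least one of counts/rpkm")
        lib = pd.Series(library_size) if library_size else base.sum(axis=0)
        if counts is None:
            counts = pd.DataFrame(0, index=base.index, columns=base.columns)
        return cls(counts=counts, library_size=lib, rpkm=rpkm)


def count_reads(
    alignments_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    annotation: Annotation,
    strandedness: str = "stranded",
) -> ExpressionTable:
    """Count exon-overlapping reads per transcript for each sample.

    A read increments every transcript whose exons it overlaps by >= 1 base
    (sense-only under ``strandedness="stranded"``); no fractional assignment
    is made for multi-overlap reads.  The library size is the total number
    of primary alignments in the sample, whether or not they hit a feature.
    """
    if strandedness not in ("stranded", "unstranded"):
        raise ValueError(f"strandedness must be stranded/unstranded, got {strandedness!r}")
    trees = annotation.interval_index()["exons_by_tid"]
    tids = list(annotation.transcripts)
    counts = pd.DataFrame(0, index=tids, columns=list(alignments_by_sample), dtype=int)
    lib = {}
    for sample, alignments in alignments_by_sample.items():
        n = 0
        col = {tid: 0 for tid in tids}
        for aln in alignments:
            if not aln.is_primary:
                continue
            n += 1
            hits = _overlap_hits(trees, aln.chrom, aln.start, aln.end, 1)
            seen: set[str] = set()
            for iv in hits:
                tid, strand = iv.data
                if strandedness == "stranded" and strand != aln.strand:
                    continue
                if tid not in seen:
                    col[tid] += 1
                    seen.add(tid)
        counts[sample] = pd.Series(col)
        lib[sample] = n
    return ExpressionTable(counts=counts, library_size=pd.Series(lib, dtype=int))


def compute_rpkm(
    counts: pd.DataFrame,
    exonic_lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """RPKM = count / (exonic length in kb) / (library size in millions)."""
    lengths = pd.Series(exonic_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing exonic length for transcripts: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ValueError(f"non-positive exonic length for transcripts: {bad}")
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        bad = list(libs.index[libs.isna() | (libs <= 0)])
        raise ValueError(f"missing or non-positive library size for samples: {bad}")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


@dataclass(frozen=True)
class SpikeInReference:
    """Known spike-in species: expected concentration and length per id."""

    entries: dict[str, tuple[float, int]]

    def __post_init__(self) -> None:
        for sid, (conc, length) in self.entries.items():
            if conc <= 0:
                raise ValueError(f"{sid}: concentration must be positive")
            if length <= 0:
                raise ValueError(f"{sid}: length must be positive")

    @property
    def dynamic_range(self) -> float:
        concs = [c for c, _ in self.entries.values()]
        return max(concs) / min(concs)

    def concentrations(self) -> pd.Series:
        return pd.Series({sid: c for sid, (c, _) in self.entries.items()})

    @classmethod
    def from_table(cls, path: str | Path) -> "SpikeInReference":
        """Read an ERCC-style tab-separated concentration table.

        Columns are located by name (id / concentration / length,
        case-insensitive, ERCC "concentration in Mix 1" style headers
        accepted); otherwise the first three columns are used.
        """
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}

        def find(*needles):
            for low, orig in cols.items():
                if any(n in low for n in needles):
                    return orig
            return None

        id_col = find("ercc id", "id") or df.columns[0]
        conc_col = find("concentration") or df.columns[1]
        len_col = find("length") or df.columns[2]
        entries = {
            str(r[id_col]): (float(r[conc_col]), int(r[len_col]))
            for _, r in df.iterrows()
        }
        return cls(entries)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tconcentration\tlength\n")
            for sid, (conc, length) in self.entries.items():
                fh.write(f"{sid}\t{conc:.10g}\t{length}\n")


@dataclass
class SpikeInCorrelationReport:
    """Pearson correlations quantifying priming/amplification bias.

    ``reference_r`` correlates each sample's spike-in RPKM with the known
    ladder concentrations; ``pairwise_spike_r`` compares samples over
    spike-ins only, and ``pairwise_all_r`` over every quantified transcript
    (the replicate-agreement view).  ``detected`` counts ladder species at
    or above the detection threshold per sample.
    """

    reference_r: dict[str, float | None]
    reference_p: dict[str, float | None]
    detected: dict[str, int]
    pairwise_spike_r: pd.DataFrame
    pairwise_all_r: pd.DataFrame
    scale: str
    pseudocount: float
    min_count: int


def _transform(values: pd.Series | np.ndarray, scale: str, pseudocount: float):
    arr = np.asarray(values, dtype=float)
    if scale == "log10":
        return np.log10(arr + pseudocount)
    if scale == "linear":
        return arr
    raise ValueError(f"scale must be 'log10' or 'linear', got {scale!r}")


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spikein_correlation(
    table: ExpressionTable,
    ref: SpikeInReference,
    scale: str = "log10",
    pseudocount: float = 0.01,
    min_count: int = 5,
) -> SpikeInCorrelationReport:
    """Correlate observed spike-in RPKM with the reference ladder.

    Species with fewer than ``min_count`` reads in a sample are treated as
    below the detection limit and excluded from that sample's correlations:
    at the bottom of a 10^6-fold ladder, log-scale Pearson is otherwise
    dominated by shot noise rather than priming bias.
    """
    if table.rpkm is None:
        raise ValueError("ExpressionTable has no RPKM; run compute_rpkm first")
    spike_ids = [sid for sid in ref.entries if sid in table.rpkm.index]
    if len(spike_ids) < 3:
        raise ValueError(
            f"need at least 3 spike-in species common to table and reference, got {len(spike_ids)}"
        )
    conc = ref.concentrations()[spike_ids]
    samples = table.samples
    detected_mask = table.counts.loc[spike_ids, samples] >= min_count

    reference_r: dict[str, float | None] = {}
    reference_p: dict[str, float | None] = {}
    detected: dict[str, int] = {}
    for s in samples:
        ids = detected_mask.index[detected_mask[s]]
        detected[s] = int(len(ids))
        if len(ids) < 3:
            reference_r[s], reference_p[s] = None, None
            continue
        x = _transform(conc[ids], scale, 0.0)
        y = _transform(table.rpkm.loc[ids, s], scale, pseudocount)
        reference_r[s], reference_p[s] = _safe_pearson(x, y)

    def pairwise(ids_universe, mask: pd.DataFrame | None) -> pd.DataFrame:
        mat = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
        for i, a in enumerate(samples):
            mat.loc[a, a] = 1.0
            for b in samples[i + 1 :]:
                if mask is not None:
                    ids = [t for t in ids_universe if mask.loc[t, a] and mask.loc[t, b]]
                else:
                    ids = list(ids_universe)
                if len(ids) < 3:
                    continue
                x = _transform(table.rpkm.loc[ids, a], scale, pseudocount)
                y = _transform(table.rpkm.loc[ids, b], scale, pseudocount)
                r, _ = _safe_pearson(x, y)
                if r is not None:
                    mat.loc[a, b] = mat.loc[b, a] = r
        return mat

    all_mask = table.counts >= min_count
    pairwise_spike = pairwise(spike_ids, detected_mask)
    pairwise_all = pairwise(list(table.rpkm.index), all_mask)
    return SpikeInCorrelationReport(
        reference_r=reference_r,
        reference_p=reference_p,
        detected=detected,
        pairwise_spike_r=pairwise_spike,
        pairwise_all_r=pairwise_all,
        scale=scale,
        pseudocount=pseudocount,
        min_count=min_count,
    )
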