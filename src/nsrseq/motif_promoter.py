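"""Promoter extraction and degenerate IUPAC motif scanning.

Promoter windows span a configurable stretch upstream and downstream of each
transcription start site (default 2 kb up / 500 bp down), oriented in the
direction of transcription so that position 0 is always the most-upstream
base.  Windows are scanned for degenerate IUPAC patterns; the default,
RRRCWWGYYY, is the p53-family response-element half site used for
CEP-1/p53 binding-site prediction.  Ambiguity codes are expanded in the
pattern only — an N in the genome matches nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .expression_quant import Annotation, TranscriptModel
from .primer_design import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "MotifHit",
    "DEFAULT_PATTERN",
    "IUPAC_SETS",
    "matches_iupac",
    "extract_promoter",
    "scan_motif",
    "scan_promoters",
    "motif_fraction",
    "write_hits_tsv",
    "write_hits_bed6",
]

DEFAULT_PATTERN = "RRRCWWGYYY"

#: Concrete bases each IUPAC letter stands for (pattern side only).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def _pattern_sets(pattern: str) -> list[frozenset[str]]:
    sets = []
    for ch in pattern.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern {pattern!r}")
        sets.append(IUPAC_SETS[ch])
    return sets


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if a concrete DNA string satisfies an IUPAC pattern.

    Degenerate genome characters never match (a genomic N is unknown, not
    'anything')."""
    if len(seq) != len(pattern):
        return False
    return all(base in pset for base, pset in zip(seq.upper(), _pattern_sets(pattern)))


@dataclass(frozen=True)
class PromoterWindow:
    """A strand-aware promoter sequence around one TSS.

    ``start``/``end`` are the genomic half-open interval; ``sequence`` is
    oriented in transcription direction (reverse-complemented for minus
    strand), and ``tss_index`` is the position of the TSS base within it
    (equal to ``upstream_len`` unless the window was clipped at a
    chromosome edge, recorded in ``clipped``).
    """

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    tss_index: int
    upstream_len: int
    downstream_len: int
    clipped: bool = False


@dataclass(frozen=True)
class MotifHit:
    """One degenerate-pattern match inside a promoter window.

    ``tss_offset`` locates the match's most-upstream base relative to the
    TSS (negative = upstream).  For antisense hits ``matched_sequence`` is
    the reverse complement of the window substring, i.e. the strand on
    which the pattern is satisfied.
    """

    transcript_id: str
    pattern: str
    matched_sequence: str
    strand_relative: str  # "sense" | "antisense" of the promoter orientation
    tss_offset: int
    window_pos: int


def _chrom_seq(genome, chrom: str) -> str:
    if hasattr(genome, "keys") and chrom not in genome.keys():
        raise KeyError(f"chromosome {chrom!r} not present in genome")
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not present in genome") from exc
    return str(seq[:]) if not isinstance(seq, str) else seq


def extract_promoter(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    upstream_len: int = 2000,
    downstream_len: int = 500,
) -> PromoterWindow:
    """Extract the promoter window of one transcript.

    ``genome`` is any mapping from chromosome name to sequence (a
    ``pyfaidx.Fasta`` works).  Windows running off a chromosome end are
    clipped with a warning.
    """
    chrom_seq = _chrom_seq(genome, transcript.chrom).upper()
    clen = len(chrom_seq)
    tss = transcript.tss
    if transcript.strand == "+":
        gstart, gend = tss - upstream_len, tss + downstream_len
    else:
        gstart, gend = tss - downstream_len + 1, tss + upstream_len + 1
    cstart, cend = max(0, gstart), min(clen, gend)
    clipped = (cstart != gstart) or (cend != gend)
    if clipped:
        logger.warning(
            "promoter window of %s clipped at chromosome edge (%d..%d -> %d..%d)",
            transcript.id, gstart, gend, cstart, cend,
        )
    raw = chrom_seq[cstart:cend]
    if transcript.strand == "+":
        sequence = raw
        tss_index = tss - cstart
    else:
        sequence = reverse_complement(raw)
        tss_index = (cend - 1) - tss
    return PromoterWindow(
        transcript_id=transcript.id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        start=cstart,
        end=cend,
        sequence=sequence,
        tss_index=tss_index,
        upstream_len=upstream_len,
        downstream_len=downstream_len,
        clipped=clipped,
    )


def scan_motif(
    window: PromoterWindow,
    pattern: str = DEFAULT_PATTERN,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (overlapping) pattern matches in a promoter window.

    Sense hits satisfy the pattern on the window orientation; with
    ``both_strands`` the reverse complement of each substring is tested as
    well and reported as an antisense hit at the same offset.
    """
    psets = _pattern_sets(pattern)
    L = len(psets)
    rc_psets = _pattern_sets(reverse_complement(pattern.upper()))
    seq = window.sequence.upper()
    hits: list[MotifHit] = []
    for i in range(len(seq) - L + 1):
        sub = seq[i : i + L]
        if all(b in s for b, s in zip(sub, psets)):
            hits.append(
                MotifHit(
                    transcript_id=window.transcript_id,
                    pattern=pattern,
                    matched_sequence=sub,
                    strand_relative="sense",
                    tss_offset=i - window.tss_index,
                    window_pos=i,
                )
            )
        if both_strands and all(b in s for b, s in zip(sub, rc_psets)):
            hits.append(
                MotifHit(
                    transcript_id=window.transcript_id,
                    pattern=pattern,
                    matched_sequence=reverse_complement(sub),
                    strand_relative="antisense",
                    tss_offset=i - window.tss_index,
                    window_pos=i,
                )
            )
    return hits


def scan_promoters(
    annotation: Annotation,
    genome: Mapping[str, str],
    gene_ids: Sequence[str] | None = None,
    pattern: str = DEFAULT_PATTERN,
    upstream_len: int = 2000,
    downstream_len: int = 500,
    both_strands: bool = True,
) -> dict[str, list[MotifHit]]:
    """Extract-and-scan over a gene set; returns hits keyed by transcript id."""
    ids = list(gene_ids) if gene_ids is not None else [t.id for t in annotation]
    out: dict[str, list[MotifHit]] = {}
    for tid in ids:
        if tid not in annotation:
            raise KeyError(f"gene {tid!r} not in annotation")
        window = extract_promoter(
            annotation[tid], genome, upstream_len, downstream_len
        )
        out[tid] = scan_motif(window, pattern, both_strands)
    return out


def motif_fraction(
    gene_set: Sequence[str], hits: Mapping[str, Sequence[MotifHit]]
) -> tuple[int, int, float]:
    """(genes with >= 1 hit, gene-set size, fraction)."""
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    with_hit = sum(1 for g in gene_set if hits.get(g))
    return with_hit, len(gene_set), with_hit / len(gene_set)


def write_hits_tsv(hits: Mapping[str, Sequence[MotifHit]], path) -> None:
    """TSV of hits; tss_offset is the match's most-upstream base relative to
    the TSS, negative upstream."""
    with open(path, "w") as fh:
        fh.write("transcript_id\ttss_offset\tstrand_relative\tmatched_sequence\tpattern\n")
        for tid in hits:
            for h in hits[tid]:
                fh.write(
                    f"{h.transcript_id}\t{h.tss_offset}\t{h.strand_relative}"
                    f"\t{h.matched_sequence}\t{h.pattern}\n"
                )


def write_hits_bed6(
    hits: Mapping[str, Sequence[MotifHit]],
    windows: Mapping[str, PromoterWindow],
    path,
) -> None:
    """BED6 of hit genomic coordinates (strand = genomic strand of the match)."""
    with open(path, "w") as fh:
        for tid in hits:
            w = windows[tid]
            L = None
            for h in hits[tid]:
                L = len(h.matched_sequence)
                if w.strand == "+":
                    gstart = w.start + h.window_pos
                else:
                    gstart = (w.end - 1) - (h.window_pos + L - 1)
                gstrand = w.strand if h.strand_relative == "sense" else (
                    "-" if w.strand == "+" else "+"
                )
                fh.write(
                    f"{w.chrom}\t{gstart}\t{gstart + L}\t{tid}|{h.matched_sequence}"
                    f"\t0\t{gstrand}\n"
                )
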