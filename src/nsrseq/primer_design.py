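"""Design of rRNA-depleting "not-so-random" (NSR) primer sets.

The NSR strategy builds a reverse-transcription primer pool from every DNA
k-mer (hexamers by default) *except* those that perfectly match an rRNA
reference.  Libraries primed with the surviving set are strongly depleted of
rRNA-derived cDNA without a separate subtraction step, while retaining dense
priming coverage of mRNAs and non-coding RNAs.

The module enumerates k-mers, filters them against an rRNA reference under a
configurable strand convention, emits adapter-bearing oligo sequences for
first- and second-strand synthesis, and summarises how densely the surviving
set covers a target transcript collection.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "HexamerSet",
    "RnaReference",
    "PrimerOligo",
    "CoverageStats",
    "enumerate_kmers",
    "filter_against_reference",
    "emit_oligos",
    "coverage_stats",
    "write_oligo_sheet",
    "read_oligo_sheet",
    "reverse_complement",
    "DEFAULT_ADAPTER1",
    "DEFAULT_ADAPTER2",
]

BASES = "ACGT"
#: IUPAC nucleotide codes accepted in reference sequences; windows containing
#: any character outside plain ACGT can never be perfectly matched by a primer.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: 5' annealing sites from the original NSR oligo design: first-strand primers
#: carry adapter1 + N + reverse-complement(hexamer), second-strand primers
#: carry adapter2 + N + hexamer.
DEFAULT_ADAPTER1 = "TCCGATCTCT"
DEFAULT_ADAPTER2 = "TCCGATCTGA"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FILTER_MODES = ("sense", "antisense", "both")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HexamerSet:
    """An ordered collection of distinct uppercase DNA k-mers.

    ``filter_mode`` records which orientation against the rRNA reference
    caused removals (``None`` until filtered) and ``source_digest`` is a
    checksum of the reference used, so a primer sheet can always be traced
    back to the exact filter input.
    """

    k: int
    members: tuple[str, ...]
    filter_mode: str | None = None
    source_digest: str | None = None
    removed: int = 0

    def __post_init__(self) -> None:
        if not all(len(m) == self.k and set(m) <= set(BASES) for m in self.members):
            raise ValueError("all members must be length-k strings over A/C/G/T")
        if len(set(self.members)) != len(self.members):
            raise ValueError("members must be unique")
        if len(self.members) > 4 ** self.k:
            raise ValueError("more members than possible k-mers")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, kmer: str) -> bool:
        return kmer in set(self.members)


@dataclass(frozen=True)
class RnaReference:
    """rRNA reference: (id, sequence) records, DNA alphabet, U normalised to T."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        for rid, seq in self.records:
            if not seq:
                raise ValueError(f"reference record {rid!r} has an empty sequence")
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"reference record {rid!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "RnaReference":
        """Build a reference, uppercasing and converting U to T on ingest."""
        norm = tuple(
            (rid, str(seq).upper().replace("U", "T")) for rid, seq in records
        )
        return cls(norm)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RnaReference":
        return cls.from_records(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )

    @property
    def digest(self) -> str:
        h = hashlib.sha256()
        for rid, seq in self.records:
            h.update(rid.encode())
            h.update(b"\0")
            h.update(seq.encode())
            h.update(b"\n")
        return h.hexdigest()

    def kmer_inventory(self, k: int) -> set[str]:
        """All distinct plain-ACGT k-length substrings across all records.

        Windows containing an ambiguity code contribute nothing: a primer
        cannot perfectly match an ambiguous base.  Records shorter than k
        contribute nothing (with a warning).
        """
        inventory: set[str] = set()
        acgt = set(BASES)
        for rid, seq in self.records:
            if len(seq) < k:
                warnings.warn(
                    f"reference record {rid!r} is shorter than k={k}; "
                    "it contributes no k-mer occurrences",
                    stacklevel=2,
                )
                continue
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if set(window) <= acgt:
                    inventory.add(window)
        return inventory


@dataclass(frozen=True)
class PrimerOligo:
    """One NSR hexamer with its first- and second-strand synthesis oligos."""

    hexamer: str
    first_strand: str
    second_strand: str


@dataclass(frozen=True)
class CoverageStats:
    """Coverage of a transcript collection by a primer set.

    ``per_transcript`` counts *distinct* set members occurring as substrings
    of each transcript; ``density`` is the mean spacing in bases between
    match start sites (total length / total occurrences, with overlapping
    occurrences counted because each is a distinct priming start site), or
    ``None`` when there are no occurrences at all.
    """

    per_transcript: dict[str, int]
    mean_matches: float
    density: float | None
    total_occurrences: int = 0


def enumerate_kmers(k: int) -> HexamerSet:
    """All 4**k DNA k-mers in lexicographic order.

    Parameters
    ----------
    k : int
        k-mer length, 1 <= k <= 12 (4**12 ~ 16.8M is the practical ceiling
        for an in-memory enumeration of a primer candidate pool).
    """
    if not isinstance(k, int) or not (1 <= k <= 12):
        raise ValueError(f"k must be an integer in [1, 12], got {k!r}")
    members = tuple("".join(p) for p in itertools.product(BASES, repeat=k))
    return HexamerSet(k=k, members=members)


def filter_against_reference(
    hexamers: HexamerSet, ref: RnaReference, mode: str = "sense"
) -> HexamerSet:
    """Remove every k-mer with a perfect substring occurrence in the reference.

    ``mode`` selects the orientation that triggers removal:

    - ``"sense"``      — the k-mer itself occurs in a reference sequence;
    - ``"antisense"``  — its reverse complement occurs;
    - ``"both"``       — either orientation occurs.

    Retained members keep their original order.  The returned set records the
    removal count, the mode, and a digest of the reference used.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"mode must be one of {FILTER_MODES}, got {mode!r}")
    if len(hexamers) == 0:
        raise ValueError("hexamer set is empty")
    inventory = ref.kmer_inventory(hexamers.k)

    def hit(m: str) -> bool:
        if mode == "sense":
            return m in inventory
        if mode == "antisense":
            return reverse_complement(m) in inventory
        return m in inventory or reverse_complement(m) in inventory

    retained = tuple(m for m in hexamers.members if not hit(m))
    return HexamerSet(
        k=hexamers.k,
        members=retained,
        filter_mode=mode,
        source_digest=ref.digest,
        removed=len(hexamers) - len(retained),
    )


def emit_oligos(
    hexamers: HexamerSet,
    adapter1: str = DEFAULT_ADAPTER1,
    adapter2: str = DEFAULT_ADAPTER2,
) -> list[PrimerOligo]:
    """One adapter-bearing oligo pair per set member, in set order.

    First strand: ``adapter1 + N + revcomp(hexamer)`` (anneals to the RNA
    template); second strand: ``adapter2 + N + hexamer``.
    """
    for name, adapter in (("adapter1", adapter1), ("adapter2", adapter2)):
        if not adapter:
            raise ValueError(f"{name} must be a non-empty DNA string")
        bad = set(adapter.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    return [
        PrimerOligo(
            hexamer=m,
            first_strand=f"{adapter1}N{reverse_complement(m)}",
            second_strand=f"{adapter2}N{m}",
        )
        for m in hexamers.members
    ]


def coverage_stats(
    hexamers: HexamerSet,
    transcripts: Sequence[tuple[str, str]],
    both_strands: bool = False,
) -> CoverageStats:
    """Distinct-member counts and priming-site density over transcripts.

    Matching is against the sense strand of each supplied transcript sequence
    (``both_strands=True`` also matches members' reverse complements).
    Transcript sequences are uppercased with U normalised to T.
    """
    if len(transcripts) == 0:
        raise ValueError("transcript collection is empty")
    k = hexamers.k
    sense_set = set(hexamers.members)
    member_set = set(sense_set)
    canonical: dict[str, str] = {}
    if both_strands:
        canonical = {reverse_complement(m): m for m in hexamers.members}
        member_set |= set(canonical)
    per_transcript: dict[str, int] = {}
    total_occ = 0
    total_len = 0
    for tid, raw in transcripts:
        seq = str(raw).upper().replace("U", "T")
        total_len += len(seq)
        distinct: set[str] = set()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if window in member_set:
                total_occ += 1
                distinct.add(window if window in sense_set else canonical[window])
        per_transcript[tid] = len(distinct)
    mean_matches = sum(per_transcript.values()) / len(per_transcript)
    density = (total_len / total_occ) if total_occ else None
    return CoverageStats(
        per_transcript=per_transcript,
        mean_matches=mean_matches,
        density=density,
        total_occurrences=total_occ,
    )


def write_oligo_sheet(oligos: Iterable[PrimerOligo], path: str | Path) -> None:
    """Tab-separated oligo sheet: hexamer, first_strand, second_strand."""
    with open(path, "w") as fh:
        fh.write("hexamer\tfirst_strand\tsecond_strand\n")
        for o in oligos:
            fh.write(f"{o.hexamer}\t{o.first_strand}\t{o.second_strand}\n")


def read_oligo_sheet(path: str | Path) -> list[PrimerOligo]:
    oligos = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["hexamer", "first_strand", "second_strand"]:
            raise ValueError(f"unrecognised oligo sheet header in {path}")
        for line in fh:
            hexamer, first, second = line.rstrip("\n").split("\t")
            oligos.append(PrimerOligo(hexamer, first, second))
    return oligos
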