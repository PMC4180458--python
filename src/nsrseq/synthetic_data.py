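"""Self-contained synthetic fixtures with a ground-truth ledger.

Generates a toy genome (GC 0.36, the C. elegans genome-wide value), an
annotation with rRNA / mRNA / ncRNA / TUF loci, an external spike-in ladder
(92 species, 250-2000 nt, 10^6-fold concentration range, mirroring the ERCC
mix), and per-sample read alignments for a two-genotype (wild type vs
regulator mutant), optionally two-treatment (untreated vs UV) design.
Differential loci, genomic clusters of differential loci, status shifts
between treatments, and promoter motif instances are planted, and every
planted quantity is recorded in a TruthLedger so each downstream module can
be scored exactly.

Count model: expected reads per locus carry a lognormal inter-locus spread
(sigma on the log10 scale, shared across samples so that fold changes are
perturbed only by counting noise), then Poisson sampling per sample
(``count_model="exact"`` rounds the expectation instead, for deterministic
fixtures).  Reads are 80 nt, placed uniformly within single exons on the
correct strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_quant import Annotation, SpikeInReference, TranscriptModel
from .motif_promoter import IUPAC_SETS, DEFAULT_PATTERN
from .primer_design import RnaReference, reverse_complement

__all__ = [
    "FixtureSpec",
    "ClusterPlan",
    "TruthLedger",
    "Fixture",
    "InfeasibleSpecError",
    "make_fixture",
    "make_rrna_filter_case",
    "N2_CATEGORY_MIX",
]


class InfeasibleSpecError(ValueError):
    """The requested fixture cannot be laid out; nothing was written."""


#: Genomic read-category proportions of the untreated wild-type sample in the
#: original worm NSR-seq study; useful for classification-style fixtures.
N2_CATEGORY_MIX = {
    "rRNA": 0.0197,
    "mRNA": 0.8382,
    "known_ncRNA": 0.0230,
    "antisense": 0.0413,
    "intergenic": 0.0678,
    "intronic": 0.0099,
}

#: Default mix for the ncRNA-focused differential fixture: most of the read
#: budget goes to the 200 ncRNA loci so threshold calling is limited by the
#: planted folds, not by counting noise (emulating the deep real libraries
#: at desk scale).
DEFAULT_CATEGORY_MIX = {
    "rRNA": 0.02,
    "mRNA": 0.10,
    "known_ncRNA": 0.80,
    "antisense": 0.03,
    "intergenic": 0.04,
    "intronic": 0.01,
}

CHROMS = ("I", "II", "III", "IV", "V", "X")


@dataclass(frozen=True)
class ClusterPlan:
    """A planted run of differential ncRNA loci.

    ``gap`` is the start-to-start spacing in bases between consecutive
    members; ``direction`` is "repressed" or "activated" (relative to the
    regulator, i.e. repressed = higher in the mutant)."""

    chrom: str
    n_members: int
    gap: int
    direction: str


@dataclass
class FixtureSpec:
    """Everything the generator needs; identical spec + seed => identical files."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {c: 200_000 for c in CHROMS}
    )
    gc: float = 0.36
    read_length: int = 80

    # loci
    n_mrna: int = 30
    n_ncrna: int = 200
    n_tuf: int = 12
    rrna_lengths: tuple[int, ...] = (1800, 2600)

    # spike-in ladder
    spike_species: int = 92
    spike_length_range: tuple[int, int] = (250, 2000)
    spike_dynamic_range: float = 1e6
    spike_max_expected: float = 1500.0  # expected reads of the top species

    # samples & depth
    with_uv: bool = True
    total_reads: int = 100_000  # genomic reads per sample (spike-ins extra)
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    exact_mix: bool = False  # exact per-category totals (largest remainder)

    # noise
    noise_sigma: float = 0.1  # lognormal sigma on log10 expected counts
    count_model: str = "poisson"  # "poisson" | "exact"

    # planted signal
    n_de_scattered: int = 10
    de_fold: float = 2.5
    clusters: tuple[ClusterPlan, ...] = (
        ClusterPlan("X", 3, 4000, "repressed"),
        ClusterPlan("X", 4, 4000, "repressed"),
        ClusterPlan("V", 3, 4000, "activated"),
    )
    n_status_shifts: int = 10  # repressed->activated between contrasts

    # planted promoter motifs
    motif_pattern: str = DEFAULT_PATTERN
    n_motif_genes: int = 40
    motif_universe: int = 100  # motifs planted among the first N ncRNA loci
    motif_offset_range: tuple[int, int] = (-1900, -50)

    # optional NSR-style priming bias: read starts restricted to positions
    # where the genome matches one of these hexamers
    priming_hexamers: frozenset[str] | None = None

    min_gap: int = 2200  # inter-locus gap; leaves promoter space uncontested

    def validate(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise InfeasibleSpecError("category_mix must sum to 1")
        if any(v < 0 for v in self.category_mix.values()):
            raise InfeasibleSpecError("category_mix entries must be non-negative")
        if self.spike_dynamic_range < 1:
            raise InfeasibleSpecError("spike dynamic range must be >= 1")
        if self.count_model not in ("poisson", "exact"):
            raise InfeasibleSpecError(f"unknown count_model {self.count_model!r}")
        if not (0 < self.gc < 1):
            raise InfeasibleSpecError("gc must be in (0, 1)")
        for cp in self.clusters:
            if cp.chrom not in self.chrom_lengths:
                raise InfeasibleSpecError(f"cluster chromosome {cp.chrom!r} unknown")
            if cp.direction not in ("repressed", "activated"):
                raise InfeasibleSpecError(f"cluster direction {cp.direction!r} invalid")
        n_clustered = sum(cp.n_members for cp in self.clusters)
        if n_clustered + self.n_de_scattered > self.n_ncrna:
            raise InfeasibleSpecError("more planted DE loci than ncRNA loci")
        if self.n_motif_genes > min(self.motif_universe, self.n_ncrna):
            raise InfeasibleSpecError("n_motif_genes exceeds the motif universe")
        lo, hi = self.motif_offset_range
        if not (-self.min_gap + len(self.motif_pattern) + 100 <= lo <= hi <= -len(self.motif_pattern)):
            raise InfeasibleSpecError(
                "motif offsets must lie in the upstream inter-locus gap"
            )

    @property
    def samples(self) -> tuple[str, ...]:
        return ("N2", "cep1", "N2_UV", "cep1_UV") if self.with_uv else ("N2", "cep1")

    @property
    def contrasts(self) -> dict[str, tuple[str, str]]:
        """contrast name -> (wild-type sample, mutant sample)."""
        c = {"normal": ("N2", "cep1")}
        if self.with_uv:
            c["uv"] = ("N2_UV", "cep1_UV")
        return c


@dataclass
class TruthLedger:
    """Planted ground truth, sufficient to score every downstream module."""

    locus_counts: pd.DataFrame  # locus x sample true placed read counts
    category_counts: dict[str, dict[str, int]]  # sample -> category -> reads
    library_size: dict[str, int]
    planted_de: pd.DataFrame  # locus, contrast, fold, direction
    clusters: list[dict]  # chrom, direction, gap, members
    motifs: dict[str, dict]  # locus -> {offset, instance}
    spike_expected: dict[str, float]

    def de_loci(self, contrast: str = "normal") -> pd.DataFrame:
        return self.planted_de[self.planted_de["contrast"] == contrast]


@dataclass
class Fixture:
    """Paths to the emitted files plus the in-memory truth."""

    outdir: Path
    genome_fasta: Path
    annotation_gff3: Path
    rrna_fasta: Path
    spikein_tsv: Path
    sam_by_sample: dict[str, Path]
    ledger_json: Path
    locus_counts_tsv: Path
    ledger: TruthLedger
    annotation: Annotation
    spikein: SpikeInReference
    genome: dict[str, str]


# --------------------------------------------------------------- planning


@dataclass
class _Locus:
    id: str
    biotype: str
    chrom: str
    strand: str
    length: int
    exon_layout: tuple[tuple[int, int], ...]  # offsets within the locus
    start: int = -1

    def model(self) -> TranscriptModel:
        exons = tuple((self.start + s, self.start + e) for s, e in self.exon_layout)
        return TranscriptModel(
            id=self.id,
            chrom=self.chrom,
            strand=self.strand,
            start=self.start,
            end=self.start + self.length,
            exons=exons,
            biotype=self.biotype,
        )


def _plan_loci(spec: FixtureSpec, rng: np.random.Generator):
    """Create all loci with exon layouts and assign them to chromosomes."""
    loci: list[_Locus] = []
    chroms = list(spec.chrom_lengths)

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    for i, length in enumerate(spec.rrna_lengths, 1):
        loci.append(
            _Locus(f"rRNA_{i:04d}", "rRNA", chroms[0], "+", length, ((0, length),))
        )
    for i in range(1, spec.n_mrna + 1):
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(300, 801, n_ex)
        intron_lens = rng.integers(250, 601, n_ex - 1)
        layout, pos = [], 0
        for j, el in enumerate(exon_lens):
            layout.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_ex - 1:
                pos += int(intron_lens[j])
        loci.append(
            _Locus(
                f"mRNA_{i:04d}",
                "mRNA",
                chroms[(i - 1) % len(chroms)],
                rand_strand(),
                pos,
                tuple(layout),
            )
        )
    for i in range(1, spec.n_ncrna + 1):
        length = int(rng.integers(150, 501))
        loci.append(
            _Locus(
                f"ncRNA_{i:04d}",
                "known_ncRNA",
                chroms[(i - 1) % len(chroms)],  # provisional; clusters reassign
                rand_strand(),
                length,
                ((0, length),),
            )
        )
    for i in range(1, spec.n_tuf + 1):
        length = int(rng.integers(100, 201))
        loci.append(
            _Locus(
                f"TUF_{i:04d}",
                "TUF",
                chroms[(i - 1) % len(chroms)],
                rand_strand(),
                length,
                ((0, length),),
            )
        )
    return loci


def _plan_planted(spec: FixtureSpec, loci: list[_Locus], rng: np.random.Generator):
    """Choose cluster members, scattered DE loci and status shifts."""
    ncrna = [l for l in loci if l.biotype == "known_ncRNA"]
    by_id = {l.id: l for l in loci}

    # cluster members: the last ncRNA indices, reassigned to the cluster chrom
    n_clustered = sum(cp.n_members for cp in spec.clusters)
    cluster_members: list[list[str]] = []
    pool = [l.id for l in ncrna[len(ncrna) - n_clustered :]]
    idx = 0
    for cp in spec.clusters:
        members = pool[idx : idx + cp.n_members]
        idx += cp.n_members
        for mid in members:
            by_id[mid].chrom = cp.chrom
        cluster_members.append(members)

    # scattered DE among non-cluster, non-motif-universe ncRNAs, biased to X/V
    candidates = [l for l in ncrna[spec.motif_universe : len(ncrna) - n_clustered]]
    if len(candidates) < spec.n_de_scattered:
        candidates = [l for l in ncrna[: len(ncrna) - n_clustered]]
    weights = np.array(
        [3.0 if l.chrom == "X" else 2.0 if l.chrom == "V" else 1.0 for l in candidates]
    )
    chosen = rng.choice(
        len(candidates), size=spec.n_de_scattered, replace=False, p=weights / weights.sum()
    )
    scattered = [candidates[i].id for i in sorted(chosen)]

    de_rows = []
    for cp, members in zip(spec.clusters, cluster_members):
        for mid in members:
            de_rows.append((mid, cp.direction))
    for j, mid in enumerate(scattered):
        de_rows.append((mid, "repressed" if j % 2 == 0 else "activated"))

    planted = []
    for mid, direction in de_rows:
        planted.append(
            {"locus": mid, "contrast": "normal", "fold": spec.de_fold, "direction": direction}
        )
    shifted: list[str] = []
    if spec.with_uv:
        repressed = [mid for mid, d in de_rows if d == "repressed"]
        if spec.n_status_shifts > len(repressed):
            raise InfeasibleSpecError(
                "n_status_shifts exceeds the number of repressed planted loci"
            )
        shifted = repressed[: spec.n_status_shifts]
        for mid, direction in de_rows:
            uv_dir = "activated" if mid in shifted else direction
            planted.append(
                {"locus": mid, "contrast": "uv", "fold": spec.de_fold, "direction": uv_dir}
            )
    planted_de = pd.DataFrame(planted, columns=["locus", "contrast", "fold", "direction"])
    return planted_de, cluster_members, shifted


def _place_on_chromosomes(spec: FixtureSpec, loci: list[_Locus], rng: np.random.Generator):
    """Assign genomic start coordinates; clusters keep their planned spacing."""
    by_id = {l.id: l for l in loci}
    clustered_ids = set()
    blocks_by_chrom: dict[str, list[tuple[int, list[tuple[str, int]]]]] = {
        c: [] for c in spec.chrom_lengths
    }
    # composite cluster blocks: (block length, [(locus id, offset in block)])
    ncrna = [l for l in loci if l.biotype == "known_ncRNA"]
    n_clustered = sum(cp.n_members for cp in spec.clusters)
    pool = [l.id for l in ncrna[len(ncrna) - n_clustered :]]
    idx = 0
    for cp in spec.clusters:
        members = pool[idx : idx + cp.n_members]
        idx += cp.n_members
        offsets = [(mid, i * cp.gap) for i, mid in enumerate(members)]
        if any(by_id[m].length >= cp.gap for m in members[:-1]):
            raise InfeasibleSpecError("cluster members longer than the cluster gap")
        block_len = (cp.n_members - 1) * cp.gap + by_id[members[-1]].length
        blocks_by_chrom[cp.chrom].append((block_len, offsets))
        clustered_ids.update(members)
    for l in loci:
        if l.id in clustered_ids:
            continue
        blocks_by_chrom[l.chrom].append((l.length, [(l.id, 0)]))

    for chrom, blocks in blocks_by_chrom.items():
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        clen = spec.chrom_lengths[chrom]
        fixed = spec.min_gap + sum(b[0] + spec.min_gap for b in blocks) + 1000
        slack = clen - fixed
        if slack < 0:
            raise InfeasibleSpecError(
                f"chromosome {chrom} too short by {-slack} bases for its loci"
            )
        pvals = np.full(len(blocks) + 1, 1.0 / (len(blocks) + 1))
        pvals[-1] = 1.0 - pvals[:-1].sum()
        extras = rng.multinomial(slack, pvals)
        cursor = spec.min_gap + int(extras[0])
        for i, (block_len, members) in enumerate(blocks):
            for mid, off in members:
                by_id[mid].start = cursor + off
            cursor += block_len + spec.min_gap + int(extras[i + 1])
            if cursor > clen:
                raise InfeasibleSpecError(f"placement overflow on chromosome {chrom}")


# --------------------------------------------------------------- sequences


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _plant_motifs(
    spec: FixtureSpec,
    loci: list[_Locus],
    genome: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, dict]:
    """Write one concrete motif instance into chosen ncRNA promoters.

    Offsets are upstream of the TSS (within the reserved inter-locus gap),
    reported for the instance's most-upstream base in promoter orientation.
    """
    ncrna = [l for l in loci if l.biotype == "known_ncRNA"]
    universe = ncrna[: spec.motif_universe]
    chosen = sorted(
        rng.choice(len(universe), size=spec.n_motif_genes, replace=False)
    )
    lo, hi = spec.motif_offset_range
    pattern = spec.motif_pattern.upper()
    out: dict[str, dict] = {}
    for ci in chosen:
        locus = universe[ci]
        offset = int(rng.integers(lo, hi + 1))
        instance = "".join(
            sorted(IUPAC_SETS[ch])[rng.integers(0, len(IUPAC_SETS[ch]))]
            for ch in pattern
        )
        model = locus.model()
        if locus.strand == "+":
            gstart = model.tss + offset  # offset negative -> upstream (left)
            ins = instance
        else:
            gend_incl = model.tss - offset  # upstream is genomic right
            gstart = gend_incl - len(pattern) + 1
            ins = reverse_complement(instance)
        arr = genome[locus.chrom]
        if gstart < 0 or gstart + len(pattern) > len(arr):
            raise InfeasibleSpecError(f"motif for {locus.id} falls off the chromosome")
        arr[gstart : gstart + len(pattern)] = np.frombuffer(ins.encode(), dtype="S1")
        out[locus.id] = {"offset": offset, "instance": instance}
    return out


# --------------------------------------------------------------- expression


def _spike_ladder(spec: FixtureSpec, rng: np.random.Generator):
    n = spec.spike_species
    if n == 0:
        return SpikeInReference(entries={}), {}
    lo_len, hi_len = spec.spike_length_range
    conc = 1e-3 * spec.spike_dynamic_range ** (np.arange(n) / max(n - 1, 1))
    lengths = rng.integers(lo_len, hi_len + 1, size=n)
    # keep the ladder extremes length-matched so expected read counts span
    # the configured dynamic range within a factor of ~2
    mid = (lo_len + hi_len) // 2
    if n >= 2:
        lengths[0], lengths[-1] = mid, int(mid * 1.3)
    ids = [f"SPIKE-{i + 1:04d}" for i in range(n)]
    entries = {sid: (float(c), int(L)) for sid, c, L in zip(ids, conc, lengths)}
    ref = SpikeInReference(entries=entries)
    cl = conc * lengths
    expected = spec.spike_max_expected * cl / cl.max()
    return ref, {sid: float(e) for sid, e in zip(ids, expected)}


def _expected_counts(
    spec: FixtureSpec,
    loci: list[_Locus],
    planted_de: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expected sense-read counts per locus per sample (genomic loci only)."""
    weights = {l.id: 10 ** (spec.noise_sigma * rng.standard_normal()) for l in loci}
    groups = {
        "rRNA": [l for l in loci if l.biotype == "rRNA"],
        "mRNA": [l for l in loci if l.biotype == "mRNA"],
        "known_ncRNA": [l for l in loci if l.biotype in ("known_ncRNA", "TUF")],
    }
    fold = {
        (r["locus"], r["contrast"]): (r["fold"], r["direction"])
        for _, r in planted_de.iterrows()
    }
    mutant_of = {v[1]: k for k, v in spec.contrasts.items()}  # sample -> contrast
    expected = pd.DataFrame(
        0.0, index=[l.id for l in loci], columns=list(spec.samples)
    )
    for cat, members in groups.items():
        if not members:
            continue
        budget = spec.total_reads * spec.category_mix.get(cat, 0.0)
        base = budget / len(members)
        for l in members:
            for s in spec.samples:
                e = base * weights[l.id]
                contrast = mutant_of.get(s)
                if contrast and (l.id, contrast) in fold:
                    f, direction = fold[(l.id, contrast)]
                    e = e * f if direction == "repressed" else e / f
                expected.loc[l.id, s] = e
    return expected


def _draw_counts(
    spec: FixtureSpec, expected: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    if spec.count_model == "exact":
        return expected.round().astype(int)
    return pd.DataFrame(
        rng.poisson(expected.values),
        index=expected.index,
        columns=expected.columns,
    )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


# --------------------------------------------------------------- emission


def _write_fasta(path: Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, models: Sequence[TranscriptModel], chrom_lengths: Mapping[str, int]) -> None:
    type_of = {
        "rRNA": "rRNA",
        "mRNA": "mRNA",
        "known_ncRNA": "ncRNA",
        "TUF": "ncRNA",
        "spike_in": "spike_in",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, clen in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {clen}\n")
        for t in models:
            ftype = type_of[t.biotype]
            attrs = f"ID={t.id};biotype={t.biotype}"
            fh.write(
                f"{t.chrom}\tnsrseq_sim\t{ftype}\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for j, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\tnsrseq_sim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.id}.exon{j};Parent={t.id}\n"
                )


class _SamWriter:
    def __init__(self, path: Path, chrom_lengths: Mapping[str, int]):
        self.fh = open(path, "w")
        self.fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, clen in chrom_lengths.items():
            self.fh.write(f"@SQ\tSN:{chrom}\tLN:{clen}\n")
        self.n = 0

    def write(self, read_id: str, chrom: str, start: int, strand: str, seq: str) -> None:
        flag = 16 if strand == "-" else 0
        self.fh.write(
            f"{read_id}\t{flag}\t{chrom}\t{start + 1}\t255\t{len(seq)}M\t*\t0\t0\t"
            f"{seq}\tI" + "I" * (len(seq) - 1) + "\n"
        )
        self.n += 1

    def close(self) -> None:
        self.fh.close()


def _exon_positions(model: TranscriptModel, read_len: int) -> list[tuple[int, int]]:
    """(start_min, start_max_exclusive) windows for fully-exonic reads."""
    return [
        (s, e - read_len + 1) for s, e in model.exons if e - s >= read_len
    ]


def _sample_starts(
    windows: list[tuple[int, int]], count: int, rng: np.random.Generator
) -> np.ndarray:
    sizes = np.array([hi - lo for lo, hi in windows])
    if sizes.sum() <= 0 or count == 0:
        return np.empty(0, dtype=int)
    which = rng.choice(len(windows), size=count, p=sizes / sizes.sum())
    offs = rng.integers(0, sizes[which])
    return np.array([windows[w][0] for w in which]) + offs


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Generate all fixture files plus the ground-truth ledger.

    Validates and plans the full layout before any file is written, so an
    infeasible spec leaves the output directory untouched.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)

    loci = _plan_loci(spec, rng)
    planted_de, cluster_members, shifted = _plan_planted(spec, loci, rng)
    _place_on_chromosomes(spec, loci, rng)
    models = [l.model() for l in loci]

    # genome + spike contigs
    genome_arr = {
        chrom: _random_bases(rng, clen, spec.gc)
        for chrom, clen in spec.chrom_lengths.items()
    }
    motifs = _plant_motifs(spec, loci, genome_arr, rng)
    spike_ref, spike_expected = _spike_ladder(spec, rng)
    spike_models = []
    for sid, (_conc, length) in spike_ref.entries.items():
        genome_arr[sid] = _random_bases(rng, length, 0.5)
        spike_models.append(
            TranscriptModel(
                id=sid, chrom=sid, strand="+", start=0, end=length,
                exons=((0, length),), biotype="spike_in",
            )
        )
    genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}
    all_models = models + spike_models
    annotation = Annotation(all_models)
    all_chrom_lengths = dict(spec.chrom_lengths)
    all_chrom_lengths.update(
        {sid: e[1] for sid, e in spike_ref.entries.items()}
    )

    expected = _expected_counts(spec, loci, planted_de, rng)
    counts = _draw_counts(spec, expected, rng)
    if spec.exact_mix:
        groups = {
            "rRNA": [l.id for l in loci if l.biotype == "rRNA"],
            "mRNA": [l.id for l in loci if l.biotype == "mRNA"],
            "known_ncRNA": [l.id for l in loci if l.biotype in ("known_ncRNA", "TUF")],
        }
        for cat, ids in groups.items():
            total = round(spec.total_reads * spec.category_mix.get(cat, 0.0))
            for s in spec.samples:
                w = expected.loc[ids, s].values
                counts.loc[ids, s] = _largest_remainder(w, total)

    # spike counts (ladder identical in every sample up to counting noise)
    spike_exp_series = pd.Series(spike_expected, dtype=float)
    spike_counts = pd.DataFrame(
        0, index=spike_exp_series.index, columns=list(spec.samples), dtype=int
    )
    for s in spec.samples:
        if spec.count_model == "exact":
            spike_counts[s] = spike_exp_series.round().astype(int)
        else:
            spike_counts[s] = rng.poisson(spike_exp_series.values)

    # background category totals
    bg_cats = ("antisense", "intronic", "intergenic")
    bg_totals: dict[str, dict[str, int]] = {}
    for s in spec.samples:
        bg_totals[s] = {}
        for cat in bg_cats:
            exp = spec.total_reads * spec.category_mix.get(cat, 0.0)
            if spec.exact_mix or spec.count_model == "exact":
                bg_totals[s][cat] = round(exp)
            else:
                bg_totals[s][cat] = int(rng.poisson(exp))

    # placement targets for background reads
    model_by_id = {m.id: m for m in all_models}
    mrna_models = [m for m in models if m.biotype == "mRNA"]
    anti_windows = [
        (m, _exon_positions(m, spec.read_length)) for m in mrna_models
    ]
    intron_windows = [
        (m, [(s, e - spec.read_length + 1) for s, e in m.introns if e - s >= spec.read_length])
        for m in mrna_models
    ]
    intron_windows = [(m, w) for m, w in intron_windows if w]
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom, clen in spec.chrom_lengths.items():
        occupied = sorted(
            (m.start, m.end) for m in models if m.chrom == chrom
        )
        cursor, out = 0, []
        for s, e in occupied:
            if s - cursor >= spec.read_length:
                out.append((cursor, s - spec.read_length + 1))
            cursor = max(cursor, e)
        if clen - cursor >= spec.read_length:
            out.append((cursor, clen - spec.read_length + 1))
        gaps[chrom] = out

    priming = spec.priming_hexamers

    def locus_read_starts(model: TranscriptModel, n: int) -> np.ndarray:
        windows = _exon_positions(model, spec.read_length)
        if not windows:
            return np.empty(0, dtype=int)
        if priming:
            k = len(next(iter(priming)))
            chrom_seq = genome[model.chrom]
            sites = [
                p
                for lo, hi in windows
                for p in range(lo, hi)
                if chrom_seq[p : p + k] in priming
            ]
            if sites:
                return rng.choice(np.array(sites), size=n)
        return _sample_starts(windows, n, rng)

    # emit files
    outdir.mkdir(parents=True, exist_ok=True)
    genome_fasta = outdir / "genome.fa"
    _write_fasta(genome_fasta, genome.items())
    rrna_fasta = outdir / "rrna.fa"
    _write_fasta(
        rrna_fasta,
        [
            (m.id, genome[m.chrom][m.start : m.end])
            for m in models
            if m.biotype == "rRNA"
        ],
    )
    annotation_gff3 = outdir / "annotation.gff3"
    _write_gff3(annotation_gff3, all_models, all_chrom_lengths)
    spikein_tsv = outdir / "spikein.tsv"
    spike_ref.to_table(spikein_tsv)

    sam_by_sample: dict[str, Path] = {}
    category_counts: dict[str, dict[str, int]] = {}
    library_size: dict[str, int] = {}
    for s in spec.samples:
        path = outdir / f"alignments_{s}.sam"
        w = _SamWriter(path, all_chrom_lengths)
        cat_counts = {
            "rRNA": 0, "mRNA": 0, "known_ncRNA": 0,
            "antisense": 0, "intergenic": 0, "intronic": 0, "spike_in": 0,
        }
        i = 0
        for lid in counts.index:
            model = model_by_id[lid]
            n = int(counts.loc[lid, s])
            cat = "known_ncRNA" if model.biotype == "TUF" else model.biotype
            for start in locus_read_starts(model, n):
                seq = genome[model.chrom][start : start + spec.read_length]
                w.write(f"{s}:r{i:07d}", model.chrom, int(start), model.strand, seq)
                i += 1
            cat_counts[cat] += n
        for sid in spike_counts.index:
            model = model_by_id[sid]
            n = int(spike_counts.loc[sid, s])
            for start in locus_read_starts(model, n):
                seq = genome[sid][start : start + spec.read_length]
                w.write(f"{s}:r{i:07d}", sid, int(start), "+", seq)
                i += 1
            cat_counts["spike_in"] += n
        # antisense of coding exons
        n_anti = bg_totals[s]["antisense"]
        usable = [(m, wins) for m, wins in anti_windows if wins]
        for _ in range(n_anti):
            m, wins = usable[rng.integers(0, len(usable))]
            start = int(_sample_starts(wins, 1, rng)[0])
            strand = "-" if m.strand == "+" else "+"
            seq = genome[m.chrom][start : start + spec.read_length]
            w.write(f"{s}:r{i:07d}", m.chrom, start, strand, seq)
            i += 1
        cat_counts["antisense"] += n_anti
        # intronic
        n_intr = bg_totals[s]["intronic"]
        if n_intr and not intron_windows:
            raise InfeasibleSpecError("intronic reads requested but no intron fits a read")
        for _ in range(n_intr):
            m, wins = intron_windows[rng.integers(0, len(intron_windows))]
            start = int(_sample_starts(wins, 1, rng)[0])
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome[m.chrom][start : start + spec.read_length]
            w.write(f"{s}:r{i:07d}", m.chrom, start, strand, seq)
            i += 1
        cat_counts["intronic"] += n_intr
        # intergenic
        n_inter = bg_totals[s]["intergenic"]
        chrom_list = list(gaps)
        gap_weights = np.array(
            [sum(hi - lo for lo, hi in gaps[c]) for c in chrom_list], dtype=float
        )
        for _ in range(n_inter):
            c = chrom_list[
                rng.choice(len(chrom_list), p=gap_weights / gap_weights.sum())
            ]
            start = int(_sample_starts(gaps[c], 1, rng)[0])
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome[c][start : start + spec.read_length]
            w.write(f"{s}:r{i:07d}", c, start, strand, seq)
            i += 1
        cat_counts["intergenic"] += n_inter
        w.close()
        sam_by_sample[s] = path
        category_counts[s] = cat_counts
        library_size[s] = w.n

    locus_counts = pd.concat([counts, spike_counts])
    locus_counts_tsv = outdir / "locus_counts.tsv"
    locus_counts.to_csv(locus_counts_tsv, sep="\t", index_label="locus")

    clusters_truth = [
        {
            "chrom": cp.chrom,
            "direction": cp.direction,
            "gap": cp.gap,
            "members": members,
        }
        for cp, members in zip(spec.clusters, cluster_members)
    ]
    ledger = TruthLedger(
        locus_counts=locus_counts,
        category_counts=category_counts,
        library_size=library_size,
        planted_de=planted_de,
        clusters=clusters_truth,
        motifs=motifs,
        spike_expected=spike_expected,
    )
    ledger_json = outdir / "truth_ledger.json"
    with open(ledger_json, "w") as fh:
        json.dump(
            {
                "planted_de": planted_de.to_dict(orient="records"),
                "clusters": clusters_truth,
                "status_shift_loci": shifted,
                "motifs": motifs,
                "category_counts": category_counts,
                "library_size": library_size,
                "spike_expected": spike_expected,
            },
            fh,
            indent=1,
        )
    return Fixture(
        outdir=outdir,
        genome_fasta=genome_fasta,
        annotation_gff3=annotation_gff3,
        rrna_fasta=rrna_fasta,
        spikein_tsv=spikein_tsv,
        sam_by_sample=sam_by_sample,
        ledger_json=ledger_json,
        locus_counts_tsv=locus_counts_tsv,
        ledger=ledger,
        annotation=annotation,
        spikein=spike_ref,
        genome=genome,
    )


def make_rrna_filter_case(target_removed: int, k: int = 6) -> RnaReference:
    """A reference whose distinct ACGT k-mer inventory has exactly
    ``target_removed`` members.

    Chosen k-mers are joined with 'N' separators so junction windows
    contain an ambiguity code and contribute nothing; the inventory is
    verified before the reference is returned.
    """
    if not (0 <= target_removed <= 4 ** k):
        raise ValueError(f"target_removed must be in [0, 4^{k}]")
    if target_removed == 0:
        return RnaReference(records=())
    from .primer_design import enumerate_kmers

    chosen = enumerate_kmers(k).members[:target_removed]
    seq = "N".join(chosen)
    ref = RnaReference.from_records([("synthetic_rrna", seq)])
    inventory = ref.kmer_inventory(k)
    if inventory != set(chosen):
        raise AssertionError("inventory verification failed")  # pragma: no cover
    return ref
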