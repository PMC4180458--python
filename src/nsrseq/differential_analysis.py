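"""Threshold-based differential calling of ncRNA loci and its summaries.

Differential expression between a wild-type and a regulator-deficient mutant
(or any two conditions) is called with the simple rule used throughout
small-RNA/ncRNA profiling: a locus passes when the larger of the two RPKM
values exceeds ``rpkm_min`` and the pseudocounted fold change is at least
``fc_min`` in either direction.  "Repressed" means higher expression in the
mutant (the regulator normally represses the locus); "activated" means lower
in the mutant.

Downstream summaries: per-chromosome enrichment (exact binomial test against
the annotation universe), single-linkage genomic clustering of differential
loci, condition-dependent status shifts, and the 2^-ddCt calculator used for
qPCR validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_quant import Annotation, ExpressionTable

__all__ = [
    "DifferentialCall",
    "LocusCluster",
    "StatusShift",
    "DdctMeasurement",
    "DdctResult",
    "DIRECTIONS",
    "call_differential",
    "summarize_calls",
    "chromosome_enrichment",
    "find_clusters",
    "status_shift",
    "ddct_fold_change",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_clusters_bed",
]

REPRESSED = "repressed_by_CEP1"  # higher in the mutant
ACTIVATED = "activated_by_CEP1"  # lower in the mutant
UNCHANGED = "unchanged"
DIRECTIONS = (REPRESSED, ACTIVATED, UNCHANGED)


@dataclass(frozen=True)
class DifferentialCall:
    """Fold change and filter status for one locus between two samples."""

    transcript_id: str
    rpkm_wildtype: float
    rpkm_mutant: float
    fold_change: float
    direction: str
    passes: bool
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass(frozen=True)
class LocusCluster:
    """A run of nearby same-direction differential loci on one chromosome."""

    chrom: str
    members: tuple[str, ...]
    start: int
    end: int
    direction: str


@dataclass(frozen=True)
class StatusShift:
    """A locus whose passing direction differs between two conditions."""

    transcript_id: str
    status_normal: str
    status_uv: str


def call_differential(
    table: ExpressionTable,
    sample_a: str,
    sample_b: str,
    fc_min: float = 2.0,
    rpkm_min: float = 1.0,
    epsilon: float = 0.01,
    annotation: Annotation | None = None,
) -> list[DifferentialCall]:
    """One call per transcript; ``sample_a`` is the wild type / reference.

    fold_change = (rpkm_b + eps) / (rpkm_a + eps); a call passes when
    max(rpkm_a, rpkm_b) > rpkm_min and the fold change clears ``fc_min`` in
    either direction.  The pseudocount keeps on/off loci (zero in one
    condition) callable.  When an annotation is supplied, genomic
    coordinates are attached for clustering and enrichment.
    """
    if table.rpkm is None:
        raise ValueError("ExpressionTable has no RPKM; run compute_rpkm first")
    for s in (sample_a, sample_b):
        if s not in table.rpkm.columns:
            raise ValueError(f"sample {s!r} not present in expression table")
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    calls = []
    for tid, row in table.rpkm[[sample_a, sample_b]].iterrows():
        a, b = float(row[sample_a]), float(row[sample_b])
        fold = (b + epsilon) / (a + epsilon)
        passes = max(a, b) > rpkm_min and (fold >= fc_min or fold <= 1.0 / fc_min)
        if passes:
            direction = REPRESSED if fold >= fc_min else ACTIVATED
        else:
            direction = UNCHANGED
        coords: dict = {}
        if annotation is not None and tid in annotation:
            t = annotation[tid]
            coords = dict(chrom=t.chrom, start=t.start, end=t.end, strand=t.strand)
        calls.append(
            DifferentialCall(
                transcript_id=tid,
                rpkm_wildtype=a,
                rpkm_mutant=b,
                fold_change=fold,
                direction=direction,
                passes=passes,
                **coords,
            )
        )
    return calls


def summarize_calls(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    """Counts per direction and per chromosome over passing calls."""
    rows = [
        {"chrom": c.chrom or "NA", "direction": c.direction}
        for c in calls
        if c.passes
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "direction", "count"])
    df = pd.DataFrame(rows)
    return df.value_counts(["chrom", "direction"]).rename("count").reset_index()


def chromosome_enrichment(
    calls: Sequence[DifferentialCall],
    universe: Annotation | Mapping[str, int],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-chromosome enrichment of passing loci vs the annotation universe.

    ``universe`` is either an Annotation (its per-chromosome locus counts
    define the null proportions) or a mapping chrom -> locus count.  For
    each chromosome a one-sided (greater) exact binomial test compares the
    observed fraction of passing loci against the universe proportion.
    """
    passing = [c for c in calls if c.passes]
    if not passing:
        raise ValueError("no passing calls: nothing to test")
    if isinstance(universe, Annotation):
        uni_counts: dict[str, int] = {}
        for t in universe:
            uni_counts[t.chrom] = uni_counts.get(t.chrom, 0) + 1
    else:
        uni_counts = dict(universe)
    uni_total = sum(uni_counts.values())
    if uni_total <= 0:
        raise ValueError("empty universe")
    obs: dict[str, int] = {}
    for c in passing:
        if c.chrom is None:
            raise ValueError(f"call {c.transcript_id!r} has no chromosome")
        obs[c.chrom] = obs.get(c.chrom, 0) + 1
    n = len(passing)
    rows = []
    n_tests = len(uni_counts)
    for chrom in sorted(uni_counts):
        k = obs.get(chrom, 0)
        p_null = uni_counts[chrom] / uni_total
        pval = stats.binomtest(k, n, p_null, alternative="greater").pvalue
        if bonferroni:
            pval = min(1.0, pval * n_tests)
        rows.append(
            {
                "chrom": chrom,
                "observed": k,
                "observed_fraction": k / n,
                "universe_fraction": p_null,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def find_clusters(
    calls: Sequence[DifferentialCall],
    max_gap: int = 10_000,
    min_size: int = 3,
    same_direction: bool = True,
) -> list[LocusCluster]:
    """Single-linkage chaining of passing loci along each chromosome.

    Loci (optionally restricted to a shared direction) whose successive
    start coordinates lie within ``max_gap`` bases merge into a chain;
    chains with at least ``min_size`` members are reported.  The output is
    deterministic and independent of input ordering.
    """
    passing = [c for c in calls if c.passes and c.chrom is not None]
    clusters: list[LocusCluster] = []
    if same_direction:
        groups = [
            (d, [c for c in passing if c.direction == d])
            for d in (REPRESSED, ACTIVATED)
        ]
    else:
        groups = [("any", passing)]
    for direction, group in groups:
        by_chrom: dict[str, list[DifferentialCall]] = {}
        for c in group:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom in sorted(by_chrom):
            loci = sorted(by_chrom[chrom], key=lambda c: (c.start, c.transcript_id))
            chain: list[DifferentialCall] = []
            for c in loci:
                if chain and c.start - chain[-1].start <= max_gap:
                    chain.append(c)
                else:
                    if len(chain) >= min_size:
                        clusters.append(_make_cluster(chrom, chain, direction))
                    chain = [c]
            if len(chain) >= min_size:
                clusters.append(_make_cluster(chrom, chain, direction))
    clusters.sort(key=lambda cl: (cl.chrom, cl.start, cl.direction))
    return clusters


def _make_cluster(chrom: str, chain: Sequence[DifferentialCall], direction: str) -> LocusCluster:
    if direction == "any":
        dirs = {c.direction for c in chain}
        direction = dirs.pop() if len(dirs) == 1 else "mixed"
    return LocusCluster(
        chrom=chrom,
        members=tuple(c.transcript_id for c in chain),
        start=min(c.start for c in chain),
        end=max(c.end if c.end is not None else c.start for c in chain),
        direction=direction,
    )


def status_shift(
    calls_normal: Sequence[DifferentialCall],
    calls_uv: Sequence[DifferentialCall],
) -> list[StatusShift]:
    """Loci whose passing direction differs between two condition contrasts.

    A record is emitted only when the directions differ; the
    repressed -> activated subset can be counted from the records.
    """
    normal = {c.transcript_id: c.direction for c in calls_normal}
    uv = {c.transcript_id: c.direction for c in calls_uv}
    shared = set(normal) & set(uv)
    if not shared:
        raise ValueError("the two call sets share no transcripts")
    shifts = [
        StatusShift(tid, normal[tid], uv[tid])
        for tid in sorted(shared)
        if normal[tid] != uv[tid]
    ]
    return shifts


@dataclass(frozen=True)
class DdctMeasurement:
    """Replicate Ct values for a target and a reference gene in a sample
    (e.g. mutant) and a control (e.g. wild type) condition.

    Replicates are paired across the four series (same run order)."""

    ct_target_sample: tuple[float, ...]
    ct_reference_sample: tuple[float, ...]
    ct_target_control: tuple[float, ...]
    ct_reference_control: tuple[float, ...]

    def __post_init__(self) -> None:
        series = (
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_control,
            self.ct_reference_control,
        )
        if any(len(s) == 0 for s in series):
            raise ValueError("all four Ct series need at least one replicate")
        if len({len(s) for s in series}) != 1:
            raise ValueError("Ct series must have equal replicate counts (paired)")
        if any(v <= 0 for s in series for v in s):
            raise ValueError("Ct values must be positive")

    @property
    def n_replicates(self) -> int:
        return len(self.ct_target_sample)


@dataclass(frozen=True)
class DdctResult:
    fold: float
    ddct_mean: float
    ddct_sem: float | None
    n_replicates: int


def ddct_fold_change(m: DdctMeasurement) -> DdctResult:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,control -
    Ct_ref,control), computed per replicate pair; fold = 2^-mean(ddCt) with
    the SEM reported on the ddCt (cycle) scale.
    """
    ddct = [
        (ts - rs) - (tc - rc)
        for ts, rs, tc, rc in zip(
            m.ct_target_sample,
            m.ct_reference_sample,
            m.ct_target_control,
            m.ct_reference_control,
        )
    ]
    mean = float(np.mean(ddct))
    sem = (
        float(np.std(ddct, ddof=1) / math.sqrt(len(ddct))) if len(ddct) > 1 else None
    )
    return DdctResult(
        fold=2.0 ** (-mean), ddct_mean=mean, ddct_sem=sem, n_replicates=len(ddct)
    )


# ------------------------------------------------------------------ I/O

_CALL_COLUMNS = [
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
    "rpkm_wildtype",
    "rpkm_mutant",
    "fold_change",
    "direction",
    "passes",
]


def write_calls_tsv(calls: Iterable[DifferentialCall], path) -> None:
    df = pd.DataFrame([c.__dict__ for c in calls])
    df = df[_CALL_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[DifferentialCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            DifferentialCall(
                transcript_id=str(r["transcript_id"]),
                rpkm_wildtype=float(r["rpkm_wildtype"]),
                rpkm_mutant=float(r["rpkm_mutant"]),
                fold_change=float(r["fold_change"]),
                direction=str(r["direction"]),
                passes=bool(r["passes"]),
                chrom=None if pd.isna(r["chrom"]) else str(r["chrom"]),
                start=None if pd.isna(r["start"]) else int(r["start"]),
                end=None if pd.isna(r["end"]) else int(r["end"]),
                strand=None if pd.isna(r["strand"]) else str(r["strand"]),
            )
        )
    return calls


def write_clusters_bed(clusters: Iterable[LocusCluster], path, header: str | None = None) -> None:
    """BED: chrom, start, end, cluster id, member count, direction column."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, cl in enumerate(clusters, 1):
            fh.write(
                f"{cl.chrom}\t{cl.start}\t{cl.end}\tcluster_{i:03d}|{cl.direction}"
                f"\t{len(cl.members)}\t+\n"
            )
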