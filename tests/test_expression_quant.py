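"""Tests for read classification, counting, RPKM and spike-in correlation."""

import numpy as np
import pandas as pd
import pytest

from nsrseq import expression_quant as eq
from nsrseq import synthetic_data as sd
from nsrseq.expression_quant import (
    AlignmentRecord,
    Annotation,
    ExpressionTable,
    SpikeInReference,
    TranscriptModel,
    classify_alignments,
    compute_rpkm,
    count_reads,
    spikein_correlation,
)


@pytest.fixture()
def toy_annotation():
    return Annotation(
        [
            TranscriptModel("rrna1", "I", "+", 100, 300, ((100, 300),), "rRNA"),
            TranscriptModel(
                "m1", "I", "+", 200, 1000, ((200, 500), (800, 1000)), "mRNA"
            ),
            TranscriptModel("nc1", "I", "-", 2000, 2400, ((2000, 2400),), "known_ncRNA"),
        ]
    )


def aln(chrom="I", strand="+", start=0, end=80, name="r", primary=True):
    return AlignmentRecord(name, chrom, strand, start, end, primary)


class TestTranscriptModel:
    def test_tss_is_strand_aware(self):
        plus = TranscriptModel("a", "I", "+", 10, 50, ((10, 50),), "mRNA")
        minus = TranscriptModel("b", "I", "-", 10, 50, ((10, 50),), "mRNA")
        assert plus.tss == 10 and minus.tss == 49

    def test_exons_validated(self):
        with pytest.raises(ValueError, match="outside span"):
            TranscriptModel("a", "I", "+", 10, 50, ((5, 20),), "mRNA")
        with pytest.raises(ValueError, match="sorted"):
            TranscriptModel("a", "I", "+", 0, 100, ((50, 80), (10, 40)), "mRNA")

    def test_introns_are_exon_gaps(self):
        t = TranscriptModel("a", "I", "+", 0, 100, ((0, 20), (50, 100)), "mRNA")
        assert t.introns == ((20, 50),)
        assert t.exonic_length == 70


class TestClassify:
    def test_priority_rrna_beats_mrna(self, toy_annotation):
        # read overlaps both the rRNA exon and the mRNA first exon
        bd = classify_alignments([aln(start=250, end=330)], toy_annotation)
        assert bd.counts["rRNA"] == 1 and bd.n_classified == 1

    def test_antisense_of_coding_exon(self, toy_annotation):
        bd = classify_alignments([aln(strand="-", start=820, end=900)], toy_annotation)
        assert bd.counts["antisense"] == 1

    def test_sense_ncrna_and_intronic_and_intergenic(self, toy_annotation):
        reads = [
            aln(strand="-", start=2100, end=2180, name="nc"),
            aln(strand="+", start=600, end=700, name="intr"),  # inside m1 intron
            aln(strand="+", start=5000, end=5080, name="inter"),
        ]
        bd = classify_alignments(reads, toy_annotation)
        assert bd.counts["known_ncRNA"] == 1
        assert bd.counts["intronic"] == 1
        assert bd.counts["intergenic"] == 1
        assert sum(bd.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_chromosome_goes_intergenic(self, toy_annotation):
        bd = classify_alignments([aln(chrom="chrUn")], toy_annotation)
        assert bd.counts["intergenic"] == 1

    def test_secondary_alignments_ignored_and_empty_errors(self, toy_annotation):
        with pytest.raises(ValueError, match="empty"):
            classify_alignments([aln(primary=False)], toy_annotation)

    def test_exact_mix_fixture_recovers_planted_fractions(self, tmp_path):
        """1000 reads at 600/100/50/50/100/100 planted placement."""
        mix = {
            "mRNA": 0.60,
            "rRNA": 0.10,
            "known_ncRNA": 0.05,
            "antisense": 0.05,
            "intronic": 0.10,
            "intergenic": 0.10,
        }
        spec = sd.FixtureSpec(
            seed=11,
            chrom_lengths={c: 60_000 for c in sd.CHROMS},
            n_mrna=6,
            n_ncrna=20,
            n_tuf=2,
            total_reads=1000,
            category_mix=mix,
            exact_mix=True,
            spike_species=0,
            with_uv=False,
            n_de_scattered=2,
            clusters=(),
            n_motif_genes=5,
            motif_universe=10,
        )
        fx = sd.make_fixture(spec, tmp_path)
        bd = classify_alignments(
            eq.read_sam(fx.sam_by_sample["N2"]), fx.annotation
        )
        assert bd.fractions == pytest.approx(
            {
                "mRNA": 0.60,
                "rRNA": 0.10,
                "known_ncRNA": 0.05,
                "antisense": 0.05,
                "intronic": 0.10,
                "intergenic": 0.10,
            }
        )
        assert bd.counts == {
            k: fx.ledger.category_counts["N2"][k] for k in bd.counts
        }


class TestCounting:
    def test_stranded_counting(self, toy_annotation):
        same = count_reads(
            {"s": [aln(strand="-", start=2100, end=2180)]}, toy_annotation
        )
        assert same.counts.loc["nc1", "s"] == 1
        opposite = count_reads(
            {"s": [aln(strand="+", start=2100, end=2180)]}, toy_annotation
        )
        assert opposite.counts.loc["nc1", "s"] == 0
        unstranded = count_reads(
            {"s": [aln(strand="+", start=2100, end=2180)]},
            toy_annotation,
            strandedness="unstranded",
        )
        assert unstranded.counts.loc["nc1", "s"] == 1

    def test_multi_overlap_increments_each_transcript(self, toy_annotation):
        # read overlapping both the rRNA and the mRNA exon on + strand
        table = count_reads({"s": [aln(start=250, end=330)]}, toy_annotation)
        assert table.counts.loc["rrna1", "s"] == 1
        assert table.counts.loc["m1", "s"] == 1
        assert table.library_size["s"] == 1

    def test_fixture_counts_recovered_exactly(self, study):
        ledger = study.fixture.ledger.locus_counts
        got = study.table.counts.loc[ledger.index]
        assert (got == ledger).all().all()


class TestRpkm:
    def test_identity_example(self):
        counts = pd.DataFrame({"s": [10]}, index=["t"])
        rpkm = compute_rpkm(counts, {"t": 500}, {"s": 1_000_000})
        assert rpkm.loc["t", "s"] == pytest.approx(20.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s": [0]}, index=["t"])
        assert compute_rpkm(counts, {"t": 100}, {"s": 1000}).loc["t", "s"] == 0

    def test_spreadsheet_oracle(self):
        # 7 / (1234/1000) / (3.3e6/1e6) computed independently = 1.71905...
        counts = pd.DataFrame({"s": [7]}, index=["t"])
        rpkm = compute_rpkm(counts, {"t": 1234}, {"s": 3_300_000})
        assert rpkm.loc["t", "s"] == pytest.approx(7 / 1.234 / 3.3)

    def test_errors_name_offender(self):
        counts = pd.DataFrame({"s": [1]}, index=["t"])
        with pytest.raises(ValueError, match="t"):
            compute_rpkm(counts, {"t": 0}, {"s": 1000})
        with pytest.raises(ValueError, match="s"):
            compute_rpkm(counts, {"t": 10}, {"s": 0})

    def test_invariant_to_duplicating_library(self, study):
        counts = study.table.counts
        lengths = study.annotation.exonic_lengths()
        libs = study.table.library_size
        doubled = compute_rpkm(counts * 2, lengths, libs * 2)
        base = compute_rpkm(counts, lengths, libs)
        assert np.allclose(doubled.values, base.values)

    def test_inversion_recovers_counts(self, study):
        rpkm = study.table.rpkm
        lengths = study.annotation.exonic_lengths().reindex(rpkm.index)
        libs = study.table.library_size
        back = rpkm.mul(lengths / 1e3, axis=0).mul(libs / 1e6, axis=1)
        assert np.allclose(back.values, study.table.counts.values)
        assert np.abs(back.values - np.round(back.values)).max() < 1e-6


def ladder_table(concentrations, lengths, lib=1_000_000, scale=5.0, samples=("a",)):
    """Expression table whose RPKM is exactly proportional to concentration.

    Counts are integers, and the reference concentrations are set to
    count/scale so the proportionality is exact despite rounding."""
    ids = [f"S{i:03d}" for i in range(len(concentrations))]
    vec = np.maximum(1, np.round(scale * np.asarray(concentrations))).astype(int)
    counts = pd.DataFrame({s: vec for s in samples}, index=ids)
    table = ExpressionTable(counts=counts, library_size=pd.Series({s: lib for s in samples}))
    table.rpkm = compute_rpkm(counts, dict(zip(ids, lengths)), table.library_size)
    ref = SpikeInReference(
        entries={i: (float(c), int(l)) for i, c, l in zip(ids, vec / scale, lengths)}
    )
    return table, ref


class TestSpikeInCorrelation:
    def test_proportional_observation_gives_r_of_one(self):
        conc = np.geomspace(1, 1e4, 24)
        table, ref = ladder_table(conc, [1000] * 24)
        rep = spikein_correlation(table, ref, min_count=1, pseudocount=0.0)
        assert rep.reference_r["a"] == pytest.approx(1.0, abs=1e-12)

    def test_log_correlation_invariant_to_global_scaling(self):
        conc = np.geomspace(1, 1e4, 24)
        table, ref = ladder_table(conc, [1000] * 24)
        r1 = spikein_correlation(table, ref, pseudocount=0.0).reference_r["a"]
        table.rpkm = table.rpkm * 37.5
        r2 = spikein_correlation(table, ref, pseudocount=0.0).reference_r["a"]
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_identical_samples_have_pairwise_r_one(self):
        conc = np.geomspace(1, 1e4, 24)
        table, ref = ladder_table(conc, [1000] * 24, samples=("a", "b"))
        rep = spikein_correlation(table, ref)
        assert rep.pairwise_spike_r.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_three_species_errors(self):
        table, ref = ladder_table([1.0, 10.0], [500, 500])
        with pytest.raises(ValueError, match="3 spike-in"):
            spikein_correlation(table, ref)

    def test_zero_variance_reports_undefined_not_nan(self):
        table, ref = ladder_table([5.0, 5.0, 5.0, 5.0], [500] * 4)
        rep = spikein_correlation(table, ref, min_count=1)
        assert rep.reference_r["a"] is None

    def test_noisy_ladder_r_within_simulation_band(self):
        """Lognormal sigma=0.2 on log10 counts: band fixed by a replicated
        independent simulation of the same generative model."""
        rng = np.random.default_rng(42)
        conc = np.geomspace(1e-1, 1e5, 92)
        log_expected = np.log10(conc) + 1.0
        rs = []
        for _ in range(200):
            obs = 10 ** (log_expected + 0.2 * rng.standard_normal(92))
            keep = obs >= 5
            r = np.corrcoef(np.log10(conc[keep]), np.log10(obs[keep]))[0, 1]
            rs.append(r)
        lo, hi = np.quantile(rs, [0.001, 0.999])
        obs = 10 ** (log_expected + 0.2 * np.random.default_rng(7).standard_normal(92))
        counts = np.round(obs).astype(int)
        ids = [f"S{i:03d}" for i in range(92)]
        table = ExpressionTable(
            counts=pd.DataFrame({"a": counts}, index=ids),
            library_size=pd.Series({"a": 1_000_000}),
        )
        table.rpkm = compute_rpkm(
            table.counts, {i: 1000 for i in ids}, table.library_size
        )
        ref = SpikeInReference(
            entries={i: (float(c), 1000) for i, c in zip(ids, conc)}
        )
        r = spikein_correlation(table, ref).reference_r["a"]
        assert lo <= r <= hi


class TestIO:
    def test_sam_roundtrip_via_pysam(self, small_fixture):
        recs = list(eq.read_sam(small_fixture.sam_by_sample["N2"]))
        assert len(recs) == small_fixture.ledger.library_size["N2"]
        assert all(r.end - r.start == 80 for r in recs)
        assert {r.strand for r in recs} == {"+", "-"}

    def test_bed_alignment_reader(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("I\t100\t180\tread1\t0\t-\n")
        (rec,) = eq.read_bed_alignments(bed)
        assert (rec.chrom, rec.start, rec.end, rec.strand) == ("I", 100, 180, "-")

    def test_gff3_roundtrip_matches_in_memory_annotation(self, small_fixture):
        loaded = eq.Annotation.from_gff3(small_fixture.annotation_gff3)
        orig = small_fixture.annotation
        assert set(loaded.transcripts) == set(orig.transcripts)
        for tid in orig.transcripts:
            a, b = orig[tid], loaded[tid]
            assert (a.chrom, a.strand, a.start, a.end, a.exons, a.biotype) == (
                b.chrom, b.strand, b.start, b.end, b.exons, b.biotype
            )

    def test_bed12_parsing(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text(
            "I\t100\t1000\ttx1\t0\t+\t100\t1000\t0\t2\t200,300\t0,600\n"
        )
        ann = eq.Annotation.from_bed12(bed, biotype="mRNA")
        t = ann["tx1"]
        assert t.exons == ((100, 300), (700, 1000))
        assert t.biotype == "mRNA"

    def test_spikein_table_roundtrip(self, small_fixture, tmp_path):
        ref = eq.SpikeInReference.from_table(small_fixture.spikein_tsv)
        assert ref.entries.keys() == small_fixture.spikein.entries.keys()
        for k, (c, l) in small_fixture.spikein.entries.items():
            assert ref.entries[k][0] == pytest.approx(c, rel=1e-9)
            assert ref.entries[k][1] == l
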