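from types import SimpleNamespace

import pytest

from nsrseq import differential_analysis as da
from nsrseq import expression_quant as eq
from nsrseq import synthetic_data as sd


def run_pipeline(fixture: sd.Fixture) -> SimpleNamespace:
    """Count reads from the SAM files and compute RPKM for all samples."""
    table = eq.count_reads(
        {s: eq.read_sam(p) for s, p in fixture.sam_by_sample.items()},
        fixture.annotation,
    )
    table.rpkm = eq.compute_rpkm(
        table.counts, fixture.annotation.exonic_lengths(), table.library_size
    )
    return SimpleNamespace(fixture=fixture, annotation=fixture.annotation, table=table)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The default two-genotype x two-treatment study fixture, quantified.

    200 ncRNA loci with 20 planted >=2.5-fold differential loci (10 of them
    in three genomic clusters), 92-species spike-in ladder, Poisson counts
    with lognormal inter-locus spread sigma = 0.1.
    """
    fixture = sd.make_fixture(
        sd.FixtureSpec(seed=1), tmp_path_factory.mktemp("study")
    )
    ns = run_pipeline(fixture)
    ns.calls_normal = da.call_differential(
        ns.table, "N2", "cep1", annotation=ns.annotation
    )
    ns.calls_uv = da.call_differential(
        ns.table, "N2_UV", "cep1_UV", annotation=ns.annotation
    )
    ns.ncrna_ids = [t.id for t in ns.annotation if t.biotype == "known_ncRNA"]
    return ns


@pytest.fixture(scope="session")
def zero_noise(tmp_path_factory):
    """Deterministic fixture: sigma = 0 and exact (rounded) expected counts."""
    fixture = sd.make_fixture(
        sd.FixtureSpec(seed=2, noise_sigma=0.0, count_model="exact", with_uv=False),
        tmp_path_factory.mktemp("zero_noise"),
    )
    return run_pipeline(fixture)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A light fixture for I/O and CLI tests."""
    spec = sd.FixtureSpec(
        seed=7,
        chrom_lengths={c: 60_000 for c in sd.CHROMS},
        n_mrna=8,
        n_ncrna=40,
        n_tuf=4,
        total_reads=6_000,
        spike_species=12,
        spike_max_expected=300.0,
        with_uv=False,
        n_de_scattered=4,
        clusters=(sd.ClusterPlan("X", 3, 4000, "repressed"),),
        n_motif_genes=10,
        motif_universe=20,
    )
    return sd.make_fixture(spec, tmp_path_factory.mktemp("small"))
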