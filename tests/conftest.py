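import pytest

import clipinv as ci
from clipinv.splitread import reconstruct_reference_segments


@pytest.fixture(scope="session")
def fixture_set():
    return ci.load_fixtures()


@pytest.fixture(scope="session")
def segments(fixture_set):
    """Local 7p/7q reference segments reconstructed from the evidence reads."""
    return reconstruct_reference_segments(fixture_set.table2_reads)


@pytest.fixture(scope="session")
def fixture_sam(tmp_path_factory, fixture_set):
    header, records = ci.build_fixture_sam(fixture_set)
    path = tmp_path_factory.mktemp("fixture") / "published.sam"
    ci.write_sam(path, records, header)
    return path


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_sam, fixture_set, segments):
    """(result, config) of the end-to-end run on the published evidence."""
    cfg = ci.PipelineConfig(
        scan=ci.ScanConfig(
            region_a=fixture_set.region_a, region_b=fixture_set.region_b
        ),
        segments=segments,
        sample_id="proband",
    )
    return ci.run_pipeline(fixture_sam, cfg), cfg


def run_sim_pipeline(ds, tmpdir):
    """Simulate -> pipeline convenience used by several test modules."""
    cfg = ds.config
    sam = tmpdir / f"sim_{cfg.seed}_{cfg.homology_len}.sam"
    fasta = tmpdir / f"sim_{cfg.seed}_{cfg.homology_len}.fasta"
    ds.write_truth_sam(sam)
    ds.write_reference_fasta(fasta)
    pcfg = ci.PipelineConfig(
        scan=ci.ScanConfig(
            region_a=ci.GenomicInterval(cfg.chrom, 1, cfg.centromere),
            region_b=ci.GenomicInterval(
                cfg.chrom, cfg.centromere + 1, cfg.genome_length
            ),
        ),
        reference_fasta=str(fasta),
    )
    return ci.run_pipeline(sam, pcfg), pcfg


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """One default-condition simulated dataset plus its pipeline result."""
    ds = ci.simulate(ci.SimulationConfig(seed=1))
    result, cfg = run_sim_pipeline(ds, tmp_path_factory.mktemp("sim"))
    return ds, result, cfg
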