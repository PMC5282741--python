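import pytest

from annoforge.forge import DefectKind, ForgeConfig, run_forge

#: the planted-defect census used for end-to-end ledger-recovery checks
FULL_DEFECT_SPEC = {
    DefectKind.UTR_MISSING: 10,
    DefectKind.SPLIT_MODEL: 3,
    DefectKind.HIDDEN_ISOFORM: 4,
    DefectKind.NOVEL_GENE_UNANNOTATED: 5,
    DefectKind.GENOME_BASE_DELETION: 2,
    DefectKind.GENOME_BASE_SUBSTITUTION: 2,
    DefectKind.CONTAMINANT_CONTIG: 8,
    DefectKind.SPIKEIN_CONTIG: 4,
    DefectKind.ARTEFACT_TRANSCRIPT: 3,
}

FORGE_SEED = 11


@pytest.fixture(scope="session")
def full_config() -> ForgeConfig:
    return ForgeConfig(seed=FORGE_SEED, n_genes=120,
                       defect_spec=dict(FULL_DEFECT_SPEC))


@pytest.fixture(scope="session")
def full_run(full_config):
    """Forge run with every defect kind planted, error-free transcripts."""
    return run_forge(full_config, error_rate=0.0)


@pytest.fixture(scope="session")
def noisy_run(full_config):
    """Same forge genome with 0.5% per-base substitution errors."""
    return run_forge(full_config, error_rate=0.005)


@pytest.fixture(scope="session")
def clean_run():
    """A defect-free forge run: observed annotation equals truth."""
    return run_forge(ForgeConfig(seed=5, n_genes=40), error_rate=0.0)


def run_full_pipeline(run):
    from annoforge.pipeline import run_pipeline

    return run_pipeline(
        run.genome, run.observed, run.evidence.transcripts,
        run.evidence.read_counts, run.evidence.pileup,
        run.evidence.taxon_map, spikein_db=run.output.spikein_db,
        nonrelated_db=run.output.contaminants)


@pytest.fixture(scope="session")
def full_pipeline_result(full_run):
    return run_full_pipeline(full_run)


@pytest.fixture(scope="session")
def noisy_pipeline_result(noisy_run):
    return run_full_pipeline(noisy_run)
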