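import pytest

from geneburden import (
    GeneSpec,
    SimulationConfig,
    archetype_cohort,
    build_matrix,
    default_gene_panel,
    gene_targeted_length,
    intersect_beds,
    read_cohort,
    read_gene_model,
    read_sex_file,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small mixed cohort: autosomal + X genes, multi-allelic sites, all classes."""
    config = SimulationConfig(
        n_cases=25,
        n_controls=25,
        genes=default_gene_panel(12, x_genes=2),
        seed=11,
        multiallelic_fraction=0.2,
    )
    return simulate_cohort(config, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def archetype_bundle(tmp_path_factory):
    return archetype_cohort(
        tmp_path_factory.mktemp("arch"), n_genes=200, n_samples=4, seed=7
    )


@pytest.fixture(scope="session")
def score_bundle():
    """Callable scoring a generated bundle through the full file-based pipeline."""

    def _score(bundle, metric="CADD", corrected=False):
        regions = intersect_beds([str(p) for p in bundle.bed_files])
        gene_targeted_length(regions, read_gene_model(str(bundle.gene_model)))
        cohort = read_cohort(
            str(bundle.vcf),
            str(bundle.annotations),
            metrics=[metric],
            sex_map=read_sex_file(str(bundle.sex_file)),
        )
        return build_matrix(cohort, metric, regions=regions, corrected=corrected)

    return _score
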