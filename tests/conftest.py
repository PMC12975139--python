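import pytest

from osccohort.synthetic import SimulationConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A desk-sized cohort: 4 pairs + 2 tumor-only + 1 normal-only, ~40
    relevant variants per patient, 3 planted exclusives, tiny PRS block."""
    defaults = dict(
        n_paired=4,
        n_tumor_only=2,
        n_normal_only=1,
        relevant_count_mean=40.0,
        relevant_count_sd=4.0,
        relevant_count_min=32,
        relevant_count_max=48,
        background_pool_size=120,
        core_genes=("ABCB1", "TLR1", "VKORC1"),
        gene_prevalence_spectrum={"PERM1": 1.0, "XRCC1": 0.8, "TP53": 0.5},
        exclusive_variants=(
            ("rs5743618", 1.00, "chr4", 38798648, "SNV", "missense_variant",
             "TLR1", "Uncertain_risk_allele"),
            ("rs1805010", 0.46, "chr16", 27356203, "SNV",
             "regulatory_region_variant", "IL4R", "Pathogenic"),
            ("rs546905091", 0.15, "chr8", 48844056, "insertion",
             "intron_variant", "PRKDC", "Pathogenic"),
        ),
        prs_n_snps=80,
        prs_n_controls=40,
        prs_case_shift=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_cohort")
    return generate_cohort(small_config(), outdir)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The study-scale cohort: 14 pairs + 5 tumor-only + 2 normal-only,
    ~171 relevant variants per tumor patient, 5341-SNP PRS over 225
    individuals."""
    outdir = tmp_path_factory.mktemp("default_cohort")
    return generate_cohort(SimulationConfig(seed=11), outdir)
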