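import pytest
from hypothesis import HealthCheck, settings

from bsamap.synthetic_population import SimConfig, emit_dataset, run_simulation

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# A scaled-down cross used by most tests: same architecture as the full study
# design (two homozygous parents, haploid progeny, two bulks, Poisson pool
# depth) on a 0.6 Mb two-scaffold genome so one simulation runs in ~10 ms.
SMALL_CONFIG = SimConfig(
    n_scaffolds=2,
    scaffold_lengths=(300_000, 300_000),
    n_markers=240,
    n_progeny=60,
    pool_size=12,
    mean_depth=40.0,
    causal_locus=("scaffold1", 150_000),
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_sim():
    return run_simulation(SMALL_CONFIG)


@pytest.fixture(scope="session")
def dataset_paths(tmp_path_factory, small_sim):
    """The small simulation emitted to disk (VCF/GFF3/FASTA/TSV)."""
    outdir = tmp_path_factory.mktemp("dataset")
    return emit_dataset(small_sim, outdir)


@pytest.fixture(scope="session")
def default_sim():
    """One simulation at the full study-design defaults (7021 markers)."""
    return run_simulation(SimConfig(), seed=1)
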