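import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n))


@pytest.fixture(scope="session")
def tiny_genome():
    """A small genome with one clean X array, one Y repeat and a decoy."""
    from kshred.simulate import GenomeSpec, RepeatClusterSpec, build_genome

    spec = GenomeSpec(
        chromosomes={"A1": 60_000, "X": 30_000, "Y": 12_000},
        mito_length=1_500,
        gc=0.4,
        clusters=[
            RepeatClusterSpec("X", 300, 20, unit_seed=11, start=2_000, name="x_array"),
            RepeatClusterSpec("X", 200, 12, unit_seed=12, start=12_000, inverted_block=(5, 8), name="x_inv"),
            RepeatClusterSpec("A1", 250, 10, unit_seed=13, start=5_000, name="a_array"),
            RepeatClusterSpec("Y", 150, 8, unit_seed=14, start=1_000, name="y_array"),
        ],
        seed=7,
    )
    genome, truth = build_genome(spec)
    return spec, genome, truth


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One small end-to-end simulation + census + binning, shared by tests."""
    from kshred.binning import BinningParams, process_long_reads
    from kshred.census import CensusParams, count_kmers, merge_census
    from kshred.demo import demo_longread_params, demo_read_params, mini_genome_spec
    from kshred.simulate import build_genome, simulate_long_reads, simulate_short_reads

    d = tmp_path_factory.mktemp("mini_run")
    spec = mini_genome_spec(seed=1)
    genome, truth = build_genome(spec)
    simulate_short_reads(genome, demo_read_params("male", 11), d / "m.fastq")
    simulate_short_reads(genome, demo_read_params("female", 12), d / "f.fastq")
    simulate_long_reads(genome, demo_longread_params(13), d / "lr.fasta")
    params = CensusParams()
    census = merge_census(
        count_kmers(d / "m.fastq", params), count_kmers(d / "f.fastq", params), params
    )
    result = process_long_reads(d / "lr.fasta", census, genome["MT"], BinningParams())
    return {
        "dir": d,
        "spec": spec,
        "genome": genome,
        "truth": truth,
        "census": census,
        "result": result,
    }
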