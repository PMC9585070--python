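import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pamscape import default_registry
from pamscape import segmentation as seg
from pamscape import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def toy_genome_spec():
    """300 kb two-chromosome genome: one GC-rich block, one all-N run."""
    return sim.GenomeSpec(
        chrom_lengths={"1": 200_000, "2": 100_000},
        background_gc=0.41,
        gc_blocks=(("1", 0, 50_000, 0.70),),
        n_runs=(("2", 0, 10_000),),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory, toy_genome_spec):
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    sim.write_fasta(sim.generate_genome(toy_genome_spec), path)
    return path


@pytest.fixture(scope="session")
def toy_concat(toy_fasta):
    return seg.concatenate_autosomes(toy_fasta)


@pytest.fixture(scope="session")
def toy_segments(toy_fasta, toy_concat):
    """30 segments of 10 kb over the toy genome."""
    return seg.segment_table(toy_fasta, toy_concat, 30)


@pytest.fixture(scope="session")
def toy_plan(toy_concat):
    return seg.plan_segments(toy_concat.total_length, 30)


@pytest.fixture(scope="session")
def toy_seqs(toy_fasta, toy_concat, toy_plan):
    return list(seg.segment_sequences(toy_fasta, toy_concat, toy_plan))
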