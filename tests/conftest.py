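import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sisterstrand import annotation as am
from sisterstrand import synthetic_data as sim
from sisterstrand.datasets import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_study():
    """The standard simulated study: 2 tissues x 20 samples, 50 pairs/mode."""
    return sim.simulate_study(sim.SimulationConfig(seed=1))


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[6.0, 2.0, 7.0, 1.0], [3.0, 7.0, 2.0, 8.0], [1.0, 1.0, 1.0, 1.0]],
        index=["m1", "m2", "m3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


def make_interval(start, end, strand="+", chrom="chr1"):
    return am.GenomicInterval(chrom, start, end, strand)


def make_gene(gene_id, start, end, strand="+"):
    return am.GeneRecord(gene_id, make_interval(start, end, strand))


def make_hairpin(hid, start, end, strand="+", mature_ids=()):
    return am.HairpinRecord(hid, make_interval(start, end, strand), list(mature_ids))


def make_mature(mid, hid, start, end, strand="+", arm=None):
    return am.MatureRecord(mid, hid, make_interval(start, end, strand), arm)
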