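import numpy as np
import pytest

from svscape.model import GenomeModel, SVCatalog, SVRecord
from svscape.simulate import SimulationConfig, simulate_world


def small_config(seed: int = 7) -> SimulationConfig:
    """Reduced world for unit tests: ~45 SVs, 60 genes, 2 x 1.5 Mb."""
    return SimulationConfig(
        seed=seed,
        chrom_lengths={"1": 1_500_000, "2": 1_500_000},
        n_genes=60,
        sv_counts={"DEL": 20, "MEI": 10, "DUP": 5, "INV": 2, "BND": 8},
        n_snps=60,
        n_coupled_svs=4,
        n_tissues=2,
        n_traits=4,
        n_repeats_random=10,
    )


@pytest.fixture(scope="session")
def world():
    return simulate_world(small_config())


@pytest.fixture
def toy_genome():
    return GenomeModel({"1": 100_000, "2": 100_000},
                       gaps=[("1", 5_000, 6_000)])


def make_record(chrom="1", start=1000, end=1999, svtype="DEL", **kw) -> SVRecord:
    sv_id = kw.pop("id", f"{chrom}:{start}-{end}:{svtype}")
    return SVRecord(id=sv_id, chrom=chrom, start=start, end=end, svtype=svtype, **kw)


def make_catalog(records, n_samples=4) -> SVCatalog:
    samples = tuple(f"S{i}" for i in range(n_samples))
    return SVCatalog(list(records), samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
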