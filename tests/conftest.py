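import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panpav.simdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A small two-group panel whose class bands are all feasible (N = 24)."""
    return SimConfig(
        seed=11,
        groups=(("G1", 14), ("G2", 10)),
        n_core_genes=20, n_softcore=0, n_shell=40, n_cloud=30,
        group_preferred={"G1": 5, "G2": 5}, preferred_leak_max=0.0,
        n_sites=400, chrom_length=300_000,
        n_contigs_per_accession=1, contig_length_range=(30_000, 50_000),
    )


def random_records(rng, n, min_len=30, max_len=200):
    from panpav.io_formats import SequenceRecord

    out = []
    for i in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGT"), size=ln))
        out.append(SequenceRecord(f"rec{i}", seq))
    return out
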