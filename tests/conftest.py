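import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def snp_table():
    from smarttissue import SnpTable

    pos = np.array([100, 101, 200, 201, 150, 5_000])
    return SnpTable(
        snp_id=np.array([f"rs{i}" for i in range(6)], dtype=object),
        chrom=np.array(["chr1"] * 6, dtype=object),
        pos=pos,
    )
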