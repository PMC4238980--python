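import numpy as np
import pandas as pd
import pytest

from sysgen.io_formats import GeneticMap, GenotypeMatrix


@pytest.fixture
def small_map() -> GeneticMap:
    rows = [
        {"marker_id": f"m{c}_{j}", "chrom": str(c), "pos_cM": j * 10.0,
         "pos_bp": 1_000_000 + j * 5_000_000}
        for c in (1, 2) for j in range(5)
    ]
    return GeneticMap(pd.DataFrame(rows))


@pytest.fixture
def small_geno(small_map) -> GenotypeMatrix:
    rng = np.random.default_rng(7)
    n = 80
    codes = rng.integers(0, 3, size=(n, len(small_map.marker_ids))).astype(float)
    return GenotypeMatrix([f"s{i}" for i in range(n)], small_map.marker_ids, codes)


@pytest.fixture
def single_marker_map() -> GeneticMap:
    return GeneticMap(pd.DataFrame(
        [{"marker_id": "m1", "chrom": "1", "pos_cM": 0.0, "pos_bp": 100}]
    ))
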