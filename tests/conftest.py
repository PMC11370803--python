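import numpy as np
import pandas as pd
import pytest

from mitopop.alignment import HaplotypeAlignment


@pytest.fixture
def toy_alignment():
    """Five 40 bp sequences with a mix of shared and singleton variants."""
    rng = np.random.default_rng(1234)
    base = rng.integers(0, 4, 40)
    rows = np.tile(base, (5, 1)).astype(np.uint8)
    rows[1, 3] = (rows[1, 3] + 1) % 4       # singleton
    rows[2, 10] = (rows[2, 10] + 2) % 4     # shared with row 3
    rows[3, 10] = rows[2, 10]
    rows[4, 25] = (rows[4, 25] + 1) % 4     # singleton
    ids = [f"s{i}" for i in range(5)]
    return HaplotypeAlignment(ids, rows)


@pytest.fixture
def random_alignment_factory():
    """Random small alignments (optionally with missing data) for oracles."""

    def make(seed, n=None, L=None, missing=0.0):
        rng = np.random.default_rng(seed)
        n = n or int(rng.integers(4, 9))
        L = L or int(rng.integers(10, 51))
        anc = rng.integers(0, 4, L)
        mat = np.tile(anc, (n, 1))
        n_mut = int(rng.integers(0, L))
        for _ in range(n_mut):
            i, j = int(rng.integers(0, n)), int(rng.integers(0, L))
            mat[i, j] = (mat[i, j] + int(rng.integers(1, 4))) % 4
        if missing:
            mask = rng.random((n, L)) < missing
            mat[mask] = 4
        ids = [f"r{i}" for i in range(n)]
        return HaplotypeAlignment(ids, mat.astype(np.uint8))

    return make


@pytest.fixture
def marker_panel():
    rng = np.random.default_rng(991199)
    return {
        f"wsp_{i}": "".join("ACGT"[c] for c in rng.integers(0, 4, 500))
        for i in range(3)
    }


@pytest.fixture
def sample_metadata():
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(5)],
            "population": ["P1", "P1", "P2", "P2", "P2"],
            "species": ["gambiae"] * 3 + ["coluzzii"] * 2,
            "latitude": [10.0, 10.1, 11.0, 11.1, 11.2],
            "longitude": [-15.0, -14.9, -10.0, -9.9, -9.8],
            "sex": ["F", "M", "F", "F", "M"],
        }
    )
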