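import numpy as np
import pandas as pd
import pytest

from isoclust import ChunkCollection, ReflectionChunk, UnitCell


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def ortho_cell():
    return UnitCell(54.7, 58.5, 67.4)


def make_chunk(chunk_id, records, cell=None, label=None, crystal_id=None):
    """Build a ReflectionChunk from {(h,k,l): (intensity, sigma)}."""
    cell = cell or UnitCell(10.0, 10.0, 10.0)
    hkl = list(records.keys())
    df = pd.DataFrame(
        {
            "h": [t[0] for t in hkl],
            "k": [t[1] for t in hkl],
            "l": [t[2] for t in hkl],
            "intensity": [records[t][0] for t in hkl],
            "sigma": [records[t][1] for t in hkl],
        }
    )
    return ReflectionChunk(
        chunk_id=chunk_id,
        crystal_id=crystal_id or chunk_id,
        records=df,
        cell=cell,
        label=label,
    )


@pytest.fixture
def chunk_factory():
    return make_chunk


@pytest.fixture
def correlated_chunks(cubic_cell):
    """Four chunks over a shared index set with strongly correlated intensities."""
    rng = np.random.default_rng(11)
    hkl = [(h, k, l) for h in range(1, 5) for k in range(4) for l in range(4)]
    base = rng.exponential(100.0, len(hkl))
    chunks = []
    for i in range(4):
        noisy = base + rng.normal(0, 5.0, len(hkl))
        chunks.append(
            make_chunk(
                f"c{i}",
                {t: (v, 1.0) for t, v in zip(hkl, noisy)},
                cell=cubic_cell,
            )
        )
    return ChunkCollection(chunks=chunks)
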