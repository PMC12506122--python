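import numpy as np
import pytest

from smdiv.incidence import BgcRecord, IncidenceMatrix


@pytest.fixture
def toy_records():
    """Seven BGCs in four species, four GCFs with occupancies (1, 1, 2, 4)."""
    rows = [
        # gcf A: species s1 only (two BGC copies -> collapse)
        ("b1", "A", "s1"), ("b2", "A", "s1"),
        # gcf B: species s2 only
        ("b3", "B", "s2"),
        # gcf C: species s1 and s3
        ("b4", "C", "s1"), ("b5", "C", "s3"),
        # gcf D: all four species (b6..b9)
        ("b6", "D", "s1"), ("b7", "D", "s2"), ("b8", "D", "s3"), ("b9", "D", "s4"),
    ]
    return [BgcRecord(bgc_id=b, gcf_id=g, genome_id=f"g_{s}", species_id=s)
            for b, g, s in rows]


@pytest.fixture
def toy_matrix():
    """4 units x 3 GCFs with occupancies (1, 2, 4) — the worked interpolation case."""
    cells = np.array([
        [1, 1, 1],
        [0, 1, 1],
        [0, 0, 1],
        [0, 0, 1],
    ], dtype=np.uint8)
    return IncidenceMatrix(unit_ids=["s1", "s2", "s3", "s4"],
                           gcf_ids=["A", "B", "C"], cells=cells)


def random_incidence(rng: np.random.Generator, T: int, S: int) -> IncidenceMatrix:
    """Random binary matrix with every GCF present somewhere."""
    cells = (rng.random((T, S)) < rng.uniform(0.15, 0.85)).astype(np.uint8)
    for j in range(S):  # guarantee each column is occupied
        if cells[:, j].sum() == 0:
            cells[rng.integers(T), j] = 1
    return IncidenceMatrix(unit_ids=[f"u{i}" for i in range(T)],
                           gcf_ids=[f"g{j}" for j in range(S)], cells=cells)
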