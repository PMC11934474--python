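import numpy as np
import pytest

from binsig import BinGrid, SampleTrack, TrackSet


def grid_from_rows(rows):
    """rows: list of (chrom, start, end)."""
    return BinGrid.from_arrays(
        np.array([r[0] for r in rows], dtype=object),
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
    )


@pytest.fixture
def small_grid():
    return grid_from_rows([
        ("chr1", 0, 10_000), ("chr1", 10_000, 20_000),
        ("chr1", 20_000, 30_000), ("chr2", 0, 10_000),
        ("chr2", 10_000, 20_000),
    ])


@pytest.fixture
def small_trackset(small_grid):
    t1 = SampleTrack("s1", [5.0, 0.0, 3.0, 7.0, 1.0], small_grid,
                     condition="wt", replicate="1")
    t2 = SampleTrack("s2", [4.0, 0.0, 2.0, 9.0, 0.0], small_grid,
                     condition="ko", replicate="1")
    return TrackSet(small_grid, [t1, t2])


def write_bed(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
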