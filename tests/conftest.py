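import numpy as np
import pytest

from ddasim.chemicals import Chemical
from ddasim.geometry import Rect
from ddasim.roi import Ms1Point, Roi


@pytest.fixture
def worked_query():
    """The worked dissection fixture: query 2x2 box, one offset 2x2 box.

    Overlap is the unit square, so the uncovered fraction is 3/4 and the
    covered fraction 1/4 — exact by elementary geometry.
    """
    query = Rect(0.0, 2.0, 10.0, 12.0)
    other = Rect(1.0, 3.0, 11.0, 13.0)
    return query, other


def make_roi(rts, mzs, intensities, roi_id=0):
    roi = Roi(roi_id, Ms1Point(mzs[0], rts[0], intensities[0]))
    for rt, mz, i in zip(rts[1:], mzs[1:], intensities[1:]):
        roi.add_point(Ms1Point(mz, rt, i))
    return roi


@pytest.fixture
def gaussian_chemical():
    return Chemical(id=0, mz=150.0, apex_rt=300.0, apex_intensity=1e6,
                    sigma=10.0)


def raster_oracle(query: Rect, others, n: int = 500):
    """Grid-rasterization oracle for dissection areas.

    Splits the query into an n x n grid and labels each cell centre with
    the set of other boxes containing it.  Returns (area per owner
    combination, uncovered area), in absolute units.
    """
    rt_edges = np.linspace(query.rt_lo, query.rt_hi, n + 1)
    mz_edges = np.linspace(query.mz_lo, query.mz_hi, n + 1)
    rt_c = 0.5 * (rt_edges[:-1] + rt_edges[1:])
    mz_c = 0.5 * (mz_edges[:-1] + mz_edges[1:])
    cell = (rt_edges[1] - rt_edges[0]) * (mz_edges[1] - mz_edges[0])
    codes = np.zeros((n, n), dtype=np.int64)
    ids = [oid for oid, _ in others]
    for bit, (oid, r) in enumerate(others):
        inside = ((rt_c[:, None] >= r.rt_lo) & (rt_c[:, None] <= r.rt_hi) &
                  (mz_c[None, :] >= r.mz_lo) & (mz_c[None, :] <= r.mz_hi))
        codes[inside] |= 1 << bit
    areas = {}
    vals, counts = np.unique(codes, return_counts=True)
    for v, c in zip(vals, counts):
        owners = frozenset(ids[b] for b in range(len(ids)) if v >> b & 1)
        areas[owners] = c * cell
    return areas, areas.get(frozenset(), 0.0)
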