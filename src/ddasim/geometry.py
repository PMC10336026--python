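"""Axis-aligned rectangle algebra in (rt, m/z) space.

Regions of interest, dynamic exclusion windows and picked peaks are all
axis-aligned boxes with retention time on one axis and m/z on the other.
The area-weighted scores used by the Non-Overlap family of acquisition
strategies need to know, for a query box ``a`` and a set of previously
fragmented boxes, which parts of ``a`` are covered by which subsets of
those boxes.  :func:`dissect` splits the query into interior-disjoint
rectangular pieces, each labelled with the exact subset of other boxes
covering it; :func:`non_overlap_proportion` and
:func:`intensity_region_sum` reduce that dissection to the two scalar
quantities the scoring strategies consume.

Intervals are closed.  Rectangles that merely touch at a boundary have a
zero-area intersection and are treated as non-overlapping: every score
here is an area integral, so measure-zero sets cannot matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping


@dataclass(frozen=True)
class Rect:
    """A closed axis-aligned box: [rt_lo, rt_hi] x [mz_lo, mz_hi]."""

    rt_lo: float
    rt_hi: float
    mz_lo: float
    mz_hi: float

    def __post_init__(self) -> None:
        if self.rt_lo > self.rt_hi or self.mz_lo > self.mz_hi:
            raise ValueError(f"invalid rectangle bounds: {self}")

    @property
    def area(self) -> float:
        return (self.rt_hi - self.rt_lo) * (self.mz_hi - self.mz_lo)

    def contains(self, mz: float, rt: float) -> bool:
        return self.mz_lo <= mz <= self.mz_hi and self.rt_lo <= rt <= self.rt_hi

    def intersect(self, other: "Rect") -> "Rect | None":
        """Intersection with positive area, or None (touching is not overlap)."""
        rt_lo = max(self.rt_lo, other.rt_lo)
        rt_hi = min(self.rt_hi, other.rt_hi)
        mz_lo = max(self.mz_lo, other.mz_lo)
        mz_hi = min(self.mz_hi, other.mz_hi)
        if rt_lo >= rt_hi or mz_lo >= mz_hi:
            return None
        return Rect(rt_lo, rt_hi, mz_lo, mz_hi)

    def overlaps(self, other: "Rect") -> bool:
        return self.intersect(other) is not None


@dataclass
class Dissection:
    """Interior-disjoint pieces of a query rectangle, labelled by owners.

    Each piece is a ``(rect, owners)`` pair where ``owners`` is the exact
    (possibly empty) frozenset of other-box ids covering that piece.  The
    empty frozenset plays the role of the "no other boxes" combination.
    Piece areas sum to the query area; zero-area pieces are omitted.
    """

    query: Rect
    pieces: list[tuple[Rect, frozenset]] = field(default_factory=list)
    degenerate: bool = False

    @property
    def query_area(self) -> float:
        return self.query.area

    def area_by_owners(self) -> dict[frozenset, float]:
        """Total piece area for each distinct owner combination."""
        out: dict[frozenset, float] = {}
        for rect, owners in self.pieces:
            out[owners] = out.get(owners, 0.0) + rect.area
        return out

    @property
    def uncovered_area(self) -> float:
        return sum(r.area for r, owners in self.pieces if not owners)


def dissect(query: Rect, others: Iterable[tuple[Hashable, Rect]]) -> Dissection:
    """Split ``query`` into disjoint rectangles labelled by covering boxes.

    The split is the grid formed by every rt and m/z breakpoint of the
    query and of each other box clipped to the query.  Each grid cell is
    either fully inside or fully outside every clipped box, so the owner
    set of a cell can be read off its centre point.

    A zero-area query yields a single degenerate piece owning nothing;
    callers treat its non-overlap proportion as 1.
    """
    if query.area == 0.0:
        return Dissection(query, [(query, frozenset())], degenerate=True)

    clipped: list[tuple[Hashable, Rect]] = []
    seen_ids = set()
    for oid, rect in others:
        if oid in seen_ids:
            raise ValueError(f"duplicate rectangle id: {oid!r}")
        seen_ids.add(oid)
        inter = query.intersect(rect)
        if inter is not None:
            clipped.append((oid, inter))

    if not clipped:
        return Dissection(query, [(query, frozenset())])

    rt_cuts = sorted({query.rt_lo, query.rt_hi, *(r.rt_lo for _, r in clipped),
                      *(r.rt_hi for _, r in clipped)})
    mz_cuts = sorted({query.mz_lo, query.mz_hi, *(r.mz_lo for _, r in clipped),
                      *(r.mz_hi for _, r in clipped)})

    pieces: list[tuple[Rect, frozenset]] = []
    for i in range(len(rt_cuts) - 1):
        rt_lo, rt_hi = rt_cuts[i], rt_cuts[i + 1]
        if rt_hi <= rt_lo:
            continue
        rt_mid = 0.5 * (rt_lo + rt_hi)
        for j in range(len(mz_cuts) - 1):
            mz_lo, mz_hi = mz_cuts[j], mz_cuts[j + 1]
            if mz_hi <= mz_lo:
                continue
            mz_mid = 0.5 * (mz_lo + mz_hi)
            owners = frozenset(
                oid for oid, r in clipped
                if r.rt_lo <= rt_mid <= r.rt_hi and r.mz_lo <= mz_mid <= r.mz_hi
            )
            pieces.append((Rect(rt_lo, rt_hi, mz_lo, mz_hi), owners))
    return Dissection(query, pieces)


def non_overlap_proportion(d: Dissection) -> float:
    """Fraction of the query's area covered by no other box, in [0, 1]."""
    if d.degenerate:
        return 1.0
    return d.uncovered_area / d.query_area


def intensity_region_sum(
    d: Dissection,
    lam_query: float,
    lam_others: Mapping[Hashable, float],
) -> float:
    """Sum of modified intensities raised to their proportional areas.

    For each owner combination B with positive area, the modified
    intensity is the query intensity minus the largest intensity among
    the boxes in B (zero for the empty combination).  Each positive
    modified intensity is raised to the power area(B)/area(query) and the
    terms are summed; non-positive modified intensities contribute 0.
    This is the argument of the log in the Intensity Non-Overlap score.
    """
    if lam_query < 0:
        raise ValueError("query intensity must be non-negative")
    if d.degenerate:
        return lam_query
    qarea = d.query_area
    total = 0.0
    for owners, area in d.area_by_owners().items():
        if area <= 0.0:
            continue
        ceiling = max((lam_others[o] for o in owners), default=0.0)
        lam_mod = lam_query - ceiling
        if lam_mod > 0.0:
            total += lam_mod ** (area / qarea)
    return total
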