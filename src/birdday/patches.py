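"""Patch construction, MCP areas, daily union and the spatiotemporal
contagion index (SCI).

A patch groups the segments of one bird day whose anchor fixes lie within
the join distance (default 300 m) of each other, by single linkage —
patches are spatially continuous but may be temporally discontinuous when
the bird revisits an area later in the day. Each patch carries a minimum
convex polygon (MCP) over its member fixes buffered by the GPS error
radius, so even a single-fix patch has positive area.

The SCI quantifies whether a day's time was spent among clustered or
among remote patches: it is the ratio of the time-weighted to the
unweighted standard distance of the patch centres, where a patch's weight
is its fix count (1 fix = 30 min). SCI < 1 means time concentrated in
mutually close patches; > 1 means time concentrated in a patch remote
from the rest; equal time in equidistant patches gives exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from shapely.geometry import Point
from shapely.ops import unary_union

from .config import RunConfig
from .segmentation import Segment

_BUFFER_QUAD_SEGS = 32  # fine polygonal approximation of the GPS-error disk


@dataclass
class Patch:
    patch_id: int
    member_segments: list[Segment] = field(repr=False)
    mcp: object = field(repr=False, default=None)  # shapely Polygon
    area_ha: float = np.nan

    @property
    def n_segments(self) -> int:
        return len(self.member_segments)

    @property
    def n_fixes(self) -> int:
        return sum(s.n_fixes for s in self.member_segments)

    @property
    def center(self) -> tuple[float, float]:
        xs = np.concatenate([s.fixes["x"].to_numpy() for s in self.member_segments])
        ys = np.concatenate([s.fixes["y"].to_numpy() for s in self.member_segments])
        return float(xs.mean()), float(ys.mean())

    @property
    def n_revisit_joins(self) -> int:
        return self.n_segments - 1


def build_patches(segments: list[Segment], config: RunConfig) -> list[Patch]:
    """Group segments into patches by single-linkage on anchor points at
    the patch-join distance (chaining allowed), then attach MCPs."""
    if not segments:
        return []
    anchors = np.array([[s.anchor_x, s.anchor_y] for s in segments])
    if len(segments) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(anchors), method="single")
        labels = fcluster(z, t=config.patch_join_m, criterion="distance")
    patches = []
    for pid in np.unique(labels):
        members = [s for s, l in zip(segments, labels) if l == pid]
        p = Patch(patch_id=int(pid), member_segments=members)
        p.mcp, p.area_ha = patch_mcp(p, config)
        patches.append(p)
    # stable ordering by first member's segment id
    patches.sort(key=lambda p: p.member_segments[0].segment_id)
    for i, p in enumerate(patches, start=1):
        p.patch_id = i
    return patches


def patch_mcp(patch: Patch, config: RunConfig):
    """Convex hull of the union of GPS-error disks around member fixes.

    Returns (polygon in planar metres, area in hectares).
    """
    pts = []
    for s in patch.member_segments:
        pts.extend(Point(x, y) for x, y in zip(s.fixes["x"], s.fixes["y"]))
    disks = unary_union([p.buffer(config.gps_buffer_m, quad_segs=_BUFFER_QUAD_SEGS)
                         for p in pts])
    hull = disks.convex_hull
    return hull, float(hull.area) / 1e4


def daily_union(patches: list[Patch]) -> tuple[float, float]:
    """(total_area_ha of the geometric union, overlap_pct).

    overlap_pct = 100 * (sum of patch areas - union area) / sum of areas,
    so disjoint patches give 0 and fully coincident ones approach 100.
    """
    if not patches:
        raise ValueError("no patches")
    union = unary_union([p.mcp for p in patches])
    total_ha = float(union.area) / 1e4
    sum_ha = float(sum(p.area_ha for p in patches))
    overlap_pct = 100.0 * (sum_ha - total_ha) / sum_ha if sum_ha > 0 else 0.0
    return total_ha, max(overlap_pct, 0.0)


def count_revisits(patches: list[Patch]) -> int:
    """Number of within-day returns to an already-used patch: for each
    patch, member segments beyond the first are revisits."""
    return sum(p.n_revisit_joins for p in patches)


def standard_distance(points: np.ndarray, weights: np.ndarray | None = None,
                      center: np.ndarray | None = None) -> float:
    """Root mean squared (optionally weighted) distance of a planar point
    set from its mean centre, or from an explicitly supplied centre."""
    pts = np.asarray(points, dtype=float)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    if center is None:
        center = (pts * w[:, None]).sum(axis=0) / w.sum()
    sq = ((pts - np.asarray(center, float)) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def sci(patches: list[Patch]) -> tuple[float, float] | None:
    """Spatiotemporal contagion index over a day's patches.

    Ratio of the time-weighted to the unweighted standard distance of the
    patch centres, both measured about the unweighted mean centre of the
    patch layout. Weighting by time spent (fix count) and keeping the
    geometric reference centre fixed makes the index respond to *where*
    the time went: < 1 when time concentrates in mutually clustered
    patches, > 1 when it concentrates in a patch remote from the rest,
    and exactly 1 when time is spread equally (or every patch is
    equidistant from the centre).

    Defined only when >= 3 patches were used and the patch centres are
    not all coincident; returns (sci, ln(sci)) or None when undefined.
    """
    if len(patches) < 3:
        return None
    centers = np.array([p.center for p in patches])
    weights = np.array([p.n_fixes for p in patches], dtype=float)
    layout_center = centers.mean(axis=0)
    sd_u = standard_distance(centers, center=layout_center)
    if sd_u == 0.0:
        return None
    sd_w = standard_distance(centers, weights, center=layout_center)
    ratio = sd_w / sd_u
    return ratio, float(np.log(ratio))
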