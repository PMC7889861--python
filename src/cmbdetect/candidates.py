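"""Per-slice circular candidate generation and physiological exclusions.

Microbleeds appear as roughly spherical signal voids, so each axial slice
of the upsampled scan is searched for dark circular outlines:

1. 3x3 Sobel gradient (magnitude + direction),
2. Canny-style non-maximum suppression and hysteresis thresholding with
   bounds expressed as fractions of the slice's maximum gradient magnitude,
3. a circular Hough transform restricted to a physiologically useful radius
   window, keeping accumulator cells above a lenient fraction (default 80%)
   of the slice's accumulator maximum.

The resulting circles are thinned with rules that mirror visual-rating
criteria: circles touching the image border are discarded; overlapping
circles on a slice are merged, groups that are too wide are too large to be
microbleeds, and singleton circles (unmerged with any other) are treated as
noise edges; groups overlapping the CSF mask are excluded as vessels.
Survivors are linked across adjacent slices into 3D candidates, each of
which gets a standardized ROI neighborhood (default 51 x 51 x 25 voxels,
about twice the maximum expected microbleed extent) for geometric
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk

from .config import CutoffConfig


class Status:
    """Candidate life-cycle labels; transitions are monotone (active -> rejected/accepted)."""

    ACTIVE = "active"
    REJECTED_EDGE = "rejected_edge"
    REJECTED_SIZE = "rejected_size"
    REJECTED_SINGLETON = "rejected_singleton"
    REJECTED_CSF = "rejected_csf"
    REJECTED_ENTROPY3D = "rejected_entropy3d"
    REJECTED_ENTROPY2D = "rejected_entropy2d"
    REJECTED_BLOB_VOLUME = "rejected_blob_volume"
    REJECTED_BLOB_COMPACTNESS = "rejected_blob_compactness"
    ACCEPTED = "accepted"


@dataclass
class GradientField:
    """Per-pixel Sobel gradient of one slice."""

    magnitude: np.ndarray
    direction: np.ndarray  # atan2(gy, gx), radians
    gx: np.ndarray
    gy: np.ndarray


@dataclass
class EdgeMap:
    slice_index: int
    edges: np.ndarray  # binary, same in-plane shape as the slice


@dataclass
class CircleCandidate:
    slice_index: int
    center: Tuple[int, int]  # (row, col) in resampled pixels
    radius: int
    score: float  # accumulator votes as fraction of the slice maximum
    status: str = Status.ACTIVE


@dataclass
class CircleGroup:
    """Overlap-merged circles on a single slice."""

    slice_index: int
    circles: List[CircleCandidate]
    center: Tuple[float, float]
    mean_radius: float
    status: str = Status.ACTIVE


@dataclass
class MicrobleedCandidate:
    """A 3D candidate: cross-slice union of circle groups."""

    center3d: Tuple[int, int, int]  # (x, y, z) resampled voxel coords
    member_circles: List[CircleCandidate]
    groups: List[CircleGroup] = field(default_factory=list)
    status: str = Status.ACTIVE

    @property
    def n_circles(self) -> int:
        return len(self.member_circles)

    @property
    def mean_radius_px(self) -> float:
        return float(np.mean([c.radius for c in self.member_circles]))

    def reject(self, status: str) -> None:
        if self.status != Status.ACTIVE:
            return  # monotone: once rejected, never re-labeled
        self.status = status


@dataclass
class RoiNeighborhood:
    """Standardized intensity crop centered on a candidate."""

    grid: np.ndarray
    offset: Tuple[int, int, int]  # crop origin in resampled voxel coords

    @property
    def center_index(self) -> Tuple[int, int, int]:
        return tuple((np.array(self.grid.shape) - 1) // 2)


# ---------------------------------------------------------------------------
# gradient + edges
# ---------------------------------------------------------------------------

def slice_gradient(slice2d: np.ndarray) -> GradientField:
    """3x3 Sobel gradient of one slice (magnitude and direction)."""
    a = np.asarray(slice2d, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("slice must be 2D and at least 3x3")
    gx = ndi.sobel(a, axis=0, mode="reflect")
    gy = ndi.sobel(a, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    return GradientField(mag, direction, gx, gy)


def _nonmax_suppress(mag: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Keep pixels that are local maxima of |grad| along the gradient direction.

    The magnitude one unit step along the (continuous) gradient direction is
    estimated by bilinear interpolation, which keeps curved ridges such as
    small circle rims intact; comparisons use >= so plateaus survive.
    """
    h, w = mag.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    ux = np.cos(direction)
    uy = np.sin(direction)
    fwd = ndi.map_coordinates(
        mag, [rows + ux, cols + uy], order=1, mode="constant", cval=0.0
    )
    bwd = ndi.map_coordinates(
        mag, [rows - ux, cols - uy], order=1, mode="constant", cval=0.0
    )
    return (mag >= fwd) & (mag >= bwd) & (mag > 0)


def detect_edges(
    grad: GradientField,
    low: float = 0.1,
    high: float = 0.15,
    slice_index: int = 0,
    floor: float = 0.0,
) -> EdgeMap:
    """Non-maximum suppression + hysteresis thresholding.

    ``low`` and ``high`` are fractions of the slice's maximum gradient
    magnitude.  Weak pixels (>= low) survive only when 8-connected to a
    strong pixel (>= high).  ``floor`` is an absolute magnitude below
    which a slice is considered featureless: per-slice relative thresholds
    would otherwise amplify numerically negligible ripple (e.g. spline
    interpolation ringing) into edges.
    """
    if not (0 < low < high <= 1):
        raise ValueError("require 0 < low < high <= 1")
    mag = grad.magnitude
    gmax = float(mag.max())
    edges = np.zeros(mag.shape, dtype=np.uint8)
    if gmax <= 0 or gmax < floor:
        return EdgeMap(slice_index, edges)
    ridge = _nonmax_suppress(mag, grad.direction)
    strong = ridge & (mag >= high * gmax)
    weak = ridge & (mag >= low * gmax)
    labels, n = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
    if n:
        keep_ids = np.unique(labels[strong])
        keep_ids = keep_ids[keep_ids > 0]
        edges = np.isin(labels, keep_ids).astype(np.uint8)
    return EdgeMap(slice_index, edges)


# ---------------------------------------------------------------------------
# circular Hough transform
# ---------------------------------------------------------------------------

def _annulus_offsets(radius: int) -> np.ndarray:
    """Integer offsets whose Euclidean length rounds to ``radius``."""
    r = int(radius)
    span = np.arange(-r - 1, r + 2)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    d = np.hypot(dy, dx)
    sel = (d >= r - 0.5) & (d < r + 0.5)
    return np.stack([dy[sel], dx[sel]], axis=1)


def hough_accumulator(edges: np.ndarray, r_min: int, r_max: int) -> np.ndarray:
    """Raw vote accumulator, shape (n_radii, H, W).

    Each edge pixel votes for every center at a (rounded) Euclidean
    distance of each radius; equivalently, the cell (a, b, r) counts the
    edge pixels inside the one-pixel-wide annulus of radius r around
    (a, b).  Radius binning by rounded distance tolerates the half-pixel
    radial jitter of rasterized and noisy edges.
    """
    h, w = edges.shape
    radii = range(r_min, r_max + 1)
    acc = np.zeros((len(radii), h, w), dtype=np.int64)
    pts = np.argwhere(edges > 0)
    if pts.size == 0:
        return acc
    # vote into a padded plane so out-of-bounds votes need no masking
    pad = r_max + 1
    hp, wp = h + 2 * pad, w + 2 * pad
    rows0 = pts[:, 0] + pad
    cols0 = pts[:, 1] + pad
    for i, r in enumerate(radii):
        off = _annulus_offsets(r)
        flat = (rows0[:, None] + off[None, :, 0]) * wp + (cols0[:, None] + off[None, :, 1])
        plane = np.bincount(flat.ravel(), minlength=hp * wp).reshape(hp, wp)
        acc[i] = plane[pad : pad + h, pad : pad + w]
    return acc


def circular_hough(
    edge_map: EdgeMap,
    r_min: int = 5,
    r_max: int = 12,
    threshold_frac: float = 0.8,
    nms: bool = True,
) -> List[CircleCandidate]:
    """Detect circles on one slice.

    The accumulator is normalized per radius by the perimeter length, so a
    cell value is the fraction of the circle actually present ("overlap").
    Cells within ``threshold_frac`` of the slice-wide accumulator maximum
    become candidates; with ``nms`` a 3x3 in-plane non-maximum suppression
    per radius plane removes duplicates one pixel apart.  Scores are
    overlap / slice maximum, hence in (0, 1].
    """
    if not (0 < r_min <= r_max):
        raise ValueError("require 0 < r_min <= r_max")
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")
    edges = edge_map.edges
    votes = hough_accumulator(edges, r_min, r_max)
    perim = np.array(
        [len(_annulus_offsets(r)) for r in range(r_min, r_max + 1)], dtype=float
    )
    overlap = votes / perim[:, None, None]
    smax = float(overlap.max(initial=0.0))
    if smax <= 0:
        return []
    mask = overlap >= threshold_frac * smax - 1e-12
    if nms:
        local = ndi.maximum_filter(overlap, size=(1, 3, 3), mode="constant")
        mask &= overlap >= local
    out: List[CircleCandidate] = []
    for i, row, col in np.argwhere(mask):
        out.append(
            CircleCandidate(
                slice_index=edge_map.slice_index,
                center=(int(row), int(col)),
                radius=int(r_min + i),
                score=float(overlap[i, row, col] / smax),
            )
        )
    return out


# ---------------------------------------------------------------------------
# physiological exclusions
# ---------------------------------------------------------------------------

def exclude_image_edge(
    cands: Sequence[CircleCandidate], slice_shape: Tuple[int, int]
) -> Tuple[List[CircleCandidate], List[CircleCandidate]]:
    """Discard circles whose circumference leaves the slice or touches its border."""
    h, w = slice_shape
    kept, rejected = [], []
    for c in cands:
        row, col = c.center
        r = c.radius
        inside = (
            row - r >= 1 and row + r <= h - 2 and col - r >= 1 and col + r <= w - 2
        )
        if inside:
            kept.append(c)
        else:
            c.status = Status.REJECTED_EDGE
            rejected.append(c)
    return kept, rejected


def _union_find(n: int):
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    return find, union


def group_and_merge(
    cands: Sequence[CircleCandidate], max_span: float = 8.0
) -> List[CircleGroup]:
    """Merge overlapping circles on one slice; apply singleton/size exclusions.

    Circles overlap when their center distance is below the sum of their
    radii.  Singleton groups are noise edges; groups whose maximum pairwise
    center distance exceeds ``max_span`` pixels are too large to be a
    microbleed.
    """
    if max_span <= 0:
        raise ValueError("max_span must be positive")
    cands = [c for c in cands if c.status == Status.ACTIVE]
    if not cands:
        return []
    centers = np.array([c.center for c in cands], dtype=float)
    radii = np.array([c.radius for c in cands], dtype=float)
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    find, union = _union_find(len(cands))
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if d[i, j] < radii[i] + radii[j]:
                union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(len(cands)):
        comps.setdefault(find(i), []).append(i)
    groups: List[CircleGroup] = []
    for members in comps.values():
        circ = [cands[i] for i in members]
        ctr = centers[members].mean(axis=0)
        grp = CircleGroup(
            slice_index=circ[0].slice_index,
            circles=circ,
            center=(float(ctr[0]), float(ctr[1])),
            mean_radius=float(radii[members].mean()),
        )
        if len(members) == 1:
            grp.status = Status.REJECTED_SINGLETON
        elif d[np.ix_(members, members)].max() > max_span:
            grp.status = Status.REJECTED_SIZE
        groups.append(grp)
    return groups


def exclude_csf(
    groups: Sequence[CircleGroup],
    csf_labels: Optional[np.ndarray],
    overlap_frac: float = 0.0,
) -> List[CircleGroup]:
    """Reject groups whose member disks overlap the CSF mask (vessel rule).

    ``csf_labels`` is the resampled 3D CSF grid; ``overlap_frac`` is the
    tolerated fraction of disk voxels inside CSF (0 = any overlap rejects).
    Passing ``None`` skips the step.
    """
    if csf_labels is None:
        return list(groups)
    for grp in groups:
        if grp.status != Status.ACTIVE:
            continue
        n_in, n_tot = 0, 0
        sl = csf_labels[:, :, grp.slice_index]
        for c in grp.circles:
            rr, cc = disk(c.center, c.radius + 0.5, shape=sl.shape)
            n_tot += rr.size
            n_in += int(np.count_nonzero(sl[rr, cc]))
        if n_tot and n_in / n_tot > overlap_frac:
            grp.status = Status.REJECTED_CSF
    return list(groups)


# ---------------------------------------------------------------------------
# cross-slice merging + ROI extraction
# ---------------------------------------------------------------------------

def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 ties toward the lower index."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def merge_across_slices(
    groups: Sequence[CircleGroup],
    link_distance: float = 8.0,
    slice_gap: int = 1,
    volume_shape: Optional[Tuple[int, int, int]] = None,
) -> List[MicrobleedCandidate]:
    """Union surviving per-slice groups into 3D microbleed candidates.

    Groups whose slices are within ``slice_gap`` of each other and whose
    in-plane centers are within ``link_distance`` pixels are transitively
    unioned; the candidate center is the rounded centroid of the member
    *group* centers (one per slice), so slices that happen to fire more
    accumulator peaks do not drag the center toward them.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be positive")
    alive = [g for g in groups if g.status == Status.ACTIVE]
    if not alive:
        return []
    centers = np.array([g.center for g in alive], dtype=float)
    slices = np.array([g.slice_index for g in alive])
    find, union = _union_find(len(alive))
    for i in range(len(alive)):
        for j in range(i + 1, len(alive)):
            if abs(int(slices[i]) - int(slices[j])) <= slice_gap and (
                np.linalg.norm(centers[i] - centers[j]) <= link_distance
            ):
                union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(len(alive)):
        comps.setdefault(find(i), []).append(i)
    out: List[MicrobleedCandidate] = []
    for members in comps.values():
        grps = [alive[i] for i in members]
        circles = [c for g in grps for c in g.circles]
        pts = np.array(
            [[g.center[0], g.center[1], g.slice_index] for g in grps], dtype=float
        )
        ctr = _round_half_down(pts.mean(axis=0))
        if volume_shape is not None:
            ctr = np.clip(ctr, 0, np.array(volume_shape) - 1)
        out.append(
            MicrobleedCandidate(
                center3d=(int(ctr[0]), int(ctr[1]), int(ctr[2])),
                member_circles=circles,
                groups=grps,
            )
        )
    return out


def refine_centers(
    volume: np.ndarray,
    cands: Sequence[MicrobleedCandidate],
    halfwidth_px: int = 6,
    halfdepth_slices: int = 6,
    smooth: int = 3,
) -> None:
    """Re-center each candidate on the local hypointensity minimum.

    A microbleed is a signal void, so its center is the darkest point of
    the merged region.  The circle-centroid estimate is accurate in plane
    but coarse along z (slices are discrete, and interpolation ringing
    extends a candidate's circle chain beyond the void); placing the
    center at the minimum of the lightly smoothed intensity in a small
    window fixes the z coordinate up to slab quantization (objects thinner
    than the slice thickness image with their void biased toward the
    dominant slice, so sub-slice z accuracy is physically limited to about
    half the slice thickness).  In-place update.
    """
    shape = np.array(volume.shape)
    half = np.array([halfwidth_px, halfwidth_px, halfdepth_slices])
    for cand in cands:
        center = np.asarray(cand.center3d)
        lo = np.maximum(center - half, 0)
        hi = np.minimum(center + half + 1, shape)
        box = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if smooth > 1:
            box = ndi.uniform_filter(box, size=smooth, mode="nearest")
        idx = np.unravel_index(int(np.argmin(box)), box.shape)
        cand.center3d = tuple(int(v) for v in (lo + np.array(idx)))


def _dedupe_candidates(
    cands: List[MicrobleedCandidate], tol_px: int = 3
) -> List[MicrobleedCandidate]:
    """Merge candidates whose refined centers landed on the same void."""
    if len(cands) < 2:
        return cands
    centers = np.array([c.center3d for c in cands])
    find, union = _union_find(len(cands))
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if np.all(np.abs(centers[i] - centers[j]) <= tol_px):
                union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(len(cands)):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        keep = max(members, key=lambda i: len(cands[i].member_circles))
        primary = cands[keep]
        for i in members:
            if i != keep:
                primary.member_circles.extend(cands[i].member_circles)
                primary.groups.extend(cands[i].groups)
        out.append(primary)
    return out


def extract_neighborhood(
    volume: np.ndarray,
    cand: MicrobleedCandidate,
    size: Tuple[int, int, int] = (51, 51, 25),
) -> RoiNeighborhood:
    """Crop the standardized ROI around a candidate (edge-replicated padding).

    ``size`` values must be odd so the candidate maps to the unique central
    voxel of the crop.
    """
    size = tuple(int(s) for s in size)
    if any(s < 1 or s % 2 == 0 for s in size):
        raise ValueError("neighborhood size values must be odd and positive")
    center = np.asarray(cand.center3d, dtype=int)
    if np.any(center < 0) or np.any(center >= np.array(volume.shape)):
        raise ValueError("candidate center lies outside the volume")
    half = np.array(size) // 2
    lo = center - half
    hi = center + half + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, volume.shape)
    crop = volume[lo_c[0] : hi_c[0], lo_c[1] : hi_c[1], lo_c[2] : hi_c[2]]
    pad = [(int(lo_c[d] - lo[d]), int(hi[d] - hi_c[d])) for d in range(3)]
    if any(p != (0, 0) for p in pad):
        crop = np.pad(crop, pad, mode="edge")
    return RoiNeighborhood(grid=np.ascontiguousarray(crop), offset=tuple(int(v) for v in lo))


# ---------------------------------------------------------------------------
# convenience driver for the candidate stage
# ---------------------------------------------------------------------------

@dataclass
class CandidateStageResult:
    candidates: List[MicrobleedCandidate]
    n_circles: int
    n_rejected_edge: int
    n_groups: int
    n_rejected_singleton: int
    n_rejected_size: int
    n_rejected_csf: int


def detect_candidates(
    resampled: np.ndarray,
    config: CutoffConfig,
    csf_labels: Optional[np.ndarray] = None,
) -> CandidateStageResult:
    """Run gradient -> edges -> Hough -> exclusions -> cross-slice merge."""
    grads = [slice_gradient(resampled[:, :, z]) for z in range(resampled.shape[2])]
    volume_gmax = max(float(g.magnitude.max()) for g in grads)
    floor = config.min_gradient_frac * volume_gmax
    all_groups: List[CircleGroup] = []
    n_circles = n_edge = 0
    for z, grad in enumerate(grads):
        sl = resampled[:, :, z]
        edge_map = detect_edges(grad, config.canny_low, config.canny_high, z, floor)
        if not edge_map.edges.any():
            continue
        circles = circular_hough(
            edge_map,
            config.hough_radius_min_px,
            config.hough_radius_max_px,
            config.hough_threshold_frac,
        )
        n_circles += len(circles)
        kept, rejected = exclude_image_edge(circles, sl.shape)
        n_edge += len(rejected)
        all_groups.extend(group_and_merge(kept, config.merge_max_span_px))
    exclude_csf(all_groups, csf_labels, config.csf_overlap_frac)
    candidates = merge_across_slices(
        all_groups,
        config.slice_link_distance_px,
        config.slice_gap,
        volume_shape=resampled.shape,
    )
    refine_centers(resampled, candidates, halfdepth_slices=2 * config.resample_factor)
    candidates = _dedupe_candidates(candidates)
    return CandidateStageResult(
        candidates=candidates,
        n_circles=n_circles,
        n_rejected_edge=n_edge,
        n_groups=len(all_groups),
        n_rejected_singleton=sum(
            g.status == Status.REJECTED_SINGLETON for g in all_groups
        ),
        n_rejected_size=sum(g.status == Status.REJECTED_SIZE for g in all_groups),
        n_rejected_csf=sum(g.status == Status.REJECTED_CSF for g in all_groups),
    )
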