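"""Geometric false-positive filtering of candidate ROIs.

Four a-priori descriptors separate true microbleeds from false positives:

* **3D image entropy** of the ROI (Shannon entropy of the 256-bin intensity
  histogram, in bits): a microbleed is a clean signal void surrounded by
  parenchyma and shows moderate entropy, while noisy high-gradient regions
  show high entropy.
* **2D entropy of the maximum intensity projection** of the ROI: the bright
  halo around a microbleed keeps the projection simple; false positives
  project to cluttered textures.
* **volume** and **compactness** of the ROI's *central blob*, obtained by
  thresholding a single-scale Frangi vesselness map and flood-filling
  (26-connectivity) from the supra-threshold voxel nearest the ROI center.
  Vessels and large voids produce big, ragged blobs; microbleeds produce
  small compact ones.

Vesselness follows Frangi's eigenvalue analysis of the image Hessian with
|lambda_1| <= |lambda_2| <= |lambda_3|, alpha = beta = 0.5, and the noise
scale c set to half the maximum Hessian norm S within the ROI.  Because the
targets are small and nearly constant in size, a single scale without
Gaussian pre-smoothing is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .candidates import MicrobleedCandidate, RoiNeighborhood, Status
from .config import CutoffConfig


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def image_entropy(grid: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram of a 2D/3D grid.

    Intensities are linearly rescaled to [0, n_bins - 1] and binned; the
    0 * log2(0) := 0 convention applies.  A constant grid has entropy 0.
    """
    a = np.asarray(grid, dtype=np.float64)
    if a.size == 0:
        raise ValueError("grid is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mn, mx = float(a.min()), float(a.max())
    if mx == mn:
        return 0.0
    scaled = np.rint((a - mn) / (mx - mn) * (n_bins - 1)).astype(np.int64)
    counts = np.bincount(scaled.ravel(), minlength=n_bins)
    p = counts[counts > 0] / a.size
    return float(-(p * np.log2(p)).sum())


def mip(roi, axis: int = 2) -> np.ndarray:
    """Maximum intensity projection of an ROI along one axis (default z)."""
    grid = roi.grid if isinstance(roi, RoiNeighborhood) else np.asarray(roi)
    return grid.max(axis=axis)


# ---------------------------------------------------------------------------
# Hessian + vesselness
# ---------------------------------------------------------------------------

@dataclass
class HessianField:
    """Per-voxel symmetric Hessian and its |.|-sorted eigenvalues."""

    hessian: np.ndarray      # (X, Y, Z, 3, 3)
    eigenvalues: np.ndarray  # (X, Y, Z, 3), |l1| <= |l2| <= |l3|


def hessian_field(roi, spacing: Optional[Sequence[float]] = None) -> HessianField:
    """Central-difference Hessian of an ROI, single scale, no pre-smoothing.

    Derivatives are taken in voxel units unless ``spacing`` (mm) is given.
    Eigenvalues are sorted by absolute value with sign retained.
    """
    grid = roi.grid if isinstance(roi, RoiNeighborhood) else np.asarray(roi)
    grid = grid.astype(np.float64)
    if grid.ndim != 3 or any(s < 3 for s in grid.shape):
        raise ValueError("ROI must be 3D with >= 3 voxels per axis")
    steps = tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)
    g = [np.gradient(grid, steps[i], axis=i) for i in range(3)]
    H = np.empty(grid.shape + (3, 3), dtype=np.float64)
    # mixed partials commute, so only the upper triangle is computed
    for i in range(3):
        for j in range(i, 3):
            H[..., i, j] = np.gradient(g[i], steps[j], axis=j)
            if j != i:
                H[..., j, i] = H[..., i, j]
    ev = _eigvalsh3(H)
    order = np.argsort(np.abs(ev), axis=-1)
    ev = np.take_along_axis(ev, order, axis=-1)
    return HessianField(hessian=H, eigenvalues=ev)


def _eigvalsh3(H: np.ndarray) -> np.ndarray:
    """Eigenvalues of a field of symmetric 3x3 matrices (ascending).

    Closed-form trigonometric solution (Cardano); an order of magnitude
    faster than LAPACK over ~1e5 small matrices and accurate to ~1e-12
    relative for the well-conditioned Hessians seen here.
    """
    a = H[..., 0, 0]
    b = H[..., 1, 1]
    c = H[..., 2, 2]
    d = H[..., 0, 1]
    e = H[..., 1, 2]
    f = H[..., 0, 2]
    q = (a + b + c) / 3.0
    da, db, dc = a - q, b - q, c - q
    p2 = (da ** 2 + db ** 2 + dc ** 2 + 2.0 * (d ** 2 + e ** 2 + f ** 2)) / 6.0
    p = np.sqrt(p2)
    # determinant of (H - q I) / p, guarded for the zero-matrix case
    safe = p > 0
    pi = np.where(safe, p, 1.0)
    r = (
        da * (db * dc - e ** 2)
        - d * (d * dc - e * f)
        + f * (d * e - db * f)
    ) / (2.0 * pi ** 3)
    r = np.clip(r, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    l1 = q + 2.0 * p * np.cos(phi)
    l3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    l2 = 3.0 * q - l1 - l3
    ev = np.stack([l3, l2, l1], axis=-1)  # ascending
    return np.where(safe[..., None], ev, q[..., None])


@dataclass
class VesselnessMap:
    v: np.ndarray
    alpha: float
    beta: float
    c: float


def frangi_vesselness(
    field: HessianField, alpha: float = 0.5, beta: float = 0.5,
    c: Optional[float] = None,
) -> VesselnessMap:
    """Frangi vesselness for dark structures on a bright background.

    V = (1 - exp(-R_A^2 / 2 alpha^2)) * exp(-R_B^2 / 2 beta^2)
        * (1 - exp(-S^2 / 2 c^2)),
    with R_A = |l2|/|l3|, R_B = |l1|/sqrt(|l2 l3|), S = sqrt(l1^2+l2^2+l3^2)
    and V = 0 wherever l2 < 0 or l3 < 0 (bright structures) or l2*l3 = 0
    (undefined ratios).  ``c`` defaults to half the maximum S over the ROI.
    """
    ev = field.eigenvalues
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    S = np.sqrt((ev ** 2).sum(axis=-1))
    if c is None:
        c = 0.5 * float(S.max(initial=0.0))
    v = np.zeros(l1.shape, dtype=np.float64)
    if c <= 0:
        return VesselnessMap(v, alpha, beta, float(c))
    valid = (l2 >= 0) & (l3 >= 0) & (np.abs(l2) > 0) & (np.abs(l3) > 0)
    a2, a3 = np.abs(l2[valid]), np.abs(l3[valid])
    ra = a2 / a3
    rb = np.abs(l1[valid]) / np.sqrt(a2 * a3)
    s = S[valid]
    v[valid] = (
        (1.0 - np.exp(-(ra ** 2) / (2 * alpha ** 2)))
        * np.exp(-(rb ** 2) / (2 * beta ** 2))
        * (1.0 - np.exp(-(s ** 2) / (2 * c ** 2)))
    )
    return VesselnessMap(np.clip(v, 0.0, 1.0), alpha, beta, float(c))


# ---------------------------------------------------------------------------
# central-blob analysis
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def central_blob(
    vmap, threshold_frac: float, center: Tuple[int, int, int]
) -> np.ndarray:
    """Binary mask of the ROI's central blob.

    Thresholds the vesselness map at ``threshold_frac`` of its maximum and
    returns the 26-connected component containing the supra-threshold voxel
    nearest ``center`` (Euclidean voxel distance, ties toward lower
    indices).  An all-zero map yields an empty blob.
    """
    v = vmap.v if isinstance(vmap, VesselnessMap) else np.asarray(vmap)
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    vmax = float(v.max(initial=0.0))
    out = np.zeros(v.shape, dtype=bool)
    if vmax <= 0:
        return out
    mask = v >= threshold_frac * vmax
    labels, n = ndi.label(mask, structure=_STRUCT26)
    if n == 0:
        return out
    coords = np.argwhere(mask)
    d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
    # primary key: distance; then lower x, y, z
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    seed = tuple(coords[order[0]])
    return labels == labels[seed]


def blob_volume(blob: np.ndarray) -> int:
    """Number of voxels in the blob."""
    return int(np.count_nonzero(blob))


def blob_perimeter_voxels(blob: np.ndarray) -> int:
    """Blob voxels with at least one face-adjacent (6-neighborhood) non-blob voxel."""
    b = np.asarray(blob, dtype=bool)
    padded = np.pad(b, 1, mode="constant")
    interior = np.ones_like(b)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return int(np.count_nonzero(b & ~interior))


def blob_compactness(blob: np.ndarray) -> float:
    """(perimeter voxel count)^2 / volume; raises on an empty blob."""
    vol = blob_volume(blob)
    if vol == 0:
        raise ValueError("compactness is undefined for an empty blob")
    return blob_perimeter_voxels(blob) ** 2 / vol


# ---------------------------------------------------------------------------
# feature assembly + cutoffs
# ---------------------------------------------------------------------------

@dataclass
class GeometricFeatures:
    """The four discriminant descriptors of one ROI."""

    entropy3d: float
    entropy2d_mip: float
    blob_volume: int
    blob_compactness: float  # 0.0 when the blob is empty
    blob_threshold_frac: float


def compute_features(
    roi: RoiNeighborhood,
    config: CutoffConfig,
    modality: str = "SWI",
) -> GeometricFeatures:
    """All four geometric descriptors of one standardized ROI."""
    grid = roi.grid
    e3 = image_entropy(grid, config.entropy_bins)
    e2 = image_entropy(mip(grid), config.entropy_bins)
    spacing = None  # voxel-unit derivatives; see CutoffConfig.spacing_aware_hessian
    field = hessian_field(grid, spacing=spacing)
    vmap = frangi_vesselness(field)
    frac = config.blob_threshold_frac[modality]
    blob = central_blob(vmap, frac, roi.center_index)
    vol = blob_volume(blob)
    comp = blob_compactness(blob) if vol else 0.0
    return GeometricFeatures(
        entropy3d=e3,
        entropy2d_mip=e2,
        blob_volume=vol,
        blob_compactness=comp,
        blob_threshold_frac=frac,
    )


def apply_cutoffs(
    cand: MicrobleedCandidate,
    feats: GeometricFeatures,
    config: CutoffConfig,
    modality: str = "SWI",
) -> MicrobleedCandidate:
    """Reject or accept a candidate from its geometric features.

    The tests run in a fixed order and the first strict violation is
    recorded; values exactly at a cutoff are kept.  Candidates already
    rejected upstream are returned unchanged.
    """
    if cand.status != Status.ACTIVE:
        return cand
    if feats.entropy3d > config.entropy3d_max[modality]:
        cand.status = Status.REJECTED_ENTROPY3D
    elif feats.entropy2d_mip > config.entropy2d_max[modality]:
        cand.status = Status.REJECTED_ENTROPY2D
    elif not (
        config.blob_volume_min[modality]
        <= feats.blob_volume
        <= config.blob_volume_max[modality]
    ):
        cand.status = Status.REJECTED_BLOB_VOLUME
    elif feats.blob_compactness > config.compactness_max[modality]:
        cand.status = Status.REJECTED_BLOB_COMPACTNESS
    else:
        cand.status = Status.ACCEPTED
    return cand


def sweep_threshold(
    rois: Sequence[RoiNeighborhood],
    labels: Sequence[bool],
    fracs: Iterable[float],
    config: Optional[CutoffConfig] = None,
    n_scans: Optional[int] = None,
) -> pd.DataFrame:
    """Blob volume/compactness ranges across vesselness thresholds.

    ``labels`` marks each ROI as true positive (True) or false positive
    (False).  For each threshold fraction the table reports the
    true-positive and false-positive ranges of blob volume and compactness
    plus the number of false positives falling outside the true-positive
    volume range (i.e. removable by a volume cutoff placed at that range).
    """
    rois = list(rois)
    labels = list(labels)
    if not rois or len(rois) != len(labels):
        raise ValueError("need equally many ROIs and truth labels")
    fracs = sorted(fracs)
    if any(not (0 < f < 1) for f in fracs):
        raise ValueError("threshold fractions must be in (0, 1)")
    config = config or CutoffConfig()
    vmaps = []
    for roi in rois:
        field = hessian_field(roi.grid)
        vmaps.append((frangi_vesselness(field), roi.center_index))
    rows = []
    for f in fracs:
        vols, comps = [], []
        for vmap, center in vmaps:
            blob = central_blob(vmap, f, center)
            vol = blob_volume(blob)
            vols.append(vol)
            comps.append(blob_compactness(blob) if vol else 0.0)
        vols = np.array(vols, dtype=float)
        comps = np.array(comps, dtype=float)
        tp = np.array(labels, dtype=bool)
        row = {"frac": f}
        for name, vals in (("volume", vols), ("compactness", comps)):
            for cls, sel in (("tp", tp), ("fp", ~tp)):
                row[f"{cls}_{name}_min"] = float(vals[sel].min()) if sel.any() else np.nan
                row[f"{cls}_{name}_max"] = float(vals[sel].max()) if sel.any() else np.nan
        if tp.any() and (~tp).any():
            lo, hi = vols[tp].min(), vols[tp].max()
            removable = int(((vols < lo) | (vols > hi))[~tp].sum())
        else:
            removable = 0
        row["fp_removable"] = removable
        row["fp_removable_per_scan"] = (
            removable / n_scans if n_scans else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
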