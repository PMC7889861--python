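"""Synthetic T2*-like phantoms with known microbleed and vessel mimics.

The generator renders, at SWI-like native resolution (0.43 x 0.43 x 2 mm),
the image features the detector is built around:

* **microbleed mimics** - dark spherical signal voids with a cosine-tapered
  shoulder and a hyperintense halo ring just outside the void.  The halo
  emulates the rim overshoot that the dipole-like susceptibility pattern
  and SWI phase processing leave around a real microbleed; it is what
  keeps the maximum-intensity projection of a true location simple;
* **vessel mimics** - dark straight cylinders;
* **CSF compartments** - hyperintense axis-aligned boxes marked in the CSF
  mask;
* additive zero-mean Gaussian noise (default sigma 1% of the background,
  i.e. a high-quality 3T susceptibility acquisition).

The halo amplitude and noise level are calibrated jointly so that the
geometric descriptors of a planted microbleed match the published
true-positive feature statistics of real scans (3D ROI entropy well below
the true-positive ceiling, 2D projection entropy close to 5 bits); see the
methods documentation for the calibration rationale.

Ground truth (sphere centers/radii in mm, tube centerlines, toy-atlas
region per structure) is returned alongside the volumes so every other
module can be tested end to end against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .volume_io import (
    REGION_LABELS,
    AtlasVolume,
    MaskVolume,
    ScanVolume,
    write_volume,
)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom (native, pre-resampling space)."""

    shape: Tuple[int, int, int] = (64, 64, 12)
    spacing: Tuple[float, float, float] = (0.43, 0.43, 2.0)
    background: float = 1000.0
    n_spheres: int = 3
    sphere_radius_mm: Tuple[float, float] = (0.7, 1.7)
    #: in-plane axis-ratio range of the (ovoid) microbleed mimics; real
    #: microbleeds are round-to-ovoid, never pixel-perfect circles
    sphere_ovality: Tuple[float, float] = (1.02, 1.08)
    #: amplitude range of the third-order angular rim modulation (lumpy
    #: boundary); short-arc irregularity of real lesions.  Kept small so
    #: the local rim curvature stays near the nominal radius.
    sphere_lobulation: Tuple[float, float] = (0.04, 0.06)
    sphere_contrast: float = 0.6   # fractional intensity drop at the center
    halo_frac: float = 1.5         # halo amplitude as fraction of the dip
    hard_edge: bool = False        # disable taper/halo (oracle geometry)
    n_tubes: int = 0
    tube_radius_mm: float = 0.8
    tube_contrast: float = 0.6
    tube_axis: Optional[str] = None  # 'x'|'y'|'z' or None for random
    csf_blocks: Tuple[Tuple[float, float, float, float, float, float], ...] = ()
    noise_sigma: float = 10.0
    modality: str = "SWI"
    seed: int = 0

    def __post_init__(self):
        if self.sphere_contrast <= 0 or self.sphere_contrast > 1:
            raise ValueError("sphere_contrast must be in (0, 1]")
        if self.sphere_radius_mm[0] <= 0 or self.sphere_radius_mm[1] < self.sphere_radius_mm[0]:
            raise ValueError("invalid sphere radius range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class TubeTruth:
    point_mm: Tuple[float, float, float]
    axis: Tuple[float, float, float]
    radius_mm: float
    region: str


@dataclass
class SphereTruth:
    center_mm: Tuple[float, float, float]
    radius_mm: float
    region: str


@dataclass
class PhantomTruth:
    spheres: List[SphereTruth] = field(default_factory=list)
    tubes: List[TubeTruth] = field(default_factory=list)
    seed: int = 0

    def sphere_centers_mm(self) -> np.ndarray:
        return np.array([s.center_mm for s in self.spheres], dtype=float).reshape(-1, 3)


@dataclass
class PhantomResult:
    scan: ScanVolume
    brain_mask: MaskVolume
    csf_mask: MaskVolume
    atlas: AtlasVolume
    truth: PhantomTruth


def _mm_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _toy_atlas(shape, spacing) -> AtlasVolume:
    """Eight axis-aligned octants labeled with the standard region names."""
    labels = np.zeros(shape, dtype=np.int32)
    hx, hy, hz = (n // 2 for n in shape)
    code = 1
    for xs in (slice(0, hx), slice(hx, None)):
        for ys in (slice(0, hy), slice(hy, None)):
            for zs in (slice(0, hz), slice(hz, None)):
                labels[xs, ys, zs] = code
                code += 1
    return AtlasVolume(labels, spacing, dict(REGION_LABELS))


def _sphere_profile(d_mm: np.ndarray, radius: float, dip: float,
                    taper: float, halo_frac: float, hard: bool) -> np.ndarray:
    """Signed intensity change at distance d from a sphere center.

    Cosine shoulder of one taper width centered on the radius (so the
    steepest gradient — where an edge detector localizes the rim — sits at
    the physical radius), then a narrow raised-cosine hyperintense halo
    peaking at halo_frac * dip just outside.  The tight halo reproduces
    the double-edge structure of a real microbleed (void rim plus blooming
    ring), whose two concentric Canny rings both fall inside the Hough
    radius window.
    """
    if hard:
        return np.where(d_mm <= radius, -dip, 0.0)
    out = np.zeros_like(d_mm)
    lo = radius - taper / 2
    hi = radius + taper / 2
    core = d_mm <= lo
    out[core] = -dip
    shoulder = (~core) & (d_mm < hi)
    t = (d_mm[shoulder] - lo) / taper
    out[shoulder] = -dip * 0.5 * (1 + np.cos(np.pi * t))
    halo = (d_mm >= hi) & (d_mm < hi + taper)
    u = (d_mm[halo] - hi) / taper
    out[halo] = halo_frac * dip * 0.5 * (1 - np.cos(2 * np.pi * u))
    return out


def _boxes_mm(csf_blocks, spacing, shape):
    ext = [n * s for n, s in zip(shape, spacing)]
    boxes = []
    for b in csf_blocks:
        x0, x1, y0, y1, z0, z1 = b
        boxes.append((
            max(0.0, x0), min(ext[0], x1),
            max(0.0, y0), min(ext[1], y1),
            max(0.0, z0), min(ext[2], z1),
        ))
    return boxes


def _point_in_boxes(p, boxes, margin=0.0) -> bool:
    x, y, z = p
    for x0, x1, y0, y1, z0, z1 in boxes:
        if (x0 - margin <= x <= x1 + margin
                and y0 - margin <= y <= y1 + margin
                and z0 - margin <= z <= z1 + margin):
            return True
    return False


def generate_phantom(spec: PhantomSpec, max_tries: int = 200) -> PhantomResult:
    """Render a phantom and its ground truth; identical seed, identical output."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    vol = np.full(shape, spec.background, dtype=np.float64)
    X, Y, Z = _mm_grids(shape, spacing)
    atlas = _toy_atlas(shape, spacing)
    boxes = _boxes_mm(spec.csf_blocks, spacing, shape)
    taper = spacing[0]  # one in-plane voxel
    # through-slice partial-volume integration: structures thinner than the
    # slice thickness contribute to each slab in proportion to overlap, as
    # on a real scanner.  Five-point average over the slab.
    n_sub = 5
    z_off = (np.arange(n_sub) - (n_sub - 1) / 2) / n_sub * spacing[2]
    Zs = Z[..., None] + z_off  # (..., n_sub)

    def region_at(p_mm) -> str:
        idx = np.minimum(
            np.maximum((np.asarray(p_mm) / spacing).astype(int), 0),
            np.array(shape) - 1,
        )
        code = int(atlas.labels[tuple(idx)])
        return atlas.label_table.get(code, "unlabeled")

    truth = PhantomTruth(seed=spec.seed)

    # ---- spheres ---------------------------------------------------------
    placed: List[Tuple[np.ndarray, float]] = []
    for _ in range(spec.n_spheres):
        r = float(rng.uniform(*spec.sphere_radius_mm))
        ok = False
        for _try in range(max_tries):
            margin_xy = r + 2.5
            margin_z = r + spacing[2]
            lo = np.array([margin_xy, margin_xy, margin_z])
            hi = extent - lo
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            if _point_in_boxes(c, boxes, margin=r + 2.0):
                continue
            if all(
                np.linalg.norm(c - pc) >= 2.0 * (r + pr) for pc, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all spheres without overlap; "
                "reduce n_spheres or enlarge the grid"
            )
        placed.append((c, r))
        # mild in-plane ovality (random axis ratio and orientation); the
        # nominal radius r is the geometric mean of the semi-axes
        ratio = float(rng.uniform(*spec.sphere_ovality))
        theta = float(rng.uniform(0, np.pi))
        a, b = np.sqrt(ratio), 1.0 / np.sqrt(ratio)
        if spec.hard_edge:
            dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        else:
            dx = X[..., None] - c[0]
            dy = Y[..., None] - c[1]
            dz = Zs - c[2]
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        d = np.sqrt((u / a) ** 2 + (v / b) ** 2 + dz ** 2)
        # lumpy rim: low-order angular modulation of the local radius, the
        # short-arc irregularity real lesions show at this resolution
        lob_amp = float(rng.uniform(*spec.sphere_lobulation))
        lob_k = 3
        lob_phase = float(rng.uniform(0, 2 * np.pi))
        ang = np.arctan2(dy, dx)
        d = d / (1.0 + lob_amp * np.cos(lob_k * ang + lob_phase))
        prof = _sphere_profile(
            d, r, spec.background * spec.sphere_contrast,
            taper, spec.halo_frac, spec.hard_edge,
        )
        vol += prof if spec.hard_edge else prof.mean(axis=-1)
        truth.spheres.append(
            SphereTruth(tuple(float(v) for v in c), r, region_at(c))
        )

    # ---- tubes -----------------------------------------------------------
    for _ in range(spec.n_tubes):
        if spec.tube_axis is not None:
            axis = {"x": (1.0, 0, 0), "y": (0, 1.0, 0), "z": (0, 0, 1.0)}[spec.tube_axis]
            axis = np.array(axis)
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
        p0 = rng.uniform(0.25 * extent, 0.75 * extent)
        dip = spec.background * spec.tube_contrast
        rx = X[..., None] - p0[0]
        ry = Y[..., None] - p0[1]
        rz = Zs - p0[2]
        proj = rx * axis[0] + ry * axis[1] + rz * axis[2]
        d = np.sqrt(np.maximum(rx**2 + ry**2 + rz**2 - proj**2, 0.0))
        if spec.hard_edge:
            vol += np.where(d <= spec.tube_radius_mm, -dip, 0.0).mean(axis=-1)
        else:
            prof = np.zeros_like(d)
            core = d <= spec.tube_radius_mm - taper
            prof[core] = -dip
            sh = (~core) & (d < spec.tube_radius_mm)
            t = (d[sh] - (spec.tube_radius_mm - taper)) / taper
            prof[sh] = -dip * 0.5 * (1 + np.cos(np.pi * t))
            vol += prof.mean(axis=-1)
        truth.tubes.append(
            TubeTruth(
                tuple(float(v) for v in p0),
                tuple(float(v) for v in axis),
                spec.tube_radius_mm,
                region_at(p0),
            )
        )

    # ---- CSF blocks ------------------------------------------------------
    csf = np.zeros(shape, dtype=np.uint8)
    for x0, x1, y0, y1, z0, z1 in boxes:
        sel = (
            (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1) & (Z >= z0) & (Z < z1)
        )
        vol[sel] = spec.background * 1.5
        csf[sel] = 1

    # ---- noise -----------------------------------------------------------
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=shape)

    scan = ScanVolume(vol, spacing, spec.modality)
    brain = MaskVolume(np.ones(shape, dtype=np.uint8), spacing, "brain")
    csf_mask = MaskVolume(csf, spacing, "csf")
    return PhantomResult(scan, brain, csf_mask, atlas, truth)


def render_confounders(
    scan: ScanVolume,
    kind: str,
    center_mm: Sequence[float],
    radius_mm: float = 5.0,
    amplitude: Optional[float] = None,
    wavelength_mm: float = 1.0,
) -> ScanVolume:
    """Add false-positive bait to a generated volume.

    ``kind='fold'`` stamps a high-gradient sinusoidal ripple patch (e.g. a
    cerebellar fold); ``kind='large_void'`` adds a hypointense region larger
    than the microbleed size range (e.g. an infarct).
    """
    vol = scan.intensities.copy()
    X, Y, Z = _mm_grids(vol.shape, scan.spacing)
    d = np.sqrt(
        (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (Z - center_mm[2]) ** 2
    )
    sel = d <= radius_mm
    if kind == "fold":
        amp = 0.3 * float(np.median(vol)) if amplitude is None else amplitude
        ripple = amp * np.sin(2 * np.pi * X / wavelength_mm) * np.sin(
            2 * np.pi * Y / wavelength_mm
        )
        vol[sel] += ripple[sel]
    elif kind == "large_void":
        amp = 0.6 * float(np.median(vol)) if amplitude is None else amplitude
        taper = scan.spacing[0]
        vol += _sphere_profile(d, radius_mm, amp, taper, 0.0, hard=False)
    else:
        raise ValueError("kind must be 'fold' or 'large_void'")
    return ScanVolume(vol, scan.spacing, scan.modality, scan.affine.copy())


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_phantom(result: PhantomResult, outdir: str | Path, scan_id: str = "phantom") -> None:
    """Write volumes as NIfTI plus truth as CSV/JSON (evaluation-compatible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(result.scan, outdir / "scan.nii.gz")
    write_volume(result.brain_mask, outdir / "brain_mask.nii.gz")
    write_volume(result.csf_mask, outdir / "csf_mask.nii.gz")
    write_volume(result.atlas, outdir / "atlas.nii.gz")
    rows = [
        {
            "scan_id": scan_id,
            "x_mm": s.center_mm[0],
            "y_mm": s.center_mm[1],
            "z_mm": s.center_mm[2],
            "certainty": "definite",
        }
        for s in result.truth.spheres
    ]
    pd.DataFrame(
        rows, columns=["scan_id", "x_mm", "y_mm", "z_mm", "certainty"]
    ).to_csv(outdir / "truth.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(asdict(result.truth), indent=2))
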