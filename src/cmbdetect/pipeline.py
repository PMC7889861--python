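"""End-to-end detection pipeline, lobar localization and report output.

``run_pipeline`` executes the full chain deterministically:

    resample -> per-slice gradient / Canny edges / circular Hough
    -> edge, size, singleton and CSF exclusions -> cross-slice merging
    -> standardized ROI extraction -> geometric features -> cutoffs
    -> atlas localization

and returns a :class:`DetectionReport` with every candidate's coordinates
(resampled voxels and mm), rejection status, features and region label.
``write_outputs`` saves rater-editable artifacts: a native-space label mask
(one integer label per accepted candidate so single detections can be
deleted in any viewer), candidate/feature CSV tables, and a JSON summary
with the lobar histogram and per-stage rejection counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .candidates import (
    MicrobleedCandidate,
    Status,
    detect_candidates,
    extract_neighborhood,
)
from .config import CutoffConfig
from .geometry import apply_cutoffs, compute_features
from .volume_io import (
    AtlasVolume,
    MaskVolume,
    ScanVolume,
    check_alignment,
    resample_volume,
)

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "candidate_id",
    "x",
    "y",
    "z",
    "x_mm",
    "y_mm",
    "z_mm",
    "n_circles",
    "mean_radius_px",
    "status",
]

FEATURE_COLUMNS = [
    "candidate_id",
    "entropy3d",
    "entropy2d_mip",
    "blob_volume",
    "blob_compactness",
    "blob_threshold_frac",
    "status",
]


@dataclass
class DetectionReport:
    """Everything a reviewer needs about one pipeline run."""

    candidates: pd.DataFrame           # CANDIDATE_COLUMNS + feature columns + region
    region_histogram: Dict[str, int] = field(default_factory=dict)
    region_percent: Dict[str, float] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)
    config: Optional[CutoffConfig] = None
    resample_factor: int = 3
    resampled_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def accepted(self) -> pd.DataFrame:
        return self.candidates[self.candidates["status"] == Status.ACCEPTED]


def localize(
    center3d: Tuple[int, int, int],
    atlas_labels: np.ndarray,
    label_table: Dict[int, str],
    spacing: Tuple[float, float, float],
    search_radius_mm: float = 5.0,
) -> str:
    """Region name at a candidate center.

    If the center falls on label 0 (a boundary gap in the co-registered
    atlas), the nearest nonzero label within ``search_radius_mm`` is used;
    failing that the candidate is 'unlabeled'.
    """
    center = np.asarray(center3d, dtype=int)
    code = int(atlas_labels[tuple(center)])
    if code != 0:
        return label_table.get(code, "unlabeled")
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.ceil(search_radius_mm / spacing).astype(int), 1)
    lo = np.maximum(center - half, 0)
    hi = np.minimum(center + half + 1, atlas_labels.shape)
    box = atlas_labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    nz = np.argwhere(box != 0)
    if nz.size == 0:
        return "unlabeled"
    d = np.linalg.norm((nz + lo - center) * spacing, axis=1)
    best = np.argmin(d)
    if d[best] > search_radius_mm:
        return "unlabeled"
    return label_table.get(int(box[tuple(nz[best])]), "unlabeled")


def run_pipeline(
    scan: ScanVolume,
    csf: Optional[MaskVolume] = None,
    atlas: Optional[AtlasVolume] = None,
    config: Optional[CutoffConfig] = None,
) -> DetectionReport:
    """Run the full detector on one scan.

    Companion masks must be co-registered to the scan's native grid; they
    are resampled with the same factor as the scan (nearest neighbor).
    Identical inputs and config produce identical reports.
    """
    config = config or CutoffConfig()
    for name, companion in (("csf", csf), ("atlas", atlas)):
        if companion is not None and not check_alignment(scan, companion):
            raise ValueError(f"{name} volume is not aligned with the scan")
    if csf is None:
        log.warning("no CSF mask supplied; vessel (CSF-overlap) exclusion skipped")

    factor = config.resample_factor
    res = resample_volume(scan, factor, "intensity")
    csf_res = resample_volume(csf, factor, "label") if csf is not None else None
    atlas_res = resample_volume(atlas, factor, "label") if atlas is not None else None

    stage = detect_candidates(
        res.intensities,
        config,
        csf_res.labels if csf_res is not None else None,
    )

    modality = scan.modality
    feats_by_id: Dict[int, object] = {}
    for cid, cand in enumerate(stage.candidates, start=1):
        roi = extract_neighborhood(res.intensities, cand, config.neighborhood_size)
        feats = compute_features(roi, config, modality)
        apply_cutoffs(cand, feats, config, modality)
        feats_by_id[cid] = feats

    rows = []
    region_hist: Dict[str, int] = {}
    for cid, cand in enumerate(stage.candidates, start=1):
        x, y, z = cand.center3d
        region = ""
        if cand.status == Status.ACCEPTED:
            if atlas_res is not None:
                region = localize(
                    cand.center3d,
                    atlas_res.labels,
                    atlas_res.label_table,
                    res.spacing,
                )
            else:
                region = "unlabeled"
            region_hist[region] = region_hist.get(region, 0) + 1
        f = feats_by_id[cid]
        rows.append(
            {
                "candidate_id": cid,
                "x": x,
                "y": y,
                "z": z,
                "x_mm": x * res.spacing[0],
                "y_mm": y * res.spacing[1],
                "z_mm": z * res.spacing[2],
                "n_circles": cand.n_circles,
                "mean_radius_px": cand.mean_radius_px,
                "status": cand.status,
                "entropy3d": f.entropy3d,
                "entropy2d_mip": f.entropy2d_mip,
                "blob_volume": f.blob_volume,
                "blob_compactness": f.blob_compactness,
                "blob_threshold_frac": f.blob_threshold_frac,
                "region": region,
            }
        )
    columns = CANDIDATE_COLUMNS + FEATURE_COLUMNS[1:-1] + ["region"]
    df = pd.DataFrame(rows, columns=columns)

    n_accepted = int((df["status"] == Status.ACCEPTED).sum()) if len(df) else 0
    totals = {
        "n_circles": stage.n_circles,
        "rejected_edge_circles": stage.n_rejected_edge,
        "n_groups": stage.n_groups,
        "rejected_singleton": stage.n_rejected_singleton,
        "rejected_size": stage.n_rejected_size,
        "rejected_csf": stage.n_rejected_csf,
        "n_candidates": len(stage.candidates),
        "rejected_entropy3d": int((df["status"] == Status.REJECTED_ENTROPY3D).sum()),
        "rejected_entropy2d": int((df["status"] == Status.REJECTED_ENTROPY2D).sum()),
        "rejected_blob_volume": int((df["status"] == Status.REJECTED_BLOB_VOLUME).sum()),
        "rejected_blob_compactness": int(
            (df["status"] == Status.REJECTED_BLOB_COMPACTNESS).sum()
        ),
        "accepted": n_accepted,
    }
    percent = (
        {r: 100.0 * n / n_accepted for r, n in region_hist.items()}
        if n_accepted and atlas is not None
        else {}
    )
    return DetectionReport(
        candidates=df,
        region_histogram=region_hist if atlas is not None else {},
        region_percent=percent,
        totals=totals,
        config=config,
        resample_factor=factor,
        resampled_spacing=res.spacing,
    )


def write_outputs(
    report: DetectionReport,
    vol: ScanVolume,
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write the editable label mask, CSV tables and JSON summary.

    The mask lives on the scan's native (un-resampled) grid; each accepted
    candidate's standardized neighborhood is filled with its candidate_id.
    Resampled voxel coordinates map back to native ones by integer division
    by the resample factor.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    factor = report.resample_factor
    size = np.asarray(report.config.neighborhood_size if report.config else (51, 51, 25))
    half = np.maximum((size // factor) // 2, 1)

    mask = np.zeros(vol.shape, dtype=np.int16)
    for _, row in report.accepted.iterrows():
        center = np.array([row["x"], row["y"], row["z"]], dtype=int) // factor
        lo = np.maximum(center - half, 0)
        hi = np.minimum(center + half + 1, vol.shape)
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = int(row["candidate_id"])
    img = nib.Nifti1Image(mask, vol.affine)
    img.header.set_zooms(vol.spacing)
    mask_path = outdir / "candidate_mask.nii.gz"
    nib.save(img, str(mask_path))

    cand_path = outdir / "candidates.csv"
    feat_path = outdir / "features.csv"
    report.candidates[CANDIDATE_COLUMNS].to_csv(cand_path, index=False)
    report.candidates[FEATURE_COLUMNS].to_csv(feat_path, index=False)

    summary = {
        "totals": report.totals,
        "region_histogram": report.region_histogram,
        "region_percent": report.region_percent,
        "resample_factor": factor,
        "resampled_spacing_mm": list(report.resampled_spacing),
        "config": report.config.to_dict() if report.config else None,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    return {
        "mask": mask_path,
        "candidates": cand_path,
        "features": feat_path,
        "summary": summary_path,
    }
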