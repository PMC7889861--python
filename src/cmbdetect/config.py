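"""Pipeline configuration.

Every tunable threshold of the detector lives in :class:`CutoffConfig` so a
full run is auditable from a single record.  Defaults follow the published
operating point of the detector: per-slice Canny hysteresis bounds of
0.10/0.15 (fractions of the slice's maximum gradient magnitude), a Hough
radius window of 5-12 resampled pixels (0.72-1.72 mm at 0.43 mm in-plane
resolution upsampled by 3), an 80% lenient accumulator threshold, and an
8-pixel (1.15 mm) in-plane size/link cutoff.

The geometric cutoffs (entropy, blob volume, blob compactness) are
modality-specific because SWI and GRE render susceptibility artifacts with
different degrees of blooming.  The shipped values are derived from the
true-positive feature distributions of the validation cohort and should be
treated as provisional starting points: they are meant to be re-tuned per
scanner/protocol from a handful of rated scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Tuple, Dict

import math

import yaml

MODALITIES = ("SWI", "GRE")


def _mod_dict(swi: float, gre: float) -> Dict[str, float]:
    return {"SWI": swi, "GRE": gre}


@dataclass
class CutoffConfig:
    """All tunable thresholds of the detection pipeline.

    Distances are in resampled pixels unless suffixed ``_mm``; entropies in
    bits; blob volumes in resampled voxels.
    """

    # -- resampling -------------------------------------------------------
    resample_factor: int = 3

    # -- edge detection ---------------------------------------------------
    canny_low: float = 0.1
    canny_high: float = 0.15
    #: slices whose max gradient falls below this fraction of the volume's
    #: max gradient are treated as featureless (suppresses interpolation
    #: ripple; real tissue edges sit orders of magnitude higher)
    min_gradient_frac: float = 0.02

    # -- circular Hough ---------------------------------------------------
    hough_radius_min_px: int = 5
    hough_radius_max_px: int = 12
    hough_threshold_frac: float = 0.8

    # -- physiological exclusions ----------------------------------------
    merge_max_span_px: float = 8.0
    slice_link_distance_px: float = 8.0
    slice_gap: int = 1
    csf_overlap_frac: float = 0.0

    # -- ROI standardization ---------------------------------------------
    neighborhood_size: Tuple[int, int, int] = (51, 51, 25)

    # -- geometric filtering ----------------------------------------------
    entropy_bins: int = 256
    blob_threshold_frac: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(0.15, 0.25)
    )
    entropy3d_max: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(6.88, 6.88)
    )
    entropy2d_max: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(6.0, 6.0)
    )
    blob_volume_min: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(0.0, 0.0)
    )
    blob_volume_max: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(2195.0, 2195.0)
    )
    compactness_max: Dict[str, float] = field(
        default_factory=lambda: _mod_dict(1368.0, 1074.0)
    )

    # -- behavior switches -------------------------------------------------
    spacing_aware_hessian: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")
        if not (0 < self.canny_low < self.canny_high <= 1):
            raise ValueError("require 0 < canny_low < canny_high <= 1")
        if not (0 <= self.min_gradient_frac < 1):
            raise ValueError("min_gradient_frac must be in [0, 1)")
        if not (0 < self.hough_radius_min_px <= self.hough_radius_max_px):
            raise ValueError("invalid Hough radius range")
        if not (0 < self.hough_threshold_frac <= 1):
            raise ValueError("hough_threshold_frac must be in (0, 1]")
        if self.merge_max_span_px <= 0 or self.slice_link_distance_px <= 0:
            raise ValueError("size/link cutoffs must be positive")
        if self.slice_gap < 0:
            raise ValueError("slice_gap must be >= 0")
        if not (0 <= self.csf_overlap_frac < 1):
            raise ValueError("csf_overlap_frac must be in [0, 1)")
        if len(self.neighborhood_size) != 3 or any(
            s < 1 or s % 2 == 0 for s in self.neighborhood_size
        ):
            raise ValueError("neighborhood_size must be three odd positive ints")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        for name in (
            "blob_threshold_frac",
            "entropy3d_max",
            "entropy2d_max",
            "blob_volume_min",
            "blob_volume_max",
            "compactness_max",
        ):
            table = getattr(self, name)
            missing = set(MODALITIES) - set(table)
            if missing:
                raise ValueError(f"{name} missing modalities: {sorted(missing)}")
        for m in MODALITIES:
            if not (0 < self.blob_threshold_frac[m] < 1):
                raise ValueError("blob_threshold_frac must be in (0, 1)")
            if self.blob_volume_min[m] > self.blob_volume_max[m]:
                raise ValueError("blob_volume_min must be <= blob_volume_max")

    # -- convenience -------------------------------------------------------
    def without_geometric_cutoffs(self) -> "CutoffConfig":
        """A copy with all geometric cutoffs disabled (set to +/- infinity).

        Useful for auditing the candidate stage: the filtering stage then
        accepts everything, so the accepted set equals the candidate set.
        """
        inf = math.inf
        return replace(
            self,
            entropy3d_max=_mod_dict(inf, inf),
            entropy2d_max=_mod_dict(inf, inf),
            blob_volume_min=_mod_dict(-inf, -inf),
            blob_volume_max=_mod_dict(inf, inf),
            compactness_max=_mod_dict(inf, inf),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neighborhood_size"] = list(self.neighborhood_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffConfig":
        d = dict(d)
        if "neighborhood_size" in d:
            d["neighborhood_size"] = tuple(d["neighborhood_size"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CutoffConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
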