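"""Scoring detections against rated ground truth.

Ground-truth microbleed locations come from visual ratings by multiple
trained raters: *definite* locations (all three raters agree) and
*probable* locations (two of three).  Detections are matched to truth
one-to-one by greedy nearest-first pairing within a millimetre tolerance
(default 3.44 mm, twice the largest radius in the Hough search window);
unmatched detections are false positives.

Summary metrics mirror the standard reporting layout: per-certainty and
combined sensitivity (algorithm-identified / rater-identified), precision
TP / (TP + FP), and the mean number of false positives per scan.  The same
one-to-one matcher scores longitudinal persistence of baseline locations
on follow-up scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: default match tolerance: twice the maximum microbleed radius (2 x 1.72 mm)
DEFAULT_TOL_MM = 3.44

CERTAINTIES = ("definite", "probable")


@dataclass
class GroundTruthSet:
    """Rated microbleed locations for one scan."""

    locations: np.ndarray          # (n, 3) mm coordinates
    certainty: List[str]           # 'definite' | 'probable' per location
    scan_id: str = ""

    def __post_init__(self):
        self.locations = np.asarray(self.locations, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.locations)):
            raise ValueError("truth coordinates must be finite")
        self.certainty = list(self.certainty)
        if len(self.certainty) != len(self.locations):
            raise ValueError("one certainty label per location required")
        bad = set(self.certainty) - set(CERTAINTIES)
        if bad:
            raise ValueError(f"unknown certainty labels: {sorted(bad)}")


@dataclass
class MatchResult:
    """One-to-one pairing between detections and truth locations."""

    pairs: List[Tuple[int, int, float]]  # (det_index, truth_index, distance_mm)
    unmatched_detections: List[int]
    unmatched_truth: List[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_detections(
    detections: Sequence[Sequence[float]],
    truth: GroundTruthSet | np.ndarray,
    tol_mm: float = DEFAULT_TOL_MM,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``tol_mm``."""
    if tol_mm <= 0:
        raise ValueError("tol_mm must be positive")
    dets = np.asarray(detections, dtype=float).reshape(-1, 3)
    pts = truth.locations if isinstance(truth, GroundTruthSet) else (
        np.asarray(truth, dtype=float).reshape(-1, 3)
    )
    if dets.size == 0 or pts.size == 0:
        return MatchResult([], list(range(len(dets))), list(range(len(pts))))
    d = np.linalg.norm(dets[:, None, :] - pts[None, :, :], axis=-1)
    order = np.argsort(d, axis=None, kind="stable")
    used_d, used_t = set(), set()
    pairs: List[Tuple[int, int, float]] = []
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > tol_mm:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(int(i))
        used_t.add(int(j))
        pairs.append((int(i), int(j), float(d[i, j])))
    return MatchResult(
        pairs,
        [i for i in range(len(dets)) if i not in used_d],
        [j for j in range(len(pts)) if j not in used_t],
    )


@dataclass
class EvaluationSummary:
    """Sensitivity / precision / FP-per-scan summary."""

    per_certainty: Dict[str, Dict[str, float]] = field(default_factory=dict)
    rater_identified: int = 0
    algorithm_identified: int = 0
    sensitivity: Optional[float] = None
    true_positives: int = 0
    false_positives: int = 0
    precision: Optional[float] = None
    fp_per_scan: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "per_certainty": self.per_certainty,
            "rater_identified": self.rater_identified,
            "algorithm_identified": self.algorithm_identified,
            "sensitivity": self.sensitivity,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "precision": self.precision,
            "fp_per_scan": self.fp_per_scan,
        }


def summarize_counts(
    rater_identified: Dict[str, int],
    algorithm_identified: Dict[str, int],
    false_positives: int = 0,
    n_scans: Optional[int] = None,
) -> EvaluationSummary:
    """Summary metrics from per-certainty identification counts.

    ``rater_identified`` / ``algorithm_identified`` map certainty class to
    counts; combined sensitivity uses the summed counts.  Precision is
    TP / (TP + FP) with TP the combined algorithm-identified count, and is
    absent when TP + FP = 0.
    """
    per: Dict[str, Dict[str, float]] = {}
    for cls, n_rater in rater_identified.items():
        n_alg = algorithm_identified.get(cls, 0)
        if n_alg > n_rater:
            raise ValueError("algorithm cannot identify more than rated locations")
        per[cls] = {
            "rater_identified": n_rater,
            "algorithm_identified": n_alg,
            "sensitivity": (n_alg / n_rater) if n_rater else None,
        }
    total_rater = sum(rater_identified.values())
    total_alg = sum(
        algorithm_identified.get(c, 0) for c in rater_identified
    )
    sens = total_alg / total_rater if total_rater else None
    tp = total_alg
    denom = tp + false_positives
    return EvaluationSummary(
        per_certainty=per,
        rater_identified=total_rater,
        algorithm_identified=total_alg,
        sensitivity=sens,
        true_positives=tp,
        false_positives=false_positives,
        precision=(tp / denom) if denom else None,
        fp_per_scan=(false_positives / n_scans) if n_scans else None,
    )


def summarize(
    scan_results: Sequence[Tuple[GroundTruthSet, MatchResult]],
    n_scans: Optional[int] = None,
) -> EvaluationSummary:
    """Aggregate per-scan pairings into one summary.

    ``n_scans`` defaults to the number of scan results; pass the full group
    size explicitly when some scans contributed no truth locations.
    """
    rater = {c: 0 for c in CERTAINTIES}
    alg = {c: 0 for c in CERTAINTIES}
    fp = 0
    for truth, match in scan_results:
        for c in truth.certainty:
            rater[c] += 1
        for _, j, _ in match.pairs:
            alg[truth.certainty[j]] += 1
        fp += len(match.unmatched_detections)
    rater = {c: n for c, n in rater.items() if n}
    return summarize_counts(rater, alg, fp, n_scans or len(scan_results))


def match_longitudinal(
    baseline: Sequence[Sequence[float]],
    followup: Sequence[Sequence[float]],
    tol_mm: float = DEFAULT_TOL_MM,
) -> pd.DataFrame:
    """Persistence of baseline locations at follow-up (one-to-one matching).

    Both coordinate lists must live in a common space (co-registration is
    the caller's responsibility).  Returns one row per baseline location
    with a ``persisted`` flag, the matched follow-up index and distance.
    """
    base = np.asarray(baseline, dtype=float).reshape(-1, 3)
    match = match_detections(followup, base, tol_mm)
    matched = {j: (i, dist) for i, j, dist in match.pairs}
    rows = []
    for j in range(len(base)):
        i, dist = matched.get(j, (None, np.nan))
        rows.append(
            {
                "baseline_index": j,
                "persisted": j in matched,
                "followup_index": i,
                "distance_mm": dist,
            }
        )
    return pd.DataFrame(
        rows, columns=["baseline_index", "persisted", "followup_index", "distance_mm"]
    )


# ---------------------------------------------------------------------------
# truth-file I/O
# ---------------------------------------------------------------------------

def read_truth_csv(path: str | Path) -> List[GroundTruthSet]:
    """Read truth files (columns scan_id, x_mm, y_mm, z_mm, certainty)."""
    df = pd.read_csv(path)
    out = []
    for scan_id, grp in df.groupby("scan_id", sort=True):
        out.append(
            GroundTruthSet(
                grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                grp["certainty"].tolist(),
                scan_id=str(scan_id),
            )
        )
    return out


def write_summary(summary: EvaluationSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))
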