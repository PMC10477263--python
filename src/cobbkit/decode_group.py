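"""Turn predicted heatmaps and offsets into 17 labelled vertebrae.

Candidate corners are heatmap local maxima (max-pool style NMS, top-k per
channel) corrected by the sub-grid center offset; each candidate carries
an estimate of its vertebra's centroid via the vertebral center offset.
Corners whose estimated centroids are close are greedily grouped, the 17
best-scoring groups become the vertebrae T1..L5 (ordered cranio-caudally),
and any group detected with only three corners gets its fourth from
parallelogram completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import maximum_filter

from .core import LandmarkSet, N_VERTEBRAE
from .data import CropTransform
from .keypoint_net import HeatmapTargets, compact_fields

#: parallelogram completion uses the fixed diagonal adjacency UL<->LR, UR<->LL
DIAGONAL = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class CandidatePoint:
    corner_type: int  # 0 UL, 1 UR, 2 LL, 3 LR
    position: np.ndarray  # (x, y) pixels in the crop frame, offset-corrected
    score: float
    estimated_center: np.ndarray  # (x, y) pixels
    cell: tuple[int, int] = (0, 0)  # (row, col) grid cell, for tie-breaks


@dataclass
class VertebraGroup:
    members: dict[int, CandidatePoint] = field(default_factory=dict)
    completed: dict[int, bool] = field(default_factory=dict)

    @property
    def group_center(self) -> np.ndarray:
        return np.mean([c.estimated_center for c in self.members.values()], axis=0)

    @property
    def group_score(self) -> float:
        """Mean member heatmap score (insensitive to size 3 vs 4)."""
        detected = [c.score for t, c in self.members.items() if not self.completed.get(t)]
        return float(np.mean(detected)) if detected else 0.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    def corners(self) -> np.ndarray:
        """(4, 2) corner array in (UL, UR, LL, LR) order; requires completeness."""
        if len(self.members) != 4:
            raise ValueError(f"group has {len(self.members)} corners, need 4")
        return np.stack([self.members[j].position for j in range(4)])


class GroupingError(RuntimeError):
    """Fewer than 17 vertebra groups could be recovered."""

    def __init__(self, recovered: int, groups: list[VertebraGroup]):
        super().__init__(f"recovered only {recovered} of 17 vertebra groups")
        self.recovered = recovered
        self.groups = groups


def decode_peaks(
    heatmaps: np.ndarray,
    center_offset: np.ndarray,
    vertebra_center_offset: np.ndarray,
    output_stride: int = 4,
    k_per_channel: int = 24,
    nms_radius: int = 1,
    layout: str = "per_corner",
    min_score: float = 0.05,
) -> list[CandidatePoint]:
    """Extract top-k offset-corrected corner candidates per corner channel.

    NMS keeps cells that equal the local maximum within ``nms_radius``;
    ties in score break in raster order.  Candidate position =
    (cell + center offset) * stride; the estimated vertebra centroid =
    position + vco * stride.  Cells scoring below ``min_score`` are
    dropped (flat background plateaus are technically local maxima).
    """
    if k_per_channel < N_VERTEBRAE:
        raise ValueError(f"k_per_channel must be >= 17 to seed 17 groups, got {k_per_channel}")
    heatmaps = np.asarray(heatmaps, dtype=float)
    candidates: list[CandidatePoint] = []
    size = 2 * nms_radius + 1
    for j in range(4):
        ch = heatmaps[j]
        is_peak = ch >= maximum_filter(ch, size=size, mode="constant", cval=-np.inf)
        flat_scores = np.where(is_peak, ch, -np.inf).ravel()
        order = np.argsort(-flat_scores, kind="stable")
        accepted: list[tuple[int, int]] = []
        for f in order:
            if len(accepted) >= k_per_channel:
                break
            if not np.isfinite(flat_scores[f]) or flat_scores[f] < min_score:
                break
            cy, cx = divmod(int(f), ch.shape[1])
            # sequential dedupe: tied plateau cells (e.g. from nearest-
            # neighbour upsampling) otherwise all pass the >= filter
            if any(abs(cy - ay) <= nms_radius and abs(cx - ax) <= nms_radius
                   for ay, ax in accepted):
                continue
            accepted.append((cy, cx))
            if layout == "per_corner":
                off = center_offset[j, :, cy, cx]
                voff = vertebra_center_offset[j, :, cy, cx]
            else:
                off = center_offset[:, cy, cx]
                row = 0 if j in (0, 1) else 2
                voff = vertebra_center_offset[row : row + 2, cy, cx]
            pos = (np.array([cx, cy]) + np.asarray(off)) * output_stride
            candidates.append(
                CandidatePoint(
                    corner_type=j,
                    position=pos,
                    score=float(ch[cy, cx]),
                    estimated_center=pos + np.asarray(voff) * output_stride,
                    cell=(cy, cx),
                )
            )
    return candidates


def decode_targets(targets: HeatmapTargets, k_per_channel: int = 24, nms_radius: int = 1):
    """Decode candidates straight from encoded targets (round-trip path)."""
    if targets.layout == "per_corner":
        return decode_peaks(
            targets.heatmaps,
            targets.center_offset,
            targets.vertebra_center_offset,
            targets.output_stride,
            k_per_channel,
            nms_radius,
            layout="per_corner",
        )
    co, vco = compact_fields(targets)
    return decode_peaks(
        targets.heatmaps, co, vco, targets.output_stride, k_per_channel, nms_radius, layout="compact"
    )


def estimate_center_spacing(candidates: list[CandidatePoint]) -> float:
    """Median inter-vertebra spacing estimated from the candidate set.

    Same-type corners of consecutive vertebrae are one vertebral pitch
    apart, and corner positions are far more precise than the regressed
    center estimates, so the pitch is read from the top-17 candidate
    positions per corner type sorted cranio-caudally.
    """
    gaps = []
    for j in range(4):
        best = sorted((c for c in candidates if c.corner_type == j), key=lambda c: -c.score)
        positions = sorted((c.position for c in best[:N_VERTEBRAE]), key=lambda p: p[1])
        for a, b in zip(positions[:-1], positions[1:]):
            gaps.append(float(np.hypot(*(np.asarray(b) - np.asarray(a)))))
    if not gaps:
        raise ValueError("cannot estimate center spacing from an empty candidate set")
    return float(np.median(gaps))


def group_candidates(
    candidates: list[CandidatePoint],
    distance_threshold: Optional[float] = None,
    allow_partial: bool = False,
) -> list[VertebraGroup]:
    """Greedy center-proximity grouping; returns 17 groups, cranio-caudal.

    Candidates are processed by descending score (raster order on ties);
    each joins the nearest existing group whose center is within the
    threshold and whose corner slot is free, else seeds a new group.
    Groups with fewer than 3 members are discarded, the top 17 by mean
    score are kept.  The default threshold is half the median
    inter-vertebra center spacing estimated from the candidates.
    """
    if len({c.corner_type for c in candidates}) < 3:
        raise ValueError("need candidates from at least 3 corner channels")
    if distance_threshold is None:
        distance_threshold = 0.5 * estimate_center_spacing(candidates)

    ordered = sorted(candidates, key=lambda c: (-c.score, c.cell[0], c.cell[1]))
    groups: list[VertebraGroup] = []
    for cand in ordered:
        best, best_d = None, np.inf
        for g in groups:
            if cand.corner_type in g.members:
                continue
            d = float(np.hypot(*(g.group_center - cand.estimated_center)))
            if d < best_d:
                best, best_d = g, d
        if best is not None and best_d <= distance_threshold:
            best.members[cand.corner_type] = cand
        else:
            groups.append(VertebraGroup(members={cand.corner_type: cand}))

    groups = [g for g in groups if g.n_members >= 3]
    groups.sort(key=lambda g: (-g.group_score, g.group_center[1]))
    groups = groups[:N_VERTEBRAE]
    groups.sort(key=lambda g: g.group_center[1])
    if len(groups) < N_VERTEBRAE and not allow_partial:
        raise GroupingError(len(groups), groups)
    return groups


def complete_missing(group: VertebraGroup) -> VertebraGroup:
    """Parallelogram-complete a 3-corner group; no-op when already complete.

    With the diagonal adjacency UL<->LR and UR<->LL, a missing corner is
    the sum of its two edge neighbours minus its diagonal opposite, e.g.
    UL = UR + LL - LR.
    """
    if group.n_members == 4:
        return group
    if group.n_members != 3:
        raise ValueError(f"completion needs exactly 3 detected corners, got {group.n_members}")
    (missing,) = set(range(4)) - set(group.members)
    diag = DIAGONAL[missing]
    others = [j for j in range(4) if j not in (missing, diag)]
    pos = (
        group.members[others[0]].position
        + group.members[others[1]].position
        - group.members[diag].position
    )
    center = np.mean([c.estimated_center for c in group.members.values()], axis=0)
    group.members[missing] = CandidatePoint(
        corner_type=missing,
        position=pos,
        score=group.group_score,
        estimated_center=center,
    )
    group.completed[missing] = True
    return group


def groups_to_landmarks(
    groups: list[VertebraGroup], transform: Optional[CropTransform] = None
) -> LandmarkSet:
    """17 complete groups -> LandmarkSet labelled T1..L5 by vertical order.

    ``transform`` maps crop-frame coordinates back to the original image
    frame (identity when omitted).
    """
    if len(groups) != N_VERTEBRAE:
        raise ValueError(f"need exactly 17 complete groups, got {len(groups)}")
    groups = sorted(groups, key=lambda g: g.group_center[1])
    points = np.zeros((N_VERTEBRAE, 4, 2))
    confidence = np.zeros((N_VERTEBRAE, 4))
    completed = np.zeros((N_VERTEBRAE, 4), dtype=bool)
    for k, g in enumerate(groups):
        pts = g.corners()
        if transform is not None:
            pts = transform.to_image(pts)
        points[k] = pts
        for j in range(4):
            confidence[k, j] = g.members[j].score
            completed[k, j] = bool(g.completed.get(j, False))
    return LandmarkSet(points, confidence=confidence, completed=completed)
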