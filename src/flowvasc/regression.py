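"""Vessel-regression (empty-sleeve) quantification from paired CD31 and
Collagen IV masks.

During vascular pruning the endothelium (CD31) withdraws from a vessel
segment while its basement-membrane sleeve (Collagen IV) persists.  An
event is therefore a connected region of the ColIV network lacking CD31
signal; its stage follows the residual CD31 coverage of the enclosing
ColIV skeleton segment (partial coverage = intermediate, none = final,
none on a ColIV fragment disconnected from any endothelialized network
= long-regressed).  Network context comes from skeletonization and
branch-point counting; the headline statistic is the regression
frequency per 100 CD31 branching points, alongside CD31/ColIV density
ratios normalized to the ROI volume ratio.

2D and 3D masks are both supported; the geometric defaults are tuned
for 2D projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import skeletonize

from .core_io import ImageStack

logger = logging.getLogger(__name__)

#: events whose ColIV skeleton footprint is below this are invisible to a
#: human scorer and are discarded
DEFAULT_MIN_SIZE = 5

#: CD31 coverage of the enclosing segment above which a candidate region
#: is a staining gap, not a regression event
INTERMEDIATE_MAX_COVERAGE = 0.5


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, ImageStack):
        return mask.data.astype(bool)
    return np.asarray(mask).astype(bool)


@dataclass
class VesselNetworkStats:
    """Skeleton-derived descriptors of one channel's vessel network."""

    n_branch_points: int
    vessel_volume: float       # mask voxels x voxel volume (µm^ndim)
    roi_volume: float
    skeleton: np.ndarray

    @property
    def vessel_density(self) -> float:
        """Vessel volume as a percentage of the ROI volume."""
        return 100.0 * self.vessel_volume / self.roi_volume

    @property
    def branch_point_density(self) -> float:
        return self.n_branch_points / self.roi_volume


@dataclass
class RegressionEvent:
    event: int
    stage: str                 # intermediate | final | long-regressed
    n_voxels: int              # candidate-region voxels
    n_skeleton_voxels: int     # ColIV skeleton voxels inside the region
    centroid: tuple[float, ...]
    coverage: float            # CD31 coverage of the enclosing segment


@dataclass
class RegressionReport:
    events: list[RegressionEvent]
    cd31_branch_points: int
    frequency: float              # events per 100 CD31 branching points
    branch_density_ratio: float   # CD31/ColIV, ROI-volume normalized
    vessel_density_ratio: float
    roi_volume_ratio: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "event", "event": e.event, "stage": e.stage,
                 "n_voxels": e.n_voxels, "coverage": e.coverage,
                 "centroid_row": e.centroid[-2], "centroid_col": e.centroid[-1],
                 "frequency": np.nan, "branch_density_ratio": np.nan,
                 "vessel_density_ratio": np.nan}
                for e in self.events]
        rows.append({"kind": "summary", "event": len(self.events),
                     "stage": "", "n_voxels": np.nan, "coverage": np.nan,
                     "centroid_row": np.nan, "centroid_col": np.nan,
                     "frequency": self.frequency,
                     "branch_density_ratio": self.branch_density_ratio,
                     "vessel_density_ratio": self.vessel_density_ratio})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def skeletonize_network(mask) -> np.ndarray:
    """One-voxel-wide medial skeleton of a binary vessel mask (2D or 3D),
    preserving the number of connected components."""
    arr = _as_bool(mask)
    if not arr.any():
        raise ValueError("empty mask")
    return skeletonize(arr)


def branch_points(skeleton: np.ndarray,
                  merge_iterations: int = 1) -> tuple[int, np.ndarray]:
    """Branching points of a skeleton: voxels with >= 3 skeleton
    neighbours (full connectivity), adjacent qualifying voxels merged
    into one point.

    Returns (count, centroids); centroids is an (n, ndim) float array.
    """
    skel = skeleton.astype(bool)
    kernel = np.ones((3,) * skel.ndim)
    neighbours = ndi.convolve(skel.astype(np.uint8), kernel,
                              mode="constant") - 1
    qualifying = skel & (neighbours >= 3)
    if not qualifying.any():
        return 0, np.empty((0, skel.ndim))
    struct = ndi.generate_binary_structure(skel.ndim, skel.ndim)
    merged = ndi.binary_dilation(qualifying, struct,
                                 iterations=merge_iterations)
    labels, n = ndi.label(merged, structure=struct)
    centroids = np.array(ndi.center_of_mass(qualifying, labels * qualifying,
                                            index=range(1, n + 1)))
    return n, centroids


def network_stats(mask, roi=None, voxel_size: float = 1.0) -> VesselNetworkStats:
    """Skeletonize one channel and compute its network descriptors.

    ``roi`` may be a mask or a precomputed ROI volume (same units as the
    vessel volume: voxels x voxel_size**ndim); defaults to the full grid.
    """
    arr = _as_bool(mask)
    voxel_vol = voxel_size ** arr.ndim
    if roi is None:
        roi_volume = arr.size * voxel_vol
    elif np.isscalar(roi):
        roi_volume = float(roi)
    else:
        roi_volume = float(_as_bool(roi).sum() * voxel_vol)
    skel = skeletonize_network(arr)
    n_bp, _ = branch_points(skel)
    return VesselNetworkStats(n_branch_points=n_bp,
                              vessel_volume=float(arr.sum() * voxel_vol),
                              roi_volume=roi_volume, skeleton=skel)


def _segment_labels(coliv_skel: np.ndarray, clearance: int = 3) -> np.ndarray:
    """Label ColIV skeleton segments between branch-point clusters."""
    kernel = np.ones((3,) * coliv_skel.ndim)
    neighbours = ndi.convolve(coliv_skel.astype(np.uint8), kernel,
                              mode="constant") - 1
    bp = coliv_skel & (neighbours >= 3)
    struct = ndi.generate_binary_structure(coliv_skel.ndim, coliv_skel.ndim)
    if bp.any():
        bp = ndi.binary_dilation(bp, struct, iterations=clearance)
    seg_mask = coliv_skel & ~bp
    labels, _ = ndi.label(seg_mask, structure=struct)
    return labels


def classify_regression_events(cd31, coliv, min_size: int = DEFAULT_MIN_SIZE
                               ) -> list[RegressionEvent]:
    """Detect and stage regression events.

    Candidate voxels are ColIV-positive but outside the CD31 mask dilated
    by one voxel (the dilation absorbs ~1 px registration slack between
    channels).  Candidate components whose ColIV-skeleton footprint is at
    least ``min_size`` voxels become events; their stage follows the raw
    CD31 coverage of the enclosing skeleton segment(s): zero coverage is
    a final-stage event (or long-regressed when the whole ColIV component
    carries no CD31 anywhere), coverage up to 50% an intermediate one,
    and higher coverage is discarded as a staining gap.
    """
    cd31 = _as_bool(cd31)
    coliv = _as_bool(coliv)
    if cd31.shape != coliv.shape:
        raise ValueError("CD31 and ColIV masks must share shape")
    if min_size < 1:
        raise ValueError("min size must be >= 1")
    struct = ndi.generate_binary_structure(cd31.ndim, cd31.ndim)
    cd31_d = ndi.binary_dilation(cd31, struct)
    candidates = coliv & ~cd31_d
    if not candidates.any():
        return []
    coliv_skel = skeletonize_network(coliv)
    segments = _segment_labels(coliv_skel)
    coliv_comp, _ = ndi.label(coliv, structure=struct)
    comp_has_cd31 = np.unique(coliv_comp[cd31 & coliv])

    comp_labels, n_comp = ndi.label(candidates, structure=struct)
    events: list[RegressionEvent] = []
    for lab in range(1, n_comp + 1):
        region = comp_labels == lab
        skel_in = coliv_skel & region
        n_skel = int(skel_in.sum())
        if n_skel < min_size:
            continue
        seg_ids = np.unique(segments[region & (segments > 0)])
        if seg_ids.size == 0:
            continue
        seg_vox = np.isin(segments, seg_ids)
        coverage = float(cd31[seg_vox].mean())
        if coverage == 0.0:
            owner = np.unique(coliv_comp[region])
            orphaned = not np.isin(owner[owner > 0], comp_has_cd31).any()
            stage = "long-regressed" if orphaned else "final"
        elif coverage <= INTERMEDIATE_MAX_COVERAGE:
            stage = "intermediate"
        else:
            continue
        centroid = tuple(float(c) for c in ndi.center_of_mass(region))
        events.append(RegressionEvent(event=len(events), stage=stage,
                                      n_voxels=int(region.sum()),
                                      n_skeleton_voxels=n_skel,
                                      centroid=centroid, coverage=coverage))
    return events


def regression_report(cd31_stats: VesselNetworkStats,
                      coliv_stats: VesselNetworkStats,
                      events: list[RegressionEvent]) -> RegressionReport:
    """Regression frequency per 100 CD31 branching points plus CD31/ColIV
    density ratios normalized to the ROI volume ratio.

    Multiplying the density ratio by ROI_cd31/ROI_coliv cancels the ROI
    volume factors, so identical channels measured in different ROIs
    still yield ratios of exactly 1.
    """
    if cd31_stats.n_branch_points == 0:
        raise ValueError("zero CD31 branching points")
    roi_ratio = cd31_stats.roi_volume / coliv_stats.roi_volume
    freq = 100.0 * len(events) / cd31_stats.n_branch_points
    bp_ratio = (cd31_stats.branch_point_density /
                coliv_stats.branch_point_density) * roi_ratio
    vd_ratio = (cd31_stats.vessel_density /
                coliv_stats.vessel_density) * roi_ratio
    return RegressionReport(events=events,
                            cd31_branch_points=cd31_stats.n_branch_points,
                            frequency=freq,
                            branch_density_ratio=bp_ratio,
                            vessel_density_ratio=vd_ratio,
                            roi_volume_ratio=roi_ratio)
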