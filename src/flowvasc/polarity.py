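"""Per-cell nucleus-Golgi polarity, marker localization and shape
features from label images, with circular summary statistics.

The polarity angle of a cell is the direction of the vector from its
nucleus centroid to the intensity-weighted centroid of the Golgi channel
inside the cell (nucleus excluded), expressed in the math convention of
:mod:`flowvasc.core_io`.  Collective polarization is summarised by the
polarity index PI (mean resultant length, in [0, 1]) and the signed
polarity index V (mean cosine relative to a reference direction, in
[-1, 1]); orientation statistics use the axial (doubled-angle)
convention so that flow-parallel orientation maps to V = +1 and
perpendicular to V = -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import regionprops

from .core_io import ImageStack

logger = logging.getLogger(__name__)

#: cells less elongated than this are near-isotropic; their orientation is
#: numerical noise and they are excluded from axial statistics
MIN_ELONGATION_FOR_ORIENTATION = 1.05


@dataclass
class CellRecord:
    """Geometry, polarity and marker readouts of one cell.

    Centroids are (x, y) in µm, image coordinates.  ``ratios`` maps each
    marker name to its nuclear/cytosolic mean-intensity ratio.
    """

    cell: int
    nucleus_centroid: tuple[float, float]
    golgi_centroid: tuple[float, float]
    angle: float                 # polarity angle, (-pi, pi]
    area: float                  # µm^2
    elongation: float            # major/minor axis ratio, >= 1
    orientation: float           # [0, pi), axial
    border: bool                 # touches the image border
    nuc_mean: dict[str, float]
    cyt_mean: dict[str, float]
    ratios: dict[str, float]


@dataclass
class PolaritySummary:
    """Circular summary of a set of angles.

    ``pi_`` is the polarity index (mean resultant length); ``v`` the
    signed polarity index relative to ``reference``.  |v| <= pi_ always.
    """

    n: int
    mean_direction: float
    pi_: float
    v: float
    reference: float = 0.0
    axial: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"n": self.n, "mean_direction": self.mean_direction,
                              "PI": self.pi_, "V": self.v,
                              "reference": self.reference, "axial": self.axial}])


def _moments_shape(coords: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """(elongation, orientation) from the second central moments of a
    pixel set, in the math angle convention (x = col, y = -row).

    Each pixel contributes a 1/12 unit-square variance so that an
    axis-aligned N x M rectangle has elongation exactly N/M.
    """
    xy = np.column_stack([coords[:, 1], -coords[:, 0]]).astype(float)
    xy -= xy.mean(axis=0)
    cov = xy.T @ xy / len(xy) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    elong = float(np.sqrt(evals[1] / evals[0]))
    major = evecs[:, 1]
    orientation = float(np.arctan2(major[1], major[0]) % np.pi)
    return elong, orientation


def shape_features(cell_labels: ImageStack) -> pd.DataFrame:
    """Area (µm²), elongation (major/minor ratio) and axial orientation
    per cell; 1-pixel cells are skipped, border-touching cells flagged."""
    data = cell_labels.data
    psz = cell_labels.pixel_size
    rows = []
    border_labels = set(np.unique(np.concatenate([
        data[0, :], data[-1, :], data[:, 0], data[:, -1]])))
    for rp in regionprops(data):
        if rp.num_pixels < 2:
            logger.warning("skipping degenerate 1-pixel cell %d", rp.label)
            continue
        elong, orient = _moments_shape(rp.coords, psz)
        rows.append({"cell": rp.label,
                     "area": rp.num_pixels * psz ** 2,
                     "elongation": elong,
                     "orientation": orient,
                     "border": rp.label in border_labels})
    return pd.DataFrame(rows, columns=["cell", "area", "elongation",
                                       "orientation", "border"])


def extract_cells(cell_labels: ImageStack, nucleus_labels: ImageStack,
                  golgi: ImageStack,
                  markers: Mapping[str, ImageStack] | None = None
                  ) -> list[CellRecord]:
    """One record per cell that has both a nucleus and a Golgi locus.

    The cytosolic compartment is the cell minus its nucleus; the Golgi
    centroid is the intensity-weighted centroid of the Golgi channel in
    that compartment.  Cells without a nucleus or without Golgi signal
    are skipped with a warning; a nucleus overlapping two cells is an
    error.
    """
    markers = markers or {}
    cells = cell_labels.data
    nuclei = nucleus_labels.data
    if cells.shape != nuclei.shape or cells.shape != golgi.data.shape:
        raise ValueError("label and channel images must share shape")
    for img in markers.values():
        if img.data.shape != cells.shape:
            raise ValueError("marker images must share shape with labels")
    psz = cell_labels.pixel_size

    # map each nucleus to the unique cell beneath it
    nucleus_to_cell: dict[int, int] = {}
    for rp in regionprops(nuclei):
        under = cells[tuple(rp.coords.T)]
        owners = np.unique(under[under > 0])
        if owners.size > 1:
            raise ValueError(f"nucleus {rp.label} spans cells {owners.tolist()}")
        if owners.size == 1:
            nucleus_to_cell[rp.label] = int(owners[0])
    cell_to_nucleus = {}
    for nuc, cell in nucleus_to_cell.items():
        if cell in cell_to_nucleus:
            raise ValueError(f"cell {cell} contains two nuclei")
        cell_to_nucleus[cell] = nuc

    shapes = shape_features(cell_labels).set_index("cell")
    cyt_labels = np.where(nuclei > 0, 0, cells)
    cell_ids = np.unique(cells[cells > 0])

    # per-compartment marker means, vectorized over labels
    nuc_means = {}
    cyt_means = {}
    nuc_ids = np.array([cell_to_nucleus.get(c, 0) for c in cell_ids])
    for name, img in markers.items():
        nm = np.full(cell_ids.size, np.nan)
        has = nuc_ids > 0
        if has.any():
            nm[has] = ndi.mean(img.data, labels=nuclei, index=nuc_ids[has])
        nuc_means[name] = nm
        cyt_means[name] = ndi.mean(img.data, labels=cyt_labels, index=cell_ids)

    golgi_cyt = np.where(nuclei > 0, 0.0, golgi.data.astype(float))
    records: list[CellRecord] = []
    n_skipped = 0
    nuc_centroids = {rp.label: rp.centroid for rp in regionprops(nuclei)}
    sum_w = ndi.sum_labels(golgi_cyt, labels=cells, index=cell_ids)
    rr, cc = np.indices(cells.shape)
    sum_wr = ndi.sum_labels(golgi_cyt * rr, labels=cells, index=cell_ids)
    sum_wc = ndi.sum_labels(golgi_cyt * cc, labels=cells, index=cell_ids)

    for k, cid in enumerate(cell_ids):
        nuc = cell_to_nucleus.get(int(cid))
        if nuc is None:
            logger.warning("cell %d has no nucleus; skipped", cid)
            n_skipped += 1
            continue
        if sum_w[k] <= 0:
            logger.warning("cell %d has no Golgi signal; skipped", cid)
            n_skipped += 1
            continue
        g_row, g_col = sum_wr[k] / sum_w[k], sum_wc[k] / sum_w[k]
        n_row, n_col = nuc_centroids[nuc]
        angle = float(np.arctan2(-(g_row - n_row), g_col - n_col))
        shp = shapes.loc[int(cid)]
        records.append(CellRecord(
            cell=int(cid),
            nucleus_centroid=(n_col * psz, n_row * psz),
            golgi_centroid=(g_col * psz, g_row * psz),
            angle=angle,
            area=float(shp["area"]),
            elongation=float(shp["elongation"]),
            orientation=float(shp["orientation"]),
            border=bool(shp["border"]),
            nuc_mean={m: float(nuc_means[m][k]) for m in markers},
            cyt_mean={m: float(cyt_means[m][k]) for m in markers},
            ratios={m: float(nuc_means[m][k] / cyt_means[m][k]) for m in markers},
        ))
    if n_skipped:
        logger.info("skipped %d cells without nucleus or Golgi", n_skipped)
    return records


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"cell": r.cell, "angle": r.angle, "area": r.area,
               "elongation": r.elongation, "orientation": r.orientation,
               "border": r.border,
               "nucleus_x": r.nucleus_centroid[0], "nucleus_y": r.nucleus_centroid[1],
               "golgi_x": r.golgi_centroid[0], "golgi_y": r.golgi_centroid[1]}
        for m, v in r.ratios.items():
            row[f"ratio_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# circular statistics


def circular_summary(angles, reference: float = 0.0,
                     axial: bool = False) -> PolaritySummary:
    """Polarity index, mean direction and signed polarity index.

    With C = mean cos(theta) and S = mean sin(theta): PI = sqrt(C²+S²),
    mean direction = atan2(S, C), V = mean cos(theta - reference).  In
    axial mode angles are doubled first and the mean direction halved,
    so orientations theta and theta + pi are identified.
    """
    theta = np.asarray(angles, dtype=float)
    if theta.size == 0:
        raise ValueError("empty angle set")
    work = 2.0 * theta if axial else theta
    ref = 2.0 * reference if axial else reference
    C = np.mean(np.cos(work))
    S = np.mean(np.sin(work))
    pi_ = float(np.hypot(C, S))
    mean_dir = float(np.arctan2(S, C))
    if axial:
        mean_dir = (mean_dir / 2.0) % np.pi
    v = float(np.mean(np.cos(work - ref)))
    return PolaritySummary(n=theta.size, mean_direction=mean_dir, pi_=pi_, v=v,
                           reference=reference, axial=axial)


def rose_histogram(angles, n_bins: int = 36,
                   axial: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Counts over equal-width angular bins covering (-pi, pi].

    In axial mode the doubled angles are binned, so theta and theta + pi
    fall in the same bin.  Returns (counts, bin_edges); counts sum to n.
    """
    theta = np.asarray(angles, dtype=float)
    if theta.size == 0:
        raise ValueError("empty angle set")
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    work = 2.0 * theta if axial else theta
    wrapped = (work + np.pi) % (2 * np.pi) - np.pi
    counts, edges = np.histogram(wrapped, bins=n_bins, range=(-np.pi, np.pi))
    return counts, edges


def image_level_vscore(df: pd.DataFrame, reference: float = 0.0,
                       angle_column: str = "orientation",
                       image_column: str = "image",
                       axial: bool = True,
                       min_elongation: float = MIN_ELONGATION_FOR_ORIENTATION
                       ) -> pd.DataFrame:
    """One signed polarity index per image.

    For orientation statistics (the default), near-isotropic cells
    (elongation below ``min_elongation``) are excluded before the per-
    image V is computed; group comparisons downstream operate on these
    per-image values.
    """
    if image_column not in df.columns:
        raise ValueError(f"missing image column {image_column!r}")
    work = df
    if axial and angle_column == "orientation" and "elongation" in df.columns:
        work = df[df["elongation"] >= min_elongation]
    rows = []
    for image, grp in work.groupby(image_column):
        summ = circular_summary(grp[angle_column].to_numpy(),
                                reference=reference, axial=axial)
        rows.append({image_column: image, "n": summ.n, "V": summ.v,
                     "PI": summ.pi_})
    return pd.DataFrame(rows, columns=[image_column, "n", "V", "PI"])
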