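"""Synthetic inputs with the statistical structure each analysis assumes.

Four generators emulate the four experimental assays at desk scale:

* :func:`gen_monolayer` — a flow-exposed endothelial monolayer as label
  images plus intensity channels, with nucleus→Golgi polarity angles
  drawn from a von Mises distribution;
* :func:`gen_tracks` — drift-diffusion migration tracks (drift models
  the net flow response, diffusion the undirected motility);
* :func:`gen_retina` — a radial retina with alternating vein/artery
  rays and labelled cells placed according to a target distribution
  over the arteriovenous coordinate and radial distance;
* :func:`gen_vessel_fixture` — paired CD31/ColIV lattice networks with
  a planted set of regression events.

Every generator is fully seeded (same seed → bit-identical output) and
emits its ground truth alongside the rasters/tables, so downstream
recovery tests can consume only the generated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from .core_io import ImageStack, TrackSet
from .retina import RetinaGeometry

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# monolayer


@dataclass
class MonolayerParams:
    """Layout and statistics of a synthetic endothelial monolayer.

    Defaults model a confluent HUVEC monolayer after ~16 h of low shear
    stress: cells ~25 µm apart on a jittered hexagonal grid, polarity
    pointing against flow (mu = pi with flow along +x) with moderate
    alignment (kappa = 2), and nuclear marker enrichment of 2x.
    """

    n_cells: int = 400
    spacing_px: float = 25.0
    pixel_size: float = 1.0  # µm per pixel
    mu: float = np.pi        # von Mises mean polarity angle (rad)
    kappa: float = 2.0       # von Mises concentration, >= 0
    markers: Mapping[str, float] = field(default_factory=lambda: {"psmad159": 2.0})
    noise_sd: float = 0.0    # additive Gaussian noise on intensities
    cell_radius_px: float = 10.0
    nucleus_radius_px: float = 3.0
    golgi_offset_px: float = 6.5
    golgi_radius_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if any(r <= 0 for r in self.markers.values()):
            raise ValueError("nuclear/cytosolic ratios must be positive")
        # jitter of +-8% spacing keeps discs disjoint on the hex grid
        if self.spacing_px * (1 - 0.16) < 2 * self.cell_radius_px:
            raise ValueError("cells cannot be placed without overlap at "
                             "requested density")
        if self.golgi_offset_px + self.golgi_radius_px >= self.cell_radius_px:
            raise ValueError("Golgi locus does not fit inside the cell")
        if self.golgi_offset_px - self.golgi_radius_px <= self.nucleus_radius_px:
            raise ValueError("Golgi locus overlaps the nucleus")


@dataclass
class MonolayerSample:
    cells: ImageStack      # cell label image
    nuclei: ImageStack     # nucleus label image (ids match cells)
    golgi: ImageStack      # Golgi intensity channel
    markers: dict[str, ImageStack]
    truth: pd.DataFrame    # cell, row, col, angle, ratio_<marker>


def _paint_disc(img: np.ndarray, r0: float, c0: float, radius: float, value) -> None:
    r_int, c_int = int(round(r0)), int(round(c0))
    w = int(np.ceil(radius)) + 1
    rr, cc = np.mgrid[r_int - w:r_int + w + 1, c_int - w:c_int + w + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    keep = inside & (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    img[rr[keep], cc[keep]] = value


def gen_monolayer(params: MonolayerParams) -> MonolayerSample:
    """Generate label images, a Golgi channel and marker channels for a
    monolayer whose nucleus→Golgi angles follow von Mises(mu, kappa)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    sp = params.spacing_px
    dy = sp * np.sqrt(3) / 2
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    margin = sp
    height = int(np.ceil(2 * margin + (nrows - 1) * dy)) + 1
    width = int(np.ceil(2 * margin + (ncols - 0.5) * sp)) + 1

    jitter = rng.uniform(-0.08 * sp, 0.08 * sp, size=(n, 2))
    angles = rng.vonmises(params.mu, params.kappa, size=n) if params.kappa > 0 \
        else rng.uniform(-np.pi, np.pi, size=n)

    cells = np.zeros((height, width), dtype=np.int32)
    nuclei = np.zeros_like(cells)
    golgi = np.zeros((height, width), dtype=np.float64)
    marker_imgs = {m: np.zeros((height, width), dtype=np.float64)
                   for m in params.markers}

    rows0 = np.empty(n)
    cols0 = np.empty(n)
    for i in range(n):
        ri, ci = divmod(i, ncols)
        r0 = margin + ri * dy + jitter[i, 0]
        c0 = margin + ci * sp + (sp / 2 if ri % 2 else 0.0) + jitter[i, 1]
        rows0[i], cols0[i] = r0, c0
        lab = i + 1
        _paint_disc(cells, r0, c0, params.cell_radius_px, lab)
        _paint_disc(nuclei, r0, c0, params.nucleus_radius_px, lab)
        # angle convention: atan2(-drow, dcol); Golgi sits at the sampled
        # polarity angle relative to the nucleus centroid
        gr = r0 - params.golgi_offset_px * np.sin(angles[i])
        gc = c0 + params.golgi_offset_px * np.cos(angles[i])
        _paint_disc(golgi, gr, gc, params.golgi_radius_px, 100.0)

    cytosol = (cells > 0) & (nuclei == 0)
    base = 100.0
    for name, ratio in params.markers.items():
        img = marker_imgs[name]
        img[cytosol] = base
        img[nuclei > 0] = base * ratio
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)

    truth = pd.DataFrame({"cell": np.arange(1, n + 1),
                          "row": rows0, "col": cols0, "angle": angles})
    for name, ratio in params.markers.items():
        truth[f"ratio_{name}"] = ratio

    psz = params.pixel_size
    return MonolayerSample(
        cells=ImageStack(cells, psz, "cells", "label"),
        nuclei=ImageStack(nuclei, psz, "nuclei", "label"),
        golgi=ImageStack(golgi, psz, "golgi", "intensity"),
        markers={m: ImageStack(img, psz, m, "intensity")
                 for m, img in marker_imgs.items()},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# migration tracks


@dataclass
class TrackParams:
    """Drift-diffusion track ensemble.

    The experimental design is a 48 h time lapse at 7.5 min frame
    interval.  ``drift`` is the net velocity in µm/h in image
    coordinates (x right, y down); with flow along +x, migration
    against flow is a negative x drift.  ``diffusion`` (µm²/h) sets the
    per-step Gaussian noise variance 2·D·dt per axis.
    """

    n_tracks: int = 100
    duration: float = 48.0       # h
    interval: float = 0.125      # h (7.5 min)
    drift: tuple[float, float] = (0.0, 0.0)
    diffusion: float = 15.0
    field_um: float = 1000.0
    condition: str = ""
    replicate: int = 0
    population: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > self.interval > 0:
            raise ValueError("need duration > interval > 0")
        if self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")
        if self.n_tracks < 1:
            raise ValueError("need at least one track")


def gen_tracks(params: TrackParams) -> TrackSet:
    """Simulate tracks x(t+dt) = x(t) + drift·dt + N(0, 2·D·dt) per axis."""
    rng = np.random.default_rng(params.seed)
    dt = params.interval
    n_frames = int(round(params.duration / dt)) + 1
    drift = np.asarray(params.drift, dtype=float)
    start = rng.uniform(0.0, params.field_um, size=(params.n_tracks, 1, 2))
    steps = drift * dt + rng.normal(
        0.0, np.sqrt(2.0 * params.diffusion * dt),
        size=(params.n_tracks, n_frames - 1, 2))
    pos = np.concatenate([np.zeros((params.n_tracks, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1) + start
    frames = np.tile(np.arange(n_frames), params.n_tracks)
    tracks = np.repeat(np.arange(params.n_tracks), n_frames)
    df = pd.DataFrame({
        "condition": params.condition,
        "replicate": params.replicate,
        "population": params.population,
        "track": tracks,
        "frame": frames,
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
    })
    return TrackSet(df, frame_interval=dt)


def gen_track_experiment(drifts: Mapping[str, tuple[float, float]],
                         n_replicates: int = 4, seed: int = 0,
                         **kw) -> TrackSet:
    """Multi-condition, multi-replicate track set (one generator call per
    condition x replicate, sub-seeded from ``seed``)."""
    parts = []
    for i, (cond, drift) in enumerate(sorted(drifts.items())):
        for rep in range(n_replicates):
            p = TrackParams(condition=cond, replicate=rep, drift=drift,
                            seed=seed + 1000 * i + rep, **kw)
            parts.append(gen_tracks(p).df)
    df = pd.concat(parts, ignore_index=True)
    interval = kw.get("interval", TrackParams.interval)
    return TrackSet(df, frame_interval=interval)


# ---------------------------------------------------------------------------
# retina


@dataclass
class RetinaComponent:
    """One mixture component of the target (phi, r) distribution:
    Beta(a, b) on the arteriovenous coordinate x uniform on a radial
    annulus (fractions of the retina radius).  A point mass on phi can
    be requested with ``phi_point`` (used for boundary fixtures)."""

    weight: float
    phi_beta: tuple[float, float] = (2.0, 2.0)
    r_range: tuple[float, float] = (0.3, 0.9)
    phi_point: float | None = None


@dataclass
class RetinaParams:
    """Radial retina geometry with alternating vein/artery rays.

    Defaults model an early postnatal mouse retina: ~2 mm radius,
    four veins and four arteries alternating around the optic nerve,
    and a remodelling plexus annulus at 40-80% of the radius.
    """

    radius_um: float = 2000.0
    pixel_size: float = 5.0
    n_veins: int = 4
    n_arteries: int = 4
    plexus_band: tuple[float, float] = (0.4, 0.8)
    n_cells: int = 2000
    components: Sequence[RetinaComponent] = field(
        default_factory=lambda: (RetinaComponent(1.0),))
    nerve_radius_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_veins != self.n_arteries or self.n_veins < 1:
            raise ValueError("rays must alternate vein/artery: need equal, "
                             "positive vein and artery counts")
        w = sum(c.weight for c in self.components)
        if not np.isclose(w, 1.0):
            raise ValueError("mixture weights must sum to 1")
        for c in self.components:
            a, b = c.phi_beta
            if c.phi_point is None and (a <= 0 or b <= 0):
                raise ValueError("Beta parameters must be positive")
            if c.phi_point is not None and not 0 <= c.phi_point <= 1:
                raise ValueError("phi point mass must lie in [0, 1]")


@dataclass
class RetinaSample:
    geometry: RetinaGeometry
    gfp: ImageStack
    truth: pd.DataFrame  # cell, phi_target, r_um, row, col


def gen_retina(params: RetinaParams) -> RetinaSample:
    """Draw the ray geometry and place labelled cells so their true
    (phi, r) follow the target mixture.

    Placement uses the angular-fraction approximation: within the sector
    between a vein ray and the adjacent artery ray the azimuthal position
    is ``vein_angle + phi * sector_width``.  Cells with a point mass at
    phi = 0 or 1 are snapped onto the nearest vein/artery mask pixel.
    """
    rng = np.random.default_rng(params.seed)
    r_px = params.radius_um / params.pixel_size
    margin = 3
    size = int(np.ceil(2 * r_px)) + 2 * margin + 1
    center = size // 2

    m = 2 * params.n_veins
    ray_angles = 2 * np.pi * np.arange(m) / m  # even -> vein, odd -> artery
    vein = np.zeros((size, size), dtype=bool)
    artery = np.zeros((size, size), dtype=bool)
    for k, ang in enumerate(ray_angles):
        er = int(round(center - r_px * np.sin(ang)))
        ec = int(round(center + r_px * np.cos(ang)))
        rr, cc = draw_line(center, center, er, ec)
        (vein if k % 2 == 0 else artery)[rr, cc] = True
    struct = ndi.generate_binary_structure(2, 2)
    vein = ndi.binary_dilation(vein, struct)
    artery = ndi.binary_dilation(artery, struct)
    # the optic-nerve disc belongs to neither vessel type
    rr_idx, cc_idx = np.indices((size, size))
    dist_c = np.hypot(rr_idx - center, cc_idx - center)
    nerve_px = params.nerve_radius_um / params.pixel_size
    nerve_disc = dist_c <= nerve_px
    vein &= ~nerve_disc
    artery &= ~nerve_disc
    artery &= ~vein
    roi = dist_c <= r_px + 1

    weights = np.array([c.weight for c in params.components])
    comp_idx = rng.choice(len(params.components), size=params.n_cells, p=weights)
    phi_t = np.empty(params.n_cells)
    r_frac = np.empty(params.n_cells)
    for j, comp in enumerate(params.components):
        sel = comp_idx == j
        k = int(sel.sum())
        if comp.phi_point is not None:
            phi_t[sel] = comp.phi_point
        else:
            a, b = comp.phi_beta
            phi_t[sel] = rng.beta(a, b, size=k)
        lo, hi = comp.r_range
        r_frac[sel] = rng.uniform(lo, hi, size=k)
    if np.any(r_frac * r_px <= nerve_px):
        raise ValueError("radial range reaches into the optic-nerve disc")

    sector = rng.integers(0, m, size=params.n_cells)
    width = 2 * np.pi / m
    base = ray_angles[sector]
    even = sector % 2 == 0
    # sector ray order: even sectors run vein -> artery, odd the reverse
    ang = np.where(even, base + phi_t * width, base + (1.0 - phi_t) * width)
    radius = r_frac * r_px
    rows = np.clip(np.round(center - radius * np.sin(ang)).astype(int), 0, size - 1)
    cols = np.clip(np.round(center + radius * np.cos(ang)).astype(int), 0, size - 1)

    # snap boundary point masses exactly onto the ray masks
    for target, mask in ((0.0, vein), (1.0, artery)):
        onto = np.isclose(phi_t, target) & ~mask[rows, cols]
        if onto.any():
            tree = cKDTree(np.column_stack(np.nonzero(mask)))
            _, nearest = tree.query(np.column_stack([rows[onto], cols[onto]]))
            coords = np.column_stack(np.nonzero(mask))[nearest]
            rows[onto] = coords[:, 0]
            cols[onto] = coords[:, 1]

    gfp = np.zeros((size, size), dtype=np.uint8)
    gfp[rows, cols] = 1

    geometry = RetinaGeometry(vein=vein, artery=artery, roi=roi,
                              nerve_center=(center, center),
                              pixel_size=params.pixel_size)
    truth = pd.DataFrame({
        "cell": np.arange(params.n_cells),
        "phi_target": phi_t,
        "r_um": np.hypot(rows - center, cols - center) * params.pixel_size,
        "row": rows,
        "col": cols,
    })
    return RetinaSample(geometry=geometry,
                        gfp=ImageStack(gfp, params.pixel_size, "gfp", "mask"),
                        truth=truth)


# ---------------------------------------------------------------------------
# vessel fixture


@dataclass
class VesselFixtureParams:
    """Square-lattice vessel network with planted regression events.

    ``stages`` lists the stage of each planted event ("final" = segment
    fully erased from the CD31 channel, "intermediate" = central half
    erased).  Planted segments are node-disjoint lattice edges.
    """

    n_rows: int = 6              # lattice nodes per side
    n_cols: int = 6
    spacing_px: float = 40.0
    radius_px: int = 2
    stages: Sequence[str] = ("final", "final", "final")
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("lattice needs at least 2x2 nodes")
        bad = set(self.stages) - {"final", "intermediate"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


@dataclass
class VesselFixture:
    cd31: ImageStack
    coliv: ImageStack
    truth: pd.DataFrame       # event, stage, row, col (event centroid)
    n_branch_points: int      # analytic count for the full lattice


def lattice_branch_point_count(n_rows: int, n_cols: int) -> int:
    """Nodes of degree >= 3 in an n_rows x n_cols grid graph: interior
    nodes have degree 4, non-corner border nodes degree 3."""
    interior = max(n_rows - 2, 0) * max(n_cols - 2, 0)
    border = 2 * max(n_rows - 2, 0) + 2 * max(n_cols - 2, 0)
    return interior + border


def _edge_strip(node_a, node_b, rad):
    """Pixel-slice covering the thick edge between two lattice nodes."""
    (r1, c1), (r2, c2) = sorted([node_a, node_b])
    if r1 == r2:  # horizontal
        return slice(r1 - rad, r1 + rad + 1), slice(c1, c2 + 1)
    return slice(r1, r2 + 1), slice(c1 - rad, c1 + rad + 1)


def gen_vessel_fixture(params: VesselFixtureParams) -> VesselFixture:
    """Paired CD31/ColIV masks: ColIV is the full lattice; CD31 equals
    ColIV except on planted segments, erased per their stage."""
    rng = np.random.default_rng(params.seed)
    sp = params.spacing_px
    rad = params.radius_px
    margin = int(sp // 2)
    node_rc = lambda i, j: (int(round(margin + i * sp)), int(round(margin + j * sp)))
    height = 2 * margin + int(round((params.n_rows - 1) * sp)) + 1
    width = 2 * margin + int(round((params.n_cols - 1) * sp)) + 1

    edges = []
    for i in range(params.n_rows):
        for j in range(params.n_cols):
            if j + 1 < params.n_cols:
                edges.append(((i, j), (i, j + 1)))
            if i + 1 < params.n_rows:
                edges.append(((i, j), (i + 1, j)))

    # events are staged relative to the skeleton segment between two
    # branching points, so plant only edges whose endpoints both have
    # degree >= 3 (corner nodes are mere bends and would merge segments)
    corners = {(0, 0), (0, params.n_cols - 1), (params.n_rows - 1, 0),
               (params.n_rows - 1, params.n_cols - 1)}
    plantable = [e for e in edges if not (set(e) & corners)]

    coliv = np.zeros((height, width), dtype=np.uint8)
    for a, b in edges:
        rs, cs = _edge_strip(node_rc(*a), node_rc(*b), rad)
        coliv[rs, cs] = 1

    order = rng.permutation(len(plantable))
    planted = []
    used_nodes: set = set()
    for idx in order:
        a, b = plantable[idx]
        if a in used_nodes or b in used_nodes:
            continue
        planted.append((a, b))
        used_nodes.update((a, b))
        if len(planted) == len(params.stages):
            break
    if len(planted) < len(params.stages):
        raise ValueError("more planted segments than node-disjoint edges available")

    cd31 = coliv.copy()
    records = []
    for (a, b), stage in zip(planted, params.stages):
        (r1, c1), (r2, c2) = node_rc(*a), node_rc(*b)
        horizontal = r1 == r2
        if horizontal:
            lo, hi = sorted((c1, c2))
            span = (lo + rad + 1, hi - rad - 1)  # interior, node blobs kept
        else:
            lo, hi = sorted((r1, r2))
            span = (lo + rad + 1, hi - rad - 1)
        if stage == "intermediate":
            mid = (span[0] + span[1]) / 2
            half = (span[1] - span[0] + 1) / 4
            span = (int(np.floor(mid - half)), int(np.ceil(mid + half)))
        if horizontal:
            cd31[r1 - rad:r1 + rad + 1, span[0]:span[1] + 1] = 0
            cent = (r1, (span[0] + span[1]) / 2)
        else:
            cd31[span[0]:span[1] + 1, c1 - rad:c1 + rad + 1] = 0
            cent = ((span[0] + span[1]) / 2, c1)
        records.append({"event": len(records), "stage": stage,
                        "row": cent[0], "col": cent[1]})

    truth = pd.DataFrame(records, columns=["event", "stage", "row", "col"])
    psz = params.pixel_size
    return VesselFixture(
        cd31=ImageStack(cd31, psz, "cd31", "mask"),
        coliv=ImageStack(coliv, psz, "coliv", "mask"),
        truth=truth,
        n_branch_points=lattice_branch_point_count(params.n_rows, params.n_cols),
    )
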