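"""Seeded synthetic-data generators with attached ground truth.

Every pipeline stage in this package (traction-force computation,
focal-adhesion detection, track statistics, colocalization, differential
proteomics) can be exercised on data produced here, where the true pillar
displacements, focus geometry, drift, co-occupancy or planted fold changes
are known exactly.  All generators are pure functions of their seed: the
same scene rendered twice is bit-identical.

Coordinate convention: images are (row, col) rasters; physical coordinates
are ``x = col * pixel_size`` and ``y = row * pixel_size`` in micrometres,
0-based at the top-left pixel centre.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as draw_polygon

__all__ = [
    "PillarScene",
    "FaScene",
    "WalkModel",
    "OmicsDesign",
    "make_pillar_image",
    "make_contractile_scene",
    "make_fa_image",
    "simulate_tracks",
    "simulate_omics",
    "make_cooccupancy_pair",
    "write_table",
    "read_table",
    "write_tiff",
    "read_tiff",
    "write_scene_yaml",
]


# ---------------------------------------------------------------------------
# scene descriptions


@dataclass(frozen=True)
class PillarScene:
    """A micropillar array scene: regular lattice of fluorescent pillar tops.

    Geometry defaults follow the PDMS arrays used for VSMC traction
    measurements: 1 µm centre-to-centre pitch, 0.5 µm pillar diameter.
    ``displacements`` maps integer lattice indices (i, j) to an imposed tip
    displacement vector in µm; pillars outside ``cell_mask`` are reference
    pillars and must stay undisplaced.
    """

    lattice_pitch: float = 1.0          # µm, centre-to-centre
    pillar_diameter: float = 0.5        # µm (sets the rendered spot scale)
    image_shape: tuple[int, int] = (400, 400)
    pixel_size: float = 0.1             # µm / pixel
    psf_sigma: float = 0.15             # µm, Gaussian spot sd
    spot_amplitude: float = 1000.0      # AU above background
    background: float = 100.0           # AU
    noise_sd: float = 70.0              # AU, additive Gaussian, clipped at 0
    rotation_deg: float = 0.0
    displacements: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )
    cell_mask: np.ndarray | None = None  # bool raster, image_shape
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lattice_pitch > self.pillar_diameter > 0):
            raise ValueError("require pitch > diameter > 0")
        for ij, (dx, dy) in self.displacements.items():
            if float(np.hypot(dx, dy)) >= self.lattice_pitch / 2:
                raise ValueError(
                    f"displacement at node {ij} exceeds pitch/2: nearest-node "
                    "assignment would be ambiguous"
                )


@dataclass(frozen=True)
class FaScene:
    """A TIRF-like focal-adhesion scene: one cell with vinculin foci.

    ``foci_specs`` is a list of (centroid_xy_um, area_um2, peak_au) tuples;
    foci are rendered as uniform disks so that planted areas and centroids
    are recovered up to pixel quantization.  All centroids must fall inside
    ``cell_polygon``.
    """

    cell_polygon: tuple[tuple[float, float], ...]  # (x, y) µm vertices
    foci_specs: tuple[tuple[tuple[float, float], float, float], ...] = ()
    image_shape: tuple[int, int] = (300, 300)
    pixel_size: float = 0.1
    background_level: float = 500.0     # AU, all channels
    membrane_channel_level: float = 5000.0  # AU above background inside cell
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (cx, cy), area, peak in self.foci_specs:
            if area <= 0:
                raise ValueError("focus area must be positive")
            if peak < 0:
                raise ValueError("focus intensity must be non-negative")
            if not _point_in_polygon(cx, cy, self.cell_polygon):
                raise ValueError(f"focus centroid ({cx}, {cy}) outside cell polygon")


@dataclass(frozen=True)
class WalkModel:
    """Biased persistent random walk for cell migration/invasion tracks.

    Update rule: ``x_{t+1} = x_t + persistence*(x_t - x_{t-1}) + drift + noise``
    with isotropic Gaussian ``noise`` of sd ``step_sd`` per axis.  The
    chemoattractant gradient axis is +y ("vertical"), so ``drift=(0, d)``
    with d > 0 models chemotaxis toward the gradient.
    """

    n_tracks: int = 100
    n_steps: int = 72
    dt: float = 600.0        # s between frames (10 min, matching invasion assays)
    step_sd: float = 0.5     # µm per axis per step
    drift: tuple[float, float] = (0.0, 0.0)  # µm per step
    persistence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if not (0 <= self.persistence < 1):
            raise ValueError("persistence must lie in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class OmicsDesign:
    """Two-group protein-abundance design with planted differential proteins.

    Abundances are log-normal: per-protein baseline log2 level drawn uniform
    in [10, 20], replicate scatter of sd ``dispersion`` on the log2 scale
    (~18% CV at the default 0.25).  Proteins in ``planted_de`` are shifted by
    log2(fold change) in group B.
    """

    n_proteins: int = 500
    n_replicates: int = 4
    planted_de: tuple[tuple[str, float], ...] = ()
    dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        for pid, fc in self.planted_de:
            if fc <= 0:
                raise ValueError(f"planted fold change for {pid} must be > 0")


# ---------------------------------------------------------------------------
# pillar scenes


def _lattice_nodes(scene: PillarScene) -> tuple[np.ndarray, np.ndarray]:
    """Integer indices and ideal positions (µm) of all lattice nodes in frame."""
    h, w = scene.image_shape
    fov_x = w * scene.pixel_size
    fov_y = h * scene.pixel_size
    th = np.deg2rad(scene.rotation_deg)
    b1 = scene.lattice_pitch * np.array([np.cos(th), np.sin(th)])
    b2 = scene.lattice_pitch * np.array([-np.sin(th), np.cos(th)])
    origin = np.array([scene.lattice_pitch, scene.lattice_pitch])
    nmax = int(max(fov_x, fov_y) / scene.lattice_pitch) + 2
    ii, jj = np.meshgrid(np.arange(nmax), np.arange(nmax), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel()], axis=1)
    pos = origin + idx @ np.stack([b1, b2])
    margin = 2 * scene.psf_sigma
    keep = (
        (pos[:, 0] > margin)
        & (pos[:, 0] < fov_x - margin)
        & (pos[:, 1] > margin)
        & (pos[:, 1] < fov_y - margin)
    )
    return idx[keep], pos[keep]


def _render_gaussian_spots(
    shape: tuple[int, int],
    centers_um: np.ndarray,
    sigma_um: float,
    amplitude: float,
    pixel_size: float,
) -> np.ndarray:
    """Sum of analytic isotropic Gaussians sampled at pixel centres."""
    img = np.zeros(shape, dtype=np.float64)
    sig_px = sigma_um / pixel_size
    halfwin = max(3, int(np.ceil(5 * sig_px)))
    for cx, cy in centers_um:
        px, py = cx / pixel_size, cy / pixel_size
        r0 = max(0, int(np.floor(py)) - halfwin)
        r1 = min(shape[0], int(np.ceil(py)) + halfwin + 1)
        c0 = max(0, int(np.floor(px)) - halfwin)
        c1 = min(shape[1], int(np.ceil(px)) + halfwin + 1)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((cols - px) ** 2 + (rows - py) ** 2) / (2 * sig_px**2)
        )
    return img


def make_pillar_image(scene: PillarScene) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a pillar-array image and its ground-truth table.

    Returns ``(image, truth)`` where ``truth`` has one row per pillar with
    columns ``node_i, node_j, x_ideal, y_ideal, dx_true, dy_true, x_true,
    y_true, inside_cell``.  Displaced positions are ideal node + imposed
    displacement; reference pillars (outside the cell mask) are verified to
    carry zero displacement.
    """
    idx, ideal = _lattice_nodes(scene)
    node_key = {tuple(ij): k for k, ij in enumerate(idx)}

    disp = np.zeros_like(ideal)
    inside = np.zeros(len(ideal), dtype=bool)
    if scene.cell_mask is not None:
        px = np.clip(
            np.round(ideal / scene.pixel_size).astype(int),
            0,
            [scene.image_shape[1] - 1, scene.image_shape[0] - 1],
        )
        inside = scene.cell_mask[px[:, 1], px[:, 0]].astype(bool)
    for ij, (dx, dy) in scene.displacements.items():
        k = node_key.get(tuple(ij))
        if k is None:
            raise ValueError(f"displaced node {ij} not inside the field of view")
        if not inside[k]:
            raise ValueError(
                f"node {ij} lies outside the cell mask: reference pillars must "
                "stay undisplaced"
            )
        disp[k] = (dx, dy)

    true_pos = ideal + disp
    img = scene.background + _render_gaussian_spots(
        scene.image_shape, true_pos, scene.psf_sigma,
        scene.spot_amplitude, scene.pixel_size,
    )
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = pd.DataFrame(
        {
            "node_i": idx[:, 0],
            "node_j": idx[:, 1],
            "x_ideal": ideal[:, 0],
            "y_ideal": ideal[:, 1],
            "dx_true": disp[:, 0],
            "dy_true": disp[:, 1],
            "x_true": true_pos[:, 0],
            "y_true": true_pos[:, 1],
            "inside_cell": inside,
        }
    )
    return img, truth


def make_contractile_scene(
    seed: int,
    *,
    cell_radius_um: float = 12.0,
    displacement_range_um: tuple[float, float] = (0.03, 0.15),
    noise_sd: float = 70.0,
    centripetal: bool = True,
    **scene_kwargs,
) -> PillarScene:
    """Build a scene with a disk-shaped cell pulling on every pillar under it.

    Displacement magnitudes are drawn uniformly from ``displacement_range_um``
    (default 30–150 nm, above the ~20 nm measurement floor); directions point
    toward the cell centre when ``centripetal`` (as contracting cells pull),
    otherwise uniformly at random.
    """
    base = PillarScene(seed=seed, noise_sd=noise_sd, **scene_kwargs)
    h, w = base.image_shape
    cy_um = h * base.pixel_size / 2
    cx_um = w * base.pixel_size / 2
    rows, cols = np.mgrid[0:h, 0:w]
    rr = np.hypot(cols * base.pixel_size - cx_um, rows * base.pixel_size - cy_um)
    mask = rr <= cell_radius_um

    with_mask = replace(base, cell_mask=mask)
    idx, ideal = _lattice_nodes(with_mask)
    # displace exactly the pillars the renderer flags as inside the cell
    px = np.clip(
        np.round(ideal / base.pixel_size).astype(int), 0, [w - 1, h - 1]
    )
    inside = mask[px[:, 1], px[:, 0]]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15F]))
    lo, hi = displacement_range_um
    disp: dict[tuple[int, int], tuple[float, float]] = {}
    for ij, pos in zip(idx[inside], ideal[inside]):
        mag = rng.uniform(lo, hi)
        if centripetal:
            v = np.array([cx_um, cy_um]) - pos
            n = np.linalg.norm(v)
            ang = np.arctan2(v[1], v[0]) if n > 0 else rng.uniform(0, 2 * np.pi)
        else:
            ang = rng.uniform(0, 2 * np.pi)
        disp[tuple(ij)] = (mag * np.cos(ang), mag * np.sin(ang))
    return replace(with_mask, displacements=disp)


# ---------------------------------------------------------------------------
# focal-adhesion scenes


def _point_in_polygon(x: float, y: float, poly) -> bool:
    # even-odd ray casting; boundary points count as inside
    pts = np.asarray(poly, dtype=float)
    n = len(pts)
    inside = False
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
            elif np.isclose(x, xint):
                return True
    return inside


def _polygon_mask(scene: FaScene) -> np.ndarray:
    poly = np.asarray(scene.cell_polygon) / scene.pixel_size
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=scene.image_shape)
    mask = np.zeros(scene.image_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def make_fa_image(scene: FaScene) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-channel (nucleus, vinculin, membrane) FA scene.

    The membrane channel fills the cell polygon at
    ``membrane_channel_level`` over background; vinculin foci are uniform
    disks of the requested area and peak intensity; the nucleus channel is a
    Gaussian blob at the polygon centroid.  The ground-truth table carries a
    ``sub_minimum`` flag for foci below the canonical 0.5 µm² detection
    cutoff, so size-filter behaviour can be asserted.
    """
    h, w = scene.image_shape
    mask = _polygon_mask(scene)

    membrane = np.full((h, w), scene.background_level)
    membrane[mask] += scene.membrane_channel_level

    vinculin = np.full((h, w), scene.background_level)
    rows, cols = np.mgrid[0:h, 0:w]
    records = []
    for k, ((cx, cy), area, peak) in enumerate(scene.foci_specs):
        radius = np.sqrt(area / np.pi)
        dist = np.hypot(
            cols * scene.pixel_size - cx, rows * scene.pixel_size - cy
        )
        disk = dist <= radius
        vinculin[disk] = np.maximum(vinculin[disk], peak)
        records.append(
            {
                "focus_id": k,
                "x_um": cx,
                "y_um": cy,
                "area_um2": area,
                "peak_au": peak,
                "sub_minimum": area < 0.5,
            }
        )

    poly = np.asarray(scene.cell_polygon)
    ncx, ncy = poly.mean(axis=0)
    nucleus = np.full((h, w), scene.background_level) + _render_gaussian_spots(
        (h, w), np.array([[ncx, ncy]]), 2.0, 8000.0, scene.pixel_size
    )

    stack = np.stack([nucleus, vinculin, membrane]).astype(np.float64)
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        stack = np.clip(stack + rng.normal(0, scene.noise_sd, stack.shape), 0, None)
    truth = pd.DataFrame.from_records(
        records,
        columns=["focus_id", "x_um", "y_um", "area_um2", "peak_au", "sub_minimum"],
    )
    return stack, truth


# ---------------------------------------------------------------------------
# migration tracks


def simulate_tracks(model: WalkModel) -> pd.DataFrame:
    """Simulate a cohort of biased persistent random walks.

    Returns a long-format table with columns
    ``track_id, frame, t, x, y`` — the same layout the track-statistics
    module consumes.
    """
    rng = np.random.default_rng(model.seed)
    n, m = model.n_tracks, model.n_steps
    drift = np.asarray(model.drift)
    pos = np.zeros((n, m + 1, 2))
    prev_step = np.zeros((n, 2))
    for t in range(m):
        noise = (
            rng.normal(0.0, model.step_sd, size=(n, 2))
            if model.step_sd > 0
            else np.zeros((n, 2))
        )
        step = model.persistence * prev_step + drift + noise
        pos[:, t + 1] = pos[:, t] + step
        prev_step = step

    frames = np.tile(np.arange(m + 1), n)
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), m + 1),
            "frame": frames,
            "t": frames * model.dt,
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
        }
    )


# ---------------------------------------------------------------------------
# proteomics tables


def simulate_omics(design: OmicsDesign) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a two-group abundance table with planted differential proteins.

    Returns ``(table, groups, truth)``: a linear-scale abundance matrix
    (proteins × samples), a sample→group Series with levels ``A``/``B``, and
    a truth table listing each planted protein with its true fold change
    (group B over group A).
    """
    rng = np.random.default_rng(design.seed)
    ids = [f"P{k:05d}" for k in range(design.n_proteins)]
    planted = dict(design.planted_de)
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValueError(f"planted ids not in table: {sorted(unknown)}")

    base = rng.uniform(10.0, 20.0, size=design.n_proteins)
    nrep = design.n_replicates
    log2 = np.empty((design.n_proteins, 2 * nrep))
    log2[:, :nrep] = base[:, None]
    shift = np.array([np.log2(planted.get(pid, 1.0)) for pid in ids])
    log2[:, nrep:] = (base + shift)[:, None]
    log2 += rng.normal(0.0, design.dispersion, size=log2.shape)

    samples = [f"A{r+1}" for r in range(nrep)] + [f"B{r+1}" for r in range(nrep)]
    table = pd.DataFrame(2.0**log2, index=pd.Index(ids, name="protein"), columns=samples)
    groups = pd.Series(["A"] * nrep + ["B"] * nrep, index=samples, name="group")
    truth = pd.DataFrame(
        {"protein": list(planted), "true_fc": [planted[p] for p in planted]}
    )
    return table, groups, truth


# ---------------------------------------------------------------------------
# two-channel co-occupancy pairs (colocalization fixtures)


def make_cooccupancy_pair(
    fraction: float,
    *,
    shape: tuple[int, int] = (200, 200),
    occupancy: float = 0.3,
    level: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two binary-intensity channels with a planted co-occupancy fraction.

    Channel 1 occupies a random ``occupancy`` fraction of pixels at a uniform
    intensity; a fraction ``fraction`` of those pixels also carry channel-2
    signal, plus an equal-sized disjoint channel-2-only population.  The
    thresholded Manders coefficient tM1 of the pair converges to ``fraction``
    as the image grows.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    npx = shape[0] * shape[1]
    n1 = int(round(occupancy * npx))
    perm = rng.permutation(npx)
    ch1_idx = perm[:n1]
    n_co = int(round(fraction * n1))
    co_idx = ch1_idx[:n_co]
    only2_idx = perm[n1 : n1 + n_co]

    ch1 = np.zeros(npx)
    ch2 = np.zeros(npx)
    ch1[ch1_idx] = level
    ch2[co_idx] = level
    ch2[only2_idx] = level
    return ch1.reshape(shape), ch2.reshape(shape)


# ---------------------------------------------------------------------------
# writers / readers (lossless round-trip for ground-truth tables)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with round-trippable float formatting."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tiff(path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write a single- or multi-channel raster with pixel-size metadata."""
    import tifffile

    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={"unit": "um", "pixel_size_um": pixel_size_um},
    )


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_scene_yaml(scene, path) -> None:
    """Serialize a scene description (not its rasters) to YAML."""
    d = {}
    for key, val in vars(scene).items():
        if isinstance(val, np.ndarray):
            continue
        if isinstance(val, dict):
            val = {str(k): list(map(float, v)) for k, v in val.items()}
        if isinstance(val, tuple):
            val = _to_plain(val)
        d[key] = val
    with io.open(path, "w") as fh:
        yaml.safe_dump({"kind": type(scene).__name__, "params": d}, fh)


def _to_plain(obj):
    if isinstance(obj, tuple):
        return [_to_plain(o) for o in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
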