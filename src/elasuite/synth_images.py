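"""Synthetic fluorescence microscopy scenes with exact ground truth.

Renders the image types quantified downstream: rod-shaped (spherocylinder)
bacteria with cytoplasmic and membrane fluorescence and planted
diffraction-limited spots; two-channel scenes with a controlled
colocalization fraction; and giant unilamellar vesicle (GUV) ring images.
Every renderer returns the noisy image together with a truth object
(masks, per-cell means, spot positions, expected Pearson correlation,
GUV center/radius/profile), making the generator the oracle for the
quantification modules.

Defaults emulate Airyscan-like sampling: 0.05 um/px, coryneform rod
dimensions (length 1.5-3 um, width 0.6-0.9 um), isotropic Gaussian PSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

DEFAULT_PIXEL_SIZE = 0.05  # um / px


@dataclass(frozen=True)
class Spot:
    dlong: float   # um along the cell major axis, from the centroid
    dtrans: float  # um across the axis
    amplitude: float
    sigma: float = 0.08  # um


@dataclass(frozen=True)
class Cell:
    center: tuple[float, float]  # (x, y) in um
    angle: float                 # radians, major axis vs x-axis
    length: float                # um, tip to tip
    width: float                 # um
    cyt_intensity: float
    mem_intensity: float = 0.0   # 0 => uniform cytoplasmic signal
    spots: tuple[Spot, ...] = ()


@dataclass
class CellScene:
    shape: tuple[int, int] = (256, 256)  # (ny, nx) px
    pixel_size: float = DEFAULT_PIXEL_SIZE
    cells: tuple[Cell, ...] = ()
    background: float = 10.0
    psf_sigma: float = 0.07   # um
    gaussian_noise: float = 0.0
    poisson: bool = False
    membrane_thickness: float = 0.1  # um
    seed: int = 0


@dataclass
class CellTruth:
    label_image: np.ndarray
    centers_px: list[tuple[float, float]]      # (x, y)
    angles: list[float]
    lengths_um: list[float]
    widths_um: list[float]
    mean_intensities: list[float]              # background-subtracted, in-mask
    spot_counts: list[int]
    spot_positions_px: list[list[tuple[float, float]]]  # (x, y) per cell
    background: float = 0.0
    expected_pcc: float | None = None
    expected_pcc_per_cell: list[float] | None = None


def _cell_geometry(scene: CellScene, cell: Cell):
    px = scene.pixel_size
    ny, nx = scene.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = (xx + 0.5) * px
    y_um = (yy + 0.5) * px
    cx, cy = cell.center
    ux, uy = np.cos(cell.angle), np.sin(cell.angle)
    dx, dy = x_um - cx, y_um - cy
    dlong = dx * ux + dy * uy
    dtrans = -dx * uy + dy * ux
    half = max(cell.length - cell.width, 0.0) / 2.0  # centreline half-length
    t = np.clip(dlong, -half, half)
    dist = np.hypot(dlong - t, dtrans)
    return dlong, dtrans, dist


def render_cells(scene: CellScene) -> tuple[np.ndarray, CellTruth]:
    """Rasterize a cell scene; returns (noisy image, truth).

    Pre-noise intensities are blurred with the scene PSF before noise is
    applied; truth means are measured on the pre-noise image so downstream
    closure tests see planted values, not noise realizations.
    """
    rng = np.random.default_rng(scene.seed)
    ny, nx = scene.shape
    px = scene.pixel_size
    ideal = np.full((ny, nx), float(scene.background))
    labels = np.zeros((ny, nx), dtype=np.int32)
    centers, angles, lengths, widths = [], [], [], []
    spot_positions: list[list[tuple[float, float]]] = []

    for i, cell in enumerate(scene.cells, start=1):
        if not cell.length > cell.width > 0:
            raise ValueError(f"cell {i}: need length > width > 0")
        _, _, dist = _cell_geometry(scene, cell)
        mask = dist <= cell.width / 2.0
        if np.any(labels[mask] != 0):
            raise ValueError(f"cell {i} overlaps a previously placed cell")
        labels[mask] = i
        if cell.mem_intensity > 0:
            shell = mask & (dist > cell.width / 2.0 - scene.membrane_thickness)
            ideal[mask & ~shell] += cell.cyt_intensity
            ideal[shell] += cell.mem_intensity
        else:
            ideal[mask] += cell.cyt_intensity
        ux, uy = np.cos(cell.angle), np.sin(cell.angle)
        pos_px: list[tuple[float, float]] = []
        for spot in cell.spots:
            sx = cell.center[0] + spot.dlong * ux - spot.dtrans * uy
            sy = cell.center[1] + spot.dlong * uy + spot.dtrans * ux
            sx_px, sy_px = sx / px - 0.5, sy / px - 0.5
            yy, xx = np.mgrid[0:ny, 0:nx]
            g = spot.amplitude * np.exp(
                -(((xx - sx_px) ** 2 + (yy - sy_px) ** 2) * px ** 2)
                / (2.0 * spot.sigma ** 2))
            ideal += g
            pos_px.append((sx_px, sy_px))
        centers.append((cell.center[0] / px - 0.5, cell.center[1] / px - 0.5))
        angles.append(cell.angle)
        lengths.append(cell.length)
        widths.append(cell.width)
        spot_positions.append(pos_px)

    if scene.psf_sigma > 0:
        ideal = gaussian_filter(ideal, sigma=scene.psf_sigma / px)

    means = []
    for i in range(1, len(scene.cells) + 1):
        m = labels == i
        means.append(float(ideal[m].mean() - scene.background) if m.any() else 0.0)

    image = ideal.copy()
    if scene.poisson:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if scene.gaussian_noise > 0:
        image = image + rng.normal(0.0, scene.gaussian_noise, size=image.shape)

    truth = CellTruth(
        label_image=labels,
        centers_px=centers,
        angles=angles,
        lengths_um=lengths,
        widths_um=widths,
        mean_intensities=means,
        spot_counts=[len(c.spots) for c in scene.cells],
        spot_positions_px=spot_positions,
        background=scene.background,
    )
    return image, truth


def random_rod_scene(
    n_cells: int,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    cyt_intensity: float = 100.0,
    spots_per_cell: int = 0,
    spot_amplitude_factor: float = 5.0,
    polar_fraction: float = 0.0,
    gaussian_noise: float = 2.0,
    poisson: bool = True,
    psf_sigma: float = 0.07,
) -> CellScene:
    """Scatter non-overlapping random rods; spots optionally polar-biased.

    With ``polar_fraction`` p, each spot lands within the outer 20% of the
    half-length with probability p, else uniformly in the inner region.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    px = DEFAULT_PIXEL_SIZE
    cells: list[Cell] = []
    attempts = 0
    placed_boxes: list[tuple[float, float, float]] = []  # x, y, radius
    while len(cells) < n_cells and attempts < 2000:
        attempts += 1
        length = rng.uniform(1.5, 3.0)
        width = rng.uniform(0.6, 0.9)
        margin = length / 2 + 0.3
        cx = rng.uniform(margin, nx * px - margin)
        cy = rng.uniform(margin, ny * px - margin)
        if any(np.hypot(cx - x0, cy - y0) < r0 + length / 2 + 0.25
               for x0, y0, r0 in placed_boxes):
            continue
        angle = rng.uniform(0, np.pi)
        spots = []
        for _ in range(spots_per_cell):
            half = (length - width) / 2
            if rng.uniform() < polar_fraction:
                frac = rng.uniform(0.8, 1.0)
            else:
                frac = rng.uniform(0.0, 0.8)
            dlong = frac * half * rng.choice([-1.0, 1.0])
            dtrans = rng.uniform(-0.25, 0.25) * width / 2
            spots.append(Spot(dlong, dtrans,
                              amplitude=spot_amplitude_factor * cyt_intensity))
        cells.append(Cell((cx, cy), angle, length, width, cyt_intensity,
                          spots=tuple(spots)))
        placed_boxes.append((cx, cy, length / 2))
    if len(cells) < n_cells:
        raise RuntimeError("could not place all cells without overlap")
    return CellScene(shape=shape, cells=tuple(cells), seed=seed,
                     gaussian_noise=gaussian_noise, poisson=poisson,
                     psf_sigma=psf_sigma)


def render_two_channel(scene: CellScene, coloc: float
                       ) -> tuple[np.ndarray, np.ndarray, CellTruth]:
    """Render channel A plus a channel B sharing a ``coloc`` fraction of A's
    structure.

    Channel B's pre-noise structure is ``coloc * A_structure +
    (1 - coloc) * independent`` where the independent component is a
    PSF-smoothed random field confined to the cell masks with matched
    standard deviation.  The truth records the Pearson correlation of the
    two pre-noise images over the cell masks (global and per cell) — the
    planted, noise-free expectation.
    """
    if not 0.0 <= coloc <= 1.0:
        raise ValueError("coloc must be in [0, 1]")
    rng = np.random.default_rng(scene.seed + 7919)
    image_a, truth = render_cells(scene)
    # rebuild the pre-noise channel A structure
    noiseless = CellScene(**{**scene.__dict__, "gaussian_noise": 0.0, "poisson": False})
    ideal_a, _ = render_cells(noiseless)
    struct_a = ideal_a - scene.background

    mask = truth.label_image > 0
    field_ = rng.normal(0.0, 1.0, size=scene.shape)
    field_ = gaussian_filter(field_, sigma=max(scene.psf_sigma, 0.05) / scene.pixel_size)
    field_ *= mask
    sd_a = struct_a[mask].std()
    sd_f = field_[mask].std()
    indep = field_ * (sd_a / sd_f if sd_f > 0 else 0.0)
    indep = indep - indep[mask].min()  # keep photon counts non-negative

    ideal_b = scene.background + coloc * struct_a + (1.0 - coloc) * indep
    image_b = ideal_b.copy()
    if scene.poisson:
        image_b = rng.poisson(np.clip(image_b, 0, None)).astype(float)
    if scene.gaussian_noise > 0:
        image_b = image_b + rng.normal(0.0, scene.gaussian_noise, size=image_b.shape)

    def _pcc(a, b, m):
        if a[m].std() == 0 or b[m].std() == 0:
            return float("nan")
        return float(np.corrcoef(a[m], b[m])[0, 1])

    truth.expected_pcc = _pcc(ideal_a, ideal_b, mask)
    truth.expected_pcc_per_cell = [
        _pcc(ideal_a, ideal_b, truth.label_image == i)
        for i in range(1, len(scene.cells) + 1)]
    return image_a, image_b, truth


# ---------------------------------------------------------------------------
# GUV scenes

@dataclass(frozen=True)
class GUV:
    center: tuple[float, float]  # (x, y) um
    radius: float                # um
    membrane_intensity: float
    interior_intensity: float
    exterior_intensity: float
    ring_thickness: float = 0.3  # um


@dataclass
class GUVScene:
    shape: tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    guvs: tuple[GUV, ...] = ()
    psf_sigma: float = 0.07
    gaussian_noise: float = 0.0
    poisson: bool = False
    seed: int = 0


@dataclass
class GUVTruth:
    centers_px: list[tuple[float, float]]
    radii_px: list[float]
    radii_um: list[float]
    ideal_profiles: list[np.ndarray]  # 101 points, -50..+50 px, pre-noise


def render_guv(scene: GUVScene) -> tuple[np.ndarray, GUVTruth]:
    """Render annular GUV membranes with distinct interior/exterior levels.

    The truth profile is sampled from the pre-noise blurred image exactly as
    the downstream radial-profile measurement does (ray averages at integer
    pixel offsets from the true radius), before normalization.
    """
    rng = np.random.default_rng(scene.seed)
    ny, nx = scene.shape
    px = scene.pixel_size
    ideal = np.zeros((ny, nx))
    occupied = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = (xx + 0.5) * px
    y_um = (yy + 0.5) * px
    exterior = scene.guvs[0].exterior_intensity if scene.guvs else 0.0
    ideal += exterior
    centers, radii_px, radii_um = [], [], []
    for g in scene.guvs:
        if not g.radius > g.ring_thickness > 0:
            raise ValueError("need radius > ring thickness > 0")
        r_img = np.hypot(x_um - g.center[0], y_um - g.center[1])
        # the annulus is centered on the nominal radius (membrane midline)
        outer = r_img <= g.radius + g.ring_thickness / 2
        if np.any(occupied & outer):
            raise ValueError("GUVs overlap")
        occupied |= outer
        ring = outer & (r_img > g.radius - g.ring_thickness / 2)
        ideal[outer & ~ring] = g.interior_intensity
        ideal[ring] = g.membrane_intensity
        centers.append((g.center[0] / px - 0.5, g.center[1] / px - 0.5))
        radii_px.append(g.radius / px)
        radii_um.append(g.radius)

    if scene.psf_sigma > 0:
        ideal = gaussian_filter(ideal, sigma=scene.psf_sigma / px)

    from .coloc_guv import sample_radial_profile  # shared sampler (oracle closure)
    profiles = [sample_radial_profile(ideal, c, r, normalize=False)
                for c, r in zip(centers, radii_px)]

    image = ideal.copy()
    if scene.poisson:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if scene.gaussian_noise > 0:
        image = image + rng.normal(0.0, scene.gaussian_noise, size=image.shape)
    return image, GUVTruth(centers, radii_px, radii_um, profiles)
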