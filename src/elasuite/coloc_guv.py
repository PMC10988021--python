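"""Colocalization and GUV membrane analysis.

Per-cell Pearson correlation between two registered fluorescence channels,
circle fitting of giant unilamellar vesicle (GUV) membranes, membrane-
centered radial intensity profiles (101 points, -50..+50 px, negative
offsets toward the vesicle interior, each profile normalized to its own
maximum), and GUV diameter tables with a two-group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import sobel, threshold_otsu

from .assays_stats import StatResult, ttest

N_RAYS = 720  # profile rays; bilinear interpolation along each


def pcc(image_a: np.ndarray, image_b: np.ndarray, mask: np.ndarray
        ) -> tuple[pd.DataFrame, list[int]]:
    """Pearson correlation per cell over in-mask pixels.

    Returns the per-cell table and the ids of cells excluded for zero
    variance in either channel.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    rows, excluded = [], []
    for cid in np.unique(mask[mask > 0]):
        sel = mask == cid
        va, vb = a[sel], b[sel]
        if va.std() == 0 or vb.std() == 0:
            excluded.append(int(cid))
            continue
        rows.append({"cell_id": int(cid), "pcc": float(np.corrcoef(va, vb)[0, 1])})
    return pd.DataFrame(rows, columns=["cell_id", "pcc"]), excluded


# ---------------------------------------------------------------------------
# GUV ring fitting and radial profiles

def _kasa_circle_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit."""
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(c + cx ** 2 + cy ** 2))
    return float(cx), float(cy), r


def _ring_mean(image: np.ndarray, cx: float, cy: float, r: float) -> float:
    theta = np.linspace(0, 2 * np.pi, N_RAYS, endpoint=False)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return float(ndi.map_coordinates(image, [ys, xs], order=1, mode="nearest").mean())


def fit_guv(image: np.ndarray) -> tuple[tuple[float, float], float]:
    """Detect and fit the GUV membrane ring.

    Thresholded edge map -> algebraic circle fit, refined by maximizing the
    mean interpolated intensity on the fitted circle over a local grid of
    center and radius perturbations.  Deterministic.  Raises when no ring
    is found (blank or structureless image).
    """
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        raise ValueError("no ring found: image has no structure")
    edges = sobel(image)
    thr = threshold_otsu(edges)
    ys, xs = np.nonzero(edges > thr)
    if len(xs) < 20:
        raise ValueError("no ring found: too few edge pixels")
    cx, cy, r = _kasa_circle_fit(xs.astype(float), ys.astype(float))
    if not np.isfinite(r) or r < 3:
        raise ValueError("no ring found: degenerate circle fit")
    # refinement: climb the ring-mean objective on successively finer grids
    best = (_ring_mean(image, cx, cy, r), cx, cy, r)
    for step in (2.0, 1.0, 0.5, 0.25):
        improved = True
        while improved:
            improved = False
            _, cx, cy, r = best
            for dcx in (-step, 0.0, step):
                for dcy in (-step, 0.0, step):
                    for dr in (-step, 0.0, step):
                        if dcx == dcy == dr == 0.0:
                            continue
                        cand_r = r + dr
                        if cand_r <= 2:
                            continue
                        s = _ring_mean(image, cx + dcx, cy + dcy, cand_r)
                        if s > best[0] + 1e-9:
                            best = (s, cx + dcx, cy + dcy, cand_r)
                            improved = True
    _, cx, cy, r = best
    return (cx, cy), r


def sample_radial_profile(image: np.ndarray, center: tuple[float, float],
                          radius: float, normalize: bool = True,
                          n_rays: int = N_RAYS) -> np.ndarray:
    """Mean intensity at integer pixel offsets -50..+50 from the radius.

    Offsets below ``-radius`` are clipped at the center.  Bilinear
    interpolation along ``n_rays`` equally spaced rays.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = center
    theta = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    offsets = np.arange(-50, 51)
    profile = np.empty(101)
    for k, off in enumerate(offsets):
        rr = max(radius + off, 0.0)
        xs = cx + rr * cos_t
        ys = cy + rr * sin_t
        profile[k] = ndi.map_coordinates(image, [ys, xs], order=1,
                                         mode="nearest").mean()
    if normalize:
        m = profile.max()
        if m > 0:
            profile = profile / m
    return profile


@dataclass
class GUVProfile:
    guv_id: int
    center: tuple[float, float]  # px
    radius_px: float
    radius_um: float
    profile: np.ndarray  # 101 values, -50..+50 px, normalized to own max

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


def radial_profile(image: np.ndarray, center: tuple[float, float],
                   radius: float, pixel_size: float, guv_id: int = 0
                   ) -> GUVProfile:
    """Membrane-centered 101-point radial profile, normalized to its own
    maximum (negative offsets = vesicle interior)."""
    prof = sample_radial_profile(image, center, radius, normalize=True)
    return GUVProfile(guv_id=guv_id, center=center, radius_px=radius,
                      radius_um=radius * pixel_size, profile=prof)


def analyze_guv(image: np.ndarray, pixel_size: float, guv_id: int = 0) -> GUVProfile:
    """Fit the ring then extract the radial profile."""
    center, radius = fit_guv(image)
    return radial_profile(image, center, radius, pixel_size, guv_id=guv_id)


def guv_diameters(treated: list[np.ndarray], control: list[np.ndarray],
                  pixel_size: float) -> tuple[pd.DataFrame, StatResult]:
    """Per-GUV diameters (um) for two groups plus the unpaired two-tailed
    t-test between them."""
    rows = []
    for group, images in (("treated", treated), ("control", control)):
        for i, img in enumerate(images):
            prof = analyze_guv(img, pixel_size, guv_id=i)
            rows.append({"group": group, "guv_id": i,
                         "diameter_um": prof.diameter_um})
    df = pd.DataFrame(rows)
    result = ttest(df.loc[df.group == "treated", "diameter_um"].to_numpy(),
                   df.loc[df.group == "control", "diameter_um"].to_numpy())
    return df, result


def profiles_to_frame(profiles: list[GUVProfile]) -> pd.DataFrame:
    """Long-format profile table: mean and individual values per offset."""
    offsets = np.arange(-50, 51)
    data = {"offset_px": offsets}
    for p in profiles:
        data[f"guv{p.guv_id}"] = p.profile
    df = pd.DataFrame(data)
    df["mean"] = df[[c for c in df.columns if c.startswith("guv")]].mean(axis=1)
    return df
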