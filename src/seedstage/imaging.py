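"""Seed cabinet-image analysis: segmentation, CIELAB color summaries, ellipsoid fits.

Seeds are photographed in a controlled light cabinet on a light plate, arranged
on a fixed 12 x 8 grid so that 96 seeds can be measured in one exposure.  This
module segments such an image into per-seed regions, converts pixel colors to
CIELAB (D65 illuminant, 2 degree observer, assuming standard sRGB input) and
summarises each seed by its mean color.  A least-squares ellipsoid fit is
provided as a standalone morphology utility for 3-D seed point clouds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure

__all__ = [
    "ImagingError",
    "GridAmbiguityError",
    "SeedImage",
    "SeedRegion",
    "SeedColorRecord",
    "EllipsoidFit",
    "srgb_to_cielab",
    "chroma_hue",
    "segment_seed_grid",
    "summarize_seed_color",
    "fit_ellipsoid",
    "color_records_to_frame",
]

logger = logging.getLogger(__name__)


class ImagingError(ValueError):
    """Invalid image-analysis input."""


class GridAmbiguityError(ImagingError):
    """Two segmented regions claim the same grid cell."""


@dataclass
class SeedImage:
    """An 8-bit RGB cabinet photograph with a known seed-grid layout."""

    pixels: np.ndarray
    grid_rows: int = 8
    grid_cols: int = 12
    background_reference: Optional[tuple] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImagingError("pixels must be an HxWx3 array")
        if px.min() < 0 or px.max() > 255:
            raise ImagingError("channel values must lie in [0, 255]")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ImagingError("grid dimensions must be positive")
        self.pixels = px.astype(np.uint8)

    @property
    def expected_seeds(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class SeedRegion:
    """Connected pixel region assigned to one grid cell.

    ``seed_id`` is the (row, col) cell index; ``centroid`` is (x, y) in pixel
    units; ``pixel_mask`` is an (N, 2) array of (row, col) coordinates.
    """

    seed_id: tuple
    pixel_mask: np.ndarray
    centroid: tuple
    area_px: int


@dataclass(frozen=True)
class SeedColorRecord:
    """Per-seed CIELAB summary: mean L*, a*, b* plus derived chroma and hue."""

    seed_id: tuple
    L_star: float
    a_star: float
    b_star: float
    C_ab: float
    h_ab: float


@dataclass
class EllipsoidFit:
    """Geometric ellipsoid recovered from an algebraic least-squares quadric fit."""

    center: np.ndarray
    semi_axes: np.ndarray  # sorted descending, all > 0
    orientation: np.ndarray  # 3x3 rotation, columns = principal directions
    rms_residual: float


# High-precision sRGB -> XYZ matrix (D65 primaries, 2 degree observer).  The
# reference white is the matrix applied to RGB (1,1,1), i.e. the row sums, so
# the chain is self-consistent: the white point maps exactly to L*=100,
# a*=b*=0 instead of picking up rounding residue from a separately tabulated
# white.
_SRGB_TO_XYZ = np.array(
    [
        [0.41239079926595934, 0.357584339383878, 0.1804807884018343],
        [0.21263900587151027, 0.715168678767756, 0.07219231536073371],
        [0.01933081871559182, 0.11919477979462598, 0.9505321522496607],
    ]
)
_WHITE_XYZ = _SRGB_TO_XYZ.sum(axis=1)


def _rgb01_to_lab(rgb01: np.ndarray) -> np.ndarray:
    """Vectorised sRGB (in [0,1], shape (..., 3)) -> CIELAB (D65/2deg)."""
    c = np.asarray(rgb01, dtype=float)
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_XYZ
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def srgb_to_cielab(rgb: Sequence[float]) -> tuple:
    """Convert one 8-bit sRGB triple to CIELAB (D65, 2 degree observer).

    Uses the standard chain sRGB -> linear RGB -> XYZ -> CIELAB.

    Parameters
    ----------
    rgb : sequence of 3 channel values in [0, 255].

    Returns
    -------
    (L_star, a_star, b_star)
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ImagingError("rgb must be a 3-channel triple")
    if arr.min() < 0 or arr.max() > 255:
        raise ImagingError(f"channel out of range [0, 255]: {rgb!r}")
    lab = _rgb01_to_lab(arr / 255.0)
    return float(lab[0]), float(lab[1]), float(lab[2])


def chroma_hue(a_star: float, b_star: float) -> tuple:
    """Chroma C*ab = sqrt(a*^2 + b*^2) and hue angle h_ab in degrees [0, 360).

    The hue of the achromatic origin (a* = b* = 0) is 0 by convention.
    """
    c = math.hypot(a_star, b_star)
    if c == 0.0:
        return 0.0, 0.0
    h = math.degrees(math.atan2(b_star, a_star)) % 360.0
    if h >= 360.0:  # fmod residue for tiny negative angles
        h = 0.0
    return c, h


def _lightness(image: SeedImage) -> np.ndarray:
    return _skcolor.rgb2gray(image.pixels / 255.0)


def segment_seed_grid(
    image: SeedImage,
    min_area_px: int = 30,
    threshold_mode="fixed",
    background_threshold: float = 0.75,
) -> list:
    """Segment dark seeds on a light background and assign them to grid cells.

    A global threshold on the lightness channel (fixed value by default, Otsu
    when ``threshold_mode='otsu'``) yields a foreground mask; 8-connected
    components above ``min_area_px`` become regions.  Each region is assigned
    the (row, col) cell of an evenly divided grid that contains its centroid.

    Returns regions sorted row-major by cell.  Raises
    :class:`GridAmbiguityError` if two region centroids fall in one cell.
    """
    gray = _lightness(image)
    if threshold_mode == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(gray) == 0:
            return []
        thr = float(threshold_otsu(gray))
    elif threshold_mode == "fixed":
        thr = float(background_threshold)
    else:
        raise ImagingError(f"unknown threshold_mode: {threshold_mode!r}")

    mask = gray < thr
    labels = _skmeasure.label(mask, connectivity=2)
    h, w = image.shape
    cell_h = h / image.grid_rows
    cell_w = w / image.grid_cols

    occupied: dict = {}
    regions = []
    for prop in _skmeasure.regionprops(labels):
        if prop.area < min_area_px:
            logger.warning(
                "dropping region of %d px (< min_area_px=%d) at %s",
                prop.area, min_area_px, prop.centroid,
            )
            continue
        cy, cx = prop.centroid  # row, col in pixel units
        row = min(int(cy // cell_h), image.grid_rows - 1)
        col = min(int(cx // cell_w), image.grid_cols - 1)
        cell = (row, col)
        if cell in occupied:
            raise GridAmbiguityError(
                f"two regions map to grid cell {cell}: centroids "
                f"{occupied[cell].centroid} and {(cx, cy)}"
            )
        region = SeedRegion(
            seed_id=cell,
            pixel_mask=prop.coords.copy(),
            centroid=(float(cx), float(cy)),
            area_px=int(prop.area),
        )
        occupied[cell] = region
        regions.append(region)

    regions.sort(key=lambda r: r.seed_id)
    logger.info("segmented %d regions (expected %d)", len(regions), image.expected_seeds)
    return regions


def summarize_seed_color(region: SeedRegion, image: SeedImage) -> SeedColorRecord:
    """Mean CIELAB color of one seed region.

    Each pixel is converted to CIELAB and the coordinates are averaged
    arithmetically over the mask; chroma and hue are computed from the
    averaged a*, b* (not averaged per-pixel, so the record is internally
    consistent with the chroma formula).
    """
    coords = np.asarray(region.pixel_mask)
    if coords.size == 0:
        raise ImagingError("empty region mask")
    rows, cols = coords[:, 0], coords[:, 1]
    h, w = image.shape
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ImagingError("region mask extends outside the image")
    px = image.pixels[rows, cols].astype(float) / 255.0
    lab = _rgb01_to_lab(px)
    L, a, b = lab.mean(axis=0)
    c, hue = chroma_hue(a, b)
    return SeedColorRecord(region.seed_id, float(L), float(a), float(b), c, hue)


def color_records_to_frame(records: Sequence[SeedColorRecord], areas=None):
    """Tabulate color records as a DataFrame (seed_row, seed_col, L, a, b, C_ab, h_ab)."""
    import pandas as pd

    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "seed_row": r.seed_id[0],
                "seed_col": r.seed_id[1],
                "area_px": None if areas is None else areas[i],
                "L": r.L_star,
                "a": r.a_star,
                "b": r.b_star,
                "C_ab": r.C_ab,
                "h_ab": r.h_ab,
            }
        )
    return pd.DataFrame(rows)


def fit_ellipsoid(points: np.ndarray) -> EllipsoidFit:
    """Least-squares algebraic ellipsoid fit to a 3-D point cloud.

    Solves for the quadric  x'Ax + 2b'x = 1  minimising the algebraic residual
    over the 9 quadric coefficients, then extracts center, semi-axes and
    orientation from the eigendecomposition.  Requires at least 9 points in
    general position; coplanar/collinear clouds raise an error.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ImagingError("points must be an (N, 3) array")
    if P.shape[0] < 9:
        raise ImagingError(f"need at least 9 points, got {P.shape[0]}")

    x, y, z = P[:, 0], P[:, 1], P[:, 2]
    D = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z]
    )
    if np.linalg.matrix_rank(D) < 9:
        raise ImagingError("degenerate point cloud (rank-deficient design)")
    v, *_ = np.linalg.lstsq(D, np.ones(P.shape[0]), rcond=None)

    A = np.array(
        [[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]]
    )
    b = v[6:9]
    try:
        center = -np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ImagingError("degenerate quadric (singular shape matrix)") from exc
    # Substitute p = center + q:  q'Aq = 1 - c'Ac - 2b'c
    s = 1.0 - center @ A @ center - 2.0 * b @ center
    eigvals, eigvecs = np.linalg.eigh(A / s)
    if np.any(eigvals <= 0):
        raise ImagingError("fitted quadric is not an ellipsoid")
    semi_axes = 1.0 / np.sqrt(eigvals)  # ascending eigvals -> descending axes
    order = np.argsort(semi_axes)[::-1]
    semi_axes = semi_axes[order]
    R = eigvecs[:, order]
    if np.linalg.det(R) < 0:
        R = R.copy()
        R[:, -1] *= -1

    # Approximate geometric residual: radial distance from each point to the surface.
    q = (P - center) @ R
    m = np.sqrt(np.sum((q / semi_axes) ** 2, axis=1))
    radial = np.linalg.norm(P - center, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(m > 0, np.abs(radial * (1.0 - 1.0 / m)), radial.mean())
    rms = float(np.sqrt(np.mean(dist**2)))
    return EllipsoidFit(center=center, semi_axes=semi_axes, orientation=R, rms_residual=rms)
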