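"""Cell geometry: nucleus/cell masks, pixel scale and the analyzed area A.

Coordinates follow image convention: ``x`` runs along columns, ``y`` along
rows, both in nanometres.  A pixel with indices ``(row, col)`` covers
``[col*p, (col+1)*p) x [row*p, (row+1)*p)`` for pixel size ``p``; its centre
is at ``((col+0.5)*p, (row+0.5)*p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: XY pixel size of the imaging system emulated throughout (nm).
DEFAULT_PIXEL_SIZE_NM = 106.3
#: Z sectioning interval (nm).
DEFAULT_Z_STEP_NM = 200.0


class InvalidGeometryError(ValueError):
    """Raised when nucleus and cell masks are mutually inconsistent."""


@dataclass(frozen=True)
class CellGeometry:
    """Binary nucleus/cell masks plus the pixel scale.

    Attributes
    ----------
    nucleus_mask, cell_mask : bool arrays of identical shape
        ``nucleus_mask`` must be a subset of ``cell_mask``.
    pixel_size_nm : float
        XY sampling, nm per pixel.
    z_step_nm : float
        Axial sampling, nm per plane (used only by 3D rendering/fitting).
    """

    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_step_nm: float = DEFAULT_Z_STEP_NM

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nucleus_mask, dtype=bool)
        cell = np.asarray(self.cell_mask, dtype=bool)
        object.__setattr__(self, "nucleus_mask", nuc)
        object.__setattr__(self, "cell_mask", cell)
        if self.pixel_size_nm <= 0:
            raise InvalidGeometryError("pixel_size_nm must be positive")
        if self.z_step_nm <= 0:
            raise InvalidGeometryError("z_step_nm must be positive")
        if nuc.shape != cell.shape:
            raise InvalidGeometryError("nucleus and cell masks differ in shape")
        if not cell.any():
            raise InvalidGeometryError("cell mask is empty")
        if np.any(nuc & ~cell):
            raise InvalidGeometryError("nucleus mask extends outside the cell mask")

    # -- derived quantities -------------------------------------------------

    @property
    def image_shape_px(self) -> tuple[int, int]:
        return self.cell_mask.shape

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        """Cell pixels excluding the nucleus (where cytoplasmic spots live)."""
        return self.cell_mask & ~self.nucleus_mask

    @property
    def area_A_nm2(self) -> float:
        """Total analyzed area A: cell-mask pixel count times pixel area (nm^2)."""
        return float(self.cell_mask.sum()) * self.pixel_size_nm**2

    @property
    def cytoplasm_area_nm2(self) -> float:
        return float(self.cytoplasm_mask.sum()) * self.pixel_size_nm**2

    def nucleus_distance_map_um(self) -> np.ndarray:
        """Per-pixel Euclidean distance to the nucleus, in micrometres.

        Zero inside the nucleus.  Computed by an exact Euclidean distance
        transform of the nucleus complement.
        """
        if not self.nucleus_mask.any():
            raise InvalidGeometryError("nucleus mask is empty")
        dist_px = ndimage.distance_transform_edt(~self.nucleus_mask)
        return dist_px * (self.pixel_size_nm / 1000.0)


def _ellipse_mask(shape, center_rc, semi_rc, theta) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    dr = rows - center_rc[0]
    dc = cols - center_rc[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / semi_rc[1]) ** 2 + (v / semi_rc[0]) ** 2 <= 1.0


def make_cell_geometry(
    seed: int,
    shape_px: tuple[int, int] = (512, 512),
    nucleus_radius_um: float = 8.0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    z_step_nm: float = DEFAULT_Z_STEP_NM,
) -> CellGeometry:
    """Draw a single-cell geometry: an elliptical cell with a round nucleus.

    The cell is an ellipse of randomized orientation and semi-axes filling
    most of the field of view; the nucleus is a disc of the requested radius,
    jittered around the cell centre but guaranteed to stay inside the cell.
    Deterministic for a fixed ``seed``.

    Raises
    ------
    InvalidGeometryError
        If the nucleus cannot fit inside the cell, or the pixel size is not
        positive.
    """
    if pixel_size_nm <= 0:
        raise InvalidGeometryError("pixel_size_nm must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    nucleus_radius_px = nucleus_radius_um * 1000.0 / pixel_size_nm

    # Cell semi-axes: 0.36-0.46 of the half-extent, random orientation.
    a = rng.uniform(0.36, 0.46) * ny
    b = rng.uniform(0.36, 0.46) * nx
    theta = rng.uniform(0.0, np.pi)
    center = np.array([ny / 2.0, nx / 2.0]) + rng.uniform(-0.02, 0.02, 2) * min(ny, nx)

    margin = min(a, b) - nucleus_radius_px
    if margin <= 2.0:
        raise InvalidGeometryError(
            f"nucleus (radius {nucleus_radius_px:.0f} px) does not fit inside the "
            f"cell (min semi-axis {min(a, b):.0f} px)"
        )
    # Nucleus jitter, conservative so the disc stays inside the ellipse.
    jitter = rng.uniform(-0.3, 0.3, 2) * margin * 0.5
    nuc_center = center + jitter

    cell = _ellipse_mask(shape_px, center, (a, b), theta)
    nucleus = _ellipse_mask(
        shape_px, nuc_center, (nucleus_radius_px, nucleus_radius_px), 0.0
    )
    if np.any(nucleus & ~cell):  # pragma: no cover - jitter is conservative
        nucleus &= cell
    return CellGeometry(
        nucleus_mask=nucleus,
        cell_mask=cell,
        pixel_size_nm=pixel_size_nm,
        z_step_nm=z_step_nm,
    )
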