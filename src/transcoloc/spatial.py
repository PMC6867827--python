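"""Distance-from-nucleus spatial profiles of spots.

Distances are measured in the projection plane from the spot centroid to
the nearest nucleus-boundary pixel centre; spots lying inside the nucleus
mask are assigned distance 0 (projected FISH signal can overlie the nuclear
edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import CellGeometry


def _boundary_pixels(nucleus_mask: np.ndarray) -> np.ndarray:
    """(row, col) indices of nucleus pixels adjacent to the outside."""
    inner = ndimage.binary_erosion(nucleus_mask, border_value=0)
    boundary = nucleus_mask & ~inner
    return np.argwhere(boundary)


def distance_to_nucleus(spot_table: pd.DataFrame, geometry: CellGeometry) -> np.ndarray:
    """Euclidean distance (um) from each spot to the nucleus boundary.

    Exact: the minimum over all boundary-pixel centres, zero inside the
    nucleus mask.
    """
    if not geometry.nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    px = geometry.pixel_size_nm
    bnd = _boundary_pixels(geometry.nucleus_mask)
    centers_nm = (bnd[:, ::-1] + 0.5) * px  # (x, y) order
    tree = cKDTree(centers_nm)
    pts = spot_table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    d_nm, _ = tree.query(pts)
    rows = np.clip((pts[:, 1] // px).astype(int), 0, geometry.image_shape_px[0] - 1)
    cols = np.clip((pts[:, 0] // px).astype(int), 0, geometry.image_shape_px[1] - 1)
    inside = geometry.nucleus_mask[rows, cols]
    d_nm = np.where(inside, 0.0, d_nm)
    return d_nm / 1000.0


@dataclass
class RadialProfile:
    """Normalized histogram of spot distances from the nucleus."""

    bin_edges_um: np.ndarray
    fraction_per_bin: np.ndarray
    n_spots: int
    distances_um: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.fraction_per_bin = np.asarray(self.fraction_per_bin, dtype=float)
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if self.n_spots > 0 and abs(self.fraction_per_bin.sum() - 1.0) > 1e-9:
            raise ValueError("bin fractions must sum to 1")

    def cumulative_within(self, radius_um: float) -> float:
        """Fraction of spots within ``radius_um`` of the nucleus (exact)."""
        if self.distances_um is None:
            idx = np.searchsorted(self.bin_edges_um, radius_um, side="right") - 1
            return float(self.fraction_per_bin[:idx].sum())
        return float(np.mean(self.distances_um <= radius_um))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges_um[:-1],
                "bin_hi_um": self.bin_edges_um[1:],
                "fraction": self.fraction_per_bin,
            }
        )

    def plot(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        w = np.diff(self.bin_edges_um)
        ax.bar(self.bin_edges_um[:-1], self.fraction_per_bin, width=w, align="edge")
        ax.set_xlabel("distance from nucleus (um)")
        ax.set_ylabel("fraction of spots")
        return ax


def radial_distribution(distances_um, bin_um: float = 5.0) -> RadialProfile:
    """Bin distances into a normalized radial profile (default 5-um bins)."""
    d = np.asarray(distances_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    top = max(float(d.max()) if d.size else bin_um, bin_um)
    edges = np.arange(0.0, np.ceil(top / bin_um) * bin_um + bin_um, bin_um)
    counts, edges = np.histogram(d, bins=edges)
    frac = counts / d.size if d.size else counts.astype(float)
    return RadialProfile(edges, frac, int(d.size), distances_um=d)


def area_null_profile(geometry: CellGeometry, bin_um: float = 5.0) -> RadialProfile:
    """Expected profile for uniformly placed cytoplasmic spots.

    Uses the distance-to-nucleus of every cytoplasm pixel as the
    area-weighted null distribution.
    """
    dist = geometry.nucleus_distance_map_um()[geometry.cytoplasm_mask]
    return radial_distribution(dist, bin_um=bin_um)
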