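"""Spatial tissue architecture: epidermis, compartments, vessels, maps.

The epidermal layer is recovered as large connected patches of
keratinocytes lying above the dermis.  Every other cell is assigned to the
papillary (< 100 µm from the epidermis) or reticular (>= 100 µm)
compartment by its distance to the nearest epidermal cell.  Papillary
vessels are connected knn patches of papillary endothelial cells; each
patch's orientation is the angle between its first principal axis and the
local epidermal axis, with patches steeper than 45 degrees flagged as
perpendicular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EpidermisModel",
    "Patch",
    "DensityMap",
    "detect_epidermis",
    "distance_to_epidermis",
    "assign_compartment",
    "assign_compartments",
    "detect_vessel_patches",
    "patch_orientation",
    "kde_map",
    "principal_axis",
]

PAPILLARY_BORDER_UM = 100.0


@dataclass
class EpidermisModel:
    cell_ids: list[str]
    points: np.ndarray  # (n, 2) µm
    patch_labels: np.ndarray  # patch index per member


@dataclass
class Patch:
    cell_ids: list[str]
    points: np.ndarray
    centroid: np.ndarray = field(init=False)
    axis: np.ndarray | None = None  # first principal axis, unit vector
    angle_deg: float | None = None  # vs epidermis, in [0, 90]
    perpendicular: bool | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.centroid = self.points.mean(axis=0)

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class DensityMap:
    origin: np.ndarray  # (x0, y0) µm
    spacing_um: float
    values: np.ndarray  # (ny, nx), >= 0
    bandwidth_um: float

    def integral(self) -> float:
        return float(self.values.sum() * self.spacing_um**2)


def _radius_components(points: np.ndarray, radius: float) -> np.ndarray:
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(points)
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def detect_epidermis(
    cells: pd.DataFrame,
    keratinocyte_types: set[str] | str = "keratinocyte",
    link_radius_um: float = 30.0,
    min_patch: int = 10,
) -> EpidermisModel:
    """Find the epidermal layer as superficial keratinocyte patches.

    Connected components of keratinocytes (centroid distance <=
    ``link_radius_um``) with at least ``min_patch`` members are candidate
    patches; those whose mean depth is above the mean depth of the dermal
    (non-keratinocyte) cells are labelled epidermis.  Depth is the y
    coordinate (increasing downward).
    """
    if isinstance(keratinocyte_types, str):
        keratinocyte_types = {keratinocyte_types}
    if link_radius_um <= 0:
        raise ValueError("link_radius_um must be positive")
    type_col = "true_type" if "true_type" in cells.columns else "type"
    is_ker = cells[type_col].isin(keratinocyte_types).to_numpy()
    ker = cells.loc[is_ker]
    dermal_depth = cells.loc[~is_ker, "y_um"]
    if ker.empty or dermal_depth.empty:
        raise ValueError("no epidermal layer found")
    pts = ker[["x_um", "y_um"]].to_numpy()
    comp = _radius_components(pts, link_radius_um)

    member_ids: list[str] = []
    member_pts: list[np.ndarray] = []
    member_patch: list[int] = []
    ref_depth = dermal_depth.mean()
    n_patch = 0
    for c in np.unique(comp):
        sel = comp == c
        if sel.sum() < min_patch:
            continue
        if pts[sel, 1].mean() < ref_depth:  # above the dermis
            member_ids.extend(ker["cell_id"].to_numpy()[sel])
            member_pts.append(pts[sel])
            member_patch.extend([n_patch] * int(sel.sum()))
            n_patch += 1
    if not member_ids:
        raise ValueError("no epidermal layer found")
    return EpidermisModel(
        cell_ids=member_ids,
        points=np.vstack(member_pts),
        patch_labels=np.asarray(member_patch),
    )


def distance_to_epidermis(cells: pd.DataFrame, epi: EpidermisModel) -> pd.Series:
    """Euclidean distance (µm) to the nearest epidermal cell; 0 for members."""
    if len(epi.points) == 0:
        raise ValueError("epidermis model is empty")
    tree = cKDTree(epi.points)
    dist, _ = tree.query(cells[["x_um", "y_um"]].to_numpy())
    out = pd.Series(dist, index=cells["cell_id"].to_numpy(), name="dist_epi_um")
    out.loc[out.index.isin(epi.cell_ids)] = 0.0
    return out


def assign_compartment(distance_um: float, border_um: float = PAPILLARY_BORDER_UM) -> str:
    """Papillary below the border, reticular at or beyond it."""
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    return "papillary" if distance_um < border_um else "reticular"


def assign_compartments(
    cells: pd.DataFrame,
    epi: EpidermisModel,
    border_um: float = PAPILLARY_BORDER_UM,
) -> pd.DataFrame:
    """Append distance and compartment columns to the cell table."""
    dist = distance_to_epidermis(cells, epi)
    out = cells.copy()
    out["dist_epi_um"] = dist.to_numpy()
    is_epi = out["cell_id"].isin(epi.cell_ids).to_numpy()
    comp = np.where(out["dist_epi_um"].to_numpy() < border_um, "papillary", "reticular")
    comp[is_epi] = "epidermis"
    out["compartment"] = comp
    return out


def detect_vessel_patches(
    cells: pd.DataFrame,
    k: int = 10,
    min_size: int = 3,
    max_link_um: float | None = None,
) -> list[Patch]:
    """Group papillary endothelial cells into vessel patches.

    Builds the union knn graph (edge if either endpoint lists the other
    among its k nearest neighbours), optionally dropping edges longer than
    ``max_link_um``, and keeps connected components of at least
    ``min_size`` cells.  The caller is expected to pass only papillary
    endothelial cells.
    """
    n = len(cells)
    if n < min_size:
        return []
    pts = cells[["x_um", "y_um"]].to_numpy()
    ids = cells["cell_id"].to_numpy()
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
    dist, idx = nn.kneighbors(pts)
    rows, cols = [], []
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if max_link_um is not None and d > max_link_um:
                continue
            rows.append(i)
            cols.append(int(j))
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    patches = []
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() >= min_size:
            patches.append(Patch(cell_ids=list(ids[sel]), points=pts[sel]))
    return patches


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit first principal component of a 2-D point cloud."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate point cloud: all points identical")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def patch_orientation(
    patch: Patch,
    epi: EpidermisModel,
    local_radius_um: float = 200.0,
    angle_threshold_deg: float = 45.0,
) -> Patch:
    """Angle between the patch's principal axis and the local epidermis.

    The epidermal reference axis is the first principal component of the
    epidermal cells within ``local_radius_um`` of the patch centroid
    (falling back to the whole epidermis with a warning).  The angle is
    folded into [0, 90] and patches strictly steeper than the threshold
    are flagged perpendicular.
    """
    axis = principal_axis(patch.points)
    tree = cKDTree(epi.points)
    near = tree.query_ball_point(patch.centroid, local_radius_um)
    if len(near) >= 2:
        epi_axis = principal_axis(epi.points[near])
    else:
        logger.warning(
            "no local epidermis within %.0f µm of patch centroid %s; "
            "using the global epidermal axis",
            local_radius_um,
            patch.centroid,
        )
        epi_axis = principal_axis(epi.points)
    cosang = np.clip(abs(float(np.dot(axis, epi_axis))), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    patch.axis = axis
    patch.angle_deg = angle
    # strict > threshold; 1e-9 deg guard absorbs arccos rounding at exactly 45
    patch.perpendicular = angle > angle_threshold_deg + 1e-9
    return patch


def kde_map(
    cells: pd.DataFrame,
    weights: np.ndarray,
    bandwidth_um: float = 50.0,
    grid_spacing_um: float = 10.0,
    pad_um: float | None = None,
) -> DensityMap:
    """Weighted isotropic Gaussian kernel density surface on a regular grid.

    Each cell contributes ``w * N(p; cell, h^2 I)``; the grid extends
    ``pad_um`` (default 4 bandwidths) beyond the data so the Riemann sum of
    the map approximates the total weight.
    """
    if bandwidth_um <= 0:
        raise ValueError("bandwidth must be positive")
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    pts = cells[["x_um", "y_um"]].to_numpy()
    if len(pts) != len(w):
        raise ValueError("one weight per cell required")
    if pad_um is None:
        pad_um = 4.0 * bandwidth_um
    x0, y0 = pts.min(axis=0) - pad_um
    x1, y1 = pts.max(axis=0) + pad_um
    gx = np.arange(x0, x1 + grid_spacing_um, grid_spacing_um)
    gy = np.arange(y0, y1 + grid_spacing_um, grid_spacing_um)
    xx, yy = np.meshgrid(gx, gy)
    norm = 1.0 / (2.0 * np.pi * bandwidth_um**2)
    values = np.zeros_like(xx)
    # accumulate per cell; fine at the tissue scales this targets
    for (px, py), wi in zip(pts, w):
        if wi == 0:
            continue
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        values += wi * norm * np.exp(-0.5 * d2 / bandwidth_um**2)
    return DensityMap(
        origin=np.array([x0, y0]),
        spacing_um=grid_spacing_um,
        values=values,
        bandwidth_um=bandwidth_um,
    )
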