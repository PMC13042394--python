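"""Spot allocation plot (SAP) coordinates and crypt-region delineation.

The SAP places every spot in a 2D coordinate system encoding its position
along the crypt-villus axis: X is the Euclidean distance (µm) to the nearest
enterocyte-annotated spot, Y the distance to the nearest smooth-muscle spot.
Crypt regions are connected components of crypt-annotated spots on the
capture grid (8-connectivity by default, tolerating diagonal staircase
artifacts of rasterized anatomy).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import CryptRegion, ValidationError

logger = logging.getLogger(__name__)


def nearest_distance(
    query_points: np.ndarray,
    reference_points: np.ndarray,
    method: str = "kdtree",
) -> np.ndarray:
    """Minimum Euclidean distance from each query point to any reference point.

    ``method="kdtree"`` uses a k-d tree; ``method="exhaustive"`` is the O(n*m)
    scan kept as an independent cross-check. Both must agree to float
    precision.
    """
    query = np.asarray(query_points, dtype=float)
    ref = np.asarray(reference_points, dtype=float)
    if ref.size == 0:
        raise ValidationError("reference_points must be non-empty")
    query = np.atleast_2d(query)
    ref = np.atleast_2d(ref)
    if not (np.isfinite(query).all() and np.isfinite(ref).all()):
        raise ValidationError("coordinates must be finite")
    if method == "kdtree":
        dist, _ = cKDTree(ref).query(query, k=1)
        return np.asarray(dist, dtype=float)
    if method == "exhaustive":
        diff = query[:, None, :] - ref[None, :, :]
        return np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    raise ValueError(f"unknown method {method!r}")


def compute_sap(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-spot SAP coordinates: d_ent (X) and d_sm (Y), in input row order.

    Raises if the section lacks either reference compartment, naming it.
    """
    pts = spots[["x_um", "y_um"]].to_numpy(dtype=float)
    out = {"spot_id": spots["spot_id"].to_numpy()}
    for comp, col in (("enterocyte", "d_ent"), ("smooth_muscle", "d_sm")):
        mask = (spots["compartment"] == comp).to_numpy()
        if not mask.any():
            raise ValidationError(f"no spots annotated {comp!r} in the section")
        out[col] = nearest_distance(pts, pts[mask])
    return pd.DataFrame(out)


def _grid_indices(spots: pd.DataFrame, pitch: float | None) -> tuple[np.ndarray, np.ndarray, float]:
    """Map spot centres onto integer grid indices; infers pitch if omitted."""
    x = spots["x_um"].to_numpy(dtype=float)
    y = spots["y_um"].to_numpy(dtype=float)
    if pitch is None:
        ux = np.unique(x)
        uy = np.unique(y)
        diffs = np.concatenate([np.diff(ux), np.diff(uy)])
        diffs = diffs[diffs > 1e-9]
        if diffs.size == 0:
            raise ValidationError("cannot infer spot pitch from a single coordinate")
        pitch = float(diffs.min())
    col = np.rint((x - x.min()) / pitch).astype(int)
    row = np.rint((y - y.min()) / pitch).astype(int)
    off = np.hypot(x - (x.min() + col * pitch), y - (y.min() + row * pitch))
    if (off > 0.25 * pitch).any():
        raise ValidationError("spots do not lie on a regular grid at the given pitch")
    return row, col, pitch


def define_crypt_regions(
    spots: pd.DataFrame,
    pitch: float | None = None,
    connectivity: int = 8,
) -> list[CryptRegion]:
    """Connected components of crypt-annotated spots on the capture grid.

    Regions are labelled ``crypt_000``, ``crypt_001``, ... ordered by the
    minimum (y, x) of their member spots, so region identity is deterministic.
    Zero crypt spots yields an empty list.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    crypt = spots[spots["compartment"] == "crypt"]
    if crypt.empty:
        logger.info("no crypt-annotated spots; returning zero regions")
        return []
    row, col, _ = _grid_indices(crypt, pitch)
    occ = np.zeros((row.max() + 1, col.max() + 1), dtype=bool)
    occ[row, col] = True
    structure = np.ones((3, 3), dtype=int) if connectivity == 8 else None
    labels, n = ndimage.label(occ, structure=structure)
    comp_of_spot = labels[row, col]

    # order regions by minimum (y, x) of members
    order = []
    for lab in range(1, n + 1):
        members = np.flatnonzero(comp_of_spot == lab)
        key = min(zip(crypt["y_um"].to_numpy()[members], crypt["x_um"].to_numpy()[members]))
        order.append((key, lab))
    order.sort()
    regions = []
    ids = crypt["spot_id"].to_numpy()
    for rank, (_, lab) in enumerate(order):
        members = ids[comp_of_spot == lab]
        regions.append(CryptRegion(region_id=f"crypt_{rank:03d}",
                                   spot_ids=tuple(members)))
    return regions


def assign_spots_to_regions(
    spots: pd.DataFrame,
    regions: list[CryptRegion],
    radius_um: float,
) -> pd.Series:
    """Map each immune-labelled spot to its nearest crypt region.

    A spot is assigned to the region containing its nearest crypt spot when
    that distance is <= ``radius_um``; otherwise it is unassigned (NaN).
    Returns a Series indexed by spot_id (labelled spots only).
    """
    if radius_um < 0:
        raise ValidationError("radius_um must be >= 0")
    labelled = spots[spots["cell_type"].fillna("").astype(str) != ""]
    index = pd.Index(labelled["spot_id"], name="spot_id")
    if not regions or labelled.empty:
        return pd.Series(pd.NA, index=index, name="region_id", dtype="object")

    region_of: dict[str, str] = {
        sid: r.region_id for r in regions for sid in r.spot_ids
    }
    crypt = spots[spots["spot_id"].isin(region_of)]
    tree = cKDTree(crypt[["x_um", "y_um"]].to_numpy(dtype=float))
    dist, idx = tree.query(labelled[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
    nearest_ids = crypt["spot_id"].to_numpy()[idx]
    assigned = np.where(
        dist <= radius_um,
        [region_of[s] for s in nearest_ids],
        None,
    )
    return pd.Series(assigned, index=index, name="region_id", dtype="object")
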