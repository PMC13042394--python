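"""Crypt-region cell-type spatial proximity network with a permutation null.

Two labelled spots are "proximal" when they are assigned to the same crypt
region and their centres lie within a fixed radius (default 3x the spot
pitch). Observed per-pair counts are compared against a null in which
cell-type labels are permuted uniformly among labelled spots *within each
region* — positions and per-region label counts are preserved, so the test
asks about label co-occurrence, not tissue architecture. Enrichment p-values
use additive smoothing: p = (1 + #{null >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import HEADLINE_CELL_TYPES, ValidationError


def _assigned_labelled(spots: pd.DataFrame, region_map: pd.Series) -> pd.DataFrame:
    lab = spots[spots["cell_type"].fillna("").astype(str) != ""].copy()
    if lab.empty:
        raise ValidationError("no labelled spots")
    region = region_map.reindex(lab["spot_id"]).to_numpy()
    lab["region_id"] = region
    lab = lab[pd.notna(lab["region_id"])]
    if lab.empty:
        raise ValidationError("no labelled spots assigned to any crypt region")
    return lab.reset_index(drop=True)


def _proximal_pairs(lab: pd.DataFrame, radius_um: float) -> np.ndarray:
    """(n_pairs, 2) spot-index pairs: same region, centre distance <= radius."""
    pts = lab[["x_um", "y_um"]].to_numpy(dtype=float)
    pairs = cKDTree(pts).query_pairs(radius_um, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    region = lab["region_id"].to_numpy()
    same = region[pairs[:, 0]] == region[pairs[:, 1]]
    return pairs[same]


def _pair_counts(codes: np.ndarray, pairs: np.ndarray, k: int) -> np.ndarray:
    """Unordered type-pair counts as a flat length k*k array (upper triangle)."""
    a = codes[pairs[:, 0]]
    b = codes[pairs[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return np.bincount(lo * k + hi, minlength=k * k)


def count_proximal_pairs(
    spots: pd.DataFrame,
    radius_um: float,
    region_map: pd.Series,
    include_unclear: bool = False,
) -> pd.DataFrame:
    """Observed proximal spot-pair counts for each unordered cell-type pair.

    Self-pairs (both members the same type) count each unordered spot pair
    once. Spots not assigned to a region contribute nothing.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be > 0")
    lab = _assigned_labelled(spots, region_map)
    types = _edge_types(include_unclear)
    code_of = {t: i for i, t in enumerate(sorted(set(lab["cell_type"])))}
    codes = lab["cell_type"].map(code_of).to_numpy()
    pairs = _proximal_pairs(lab, radius_um)
    flat = _pair_counts(codes, pairs, len(code_of))
    rows = []
    for i, ta in enumerate(types):
        for tb in types[i:]:
            ca, cb = code_of.get(ta), code_of.get(tb)
            n = 0
            if ca is not None and cb is not None:
                lo, hi = min(ca, cb), max(ca, cb)
                n = int(flat[lo * len(code_of) + hi])
            rows.append((ta, tb, n))
    return pd.DataFrame(rows, columns=["type_a", "type_b", "observed"])


def _edge_types(include_unclear: bool) -> tuple[str, ...]:
    return HEADLINE_CELL_TYPES + ("Unclear",) if include_unclear else HEADLINE_CELL_TYPES


def permutation_null(
    spots: pd.DataFrame,
    radius_um: float,
    region_map: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    include_unclear: bool = False,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Proximity network edges with permutation-null summaries.

    Returns one row per unordered cell-type pair with columns observed,
    expected_mean, expected_sd, z, p_perm and estimable. ``z`` is NaN when the
    null sd is zero; a self-edge of a type with fewer than two spots is
    flagged not estimable. ``alternative="less"`` tests depletion.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    lab = _assigned_labelled(spots, region_map)
    code_of = {t: i for i, t in enumerate(sorted(set(lab["cell_type"])))}
    k = len(code_of)
    codes = lab["cell_type"].map(code_of).to_numpy()
    pairs = _proximal_pairs(lab, radius_um)
    observed = _pair_counts(codes, pairs, k)

    # permute labels within each region, positions fixed
    rng = np.random.default_rng(seed)
    region_codes, region_idx = np.unique(lab["region_id"].to_numpy(), return_inverse=True)
    groups = [np.flatnonzero(region_idx == r) for r in range(len(region_codes))]
    null = np.empty((n_perm, k * k), dtype=np.int64)
    perm_codes = codes.copy()
    for b in range(n_perm):
        for g in groups:
            perm_codes[g] = codes[g][rng.permutation(g.size)]
        null[b] = _pair_counts(perm_codes, pairs, k)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    if alternative == "greater":
        extreme = (null >= observed[None, :]).sum(axis=0)
    else:
        extreme = (null <= observed[None, :]).sum(axis=0)
    pval = (1.0 + extreme) / (1.0 + n_perm)

    n_of_type = lab["cell_type"].value_counts()
    types = _edge_types(include_unclear)
    rows = []
    for i, ta in enumerate(types):
        for tb in types[i:]:
            ca, cb = code_of.get(ta), code_of.get(tb)
            if ca is None or cb is None:
                rows.append((ta, tb, 0, 0.0, 0.0, np.nan, 1.0, False))
                continue
            lo, hi = min(ca, cb), max(ca, cb)
            j = lo * k + hi
            estimable = True
            if ta == tb and n_of_type.get(ta, 0) < 2:
                estimable = False
            z = (observed[j] - mean[j]) / sd[j] if sd[j] > 0 else np.nan
            rows.append((ta, tb, int(observed[j]), float(mean[j]),
                         float(sd[j]), z, float(pval[j]), estimable))
    edges = pd.DataFrame(
        rows,
        columns=["type_a", "type_b", "observed", "expected_mean",
                 "expected_sd", "z", "p_perm", "estimable"],
    )
    edges.attrs["n_perm"] = n_perm
    edges.attrs["radius_um"] = radius_um
    edges.attrs["alternative"] = alternative
    return edges


def to_networkx(edges: pd.DataFrame):
    """Edge table as an undirected networkx graph (edge attrs = null summaries)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(
            row["type_a"], row["type_b"],
            observed=int(row["observed"]),
            expected_mean=float(row["expected_mean"]),
            expected_sd=float(row["expected_sd"]),
            z=None if pd.isna(row["z"]) else float(row["z"]),
            p_perm=float(row["p_perm"]),
        )
    return g
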