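"""Compositional enrichment (Ro/e) and TCR repertoire statistics.

Ro/e compares the observed cell count of each (group, subset) cell against the
chi-square expected count under independence; Ro/e > 1 marks enrichment of a
subset in a group. Repertoire clonality is summarized by the Gini index over
clonotype sizes and diversity by Shannon entropy of the clonotype frequency
distribution; clones are defined within a sample and "expanded" means clone
size > 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

from .types import RoeMatrix, ValidationError

#: Default clone-size classes: singleton, doublet, expanded (>2).
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = ((1, 1), (2, 2), (3, None))


def roe_scores(
    comp: pd.DataFrame,
    rows: str = "group",
    cols: str = "subset",
) -> RoeMatrix:
    """Ratio of observed to expected cell counts over a rows x cols grid.

    ``expected_ij = row_i total * col_j total / grand total`` (the chi-square
    expected count); ``roe_ij = observed_ij / expected_ij``, NaN where the
    expected count is zero.
    """
    if comp.empty:
        raise ValidationError("composition table is empty")
    for key in (rows, cols):
        if key not in comp.columns:
            raise ValidationError(f"missing grouping column {key!r}")
    observed = pd.crosstab(comp[rows], comp[cols])
    expected = pd.DataFrame(
        expected_freq(observed.to_numpy()),
        index=observed.index,
        columns=observed.columns,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = observed / expected
    roe = roe.where(expected > 0)
    return RoeMatrix(roe=roe, observed=observed.astype(float), expected=expected)


def gini_index(clone_sizes, corrected: bool = False) -> float:
    """Gini inequality index of a clonotype size distribution, in [0, 1).

    Population formula ``G = sum_ij |x_i - x_j| / (2 n^2 mu)``; 0 for a
    perfectly even repertoire. ``corrected=True`` applies the small-sample
    factor n/(n-1).
    """
    x = np.asarray(list(clone_sizes), dtype=float)
    if x.size == 0:
        raise ValidationError("clone size list is empty")
    if (x < 1).any():
        raise ValidationError("clone sizes must be >= 1")
    n = x.size
    if n == 1:
        return 0.0
    xs = np.sort(x)
    # O(n log n) equivalent of the pairwise |difference| sum
    g = (2.0 * np.sum((np.arange(1, n + 1)) * xs) / (n * xs.sum())) - (n + 1) / n
    if corrected:
        g *= n / (n - 1)
    return float(max(g, 0.0))


def shannon_entropy(clone_sizes, base: float | None = None) -> float:
    """Shannon entropy of clonotype frequencies, in nats by default.

    ``H = -sum p_i log p_i`` with ``p_i = size_i / total``; maximal (= log k)
    for k equally sized clones. ``base=2`` gives bits.
    """
    x = np.asarray(list(clone_sizes), dtype=float)
    if x.size == 0:
        raise ValidationError("clone size list is empty")
    if (x <= 0).any():
        raise ValidationError("clone sizes must be positive")
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def clone_size_table(clones: pd.DataFrame) -> pd.DataFrame:
    """Clone sizes per (sample, clonotype_id); size = cells sharing the id
    within a sample (no cross-sample merging)."""
    _check_clonotype_table(clones)
    sizes = (
        clones.groupby(["sample", "clonotype_id"], sort=True)
        .size()
        .rename("clone_size")
        .reset_index()
    )
    return sizes


def repertoire_diversity(clones: pd.DataFrame, per_subset: bool = False) -> pd.DataFrame:
    """Gini index and Shannon entropy per sample.

    With ``per_subset=True`` the statistics are computed within each subset's
    cells as well; the whole-repertoire rows carry subset label ``all``.
    """
    _check_clonotype_table(clones)
    out = []
    for sample, grp in clones.groupby("sample", sort=True):
        sizes = grp.groupby("clonotype_id").size().to_numpy()
        out.append((sample, "all", gini_index(sizes), shannon_entropy(sizes)))
        if per_subset:
            for subset, sub in grp.groupby("subset", sort=True):
                s = sub.groupby("clonotype_id").size().to_numpy()
                out.append((sample, subset, gini_index(s), shannon_entropy(s)))
    return pd.DataFrame(out, columns=["sample", "subset", "gini", "shannon"])


def _validate_bins(bins) -> list[tuple[int, int | None]]:
    """Bins must partition the positive integers: contiguous, sorted, last open."""
    bins = [(int(lo), None if hi is None else int(hi)) for lo, hi in bins]
    if not bins:
        raise ValidationError("bins are empty")
    if bins[0][0] != 1:
        raise ValidationError("bins must start at clone size 1")
    for (lo, hi), (nlo, _) in zip(bins, bins[1:]):
        if hi is None:
            raise ValidationError("only the last bin may be open-ended")
        if nlo != hi + 1:
            raise ValidationError(
                f"bins must be contiguous: [{lo},{hi}] followed by lower edge {nlo}"
            )
    if bins[-1][1] is not None:
        raise ValidationError("last bin must be open-ended (hi=None)")
    return bins


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def clonal_size_classes(
    clones: pd.DataFrame,
    bins=DEFAULT_BINS,
) -> pd.DataFrame:
    """Per (sample, subset), the fraction of *cells* in each clone-size class.

    The default classes are {1, 2, >2}; ">2" is the expanded class. Fractions
    within each (sample, subset) sum to 1.
    """
    _check_clonotype_table(clones)
    vbins = _validate_bins(bins)
    sizes = clones.groupby(["sample", "clonotype_id"]).size().rename("clone_size")
    df = clones.merge(sizes.reset_index(), on=["sample", "clonotype_id"])
    edges = [lo - 0.5 for lo, _ in vbins] + [np.inf]
    labels = [_bin_label(lo, hi) for lo, hi in vbins]
    df["size_class"] = pd.cut(df["clone_size"], bins=edges, labels=labels)
    counts = (
        df.groupby(["sample", "subset", "size_class"], sort=True, observed=False)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby(["sample", "subset"])["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    counts["expanded"] = [lab == labels[-1] for lab in counts["size_class"]]
    return counts


def _check_clonotype_table(clones: pd.DataFrame) -> None:
    if clones.empty:
        raise ValidationError("clonotype table is empty")
    for col in ("cell_id", "clonotype_id", "subset", "sample"):
        if col not in clones.columns:
            raise ValidationError(f"clonotype table missing column {col!r}")
    if clones["cell_id"].duplicated().any():
        dups = clones.loc[clones["cell_id"].duplicated(), "cell_id"].head(5).tolist()
        raise ValidationError(f"duplicate cell_ids in clonotype table: {dups}")
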