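"""Gene-signature scoring, M2-M1 polarization delta and gene positive rates.

The signature score of a spot is the plain mean of its log-normalized
expression over the signature genes present in the matrix — deliberately free
of control-gene background correction so the statistic is exactly
reproducible. Positivity is a threshold on *raw* counts (default: count > 0).
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import GeneSignature, PositiveRate, ValidationError

logger = logging.getLogger(__name__)


def normalize_counts(counts: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalization to ``scale`` counts per spot, then log(1+x).

    Rows with zero total stay all-zero (with a logged warning). Returns a new
    AnnData with ``uns['norm_state'] == 'lognorm'``; the input is untouched.
    """
    if counts.uns.get("norm_state") != "raw":
        raise ValidationError("normalize_counts expects raw counts")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    X = sp.csr_matrix(counts.X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d spot(s) have zero total counts; left as zeros", zero.sum())
    factors = np.where(zero, 0.0, scale / np.where(zero, 1.0, totals))
    X = sp.diags(factors) @ X
    X.data = np.log1p(X.data)
    out = ad.AnnData(X=X.tocsr(), obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["norm_state"] = "lognorm"
    return out


def signature_score(counts: ad.AnnData, sig: GeneSignature) -> pd.DataFrame:
    """Per-spot mean log-normalized expression over the signature's genes.

    Genes absent from the matrix are dropped with a warning listing them;
    a signature with no present genes is an error. Returns a DataFrame with
    columns spot_id, score; row order follows the matrix.
    """
    if counts.uns.get("norm_state") != "lognorm":
        raise ValidationError("signature_score expects log-normalized counts")
    present = sorted(sig.genes & set(counts.var_names))
    missing = sorted(sig.genes - set(counts.var_names))
    if missing:
        logger.warning("signature %s: %d gene(s) not in matrix: %s",
                       sig.name, len(missing), ", ".join(missing))
    if not present:
        raise ValidationError(
            f"signature {sig.name!r}: none of its genes are in the matrix"
        )
    sub = counts[:, present].X
    score = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame({"spot_id": counts.obs_names.to_numpy(), "score": score})


def polarization_delta(s_m1: pd.DataFrame, s_m2: pd.DataFrame) -> pd.DataFrame:
    """Per-spot polarization delta = S_M2 - S_M1.

    Both inputs must cover exactly the same spots; a mismatch is an error that
    lists the symmetric difference. Returns spot_id, s_m1, s_m2, delta in the
    order of ``s_m1``.
    """
    a = set(s_m1["spot_id"])
    b = set(s_m2["spot_id"])
    if a != b or len(a) != len(s_m1) or len(b) != len(s_m2):
        diff = sorted(a ^ b)
        raise ValidationError(
            f"spot sets differ between M1 and M2 scores; symmetric difference: {diff[:20]}"
            + ("..." if len(diff) > 20 else "")
        )
    m2 = s_m2.set_index("spot_id")["score"]
    out = s_m1.rename(columns={"score": "s_m1"}).copy()
    out["s_m2"] = m2.loc[out["spot_id"]].to_numpy()
    out["delta"] = out["s_m2"] - out["s_m1"]
    return out


def positive_rate(
    counts: ad.AnnData,
    gene: str,
    spot_subset,
    threshold: int = 0,
) -> PositiveRate:
    """Fraction of subset spots whose raw count of ``gene`` exceeds ``threshold``.

    The default threshold 0 implements "expression > 0". Evaluated on raw
    counts regardless of any normalized copy in circulation.
    """
    if counts.uns.get("norm_state") != "raw":
        raise ValidationError("positive_rate expects raw counts")
    subset = list(spot_subset)
    if not subset:
        raise ValidationError("spot subset is empty")
    if gene not in counts.var_names:
        raise ValidationError(f"gene {gene!r} not in the count matrix")
    missing = set(subset) - set(counts.obs_names)
    if missing:
        raise ValidationError(f"subset spots not in the matrix: {sorted(missing)[:10]}")
    col = counts[subset, gene].X
    vals = np.asarray(col.todense() if sp.issparse(col) else col).ravel()
    n_pos = int((vals > threshold).sum())
    return PositiveRate(gene=gene, rate=n_pos / len(subset),
                        n_positive=n_pos, n_total=len(subset))
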