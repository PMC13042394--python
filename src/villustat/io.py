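"""Readers and writers for the interchange formats.

TSV dialect: tab-separated, UTF-8, mandatory header row, '.' decimal; lines
starting with '#' are metadata comments (writers use them to echo config).
Count matrices travel as MatrixMarket coordinate files next to barcodes/
features TSVs. Validation is strict: missing columns, duplicate identifiers
and unknown category labels are errors, never silent coercions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    CELL_TYPES,
    COMPARTMENTS,
    FormatError,
    GeneSignature,
    RoeMatrix,
    ValidationError,
)

__all__ = [
    "read_spot_table", "write_spot_table", "read_counts", "write_counts",
    "read_signatures", "write_signatures", "read_clonotypes",
    "read_composition", "write_table", "write_roe", "sha256_of",
]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: malformed TSV: {e}") from e


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise FormatError(f"{path}: non-numeric {col!r} on line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_spot_table(path, extra_cell_types=()) -> pd.DataFrame:
    """Read and validate a spot table TSV.

    Unknown compartment or cell-type labels are errors unless whitelisted via
    ``extra_cell_types``.
    """
    df = _read_tsv(path)
    _require_columns(df, ("spot_id", "x_um", "y_um", "compartment"), path)
    if df["spot_id"].duplicated().any():
        dups = df.loc[df["spot_id"].duplicated(), "spot_id"].head(5).tolist()
        raise FormatError(f"{path}: duplicate spot_ids: {dups}")
    out = pd.DataFrame({
        "spot_id": df["spot_id"],
        "x_um": _to_float(df, "x_um", path),
        "y_um": _to_float(df, "y_um", path),
        "compartment": df["compartment"],
    })
    unknown = set(out["compartment"]) - set(COMPARTMENTS)
    if unknown:
        raise FormatError(f"{path}: unknown compartment label(s): {sorted(unknown)}")
    if "cell_type" in df.columns:
        ct = df["cell_type"]
        allowed = set(CELL_TYPES) | set(extra_cell_types) | {""}
        unknown = set(ct) - allowed
        if unknown:
            raise FormatError(f"{path}: unknown cell_type label(s): {sorted(unknown)}")
        out["cell_type"] = ct
    else:
        out["cell_type"] = ""
    return out


def _config_header(config_echo: dict | None) -> str:
    if not config_echo:
        return ""
    blob = json.dumps(config_echo, sort_keys=True, default=str)
    return f"# villustat config: {blob}\n"


def write_table(df: pd.DataFrame, path, config_echo: dict | None = None) -> None:
    """Write any result table as TSV with an optional config-echo header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_config_header(config_echo))
        df.to_csv(fh, sep="\t", index=False)


def write_spot_table(spots: pd.DataFrame, path, config_echo: dict | None = None) -> None:
    write_table(spots[["spot_id", "x_um", "y_um", "compartment", "cell_type"]],
                path, config_echo)


def read_counts(directory) -> ad.AnnData:
    """Read a count matrix from ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``.

    Orientation: rows = spots/cells (barcodes), columns = genes (features).
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    try:
        X = scipy.io.mmread(mtx)
    except Exception as e:  # scipy raises ValueError on bad headers/entries
        raise FormatError(f"{mtx}: invalid MatrixMarket file: {e}") from e
    X = sp.csr_matrix(X)
    if (X.data < 0).any():
        raise FormatError(f"{mtx}: negative counts")
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    if len(barcodes) != X.shape[0] or len(features) != X.shape[1]:
        raise FormatError(
            f"{mtx}: dimensions {X.shape} do not match barcodes "
            f"({len(barcodes)}) / features ({len(features)})"
        )
    if barcodes.duplicated().any() or features.duplicated().any():
        raise FormatError(f"{directory}: duplicate barcodes or features")
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )
    adata.uns["norm_state"] = "raw"
    return adata


def write_counts(counts: ad.AnnData, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(counts.X)
    if counts.uns.get("norm_state") == "raw":
        X = X.astype(np.int64)
    scipy.io.mmwrite(directory / "matrix.mtx", X)
    pd.Series(counts.obs_names).to_csv(directory / "barcodes.tsv",
                                       sep="\t", index=False, header=False)
    pd.Series(counts.var_names).to_csv(directory / "features.tsv",
                                       sep="\t", index=False, header=False)


def read_signatures(path) -> list[GeneSignature]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    A line with no genes is rejected with its line number; duplicate signature
    names are errors.
    """
    sigs: list[GeneSignature] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                raise FormatError(f"{path}: line {lineno}: GMT entry has no genes")
            name = fields[0].strip()
            if not name:
                raise FormatError(f"{path}: line {lineno}: empty signature name")
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate signature {name!r}")
            seen.add(name)
            genes = [g.strip() for g in fields[2:] if g.strip()]
            sigs.append(GeneSignature.from_iterable(name, genes))
    if not sigs:
        raise FormatError(f"{path}: no signatures found")
    return sigs


def write_signatures(sigs, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, "villustat", *sorted(sig.genes)]) + "\n")


def read_clonotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ("cell_id", "clonotype_id", "subset", "sample"), path)
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].head(5).tolist()
        raise FormatError(f"{path}: duplicate cell_ids: {dups}")
    if (df["clonotype_id"] == "").any():
        line = df.index[df["clonotype_id"] == ""][0] + 2
        raise FormatError(f"{path}: empty clonotype_id on line {line}")
    return df[["cell_id", "clonotype_id", "subset", "sample"]].copy()


def read_composition(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ("cell_id", "sample", "group", "subset"), path)
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].head(5).tolist()
        raise FormatError(f"{path}: duplicate cell_ids: {dups}")
    return df[["cell_id", "sample", "group", "subset"]].copy()


def write_roe(roe: RoeMatrix, tsv_path, json_path=None,
              config_echo: dict | None = None) -> None:
    """Ro/e grid as TSV plus an optional JSON record retaining observed/expected."""
    out = roe.roe.copy()
    out.index.name = "group"
    write_table(out.reset_index(), tsv_path, config_echo)
    if json_path is not None:
        doc = {
            "roe": {g: {s: _jsonable(v) for s, v in row.items()}
                    for g, row in roe.roe.iterrows()},
            "observed": {g: dict(row) for g, row in roe.observed.iterrows()},
            "expected": {g: dict(row) for g, row in roe.expected.iterrows()},
        }
        Path(json_path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def _jsonable(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)
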