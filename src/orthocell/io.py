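"""Readers and writers for the plain-text interchange formats.

Expression matrices travel either as MatrixMarket sparse triplets with
sidecar row/column TSVs (features x cells, the 10x-style layout) or as dense
TSVs (features in rows, cells in columns).  Cell annotations are TSVs with
``cell_id`` and ``cell_type`` columns.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .exceptions import ValidationError

__all__ = [
    "read_cell_annotations",
    "read_expression_mtx",
    "read_expression_tsv",
    "write_expression_mtx",
]


def read_cell_annotations(path) -> pd.Series:
    """Read a cell annotation TSV (columns ``cell_id``, ``cell_type``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("cell_id", "cell_type"):
        if col not in df.columns:
            raise ValidationError(f"annotation file {path} lacks column {col!r}")
    if df["cell_id"].duplicated().any():
        raise ValidationError(f"duplicate cell ids in {path}")
    return df.set_index("cell_id")["cell_type"]


def _attach_cell_types(adata: ad.AnnData, cell_types: pd.Series) -> ad.AnnData:
    missing = adata.obs_names.difference(cell_types.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} cells lack a cell-type annotation "
            f"(e.g. {list(missing[:3])})"
        )
    adata.obs["cell_type"] = cell_types.reindex(adata.obs_names).astype(str).values
    return adata


def read_expression_mtx(matrix_path, features_path, cells_path,
                        annotations_path=None) -> ad.AnnData:
    """Read a features x cells MatrixMarket matrix with sidecar TSVs.

    The sidecars are one-id-per-line TSVs (first column used).  Returns an
    AnnData with cells as obs; if ``annotations_path`` is given, a
    ``cell_type`` obs column is attached.
    """
    X = sp.csr_matrix(sio.mmread(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str,
                           comment="#")[0]
    cells = pd.read_csv(cells_path, sep="\t", header=None, dtype=str,
                        comment="#")[0]
    if X.shape != (len(features), len(cells)):
        raise ValidationError(
            f"matrix shape {X.shape} does not match {len(features)} features "
            f"x {len(cells)} cells"
        )
    adata = ad.AnnData(
        X=sp.csr_matrix(X.T),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="feature")),
    )
    if annotations_path is not None:
        _attach_cell_types(adata, read_cell_annotations(annotations_path))
    return adata


def read_expression_tsv(path, annotations_path=None) -> ad.AnnData:
    """Read a dense genes x cells TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    adata = ad.AnnData(
        X=df.to_numpy(dtype=float).T,
        obs=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.index.astype(str), name="feature")),
    )
    if annotations_path is not None:
        _attach_cell_types(adata, read_cell_annotations(annotations_path))
    return adata


def write_expression_mtx(adata: ad.AnnData, directory, prefix: str = "matrix",
                         header: str | None = None) -> dict[str, Path]:
    """Write an AnnData as features x cells MTX + sidecar TSVs.

    Returns the paths written: matrix, features, cells, and (when a
    ``cell_type`` obs column exists) annotations.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    paths = {
        "matrix": directory / f"{prefix}.mtx",
        "features": directory / f"{prefix}.features.tsv",
        "cells": directory / f"{prefix}.cells.tsv",
    }
    sio.mmwrite(str(paths["matrix"]), mat, comment=header or "")
    paths["features"].write_text("\n".join(adata.var_names) + "\n")
    paths["cells"].write_text("\n".join(adata.obs_names) + "\n")
    if "cell_type" in adata.obs:
        paths["annotations"] = directory / f"{prefix}.annotations.tsv"
        pd.DataFrame(
            {"cell_id": adata.obs_names, "cell_type": adata.obs["cell_type"].values}
        ).to_csv(paths["annotations"], sep="\t", index=False)
    return paths
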