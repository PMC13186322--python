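"""Cell-type expression profiles, fold-change matrices, and activity calls.

The comparison unit downstream is not the single cell but the cell type.
This module turns an ortho-gene matrix into

1. an optional *metacell* matrix (sums of ``group_size`` same-type cells,
   reducing sparsity before averaging),
2. a depth-normalized geometric-mean profile per (OG, cell type),
3. a regularized fold-change (FC) matrix — each cell type's mean relative to
   the median across that species' cell types, with a pseudocount guarding
   against zeros — and
4. a binary activity vector: an OG is *active* (state 1) if its FC strictly
   exceeds a threshold (default 1.1) in any focal cell type.

Profiles and FC matrices are pandas DataFrames with OGs as rows and cell
types as columns; the pseudocount used is recorded in ``.attrs``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "make_metacells",
    "celltype_geometric_mean",
    "fold_change",
    "binarize_activity",
]

DEFAULT_PSEUDOCOUNT = 0.05
DEFAULT_FC_THRESHOLD = 1.1
DEFAULT_METACELL_SIZE = 10


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def make_metacells(expr: ad.AnnData, group_size: int = DEFAULT_METACELL_SIZE,
                   seed: int = 0) -> ad.AnnData:
    """Aggregate same-type cells into metacells of exactly ``group_size``.

    Cells of each type are shuffled (seeded) and partitioned into consecutive
    groups; each metacell is the element-wise sum of its members and inherits
    the type label.  Leftover cells that cannot fill a group are dropped and
    logged; a type with fewer than ``group_size`` cells yields no metacell
    and triggers a warning.
    """
    if group_size < 1:
        raise ConfigurationError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    X = _dense(expr.X)
    types = expr.obs["cell_type"].astype(str).values

    blocks, labels, names, members = [], [], [], []
    n_dropped = 0
    for ct in pd.unique(types):
        idx = np.flatnonzero(types == ct)
        idx = rng.permutation(idx)
        n_groups = len(idx) // group_size
        if n_groups == 0:
            warnings.warn(
                f"cell type {ct!r} has {len(idx)} < {group_size} cells; "
                "no metacell produced"
            )
        n_dropped += len(idx) - n_groups * group_size
        for k in range(n_groups):
            grp = idx[k * group_size:(k + 1) * group_size]
            blocks.append(X[grp].sum(axis=0))
            labels.append(ct)
            names.append(f"{ct}|mc{k}")
            members.append(tuple(expr.obs_names[grp]))
    if n_dropped:
        logger.info("metacell grouping dropped %d leftover cells", n_dropped)
    if not blocks:
        out = ad.AnnData(
            X=np.zeros((0, expr.n_vars)),
            obs=pd.DataFrame({"cell_type": pd.Series([], dtype=str)}),
            var=expr.var.copy(),
        )
    else:
        out = ad.AnnData(
            X=np.vstack(blocks),
            obs=pd.DataFrame({"cell_type": labels},
                             index=pd.Index(names, name="cell_id")),
            var=expr.var.copy(),
        )
        out.uns["metacell_members"] = {n: list(m) for n, m in zip(names, members)}
    out.uns.update(
        {k: v for k, v in expr.uns.items() if k != "metacell_members"}
    )
    out.uns["metacell_size"] = int(group_size)
    return out


def celltype_geometric_mean(expr: ad.AnnData,
                            epsilon: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Depth-normalized geometric-mean expression per (OG, cell type).

    Each cell's counts are first scaled by (median total counts over all
    cells) / (that cell's total counts) so that library-size differences
    cancel; cells with zero total counts are excluded with a warning.  The
    per-type summary is then ``exp(mean(log(scaled + epsilon))) - epsilon``,
    floored at zero — the geometric mean with a small log-offset so that the
    ubiquitous zeros remain finite.
    """
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be > 0")
    X = _dense(expr.X).astype(float)
    totals = X.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} cells with zero total counts"
        )
    X = X[keep]
    totals = totals[keep]
    types = expr.obs["cell_type"].astype(str).values[keep]
    scaled = X * (np.median(totals) / totals)[:, None]

    cols = {}
    for ct in pd.unique(types):
        logs = np.log(scaled[types == ct] + epsilon)
        cols[ct] = np.maximum(np.exp(logs.mean(axis=0)) - epsilon, 0.0)
    profile = pd.DataFrame(cols, index=pd.Index(expr.var_names, name="orthogroup"))
    profile.attrs["epsilon"] = float(epsilon)
    return profile


def fold_change(profile: pd.DataFrame,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Regularized fold change of each cell type against the per-OG median.

    ``fc(o, t) = (mean(o, t) + p) / (median_t' mean(o, t') + p)`` with
    pseudocount ``p`` (default 0.05).  The median over cell types uses the
    standard midpoint convention for even counts; the pseudocount keeps every
    entry strictly positive.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    med = profile.median(axis=1)
    fc = (profile + pseudocount).div(med + pseudocount, axis=0)
    fc.attrs["pseudocount"] = float(pseudocount)
    return fc


def binarize_activity(fc: pd.DataFrame, focal_cell_types: Sequence[str],
                      threshold: float = DEFAULT_FC_THRESHOLD) -> pd.Series:
    """Binary OG activity: 1 iff FC strictly exceeds ``threshold`` in any focal type.

    The strict ``>`` means an FC of exactly 1.1 is inactive.  Unknown focal
    labels raise :class:`~orthocell.exceptions.ConfigurationError`.
    """
    focal = list(focal_cell_types)
    if not focal:
        raise ConfigurationError("focal_cell_types must be non-empty")
    unknown = [t for t in focal if t not in fc.columns]
    if unknown:
        raise ConfigurationError(
            f"unknown focal cell types {unknown} (known: {list(fc.columns)})"
        )
    state = (fc[focal].max(axis=1) > threshold).astype(int)
    state.name = "state"
    state.attrs["focal_cell_types"] = tuple(focal)
    state.attrs["threshold"] = float(threshold)
    return state
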