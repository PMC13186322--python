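"""Shared orthologous markers and multi-species conserved-marker intersections.

Once two cell types are linked across species, the OGs driving the link are
called as *shared markers*: an OG qualifies when its fold change strictly
exceeds a minimum (default 1.1) in the linked type of **both** species and a
Wilcoxon rank-sum test of its per-cell expression (linked-type cells vs. all
other cells) is significant after Benjamini-Hochberg correction in both
species.  Per-species marker sets are then intersected across species with
UpSet semantics — every OG counted in exactly the combination of sets that
contain it — and the all-species core set is the plain intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .orthomap import OrthogroupTable

logger = logging.getLogger(__name__)

__all__ = [
    "rank_sum_test",
    "ingroup_outgroup_test",
    "group_pvalues",
    "shared_markers",
    "IntersectionReport",
    "marker_intersections",
    "conserved_deg_orthogroups",
]

DEFAULT_FC_MIN = 1.1
DEFAULT_FDR = 0.05
_EXACT_MAX_PRODUCT = 400


def rank_sum_test(ingroup: np.ndarray, outgroup: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution when ``n * m <= 400`` and the pooled
    sample has no ties, otherwise the normal approximation with tie
    correction.  A fully tied sample carries no rank information and returns
    p = 1.
    """
    x = np.asarray(ingroup, dtype=float)
    y = np.asarray(outgroup, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size * y.size <= _EXACT_MAX_PRODUCT and no_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def ingroup_outgroup_test(expr: ad.AnnData, og: str,
                          ingroup_types: Sequence[str]) -> float:
    """Rank-sum p-value for one OG: ingroup-type cells vs. all other cells."""
    if og not in expr.var_names:
        raise ValidationError(f"unknown orthogroup {og!r}")
    types = expr.obs["cell_type"].astype(str).values
    mask = np.isin(types, list(ingroup_types))
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValidationError("need >= 2 cells in both ingroup and outgroup")
    col = _dense(expr[:, og].X).ravel()
    return rank_sum_test(col[mask], col[~mask])


def group_pvalues(expr: ad.AnnData, ingroup_types: Sequence[str]) -> pd.Series:
    """Rank-sum p-values for every OG, ingroup-type cells vs. the rest.

    Vectorized over OGs with the normal approximation (appropriate at
    pipeline scale, where the product of group sizes far exceeds the exact
    regime); degenerate all-tied OGs get p = 1.
    """
    types = expr.obs["cell_type"].astype(str).values
    mask = np.isin(types, list(ingroup_types))
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValidationError("need >= 2 cells in both ingroup and outgroup")
    X = _dense(expr.X).astype(float)
    x = X[mask].T   # (n_ogs, n_in)
    y = X[~mask].T  # (n_ogs, n_out)
    if x.shape[1] * y.shape[1] <= _EXACT_MAX_PRODUCT:
        pvals = np.array([rank_sum_test(xi, yi) for xi, yi in zip(x, y)])
    else:
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", axis=1)
            pvals = np.asarray(res.pvalue, dtype=float)
        constant = np.all(np.concatenate([x, y], axis=1)
                          == x[:, :1], axis=1)
        pvals[constant | np.isnan(pvals)] = 1.0
    return pd.Series(pvals, index=expr.var_names, name="p_value")


def shared_markers(fc_a: pd.DataFrame, fc_b: pd.DataFrame,
                   link: tuple[str, str],
                   expr_a: ad.AnnData, expr_b: ad.AnnData,
                   fc_min: float = DEFAULT_FC_MIN,
                   fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Shared orthologous markers for one linked cell-type pair.

    ``link`` is ``(type_a, type_b)``, the linked cell types in the two
    species.  An OG is shared when its FC strictly exceeds ``fc_min`` in the
    linked type of both species and its BH-adjusted ingroup/outgroup p-value
    (adjustment within species over all tested OGs) is below ``fdr`` in both.
    """
    type_a, type_b = link
    a, b = fc_a.align(fc_b, join="inner", axis=0)
    p_a = group_pvalues(expr_a, [type_a]).reindex(a.index)
    p_b = group_pvalues(expr_b, [type_b]).reindex(b.index)
    q_a = pd.Series(multipletests(p_a.to_numpy(), method="fdr_bh")[1],
                    index=a.index)
    q_b = pd.Series(multipletests(p_b.to_numpy(), method="fdr_bh")[1],
                    index=b.index)
    out = pd.DataFrame(
        {
            "og": a.index,
            "type_a": type_a,
            "type_b": type_b,
            "fc_a": a[type_a].to_numpy(),
            "fc_b": b[type_b].to_numpy(),
            "p_value_a": p_a.to_numpy(),
            "p_value_b": p_b.to_numpy(),
            "q_value_a": q_a.to_numpy(),
            "q_value_b": q_b.to_numpy(),
        }
    ).reset_index(drop=True)
    out["shared"] = (
        (out["fc_a"] > fc_min)
        & (out["fc_b"] > fc_min)
        & (out["q_value_a"] < fdr)
        & (out["q_value_b"] < fdr)
    )
    return out


@dataclass(frozen=True)
class IntersectionReport:
    """UpSet-style intersection of per-species marker OG sets.

    ``combinations`` maps each non-empty species combination (a frozenset of
    species names) to the OGs found in exactly those species' sets;
    ``core_set`` is the intersection across all species.  The combination
    sizes partition the union, so they sum to its size.
    """

    species: tuple[str, ...]
    combinations: Mapping[frozenset, frozenset]
    core_set: frozenset

    def sizes(self) -> pd.DataFrame:
        rows = [
            {"combination": "&".join(sorted(k)), "degree": len(k),
             "size": len(v)}
            for k, v in self.combinations.items()
        ]
        return (pd.DataFrame(rows, columns=["combination", "degree", "size"])
                .sort_values(["degree", "combination"])
                .reset_index(drop=True))


def marker_intersections(marker_sets: Mapping[str, Iterable[str]]
                         ) -> IntersectionReport:
    """Exact membership-pattern tally of marker sets across species."""
    if len(marker_sets) < 2:
        raise ValidationError("need marker sets for >= 2 species")
    sets = {s: frozenset(v) for s, v in marker_sets.items()}
    union = frozenset().union(*sets.values())
    combos: dict[frozenset, set] = {}
    for og in union:
        pattern = frozenset(s for s, v in sets.items() if og in v)
        combos.setdefault(pattern, set()).add(og)
    core = frozenset.intersection(*sets.values())
    return IntersectionReport(
        species=tuple(sets),
        combinations={k: frozenset(v) for k, v in combos.items()},
        core_set=core,
    )


def conserved_deg_orthogroups(deg_lists: Mapping[str, Iterable[str]],
                              table: OrthogroupTable,
                              min_species: int) -> frozenset:
    """OGs containing at least one DEG in at least ``min_species`` species.

    DEG genes that map to no OG of the table are logged and ignored.
    """
    counts: dict[str, int] = {}
    for sp_name, genes in deg_lists.items():
        gene_to_og = table.genes_of(sp_name)
        hit_ogs = set()
        n_unmapped = 0
        for g in set(genes):
            og = gene_to_og.get(g)
            if og is None:
                n_unmapped += 1
            else:
                hit_ogs.add(og)
        if n_unmapped:
            logger.info("%d DEGs of %s map to no orthogroup", n_unmapped, sp_name)
        for og in hit_ogs:
            counts[og] = counts.get(og, 0) + 1
    return frozenset(og for og, n in counts.items() if n >= min_species)
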