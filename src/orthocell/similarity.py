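"""Cross-species cell-type similarity from Kullback-Leibler divergence.

Two cell types from different species are compared through their fold-change
profiles over the shared orthogroup universe: each FC vector is normalized to
a probability distribution and the (by default symmetrized) KLD between the
two distributions measures transcriptional distance.  Within every species
pair the divergences are inverted to similarity scores in [0, 1] by min–max
scaling, and the links above an empirical percentile cutoff (default the
88th, i.e. the top 12% of connections) are retained as putative homologous
cell-type pairs.

Because the percentile is taken over the similarity scores within a species
pair, any strictly decreasing inversion of KLD yields the same retained link
set; min–max scaling is purely presentational.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .exceptions import ValidationError

__all__ = [
    "joint_profiles",
    "kl_divergence",
    "symmetric_divergence",
    "pairwise_divergences",
    "link_graph",
    "similarity_scores",
    "threshold_links",
]

DEFAULT_PERCENTILE = 88.0


def joint_profiles(fc_a: pd.DataFrame, fc_b: pd.DataFrame):
    """Align two FC profiles on their common OGs, identical row order.

    Rows are restricted to the intersection of the OG indices (in the first
    profile's order); an empty intersection is an error.
    """
    common = fc_a.index.intersection(fc_b.index, sort=False)
    if len(common) == 0:
        raise ValidationError("profiles share no orthogroups")
    return fc_a.loc[common], fc_b.loc[common]


def _as_distribution(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("expected a 1-D vector of length >= 2")
    if np.any(arr <= 0):
        raise ValidationError(
            "non-positive entry in FC vector; pseudocount regularization "
            "should guarantee positivity"
        )
    return arr / arr.sum()


def kl_divergence(p_vec, q_vec) -> float:
    """Directed KLD in nats between two positive vectors.

    Both vectors are normalized to sum to one; returns
    ``sum_i P_i ln(P_i / Q_i)`` which is non-negative (Gibbs' inequality).
    """
    p = _as_distribution(p_vec)
    q = _as_distribution(q_vec)
    if p.size != q.size:
        raise ValidationError("vectors differ in length")
    return float(rel_entr(p, q).sum())


def symmetric_divergence(p_vec, q_vec) -> float:
    """Arithmetic mean of the two directed KLDs (symmetric by construction)."""
    return 0.5 * (kl_divergence(p_vec, q_vec) + kl_divergence(q_vec, p_vec))


def pairwise_divergences(fc_a: pd.DataFrame, fc_b: pd.DataFrame,
                         symmetric: bool = True) -> pd.DataFrame:
    """KLD between every cell-type pair of two species' FC profiles.

    Profiles are first aligned on their common OGs.  Returns a long-format
    frame with columns ``type_a``, ``type_b``, ``kld``.
    """
    a, b = joint_profiles(fc_a, fc_b)
    div = symmetric_divergence if symmetric else kl_divergence
    rows = [
        (ta, tb, div(a[ta].to_numpy(), b[tb].to_numpy()))
        for ta in a.columns
        for tb in b.columns
    ]
    return pd.DataFrame(rows, columns=["type_a", "type_b", "kld"])


def similarity_scores(klds: pd.DataFrame) -> pd.DataFrame:
    """Invert divergences into similarity scores within each species pair.

    ``similarity = 1 - kld / max(kld)`` per (species_a, species_b) group so
    the least similar pair scores 0 and identical profiles score 1; when all
    divergences in a group are equal (including the single-pair case) every
    similarity is 1.  Any strictly decreasing inversion produces the same
    percentile-retained link set.
    """
    out = klds.copy()

    def invert(g: pd.Series) -> pd.Series:
        m = g.max()
        if m <= 0 or g.min() == m:  # all divergences equal (incl. single pair)
            return pd.Series(1.0, index=g.index)
        return 1.0 - g / m

    if {"species_a", "species_b"}.issubset(out.columns):
        out["similarity"] = out.groupby(["species_a", "species_b"],
                                        sort=False)["kld"].transform(invert)
    else:
        out["similarity"] = invert(out["kld"])
    return out


def threshold_links(graph: pd.DataFrame,
                    percentile: float = DEFAULT_PERCENTILE,
                    per_pair: bool = True) -> pd.DataFrame:
    """Flag links whose similarity reaches the empirical percentile cutoff.

    The cutoff is the linear-interpolation percentile of the similarity
    scores, computed within each species pair by default (``per_pair=False``
    pools all pairs); ties at the cutoff are retained (``>=``).
    """
    if not 0 <= percentile <= 100:
        raise ValidationError("percentile must be in [0, 100]")
    out = graph.copy()
    group_cols = ["species_a", "species_b"]
    if per_pair and set(group_cols).issubset(out.columns):
        cutoff = out.groupby(group_cols, sort=False)["similarity"].transform(
            lambda s: np.percentile(s.to_numpy(), percentile)
        )
    else:
        cutoff = np.percentile(out["similarity"].to_numpy(), percentile)
    out["retained"] = out["similarity"] >= cutoff
    out.attrs["percentile"] = float(percentile)
    out.attrs["per_pair"] = bool(per_pair)
    return out


def link_graph(fc_by_species: Mapping[str, pd.DataFrame],
               percentile: float = DEFAULT_PERCENTILE,
               symmetric: bool = True,
               per_pair: bool = True) -> pd.DataFrame:
    """Full cross-species cell-type link graph over all species pairs.

    Computes divergences for every unordered species pair, inverts them to
    similarities and applies the percentile threshold.  Columns:
    ``species_a, type_a, species_b, type_b, kld, similarity, retained``.
    """
    frames = []
    for sa, sb in itertools.combinations(fc_by_species, 2):
        d = pairwise_divergences(fc_by_species[sa], fc_by_species[sb],
                                 symmetric=symmetric)
        d.insert(0, "species_a", sa)
        d.insert(2, "species_b", sb)
        frames.append(d)
    if not frames:
        raise ValidationError("need at least two species")
    graph = pd.concat(frames, ignore_index=True)
    graph = similarity_scores(graph)
    return threshold_links(graph, percentile=percentile, per_pair=per_pair)
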