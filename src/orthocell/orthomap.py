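"""Orthogroup tables and collapsing gene-level counts into ortho-gene matrices.

Cross-species expression comparison needs a common feature space.  That space
is the orthogroup (OG): a set of genes, across species, descended from a
single ancestral gene.  This module reads OrthoFinder-style ``Orthogroups.tsv``
tables, restricts them to OGs represented in every species of interest, and
collapses each species' gene x cell count matrix into an *ortho-gene* matrix
by summing the counts of all within-species paralogs of each OG.

Expression matrices are carried as :class:`anndata.AnnData` objects with cells
as observations, genes (or OGs) as variables, and a ``cell_type`` column in
``.obs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "OrthogroupTable",
    "read_orthogroups",
    "filter_universal_orthogroups",
    "aggregate_to_orthogenes",
]


@dataclass(frozen=True)
class OrthogroupTable:
    """Orthogroup membership: OG id -> species -> member gene ids.

    Within one species a gene may belong to at most one OG; membership lists
    carry no duplicates.  Both invariants are checked at construction.
    """

    og_ids: tuple[str, ...]
    membership: Mapping[str, Mapping[str, tuple[str, ...]]]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("species list is empty")
        for sp_name in self.species:
            seen: dict[str, str] = {}
            for og in self.og_ids:
                genes = self.membership[og].get(sp_name, ())
                if len(set(genes)) != len(genes):
                    raise ValidationError(
                        f"duplicate gene within {og} for species {sp_name!r}"
                    )
                for g in genes:
                    if g in seen:
                        raise ValidationError(
                            f"gene {g!r} of species {sp_name!r} appears in both "
                            f"{seen[g]} and {og}"
                        )
                    seen[g] = og

    def __len__(self) -> int:
        return len(self.og_ids)

    def genes_of(self, species: str) -> dict[str, str]:
        """Mapping gene id -> OG id for one species."""
        if species not in self.species:
            raise ConfigurationError(f"unknown species {species!r}")
        out: dict[str, str] = {}
        for og in self.og_ids:
            for g in self.membership[og].get(species, ()):
                out[g] = og
        return out

    def n_genes(self, species: str) -> int:
        return len(self.genes_of(species))


def _parse_gene_list(cell: object) -> tuple[str, ...]:
    # OrthoFinder emits ", "-separated lists; trim whitespace around commas.
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(g.strip() for g in text.split(",") if g.strip())


def read_orthogroups(path, species_names: Sequence[str]) -> OrthogroupTable:
    """Read an ``Orthogroups.tsv``-dialect table for the requested species.

    The file is tab-separated with the OG id in the first column and one
    comma-separated gene-list column per species.  Empty cells yield empty
    member lists.  A missing species column raises
    :class:`~orthocell.exceptions.ConfigurationError`; a gene assigned to two
    OGs raises :class:`~orthocell.exceptions.ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    for sp_name in species_names:
        if sp_name not in df.columns:
            raise ConfigurationError(
                f"species column {sp_name!r} not found in {path} "
                f"(available: {list(df.columns[1:])})"
            )
    og_ids = tuple(df[id_col].astype(str))
    if len(set(og_ids)) != len(og_ids):
        raise ValidationError(f"duplicate orthogroup ids in {path}")
    membership = {
        og: {
            sp_name: _parse_gene_list(df.iloc[i][sp_name])
            for sp_name in species_names
        }
        for i, og in enumerate(og_ids)
    }
    return OrthogroupTable(og_ids=og_ids, membership=membership,
                           species=tuple(species_names))


def filter_universal_orthogroups(
    table: OrthogroupTable, required_species: Sequence[str]
) -> OrthogroupTable:
    """Keep only OGs with at least one member gene in every required species.

    With an empty ``required_species`` the condition is vacuous and every OG
    is retained.  Order is preserved and the operation is idempotent.
    """
    for sp_name in required_species:
        if sp_name not in table.species:
            raise ConfigurationError(f"unknown species {sp_name!r}")
    kept = tuple(
        og
        for og in table.og_ids
        if all(len(table.membership[og].get(s, ())) > 0 for s in required_species)
    )
    if not kept:
        logger.warning("no orthogroup is present in all required species")
    membership = {og: table.membership[og] for og in kept}
    return OrthogroupTable(og_ids=kept, membership=membership,
                           species=table.species)


def aggregate_to_orthogenes(
    expr: ad.AnnData, table: OrthogroupTable, species: str
) -> ad.AnnData:
    """Collapse a gene-level count matrix to an OG x cell ortho-gene matrix.

    Counts of all member genes of an OG present in ``expr`` are summed per
    cell.  Genes listed in the table but absent from the matrix are dropped
    (their number is logged); OGs with no present gene keep an all-zero row
    and are flagged in ``.var["no_gene_present"]`` so matrices from different
    species stay aligned on one OG universe.

    Returns an AnnData with cells as obs (``cell_type`` copied over) and OGs
    as var, in the table's OG order.
    """
    if species not in table.species:
        raise ConfigurationError(f"unknown species {species!r}")
    if "cell_type" not in expr.obs:
        raise ValidationError("expression matrix lacks a 'cell_type' annotation")
    gene_to_og = table.genes_of(species)
    og_index = {og: j for j, og in enumerate(table.og_ids)}
    var_names = pd.Index(expr.var_names)

    rows, cols = [], []
    n_listed = len(gene_to_og)
    for g, og in gene_to_og.items():
        i = var_names.get_indexer([g])[0]
        if i >= 0:
            rows.append(i)
            cols.append(og_index[og])
    n_dropped = n_listed - len(rows)
    if n_dropped:
        logger.info(
            "%d of %d orthogroup-listed genes absent from the %s matrix; dropped",
            n_dropped, n_listed, species,
        )
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(expr.n_vars, len(table.og_ids)),
    )
    X = expr.X if sp.issparse(expr.X) else np.asarray(expr.X)
    collapsed = X @ indicator
    if sp.issparse(collapsed):
        collapsed = sp.csr_matrix(collapsed)

    n_present = np.zeros(len(table.og_ids), dtype=int)
    np.add.at(n_present, cols, 1)
    var = pd.DataFrame(
        {
            "n_genes_present": n_present,
            "no_gene_present": n_present == 0,
        },
        index=pd.Index(table.og_ids, name="orthogroup"),
    )
    out = ad.AnnData(X=collapsed, obs=expr.obs.copy(), var=var)
    out.uns["species"] = species
    out.uns["n_genes_dropped"] = int(n_dropped)
    return out
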