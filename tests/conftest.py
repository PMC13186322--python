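import anndata as ad
import numpy as np
import pandas as pd
import pytest

from orthocell import OrthogroupTable


@pytest.fixture
def og_tsv(tmp_path):
    """Write a small Orthogroups.tsv and return its path."""

    def write(rows, species=("spA", "spB")):
        lines = ["Orthogroup\t" + "\t".join(species)]
        lines += ["\t".join(r) for r in rows]
        path = tmp_path / "Orthogroups.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture
def small_table():
    return OrthogroupTable(
        og_ids=("OG1", "OG2", "OG3"),
        membership={
            "OG1": {"spA": ("g1", "g2"), "spB": ("h1",)},
            "OG2": {"spA": ("g3",), "spB": ()},
            "OG3": {"spA": (), "spB": ("h2", "h3")},
        },
        species=("spA", "spB"),
    )


def make_adata(counts, genes=None, cell_types=None):
    """Dense genes x cells array -> AnnData (cells x genes) with labels."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_cells = counts.shape
    genes = list(genes) if genes is not None else [f"g{i+1}" for i in range(n_genes)]
    cell_types = (list(cell_types) if cell_types is not None
                  else ["T1"] * n_cells)
    return ad.AnnData(
        X=counts.T.copy(),
        obs=pd.DataFrame({"cell_type": cell_types},
                         index=[f"c{i+1}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )


@pytest.fixture
def adata_factory():
    return make_adata
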