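"""Synthetic multi-species single-cell panels with known ground truth.

The generator emulates the statistical structure the comparison pipeline
assumes in real data:

* several species, each with multiple cell types and negative-binomial
  counts with per-cell library-size variation;
* species-specific paralog expansion — each OG expands to ``1 + Poisson``
  genes whose expected expression splits the OG total by a symmetric
  Dirichlet, so OG-level sums are invariant to paralog count;
* one designated *phagocyte-like* cell type per species carrying a planted
  conserved up-regulated module (the shared "phagocyte program");
* a disjoint lineage-specific module up-regulated in one species only;
* small species-specific marker modules for every cell type, so cell types
  are transcriptionally distinguishable (as real annotated clusters are);
* a planted binary gain/loss trait history on a dated species tree.

All randomness flows from a single seed through one
:class:`numpy.random.Generator`; equal seeds give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import anndata as ad
import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .orthomap import OrthogroupTable
from . import io as _io
from .trait_evolution import read_newick, node_name

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedPanel",
    "simulate_panel",
    "simulate_trait_history",
    "write_fixture_set",
    "read_fixture_set",
    "default_species_tree",
    "bilaterian_scale_tree",
]


def default_species_tree(species: tuple[str, ...]) -> str:
    """A caterpillar tree over the panel species with ~vertebrate-scale depths."""
    if len(species) == 1:
        return f"({species[0]}:100);"
    newick = species[0]
    depth = 100.0
    for sp_name in species[1:]:
        newick = f"({newick}:{depth:g},{sp_name}:{depth + 100:g})"
        depth += 100.0
    return newick + ";"


def bilaterian_scale_tree() -> str:
    """A 9-tip rooted tree with Myr-scale branch lengths.

    Mirrors the shape of a dated bilaterian species tree (three successive
    invertebrate outgroups, then a vertebrate ladder); useful as a realistic
    backbone for trait-history simulations.
    """
    return (
        "((oyster:550,shrimp:550):50,"
        "(tunicate:520,"
        "(lamprey:460,"
        "(shark:430,"
        "(teleost:400,"
        "(turtle:320,"
        "(monkey:90,human:90):230):80):30):30):60):80);"
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel; defaults are the study conditions."""

    n_species: int = 3
    cell_types_per_species: int = 4
    cells_per_type: int = 200
    n_ogs: int = 300
    planted_module_size: int = 20
    planted_fold: float = 4.0
    type_marker_size: int = 10
    type_marker_fold: float = 3.0
    paralog_rate: float = 0.5
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    depth_variation: float = 0.25
    tree: str | None = None
    trait_change_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.cell_types_per_species,
               self.cells_per_type, self.n_ogs) < 1:
            raise ConfigurationError("all sizes must be >= 1")
        if self.planted_fold <= 1:
            raise ConfigurationError("planted_fold must be > 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.planted_module_size * 2 > self.n_ogs:
            raise ConfigurationError(
                "planted and lineage modules together exceed n_ogs"
            )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))


@dataclass
class GroundTruth:
    """Everything the generator planted, for checking recovery."""

    module_ogs: tuple[str, ...]
    lineage_ogs: tuple[str, ...]
    lineage_species: str
    lineage_type: str
    homolog_map: dict[str, str]              # species -> phagocyte-like type
    type_markers: dict[str, dict[str, tuple[str, ...]]]
    gene_to_og: dict[str, dict[str, str]]    # species -> gene -> og
    tip_states: pd.DataFrame | None = None   # species x OG binary
    node_states: pd.DataFrame | None = None  # all tree nodes x OG binary
    edge_transitions: pd.DataFrame | None = None


@dataclass
class SimulatedPanel:
    config: SimulationConfig
    expression: dict[str, ad.AnnData]        # species -> cells x genes
    orthogroups: OrthogroupTable
    tree: str
    truth: GroundTruth


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + mu^2/dispersion."""
    mu = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_trait_history(tree, n_ogs: int, trait_change_prob: float,
                           seed: int | np.random.Generator = 0):
    """Plant a binary gain/loss history for ``n_ogs`` traits on a rooted tree.

    Root states are Bernoulli(0.5); along each branch every trait flips
    independently with probability ``trait_change_prob``.  Returns
    ``(tip_states, node_states, edge_transitions)``: the first two are
    binary DataFrames (rows species / all nodes, columns OG ids), the third
    counts planted gains and losses per branch.
    """
    if not 0 <= trait_change_prob < 0.5:
        raise ConfigurationError("trait_change_prob must be in [0, 0.5)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    ogs = [f"OG{i + 1:04d}" for i in range(n_ogs)]
    states: dict[dendropy.Node, np.ndarray] = {}
    gains, losses, edge_names = [], [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = (rng.random(n_ogs) < 0.5).astype(np.int64)
        else:
            flip = rng.random(n_ogs) < trait_change_prob
            parent = states[node.parent_node]
            states[node] = np.where(flip, 1 - parent, parent).astype(np.int64)
            edge_names.append(node_name(node))
            gains.append(int(((parent == 0) & (states[node] == 1)).sum()))
            losses.append(int(((parent == 1) & (states[node] == 0)).sum()))
    node_states = pd.DataFrame(
        {og: [states[n][j] for n in tree.preorder_node_iter()]
         for j, og in enumerate(ogs)},
        index=pd.Index([node_name(n) for n in tree.preorder_node_iter()],
                       name="node"),
    )
    tip_states = node_states.loc[
        [l.taxon.label for l in tree.leaf_node_iter()]
    ]
    tip_states.index.name = "species"
    edge_transitions = pd.DataFrame(
        {"gains": gains, "losses": losses},
        index=pd.Index(edge_names, name="branch"),
    )
    return tip_states, node_states, edge_transitions


def simulate_panel(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SimulatedPanel:
    """Generate the full multi-species panel with ground truth.

    ``seed`` overrides ``config.seed`` when given.  See the module docstring
    for the generative model.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    species = config.species_names
    og_ids = [f"OG{i + 1:04d}" for i in range(config.n_ogs)]

    # Planted structure: conserved module, lineage module, per-type markers.
    perm = rng.permutation(config.n_ogs)
    module_ogs = tuple(og_ids[i] for i in perm[:config.planted_module_size])
    lineage_ogs = tuple(
        og_ids[i]
        for i in perm[config.planted_module_size:2 * config.planted_module_size]
    )
    background = [og_ids[i] for i in perm[2 * config.planted_module_size:]]
    lineage_species = species[0]
    # The lineage module lives in a non-phagocyte type (when one exists) so
    # the lineage-specific signal is a separate cell identity, not a
    # corruption of the conserved phagocyte program.

    homolog_map = {
        sp_name: f"{sp_name}_c{rng.integers(config.cell_types_per_species) + 1}"
        for sp_name in species
    }
    type_labels = {
        sp_name: [f"{sp_name}_c{j + 1}"
                  for j in range(config.cell_types_per_species)]
        for sp_name in species
    }
    non_phag = [t for t in type_labels[lineage_species]
                if t != homolog_map[lineage_species]]
    lineage_type = non_phag[0] if non_phag else homolog_map[lineage_species]

    # Species-specific marker modules make the non-phagocyte cell types
    # transcriptionally distinct; the phagocyte-like type is distinguished
    # by the planted conserved module itself and gets none.
    type_markers: dict[str, dict[str, tuple[str, ...]]] = {}
    for sp_name in species:
        marked_types = [ct for ct in type_labels[sp_name]
                        if ct != homolog_map[sp_name]]
        n_marked = config.type_marker_size * len(marked_types)
        if n_marked > len(background):
            raise ConfigurationError("not enough background OGs for type markers")
        picks = rng.choice(len(background), size=n_marked, replace=False)
        type_markers[sp_name] = {
            ct: tuple(background[k] for k in
                      picks[j * config.type_marker_size:
                            (j + 1) * config.type_marker_size])
            for j, ct in enumerate(marked_types)
        }
        type_markers[sp_name][homolog_map[sp_name]] = ()

    # Shared OG baseline means (log-normal around nb_mean).
    base_mean = rng.lognormal(np.log(config.nb_mean), 0.5, size=config.n_ogs)
    og_pos = {og: j for j, og in enumerate(og_ids)}
    module_idx = np.array([og_pos[o] for o in module_ogs])
    lineage_idx = np.array([og_pos[o] for o in lineage_ogs])

    expression: dict[str, ad.AnnData] = {}
    gene_to_og: dict[str, dict[str, str]] = {}
    membership = {og: {} for og in og_ids}
    for sp_name in species:
        # Paralog expansion: OG mean splits over 1 + Poisson(rate) genes.
        n_paralogs = 1 + rng.poisson(config.paralog_rate, size=config.n_ogs)
        genes, gene_og_idx, gene_frac = [], [], []
        g2o: dict[str, str] = {}
        for j, og in enumerate(og_ids):
            k = int(n_paralogs[j])
            w = rng.dirichlet(np.ones(k))
            for c in range(k):
                name = f"{sp_name}_g{j + 1:04d}" + (f".{c + 1}" if k > 1 else "")
                genes.append(name)
                gene_og_idx.append(j)
                gene_frac.append(w[c])
                g2o[name] = og
            membership[og][sp_name] = tuple(
                g for g in genes[-k:]
            )
        gene_og_idx = np.asarray(gene_og_idx)
        gene_frac = np.asarray(gene_frac)
        gene_to_og[sp_name] = g2o

        # Per-(OG, type) fold multipliers.
        mult = np.ones((config.n_ogs, config.cell_types_per_species))
        for j, ct in enumerate(type_labels[sp_name]):
            marker_idx = np.array(
                [og_pos[o] for o in type_markers[sp_name][ct]], dtype=int
            )
            mult[marker_idx, j] *= config.type_marker_fold
            if ct == homolog_map[sp_name]:
                mult[module_idx, j] *= config.planted_fold
            if sp_name == lineage_species and ct == lineage_type:
                mult[lineage_idx, j] *= config.planted_fold

        n_cells = config.cells_per_type * config.cell_types_per_species
        cell_types = np.repeat(type_labels[sp_name], config.cells_per_type)
        size_factors = rng.lognormal(0.0, config.depth_variation, size=n_cells)
        type_idx = np.repeat(np.arange(config.cell_types_per_species),
                             config.cells_per_type)
        gene_mean = base_mean[gene_og_idx] * gene_frac          # (n_genes,)
        mu = (gene_mean[:, None]
              * mult[gene_og_idx][:, type_idx]
              * size_factors[None, :])
        counts = _nb_sample(rng, mu, config.nb_dispersion)      # genes x cells
        adata = ad.AnnData(
            X=counts.T.astype(np.float64),
            obs=pd.DataFrame(
                {"cell_type": cell_types},
                index=pd.Index([f"{sp_name}_cell{i + 1}" for i in range(n_cells)],
                               name="cell_id"),
            ),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        adata.uns["species"] = sp_name
        expression[sp_name] = adata

    table = OrthogroupTable(og_ids=tuple(og_ids), membership=membership,
                            species=species)
    tree = config.tree or default_species_tree(species)
    tip_states, node_states, edge_transitions = simulate_trait_history(
        tree, config.n_ogs, config.trait_change_prob, rng
    )
    truth = GroundTruth(
        module_ogs=module_ogs,
        lineage_ogs=lineage_ogs,
        lineage_species=lineage_species,
        lineage_type=lineage_type,
        homolog_map=homolog_map,
        type_markers=type_markers,
        gene_to_og=gene_to_og,
        tip_states=tip_states,
        node_states=node_states,
        edge_transitions=edge_transitions,
    )
    return SimulatedPanel(config=config, expression=expression,
                          orthogroups=table, tree=tree, truth=truth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(panel: SimulatedPanel, directory,
                      force: bool = False) -> Path:
    """Write a panel as plain-text fixtures with a checksummed manifest.

    Emits per-species MTX matrices with sidecar TSVs and annotations, an
    ``Orthogroups.tsv`` table, the Newick tree, the ground truth as JSON/TSV
    and a ``manifest.json`` listing every file with its sha256.  Refuses a
    non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ValidationError(
            f"directory {directory} is not empty; pass force=True to overwrite"
        )
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for sp_name, adata in panel.expression.items():
        paths = _io.write_expression_mtx(adata, directory / sp_name,
                                         prefix="counts")
        written.extend(paths.values())

    og_path = directory / "Orthogroups.tsv"
    rows = []
    for og in panel.orthogroups.og_ids:
        row = {"Orthogroup": og}
        for sp_name in panel.orthogroups.species:
            row[sp_name] = ", ".join(
                panel.orthogroups.membership[og].get(sp_name, ())
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(og_path, sep="\t", index=False)
    written.append(og_path)

    tree_path = directory / "tree.nwk"
    tree_path.write_text(panel.tree + ("\n" if not panel.tree.endswith("\n")
                                       else ""))
    written.append(tree_path)

    truth = panel.truth
    truth_json = {
        "module_ogs": list(truth.module_ogs),
        "lineage_ogs": list(truth.lineage_ogs),
        "lineage_species": truth.lineage_species,
        "lineage_type": truth.lineage_type,
        "homolog_map": truth.homolog_map,
        "type_markers": {s: {t: list(v) for t, v in d.items()}
                         for s, d in truth.type_markers.items()},
        "gene_to_og": truth.gene_to_og,
        "config": asdict(panel.config),
    }
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=1))
    written.append(truth_path)
    for name, df in (("tip_states", truth.tip_states),
                     ("node_states", truth.node_states),
                     ("edge_transitions", truth.edge_transitions)):
        if df is not None:
            p = directory / f"{name}.tsv"
            df.to_csv(p, sep="\t")
            written.append(p)

    manifest = {
        "species": list(panel.orthogroups.species),
        "files": {
            str(p.relative_to(directory)): _sha256(p) for p in written
        },
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return directory


def read_fixture_set(directory) -> SimulatedPanel:
    """Re-read a fixture directory written by :func:`write_fixture_set`."""
    from .orthomap import read_orthogroups

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    species = manifest["species"]
    truth_json = json.loads((directory / "ground_truth.json").read_text())
    expression = {}
    for sp_name in species:
        d = directory / sp_name
        expression[sp_name] = _io.read_expression_mtx(
            d / "counts.mtx", d / "counts.features.tsv", d / "counts.cells.tsv",
            d / "counts.annotations.tsv",
        )
        expression[sp_name].uns["species"] = sp_name
    table = read_orthogroups(directory / "Orthogroups.tsv", species)
    tree = (directory / "tree.nwk").read_text().strip()
    truth = GroundTruth(
        module_ogs=tuple(truth_json["module_ogs"]),
        lineage_ogs=tuple(truth_json["lineage_ogs"]),
        lineage_species=truth_json["lineage_species"],
        lineage_type=truth_json["lineage_type"],
        homolog_map=truth_json["homolog_map"],
        type_markers={s: {t: tuple(v) for t, v in d.items()}
                      for s, d in truth_json["type_markers"].items()},
        gene_to_og=truth_json["gene_to_og"],
        tip_states=pd.read_csv(directory / "tip_states.tsv", sep="\t",
                               index_col=0),
        node_states=pd.read_csv(directory / "node_states.tsv", sep="\t",
                                index_col=0),
        edge_transitions=pd.read_csv(directory / "edge_transitions.tsv",
                                     sep="\t", index_col=0),
    )
    config = SimulationConfig(**truth_json["config"])
    return SimulatedPanel(config=config, expression=expression,
                          orthogroups=table, tree=tree, truth=truth)
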