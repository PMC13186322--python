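"""End-to-end pipeline: aggregate -> profile -> similarity -> markers -> ASR.

:class:`PipelineConfig` captures every input path and tunable parameter
(defaults: pseudocount 0.05, FC threshold 1.1, 88th-percentile links,
metacells of 10 cells, BH FDR 0.05); :func:`run_pipeline` executes the
stages in order, writes every stage output as a commented TSV under the
output directory, and records a run log with the parameter echo and package
version.  Omitting the tree skips the trait-evolution stage and says so in
the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path


import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .exceptions import ConfigurationError
from .orthomap import (OrthogroupTable, aggregate_to_orthogenes,
                       filter_universal_orthogroups, read_orthogroups)
from .profiles import (DEFAULT_FC_THRESHOLD, DEFAULT_METACELL_SIZE,
                       DEFAULT_PSEUDOCOUNT, binarize_activity,
                       celltype_geometric_mean, fold_change, make_metacells)
from .similarity import DEFAULT_PERCENTILE, link_graph
from .conservation import (DEFAULT_FC_MIN, DEFAULT_FDR, group_pvalues,
                           marker_intersections, shared_markers)
from .trait_evolution import read_newick, reconstruct_trait_evolution
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "infer_focal_types"]


@dataclass
class SpeciesInput:
    """Paths to one species' expression data (MTX triplet or dense TSV)."""

    counts: str
    annotations: str
    features: str | None = None
    cells: str | None = None

    def load(self) -> ad.AnnData:
        if str(self.counts).endswith(".mtx"):
            if not (self.features and self.cells):
                raise ConfigurationError(
                    "MTX input needs 'features' and 'cells' sidecar paths"
                )
            return _io.read_expression_mtx(self.counts, self.features,
                                           self.cells, self.annotations)
        return _io.read_expression_tsv(self.counts, self.annotations)


@dataclass
class PipelineConfig:
    orthogroups: str
    species: dict[str, SpeciesInput]
    out: str
    tree: str | None = None
    focal_cell_types: dict[str, str] | None = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    percentile: float = DEFAULT_PERCENTILE
    metacell_size: int = DEFAULT_METACELL_SIZE
    fdr: float = DEFAULT_FDR
    fc_min: float = DEFAULT_FC_MIN
    symmetric: bool = True
    global_percentile: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        species = {
            name: SpeciesInput(**{k: resolve(v) for k, v in d.items()})
            for name, d in raw.pop("species").items()
        }
        for key in ("orthogroups", "tree"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        return cls(species=species, **raw)

    @classmethod
    def from_fixture_dir(cls, directory, out, **overrides) -> "PipelineConfig":
        """Build a config from a fixture directory written by the simulator."""
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        species = {
            name: SpeciesInput(
                counts=str(directory / name / "counts.mtx"),
                features=str(directory / name / "counts.features.tsv"),
                cells=str(directory / name / "counts.cells.tsv"),
                annotations=str(directory / name / "counts.annotations.tsv"),
            )
            for name in manifest["species"]
        }
        tree = directory / "tree.nwk"
        return cls(
            orthogroups=str(directory / "Orthogroups.tsv"),
            species=species,
            tree=str(tree) if tree.exists() else None,
            out=str(out),
            **{k: v for k, v in overrides.items() if v is not None},
        )

    def parameter_echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = {k: dataclasses.asdict(v) if not isinstance(v, dict)
                        else v for k, v in d["species"].items()}
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    orthogroups: OrthogroupTable
    orthogene: dict[str, ad.AnnData]
    profiles: dict[str, pd.DataFrame]
    fold_changes: dict[str, pd.DataFrame]
    links: pd.DataFrame
    focal_cell_types: dict[str, str]
    marker_calls: pd.DataFrame
    marker_sets: dict[str, frozenset]
    intersections: "object"
    activity: pd.DataFrame | None = None
    reconstruction: "object | None" = None


def infer_focal_types(links: pd.DataFrame) -> dict[str, str]:
    """Pick each species' focal cell type from the retained link graph.

    The focal (phagocyte-like) type is the cell type with the most retained
    cross-species links, ties broken by total similarity of its retained
    links.  Used when the configuration names no focal types.
    """
    retained = links[links["retained"]]
    long = pd.concat([
        retained.rename(columns={"species_a": "species", "type_a": "cell_type"})
                [["species", "cell_type", "similarity"]],
        retained.rename(columns={"species_b": "species", "type_b": "cell_type"})
                [["species", "cell_type", "similarity"]],
    ])
    focal = {}
    for sp_name, grp in long.groupby("species"):
        agg = grp.groupby("cell_type")["similarity"].agg(["count", "sum"])
        focal[sp_name] = agg.sort_values(["count", "sum"],
                                         ascending=False).index[0]
    return focal


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = True):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order, writing stage outputs and a run log."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    # No timestamp in the log: identical config + seed must give
    # byte-identical outputs.
    log_lines = [
        f"orthocell {__version__}",
        "parameters: " + json.dumps(config.parameter_echo(), default=str),
    ]
    stamp = (f"generated by orthocell run-pipeline v{__version__} "
             f"seed={config.seed} pseudocount={config.pseudocount} "
             f"fc_threshold={config.fc_threshold} percentile={config.percentile} "
             f"metacell_size={config.metacell_size} fdr={config.fdr}")

    def finish(stage: str):
        log_lines.append(f"completed stage: {stage}")

    try:
        species_names = list(config.species)
        table = read_orthogroups(config.orthogroups, species_names)
        table = filter_universal_orthogroups(table, species_names)
        expr = {s: inp.load() for s, inp in config.species.items()}
        orthogene = {
            s: aggregate_to_orthogenes(expr[s], table, s)
            for s in species_names
        }
        for s, adata in orthogene.items():
            _io.write_expression_mtx(adata, out / "orthogene" / s,
                                     prefix="orthogene", header=stamp)
        finish("aggregate")

        profiles_, fcs = {}, {}
        for s in species_names:
            mat = orthogene[s]
            if config.metacell_size > 1:
                mat = make_metacells(mat, config.metacell_size,
                                     seed=config.seed)
            profiles_[s] = celltype_geometric_mean(
                mat, epsilon=config.pseudocount
            )
            fcs[s] = fold_change(profiles_[s], pseudocount=config.pseudocount)
            _write_tsv(profiles_[s], out / "profiles" / f"{s}.profile.tsv", stamp)
            _write_tsv(fcs[s], out / "profiles" / f"{s}.fc.tsv", stamp)
        finish("profile")

        links = link_graph(
            fcs, percentile=config.percentile, symmetric=config.symmetric,
            per_pair=not config.global_percentile,
        )
        _write_tsv(links, out / "similarity" / "links.tsv", stamp, index=False)
        finish("similarity")

        focal = dict(config.focal_cell_types or infer_focal_types(links))
        for s in species_names:
            if s not in focal:
                raise ConfigurationError(f"no focal cell type for species {s!r}")
        log_lines.append("focal cell types: " + json.dumps(focal))

        retained = links[links["retained"]]
        calls = []
        for _, row in retained.iterrows():
            sa, sb = row["species_a"], row["species_b"]
            mc = shared_markers(
                fcs[sa], fcs[sb], (row["type_a"], row["type_b"]),
                orthogene[sa], orthogene[sb],
                fc_min=config.fc_min, fdr=config.fdr,
            )
            mc.insert(1, "species_a", sa)
            mc.insert(3, "species_b", sb)
            calls.append(mc)
        marker_calls = (pd.concat(calls, ignore_index=True) if calls
                        else pd.DataFrame())
        _write_tsv(marker_calls, out / "markers" / "marker_calls.tsv", stamp,
                   index=False)

        marker_sets = {}
        for s in species_names:
            fc_focal = fcs[s][focal[s]]
            pvals = group_pvalues(orthogene[s], [focal[s]])
            qvals = pd.Series(
                multipletests(pvals.to_numpy(), method="fdr_bh")[1],
                index=pvals.index,
            )
            marker_sets[s] = frozenset(
                fc_focal.index[(fc_focal > config.fc_min)
                               & (qvals < config.fdr)]
            )
        report = marker_intersections(marker_sets)
        _write_tsv(report.sizes(), out / "markers" / "intersections.tsv", stamp,
                   index=False)
        (out / "markers" / "intersections.json").write_text(json.dumps({
            "core_set": sorted(report.core_set),
            "combinations": {"&".join(sorted(k)): sorted(v)
                             for k, v in report.combinations.items()},
        }, indent=1))
        finish("markers")

        activity = None
        reconstruction = None
        if config.tree:
            tree = read_newick(config.tree)
            activity = pd.DataFrame(
                {s: binarize_activity(fcs[s], [focal[s]],
                                      threshold=config.fc_threshold)
                 for s in species_names}
            ).T
            activity.index.name = "species"
            _write_tsv(activity.T, out / "asr" / "activity.tsv", stamp)
            reconstruction = reconstruct_trait_evolution(tree, activity)
            _write_tsv(reconstruction.node_states,
                       out / "asr" / "node_states.tsv", stamp)
            edge_table = reconstruction.edge_counts.assign(
                rate_per_myr=reconstruction.rates
            )
            _write_tsv(edge_table, out / "asr" / "edge_rates.tsv", stamp)
            (out / "asr" / "annotated_tree.nwk").write_text(
                reconstruction.annotated_newick()
            )
            finish("trait_evolution")
        else:
            log_lines.append(
                "no tree supplied: trait-evolution stage skipped"
            )
    except Exception as exc:
        log_lines.append(f"FAILED: {type(exc).__name__}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    log_lines.append("pipeline finished")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        config=config,
        orthogroups=table,
        orthogene=orthogene,
        profiles=profiles_,
        fold_changes=fcs,
        links=links,
        focal_cell_types=focal,
        marker_calls=marker_calls,
        marker_sets=marker_sets,
        intersections=report,
        activity=activity,
        reconstruction=reconstruction,
    )
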