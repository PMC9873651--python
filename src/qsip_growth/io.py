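"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV. Feature tables have OTU ids in the first
column and sample ids in the header; manifests follow the FractionSample
columns; trees are newick with branch lengths; taxonomy maps OTU to
phylum/class. Lines starting with '#' are treated as comments everywhere,
which is how provenance headers written by the CLI survive a round trip.
"""

from __future__ import annotations

import math
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import InputFormatError, ValidationError
from .model import (DEFAULT_WINDOW, FeatureTable, FractionSample, Phylogeny,
                    QsipExperiment, TaxonomyMap, validate_samples)

MANIFEST_COLUMNS = ["sample_id", "tube_id", "treatment", "replicate", "isotope",
                    "day", "fraction_index", "buoyant_density", "total_copies"]


def read_feature_table(path) -> FeatureTable:
    """Read a taxon-by-sample TSV; counts are normalised to proportions.

    A column whose sum exceeds 1 (beyond numerical tolerance) is taken to be
    counts and divided by its sum; columns already in proportions pass
    through unchanged.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputFormatError(f"cannot parse feature table {path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise InputFormatError(f"feature table {path} is empty")
    if raw.index.duplicated().any():
        dup = sorted(raw.index[raw.index.duplicated()].unique())
        raise InputFormatError(f"duplicate OTU id(s) in {path}: {dup}")
    df = raw.apply(pd.to_numeric, errors="coerce").astype(float)
    bad = df.isna() & ~raw.isna()
    if bad.any().any() or raw.isna().any().any():
        nan_mask = df.isna()
        r = nan_mask.any(axis=1).idxmax()
        c = nan_mask.loc[r].idxmax()
        raise InputFormatError(
            f"non-numeric cell in {path} at OTU {r!r}, sample {c!r}")
    colsum = df.sum(axis=0)
    needs = colsum > 1 + 1e-9
    if needs.any():
        df.loc[:, needs] = df.loc[:, needs] / colsum[needs]
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path, header_lines=()) -> None:
    _write_tsv(table.df.rename_axis("otu_id"), path, header_lines)


def read_sample_manifest(path) -> list[FractionSample]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover
        raise InputFormatError(f"cannot parse manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"manifest {path} lacks column(s) {missing}")
    samples = []
    for _, row in df.iterrows():
        fi = row["fraction_index"]
        fi = None if pd.isna(fi) else int(fi)
        bd = row["buoyant_density"]
        bd = float("nan") if pd.isna(bd) else float(bd)
        samples.append(FractionSample(
            sample_id=str(row["sample_id"]), tube_id=str(row["tube_id"]),
            treatment=str(row["treatment"]), replicate=int(row["replicate"]),
            isotope=str(row["isotope"]), day=float(row["day"]),
            fraction_index=fi, buoyant_density=bd,
            total_copies=float(row["total_copies"])))
    validate_samples(samples)
    return samples


def write_sample_manifest(samples: list[FractionSample], path, header_lines=()) -> None:
    rows = [{
        "sample_id": s.sample_id, "tube_id": s.tube_id, "treatment": s.treatment,
        "replicate": s.replicate, "isotope": s.isotope, "day": s.day,
        "fraction_index": "" if s.fraction_index is None else s.fraction_index,
        "buoyant_density": "" if math.isnan(s.buoyant_density) else repr(s.buoyant_density),
        "total_copies": repr(s.total_copies),
    } for s in samples]
    _write_tsv(pd.DataFrame(rows).set_index("sample_id"), path, header_lines)


def read_tree(path) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise InputFormatError(f"cannot parse newick tree {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise InputFormatError(f"tree {path} has an edge without a branch length")
    return Phylogeny(tree)


def write_tree(phylo: Phylogeny, path) -> None:
    Path(path).write_text(phylo.as_newick() + "\n")


def read_taxonomy(path) -> TaxonomyMap:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover
        raise InputFormatError(f"cannot parse taxonomy {path}: {exc}") from exc
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path, header_lines=()) -> None:
    _write_tsv(tax.df.rename_axis("otu_id"), path, header_lines)


def assemble_experiment(table: FeatureTable, samples, tree: Phylogeny,
                        taxonomy: TaxonomyMap,
                        window: tuple[float, float] = DEFAULT_WINDOW) -> QsipExperiment:
    """Cross-validate the four inputs and fix the density window (closed
    interval; default [1.695, 1.735] g/mL)."""
    return QsipExperiment(feature_table=table, samples=list(samples), tree=tree,
                          taxonomy=taxonomy, density_window=tuple(window))


def load_experiment(feature_path, manifest_path, tree_path, taxonomy_path,
                    window=DEFAULT_WINDOW) -> QsipExperiment:
    return assemble_experiment(
        read_feature_table(feature_path), read_sample_manifest(manifest_path),
        read_tree(tree_path), read_taxonomy(taxonomy_path), window)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputFormatError(f"config {path} must be a YAML mapping")
    return cfg


def _write_tsv(df: pd.DataFrame, path, header_lines=()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")
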