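"""Core data model for an ¹⁸O-qSIP incubation experiment.

The experiment bundles four inputs: a taxon-by-sample relative-abundance
table, a sample manifest describing every density fraction (plus the
unfractionated day-0 soils), a rooted phylogeny, and a taxonomy map.
Samples are fractions of ultracentrifuge tubes; each tube is one replicate
of a (treatment, day, isotope) cell of the incubation design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import AssemblyError, ValidationError

log = logging.getLogger("qsip_growth")

TREATMENTS = ("Contr", "eT", "eCO2", "eTeCO2")
ISOTOPES = ("16O", "18O")
DAYS = (1, 3, 6)
#: Analysis intervals: growth is integrated from rewetting (day 0) to each harvest.
INTERVALS = ("0-1d", "0-3d", "0-6d")
INTERVAL_DAYS = {"0-1d": 1.0, "0-3d": 3.0, "0-6d": 6.0}
DAY_TO_INTERVAL = {1: "0-1d", 3: "0-3d", 6: "0-6d"}

DENSITY_BOUNDS = (1.60, 1.80)
#: Fractions with buoyant density in this closed window carry >99% of gene
#: copies and are the ones sequenced; the window is configurable downstream.
DEFAULT_WINDOW = (1.695, 1.735)


@dataclass(frozen=True)
class FractionSample:
    """One qPCR-quantified sample: a density fraction, or an unfractionated
    day-0 soil (which has no fraction index and no buoyant density)."""

    sample_id: str
    tube_id: str
    treatment: str
    replicate: int
    isotope: str
    day: float
    fraction_index: Optional[int]
    buoyant_density: float  # g/mL; NaN for unfractionated day-0 samples
    total_copies: float  # 16S copies per g dry soil (qPCR)

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r} "
                f"(expected one of {TREATMENTS})")
        if self.isotope not in ISOTOPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown isotope {self.isotope!r}")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")
        if self.day not in (0, 1, 3, 6):
            raise ValidationError(
                f"sample {self.sample_id!r}: day {self.day} not in {{0,1,3,6}}")
        if self.day == 0:
            if self.fraction_index is not None:
                raise ValidationError(
                    f"sample {self.sample_id!r}: day-0 samples are unfractionated "
                    f"but fraction_index={self.fraction_index}")
        else:
            if self.fraction_index is None:
                raise ValidationError(
                    f"sample {self.sample_id!r}: fractionated sample needs a fraction_index")
            if not 1 <= self.fraction_index <= 20:
                raise ValidationError(
                    f"sample {self.sample_id!r}: fraction_index {self.fraction_index} "
                    f"outside 1..20")
            if not DENSITY_BOUNDS[0] <= self.buoyant_density <= DENSITY_BOUNDS[1]:
                raise ValidationError(
                    f"sample {self.sample_id!r}: buoyant density {self.buoyant_density} "
                    f"outside [{DENSITY_BOUNDS[0]}, {DENSITY_BOUNDS[1]}] g/mL")
        if not (self.total_copies >= 0) or math.isnan(self.total_copies):
            raise ValidationError(
                f"sample {self.sample_id!r}: total_copies must be >= 0")

    @property
    def is_fractionated(self) -> bool:
        return self.fraction_index is not None


def validate_samples(samples: list[FractionSample]) -> None:
    """Cross-sample invariants: unique ids, distinct densities within a tube."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id(s): {dup}")
    by_tube: dict[str, list[FractionSample]] = {}
    for s in samples:
        if s.is_fractionated:
            by_tube.setdefault(s.tube_id, []).append(s)
    for tube, frs in by_tube.items():
        if len(frs) > 20:
            raise ValidationError(f"tube {tube!r} has {len(frs)} fractions (>20)")
        dens = [f.buoyant_density for f in frs]
        if len(set(dens)) != len(dens):
            raise ValidationError(f"tube {tube!r} has repeated buoyant densities")


class FeatureTable:
    """Taxon-by-sample relative abundances (proportions within each sample).

    Absolute 16S copy numbers are never stored; they are derived on demand
    by multiplying a sample's proportions by its qPCR total, so the qPCR
    rescaling lives in one place (`QsipExperiment.tube_profile`).
    """

    def __init__(self, df: pd.DataFrame):
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("feature table is empty")
        if df.index.duplicated().any():
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate OTU id(s): {dup}")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"non-numeric value at OTU {df.index[r]!r}, sample {df.columns[c]!r}")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at OTU {df.index[r]!r}, sample {df.columns[c]!r}")
        colsum = vals.sum(axis=0)
        if (colsum > 1 + 1e-9).any():
            bad = df.columns[colsum > 1 + 1e-9][0]
            raise ValidationError(
                f"column {bad!r} sums to more than 1; normalise counts first")
        self.df = df.astype(float)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def zero_taxa(self) -> list[str]:
        """All-zero OTU rows: retained for taxonomy joins, skipped by qSIP."""
        return list(self.df.index[(self.df.to_numpy() == 0).all(axis=1)])


class Phylogeny:
    """Rooted tree with named tips and non-negative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValidationError("tree tip names are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("tree has a negative branch length")
        self.tree = tree
        self.tip_names = tips

    def __contains__(self, name: str) -> bool:
        return name in set(self.tip_names)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


class TaxonomyMap:
    """OTU → (phylum, class); unknown OTUs fall back to "Other"."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("phylum", "class") if c not in df.columns]
        if missing:
            raise ValidationError(f"taxonomy table lacks column(s) {missing}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate OTU ids in taxonomy table")
        self.df = df[["phylum", "class"]].astype(str)

    def phylum(self, otu: str) -> str:
        if otu in self.df.index:
            return self.df.loc[otu, "phylum"]
        return "Other"

    def reindex(self, taxa: list[str]) -> pd.DataFrame:
        out = self.df.reindex(taxa)
        return out.fillna("Other")


@dataclass
class QsipExperiment:
    """Validated bundle of all pipeline inputs.

    ``density_window`` is a closed interval [low, high] in g/mL; fractions
    outside it remain in the object but are flagged excluded and are ignored
    by the weighted-average-density calculations.
    """

    feature_table: FeatureTable
    samples: list[FractionSample]
    tree: Phylogeny
    taxonomy: TaxonomyMap
    density_window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self):
        lo, hi = self.density_window
        if not lo < hi:
            raise ValidationError(f"density window {self.density_window}: low must be < high")
        validate_samples(self.samples)
        by_id = {s.sample_id: s for s in self.samples}
        missing = [s for s in self.feature_table.samples if s not in by_id]
        if missing:
            raise AssemblyError(
                f"feature-table sample(s) missing from manifest: {missing[:10]}")
        tips = set(self.tree.tip_names)
        analyzed = [t for t in self.feature_table.taxa
                    if t not in self.feature_table.zero_taxa()]
        lost = [t for t in analyzed if t not in tips]
        if lost:
            raise AssemblyError(f"OTU(s) absent from the tree: {lost[:10]}")
        cells: dict[tuple, set] = {}
        for s in self.samples:
            if s.day > 0:
                cells.setdefault((s.treatment, s.day, s.isotope), set()).add(s.tube_id)
        for cell, tubes in cells.items():
            if not tubes:
                raise AssemblyError(f"design cell {cell} has no replicate tube")
        self._by_id = by_id
        zeros = self.feature_table.zero_taxa()
        if zeros:
            log.info("retaining %d all-zero OTU row(s); excluded from qSIP estimation",
                     len(zeros))

    # -- convenience views -------------------------------------------------

    def sample(self, sample_id: str) -> FractionSample:
        return self._by_id[sample_id]

    def manifest_frame(self) -> pd.DataFrame:
        rows = [{
            "sample_id": s.sample_id, "tube_id": s.tube_id, "treatment": s.treatment,
            "replicate": s.replicate, "isotope": s.isotope, "day": s.day,
            "fraction_index": s.fraction_index, "buoyant_density": s.buoyant_density,
            "total_copies": s.total_copies,
        } for s in self.samples]
        return pd.DataFrame(rows).set_index("sample_id")

    def in_window(self, s: FractionSample) -> bool:
        lo, hi = self.density_window
        return s.is_fractionated and lo <= s.buoyant_density <= hi

    def tubes(self, treatment: str, day: float, isotope: str) -> list[str]:
        ids = sorted({s.tube_id for s in self.samples
                      if s.treatment == treatment and s.day == day
                      and s.isotope == isotope and s.is_fractionated})
        return ids

    def tube_profile(self, tube_id: str, window: bool = True):
        """Absolute copy numbers per taxon per fraction of one tube.

        Returns (densities, copies) where ``copies`` is a taxon × fraction
        DataFrame of 16S copies per g dry soil: relative abundance times the
        fraction's qPCR total. ``window=True`` keeps in-window fractions only.
        """
        frs = [s for s in self.samples if s.tube_id == tube_id and s.is_fractionated]
        if window:
            frs = [s for s in frs if self.in_window(s)]
        frs = sorted(frs, key=lambda s: s.buoyant_density)
        present = [s for s in frs if s.sample_id in self.feature_table.df.columns]
        dens = np.array([s.buoyant_density for s in present])
        rel = self.feature_table.df[[s.sample_id for s in present]]
        tot = np.array([s.total_copies for s in present])
        copies = rel * tot
        copies.columns = dens
        return dens, copies

    def day0_abundance(self, treatment: str) -> pd.Series:
        """Initial copies/g soil per taxon from the unfractionated day-0 soils
        (mean over replicates)."""
        s0 = [s for s in self.samples if s.treatment == treatment and s.day == 0]
        if not s0:
            raise ValidationError(f"no day-0 samples for treatment {treatment!r}")
        cols = [s.sample_id for s in s0 if s.sample_id in self.feature_table.df.columns]
        tot = np.array([self._by_id[c].total_copies for c in cols])
        return (self.feature_table.df[cols] * tot).mean(axis=1)
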