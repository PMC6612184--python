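"""Abundance-based taxon screening.

Builds the "all" and "abundant" taxon sets from a taxonomic-classification
summary (per-sample relative abundances in percent of reads, the shape of a
Kraken-style report aggregated to species rank).  A species enters a set when
its relative abundance *strictly* exceeds the threshold in at least one
sample; the study thresholds are 0.001% of reads for the full species list
and 0.1% for the abundant list.  Sets can be restricted to the samples of one
skin microenvironment class (dry, moist, sebaceous) and stratified by phylum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .traitdb import TraitDatabase

__all__ = [
    "AbundanceTable",
    "TaxonSet",
    "SITE_CLASSES",
    "read_classification_report",
    "select_taxa",
    "stratify",
]

SITE_CLASSES = ("dry", "moist", "sebaceous")
_SUM_TOL = 1e-6


@dataclass
class TaxonSet:
    """A named list of species with a record of how it was built."""

    name: str
    members: set[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, species: str) -> bool:
        return species in self.members

    def __iter__(self):
        return iter(sorted(self.members))


class AbundanceTable:
    """Taxon x sample relative abundances (percent of reads).

    Wraps a wide DataFrame (rows = species, columns = sample IDs) plus a
    sample -> site-class mapping.  Values must be nonnegative and each sample
    must sum to at most 100%.
    """

    def __init__(self, values: pd.DataFrame, site_class: Mapping[str, str] | None = None):
        if (values.values < 0).any():
            raise ValueError("negative abundance")
        sums = values.sum(axis=0)
        over = sums[sums > 100.0 + _SUM_TOL]
        if not over.empty:
            raise ValueError(f"sample(s) exceed 100% of reads: {list(over.index)}")
        self.values = values
        self.site_class = {s: "unclassified" for s in values.columns}
        if site_class:
            for s, label in site_class.items():
                if s in self.site_class:
                    self.site_class[s] = label

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, site_classes: Iterable[str]) -> list[str]:
        wanted = set(site_classes)
        return [s for s in self.samples if self.site_class[s] in wanted]


def read_classification_report(
    path,
    sample_metadata: "str | None" = None,
) -> AbundanceTable:
    """Parse a classification summary TSV into an :class:`AbundanceTable`.

    Two dialects are auto-detected:

    * long: columns ``taxon``, ``sample``, ``percent`` and optionally
      ``rank`` (rows not at species rank are skipped with a warning),
    * wide: first column ``taxon`` (optionally a ``rank`` column), remaining
      columns one per sample.

    *sample_metadata* is a TSV with columns ``sample_id``, ``site``,
    ``site_class``; samples missing from it are labeled "unclassified" with a
    warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("no species rows in classification report")
    # normalize only the reserved columns; sample IDs keep their case
    reserved = {"taxon", "rank", "sample", "percent"}
    df.columns = [c.lower() if c.lower() in reserved else c for c in df.columns]

    n_skipped = 0
    if "rank" in df.columns:
        keep = df["rank"].str.lower() == "species"
        n_skipped = int((~keep).sum())
        df = df[keep].drop(columns=["rank"])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-species rows")

    if {"taxon", "sample", "percent"}.issubset(df.columns):
        wide = df.pivot_table(index="taxon", columns="sample", values="percent", fill_value=0.0)
        wide.index.name = None
        wide.columns.name = None
    elif "taxon" in df.columns:
        wide = df.set_index("taxon")
        wide.index.name = None
        wide = wide.astype(float)
    else:
        raise ValueError("expected a 'taxon' column (wide) or taxon/sample/percent columns (long)")
    if wide.empty:
        raise ValueError("no species rows in classification report")

    site_class: dict[str, str] = {}
    if sample_metadata is not None:
        meta = pd.read_csv(sample_metadata, sep="\t")
        meta.columns = [c.lower() for c in meta.columns]
        site_class = dict(zip(meta["sample_id"].astype(str), meta["site_class"].astype(str)))
        missing = [s for s in wide.columns if s not in site_class]
        if missing:
            warnings.warn(f"samples missing from metadata, labeled unclassified: {missing}")
    return AbundanceTable(wide, site_class)


def select_taxa(
    table: AbundanceTable,
    threshold_percent: float,
    restrict_to_sites: Iterable[str] | None = None,
    name: str | None = None,
) -> TaxonSet:
    """Species whose abundance strictly exceeds the threshold in >=1 sample.

    With *restrict_to_sites*, only samples of those site classes count
    (raises if no sample remains).  Thresholds follow the study's strict
    reading: a species exactly at the threshold is excluded.
    """
    if threshold_percent < 0:
        raise ValueError("threshold must be >= 0")
    samples = table.samples
    provenance = f"> {threshold_percent}% of reads in >=1 sample"
    if restrict_to_sites is not None:
        samples = table.samples_in(restrict_to_sites)
        if not samples:
            raise ValueError(f"no samples in site classes {sorted(set(restrict_to_sites))}")
        provenance += f" (sites: {', '.join(sorted(set(restrict_to_sites)))})"
    sub = table.values[samples]
    members = set(sub.index[(sub > threshold_percent).any(axis=1)])
    return TaxonSet(name or f"gt_{threshold_percent}", members, provenance)


def stratify(taxon_set: TaxonSet, db: TraitDatabase, by: str = "phylum") -> tuple[dict[str, TaxonSet], list[str]]:
    """Partition a taxon set by phylum label from a trait database.

    Returns the label -> TaxonSet map and the list of members without a
    label (absent from the database or with an empty phylum).
    """
    if by != "phylum":
        raise ValueError("only stratification by phylum is supported")
    groups: dict[str, set[str]] = {}
    unlabeled: list[str] = []
    for sp in sorted(taxon_set.members):
        if sp in db and db.phylum_of(sp):
            groups.setdefault(db.phylum_of(sp), set()).add(sp)
        else:
            unlabeled.append(sp)
    out = {
        label: TaxonSet(f"{taxon_set.name}/{label}", members, f"{taxon_set.provenance}; phylum={label}")
        for label, members in groups.items()
    }
    return out, unlabeled
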