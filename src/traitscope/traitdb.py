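"""Data model and I/O for culture-derived microbial trait databases.

A trait database is a species-by-trait matrix with three trait classes:

* **binary** traits (spore formation, pigment production, enzyme activities,
  gas production, nitrate reduction) with states positive / negative /
  unknown; documented strain-to-strain variation ("v" cells) is recorded as
  unknown plus a per-record flag,
* **categorical** traits (oxygen use, motility, cell shape, Gram stain,
  aggregation) with a controlled vocabulary per trait and possibly several
  levels per species,
* **quantitative** traits: GC content and growth envelopes
  (min/max/optimum/range) for temperature, pH and NaCl.

Unknown values are explicit and are excluded from every denominator: a
prevalence is ``k`` positives over ``n`` species with a *known* state, never
over all species.  Substrate usage (can the species consume glucose,
glutamate, ...) is stored as a binary map keyed by substrate name.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._schema import QUANT_ENVELOPES, Schema

__all__ = [
    "QuantRange",
    "TaxonRecord",
    "TraitDatabase",
    "ParseReport",
    "ValidationIssue",
    "ValidationReport",
    "PrevalenceResult",
    "QuantSummary",
    "read_trait_table",
    "write_trait_table",
    "validate",
    "trait_prevalence",
    "summarize_quantitative",
]

_RANGE_TOL = 1e-9


@dataclass
class QuantRange:
    """A growth envelope: minimum, maximum and optimum of a condition.

    ``range`` is max - min; it is auto-derived when both endpoints are known
    and the cell was empty.  Unknown components are ``None``.
    """

    minimum: float | None = None
    maximum: float | None = None
    optimum: float | None = None
    range: float | None = None
    range_derived: bool = False

    def derive_range(self) -> None:
        if self.range is None and self.minimum is not None and self.maximum is not None:
            self.range = self.maximum - self.minimum
            self.range_derived = True


@dataclass
class TaxonRecord:
    species_name: str
    phylum: str = ""
    binary_traits: dict[str, str] = field(default_factory=dict)
    #: trait -> set of exhibited levels (empty set = unknown)
    categorical_traits: dict[str, set[str]] = field(default_factory=dict)
    gc_content: float | None = None
    temperature: QuantRange = field(default_factory=QuantRange)
    ph: QuantRange = field(default_factory=QuantRange)
    nacl: QuantRange = field(default_factory=QuantRange)
    substrate_use: dict[str, str] = field(default_factory=dict)
    strain_variation_flags: set[str] = field(default_factory=set)

    def envelope(self, variable: str) -> QuantRange:
        return getattr(self, variable)

    def quantitative_value(self, variable: str) -> float | None:
        """Value of e.g. ``gc_content`` or ``ph_optimum`` (None if unknown)."""
        if variable == "gc_content":
            return self.gc_content
        env, _, part = variable.partition("_")
        if env not in QUANT_ENVELOPES:
            raise KeyError(f"unknown quantitative variable: {variable!r}")
        attr = {"min": "minimum", "max": "maximum", "optimum": "optimum", "range": "range"}[part]
        return getattr(self.envelope(env), attr)


@dataclass
class ParseReport:
    """Cells coerced to unknown and other notable events during parsing."""

    coerced_cells: list[tuple[str, str, str]] = field(default_factory=list)  # (species, column, raw)
    derived_ranges: list[tuple[str, str]] = field(default_factory=list)  # (species, envelope)
    conflicting_ranges: list[tuple[str, str, float, float]] = field(default_factory=list)

    @property
    def n_coerced(self) -> int:
        return len(self.coerced_cells)


class TraitDatabase:
    """Collection of :class:`TaxonRecord` sharing one :class:`Schema`."""

    def __init__(self, records: Iterable[TaxonRecord], schema: Schema | None = None):
        self.schema = schema or Schema()
        self.records: dict[str, TaxonRecord] = {}
        for rec in records:
            if not rec.species_name:
                raise ValueError("species_name must be nonempty")
            if rec.species_name in self.records:
                raise ValueError(f"duplicate species: {rec.species_name!r}")
            self.records[rec.species_name] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, species: str) -> bool:
        return species in self.records

    def __getitem__(self, species: str) -> TaxonRecord:
        return self.records[species]

    @property
    def species_names(self) -> list[str]:
        return list(self.records)

    def phylum_of(self, species: str) -> str:
        return self.records[species].phylum

    def subset(self, species: Iterable[str]) -> "TraitDatabase":
        keep = [self.records[s] for s in species if s in self.records]
        return TraitDatabase(keep, schema=self.schema)

    def trait_kind(self, trait: str) -> str:
        """One of 'binary', 'categorical', 'quantitative', 'substrate'."""
        if trait in self.schema.binary_traits:
            return "binary"
        if trait in self.schema.categorical_vocabularies:
            return "categorical"
        if trait in self.schema.quantitative_variables:
            return "quantitative"
        if trait in self.schema.substrates:
            return "substrate"
        raise KeyError(f"unknown trait: {trait!r}")


@dataclass
class PrevalenceResult:
    trait: str
    level: str | None
    k: int  # positive / exhibiting the level
    n: int  # known values
    proportion: float | None  # None when n == 0 (flagged undefined)

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass
class QuantSummary:
    variable: str
    n: int
    mean: float | None
    sd: float | None

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    species: str
    column: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "severity": self.severity,
                "species": self.species,
                "column": self.column,
                "message": self.message,
            }
        )


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    unknown_counts: dict[str, int] = field(default_factory=dict)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for issue in self.issues:
                fh.write(issue.to_json() + "\n")


# ---------------------------------------------------------------------------
# parsing


def _parse_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw == "" or raw.lower() in {"nd", "na", "unknown", "?"}:
        return None
    return float(raw)


def _resolve(names: Iterable[str], taxon_set) -> list[str]:
    if taxon_set is None:
        return list(names)
    members = getattr(taxon_set, "members", taxon_set)
    members = set(members)
    return [s for s in names if s in members]


def read_trait_table(
    path,
    schema: Schema | None = None,
    *,
    ignore_extra_columns: bool = False,
) -> tuple[TraitDatabase, ParseReport]:
    """Read a UTF-8 TSV trait table into a :class:`TraitDatabase`.

    The first two columns must be ``species`` and ``phylum``; remaining
    columns are interpreted via the schema.  Every cell either parses or is
    mapped to unknown through the alias map; coerced cells are listed in the
    returned :class:`ParseReport`.

    Raises ``ValueError`` on duplicate species, on a column the schema does
    not declare (unless *ignore_extra_columns*), and on a categorical level
    outside the declared vocabulary.
    """
    schema = schema or Schema()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["species", "phylum"]:
        raise ValueError("first two columns must be 'species' and 'phylum'")
    known = set(schema.columns())
    extra = [c for c in df.columns if c not in known]
    if extra and not ignore_extra_columns:
        raise ValueError(f"unknown columns: {extra}")

    report = ParseReport()
    records: list[TaxonRecord] = []
    for _, row in df.iterrows():
        species = row["species"].strip()
        rec = TaxonRecord(species_name=species, phylum=row["phylum"].strip())

        def parse_binary(col: str, target: dict[str, str]) -> None:
            raw = row.get(col, "")
            state = schema.binary_aliases.get(raw.strip().lower())
            if state is None:
                report.coerced_cells.append((species, col, raw))
                state = "unknown"
            if state == "variable":
                rec.strain_variation_flags.add(col)
                state = "unknown"
            target[col] = state

        for col in schema.binary_traits:
            if col in df.columns:
                parse_binary(col, rec.binary_traits)
        for col in schema.substrate_names:
            if col in df.columns:
                parse_binary(col, rec.substrate_use)

        for col, vocab in schema.categorical_vocabularies.items():
            if col not in df.columns:
                continue
            raw = row[col].strip()
            if raw == "" or raw.lower() in {"nd", "na", "unknown", "?"}:
                if raw:
                    report.coerced_cells.append((species, col, raw))
                rec.categorical_traits[col] = set()
                continue
            levels = {part.strip().lower() for part in raw.split(schema.multivalue_sep)}
            bad = levels - set(vocab)
            if bad:
                raise ValueError(
                    f"species {species!r}, column {col!r}: level(s) {sorted(bad)} "
                    f"not in vocabulary {vocab}"
                )
            rec.categorical_traits[col] = levels

        if "gc_content" in df.columns:
            try:
                rec.gc_content = _parse_float(row["gc_content"])
            except ValueError:
                report.coerced_cells.append((species, "gc_content", row["gc_content"]))
        for env in QUANT_ENVELOPES:
            qr = rec.envelope(env)
            for part, attr in [
                ("min", "minimum"),
                ("max", "maximum"),
                ("optimum", "optimum"),
                ("range", "range"),
            ]:
                col = f"{env}_{part}"
                if col not in df.columns:
                    continue
                try:
                    setattr(qr, attr, _parse_float(row[col]))
                except ValueError:
                    report.coerced_cells.append((species, col, row[col]))
            if qr.range is None:
                before = qr.range
                qr.derive_range()
                if qr.range is not None and before is None and qr.range_derived:
                    report.derived_ranges.append((species, env))
            elif qr.minimum is not None and qr.maximum is not None:
                expected = qr.maximum - qr.minimum
                if abs(qr.range - expected) > _RANGE_TOL:
                    # stored value wins; conflict surfaces in validate()
                    report.conflicting_ranges.append((species, env, qr.range, expected))
        records.append(rec)

    return TraitDatabase(records, schema=schema), report


def write_trait_table(db: TraitDatabase, path) -> None:
    """Write a database back to the TSV dialect :func:`read_trait_table` reads."""
    schema = db.schema
    rows = []
    back = {"positive": "+", "negative": "-", "unknown": ""}
    for rec in db.records.values():
        row: dict[str, str] = {"species": rec.species_name, "phylum": rec.phylum}
        for col in schema.binary_traits:
            if col in rec.strain_variation_flags:
                row[col] = "v"
            else:
                row[col] = back[rec.binary_traits.get(col, "unknown")]
        for col in schema.substrate_names:
            if col in rec.strain_variation_flags:
                row[col] = "v"
            else:
                row[col] = back[rec.substrate_use.get(col, "unknown")]
        for col in schema.categorical_traits:
            levels = rec.categorical_traits.get(col, set())
            row[col] = schema.multivalue_sep.join(sorted(levels))
        for var in schema.quantitative_variables:
            val = rec.quantitative_value(var)
            if var.endswith("_range"):
                env = rec.envelope(var.split("_")[0])
                if env.range_derived:
                    val = None  # keep derived ranges out of the file: re-derived on read
            row[var] = "" if val is None else format(val, "g")
        rows.append(row)
    pd.DataFrame(rows, columns=schema.columns()).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation


def validate(db: TraitDatabase) -> ValidationReport:
    """Check database invariants; never raises.

    Errors: out-of-bounds GC content, negative ranges, max < min.
    Warnings: optimum outside [min, max], stored range conflicting with
    max - min (the stored value is kept).
    """
    report = ValidationReport()
    unknown: dict[str, int] = {}

    def bump(col: str) -> None:
        unknown[col] = unknown.get(col, 0) + 1

    for rec in db.records.values():
        sp = rec.species_name
        if rec.gc_content is None:
            bump("gc_content")
        elif not 0.0 <= rec.gc_content <= 100.0:
            report.issues.append(
                ValidationIssue("error", sp, "gc_content", f"gc_content {rec.gc_content} outside [0, 100]")
            )
        for col in db.schema.binary_traits:
            if rec.binary_traits.get(col, "unknown") == "unknown":
                bump(col)
        for col in db.schema.substrate_names:
            if rec.substrate_use.get(col, "unknown") == "unknown":
                bump(col)
        for col in db.schema.categorical_traits:
            if not rec.categorical_traits.get(col):
                bump(col)
        for env in QUANT_ENVELOPES:
            qr = rec.envelope(env)
            if qr.minimum is not None and qr.maximum is not None:
                if qr.maximum < qr.minimum:
                    report.issues.append(
                        ValidationIssue("error", sp, env, f"{env} max {qr.maximum} < min {qr.minimum}")
                    )
                elif qr.range is not None and abs(qr.range - (qr.maximum - qr.minimum)) > _RANGE_TOL:
                    report.issues.append(
                        ValidationIssue(
                            "warning",
                            sp,
                            f"{env}_range",
                            f"stored range {qr.range} != max-min {qr.maximum - qr.minimum}",
                        )
                    )
            if (
                qr.minimum is not None
                and qr.maximum is not None
                and qr.optimum is not None
                and not (qr.minimum - _RANGE_TOL <= qr.optimum <= qr.maximum + _RANGE_TOL)
            ):
                report.issues.append(
                    ValidationIssue(
                        "warning",
                        sp,
                        f"{env}_optimum",
                        f"optimum {qr.optimum} outside [{qr.minimum}, {qr.maximum}]",
                    )
                )
            if qr.range is not None and qr.range < 0:
                report.issues.append(
                    ValidationIssue("error", sp, f"{env}_range", f"negative range {qr.range}")
                )
    report.unknown_counts = unknown
    return report


# ---------------------------------------------------------------------------
# summaries


def trait_prevalence(
    db: TraitDatabase,
    taxon_set,
    trait: str,
    level: str | None = None,
) -> PrevalenceResult:
    """Proportion of taxa exhibiting a trait, over known values only.

    *trait* is a binary trait, a substrate name, or a categorical trait (then
    *level* selects the vocabulary level to count).  ``n`` counts species with
    a known value; species with unknown state never enter the denominator.
    When ``n == 0`` the proportion is undefined (``None``) and the result is
    flagged via ``defined``.
    """
    names = _resolve(db.species_names, taxon_set)
    kind = db.trait_kind(trait)
    k = n = 0
    if kind in ("binary", "substrate"):
        if level is not None:
            raise ValueError(f"{trait!r} is {kind}; level does not apply")
        for sp in names:
            rec = db.records[sp]
            source = rec.binary_traits if kind == "binary" else rec.substrate_use
            state = source.get(trait, "unknown")
            if state == "unknown":
                continue
            n += 1
            if state == "positive":
                k += 1
    elif kind == "categorical":
        vocab = db.schema.categorical_vocabularies[trait]
        if level is None:
            raise ValueError(f"{trait!r} is categorical; a level is required")
        if level not in vocab:
            raise KeyError(f"level {level!r} not in vocabulary of {trait!r}")
        for sp in names:
            levels = db.records[sp].categorical_traits.get(trait, set())
            if not levels:
                continue
            n += 1
            if level in levels:
                k += 1
    else:
        raise ValueError(f"{trait!r} is quantitative; use summarize_quantitative")
    return PrevalenceResult(trait, level, k, n, k / n if n else None)


def summarize_quantitative(db: TraitDatabase, taxon_set, variable: str) -> QuantSummary:
    """Mean and sd of a quantitative variable over records with a known value."""
    if variable not in db.schema.quantitative_variables:
        raise KeyError(f"unknown quantitative variable: {variable!r}")
    values = [
        v
        for sp in _resolve(db.species_names, taxon_set)
        if (v := db.records[sp].quantitative_value(variable)) is not None
    ]
    n = len(values)
    if n == 0:
        return QuantSummary(variable, 0, None, None)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return QuantSummary(variable, n, mean, sd)
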