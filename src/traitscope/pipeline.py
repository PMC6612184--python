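"""End-to-end workflow: from a config file to machine-readable result tables.

A run compares named *cohorts* (a trait database, optionally restricted by
an abundance screen, a site class, or a phylum) trait by trait:

* binary traits and substrates: binomial proportions with standard errors,
  an overall chi-square test, and the pairwise z contrast,
* categorical traits: the label-permutation randomization test, per level
  and overall,
* quantitative traits: Brunner-Munzel relative-effect contrasts,
* optionally, naive and phylogenetically corrected logistic regressions of
  cohort membership on each trait, screened against the intercept-only null
  with likelihood-ratio tests, reported side by side.

Everything is deterministic given the config seed: per-test seeds are
derived with CRC32 of the contrast/trait labels, row order is fixed, and
reruns produce byte-identical TSV output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._schema import Schema
from .freq_tests import chi_square_overall, pairwise_proportion_contrast, randomization_test, benjamini_hochberg
from .phylo import Phylogeny, lrt, naive_logistic, phylo_lrt
from .rank_tests import bm_contrast
from .screening import TaxonSet, read_classification_report, select_taxa
from .traitdb import TraitDatabase, read_trait_table, trait_prevalence, summarize_quantitative

__all__ = ["RunConfig", "ReportBundle", "run", "summarize_tables"]

DEFAULT_THRESHOLDS = {"all": 0.001, "abundant": 0.1}


@dataclass
class CohortSpec:
    database: str
    select: str | None = None  # "all" | "abundant" (needs the abundance report)
    sites: list[str] | None = None
    phylum: str | None = None


@dataclass
class ContrastSpec:
    name: str
    left: str
    right: str
    phylo: bool = False


@dataclass
class RunConfig:
    databases: dict[str, str]
    cohorts: dict[str, CohortSpec]
    contrasts: list[ContrastSpec]
    schema_path: str | None = None
    abundance_report: str | None = None
    sample_metadata: str | None = None
    tree_path: str | None = None
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    B: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    bh_adjust: bool = False
    output_dir: str = "traitscope_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ab = raw.get("abundance", {}) or {}
        tests = raw.get("tests", {}) or {}
        cohorts = {
            name: CohortSpec(
                database=c["database"],
                select=c.get("select"),
                sites=c.get("sites"),
                phylum=c.get("phylum"),
            )
            for name, c in (raw.get("cohorts") or {}).items()
        }
        contrasts = [
            ContrastSpec(
                name=c["name"], left=c["left"], right=c["right"], phylo=bool(c.get("phylo", False))
            )
            for c in (raw.get("contrasts") or [])
        ]
        cfg = cls(
            databases=dict(raw["databases"]),
            cohorts=cohorts,
            contrasts=contrasts,
            schema_path=raw.get("schema"),
            abundance_report=ab.get("report"),
            sample_metadata=ab.get("sample_metadata"),
            tree_path=raw.get("tree"),
            thresholds={**DEFAULT_THRESHOLDS, **(raw.get("thresholds") or {})},
            B=int(tests.get("B", 100_000)),
            seed=int(tests.get("seed", 0)),
            alpha=float(tests.get("alpha", 0.05)),
            bh_adjust=bool(tests.get("bh_adjust", False)),
            output_dir=raw.get("output_dir", "traitscope_out"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if any(t < 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be >= 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        for name, cohort in self.cohorts.items():
            if cohort.database not in self.databases:
                raise ValueError(f"cohort {name!r} references unknown database {cohort.database!r}")
            if cohort.select is not None:
                if cohort.select not in self.thresholds:
                    raise ValueError(f"cohort {name!r}: unknown screen {cohort.select!r}")
                if self.abundance_report is None:
                    raise ValueError(f"cohort {name!r} needs an abundance report for screening")
        for contrast in self.contrasts:
            for side in (contrast.left, contrast.right):
                if side not in self.cohorts:
                    raise ValueError(f"contrast {contrast.name!r}: unknown cohort {side!r}")
            if contrast.phylo and self.tree_path is None:
                raise ValueError(f"contrast {contrast.name!r} requests phylo but no tree is configured")


@dataclass
class ReportBundle:
    results: pd.DataFrame
    provenance: dict
    cohorts: dict[str, TraitDatabase]

    def write(self, output_dir) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        for name, table in summarize_tables(self).items():
            table.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False, float_format="%.10g")
        return out


def _derive_seed(base: int, *labels: str) -> int:
    key = ":".join([str(base), *labels])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _build_cohort(name, spec, dbs, abundance, thresholds) -> TraitDatabase:
    db = dbs[spec.database]
    members = set(db.species_names)
    if spec.select is not None:
        tset = select_taxa(abundance, thresholds[spec.select], restrict_to_sites=spec.sites, name=name)
        members &= tset.members
    if spec.phylum is not None:
        members = {s for s in members if db.phylum_of(s) == spec.phylum}
    return db.subset(sorted(members))


def _shared_traits(left: TraitDatabase, right: TraitDatabase):
    ls, rs = left.schema, right.schema
    shared = {
        "binary": [t for t in ls.binary_traits if t in rs.binary_traits],
        "categorical": [t for t in ls.categorical_traits if t in rs.categorical_traits],
        "quantitative": [v for v in ls.quantitative_variables if v in rs.quantitative_variables],
        "substrate": [s for s in ls.substrate_names if s in rs.substrate_names],
    }
    unshared = (set(ls.columns()) ^ set(rs.columns())) - {"species", "phylum"}
    return shared, sorted(unshared)


def _binary_counts(db: TraitDatabase, trait: str, kind: str):
    res = trait_prevalence(db, None, trait)
    return res.k, res.n


def _categorical_observations(db: TraitDatabase, trait: str):
    out = []
    for rec in db.records.values():
        levels = rec.categorical_traits.get(trait, set())
        if levels:
            out.append(frozenset(levels))
    return out


def _quant_values(db: TraitDatabase, variable: str):
    return np.array(
        [v for rec in db.records.values() if (v := rec.quantitative_value(variable)) is not None]
    )


def run(config: RunConfig) -> ReportBundle:
    """Execute every configured contrast and return the result bundle."""
    config.validate()
    schema = Schema.from_yaml(config.schema_path) if config.schema_path else Schema()
    dbs = {}
    for name, path in config.databases.items():
        dbs[name], _ = read_trait_table(path, schema=schema)
    abundance = None
    if config.abundance_report is not None:
        abundance = read_classification_report(config.abundance_report, config.sample_metadata)
    tree = Phylogeny.from_newick(config.tree_path) if config.tree_path else None

    cohorts = {
        name: _build_cohort(name, spec, dbs, abundance, config.thresholds)
        for name, spec in config.cohorts.items()
    }

    rows: list[dict] = []
    for contrast in config.contrasts:
        left, right = cohorts[contrast.left], cohorts[contrast.right]
        shared, unshared = _shared_traits(left, right)
        if unshared:
            raise ValueError(f"contrast {contrast.name!r}: databases do not share traits {unshared}")
        groups = (contrast.left, contrast.right)

        def base_row(trait, kind, level=None):
            return {
                "contrast": contrast.name,
                "trait": trait,
                "trait_class": kind,
                "level": "" if level is None else level,
                "group_left": groups[0],
                "group_right": groups[1],
            }

        for kind in ("binary", "substrate"):
            for trait in shared[kind]:
                k1, n1 = _binary_counts(left, trait, kind)
                k2, n2 = _binary_counts(right, trait, kind)
                row = base_row(trait, kind)
                if n1 == 0 or n2 == 0:
                    row.update(method="binomial", flags="undefined", p_value=np.nan)
                    rows.append(row)
                    continue
                pair = pairwise_proportion_contrast(k1, n1, k2, n2, groups=groups, trait=trait)
                flags = list(pair.flags)
                try:
                    chi2, df, p_chi, chi_flags = chi_square_overall(
                        [[k1, k2], [n1 - k1, n2 - k2]]
                    )
                    flags += chi_flags
                except ValueError:
                    chi2 = df = p_chi = np.nan
                    flags.append("chi_square_degenerate")
                row.update(
                    n_left=n1, n_right=n2,
                    estimate_left=pair.estimates[0], estimate_right=pair.estimates[1],
                    se_left=pair.ses[0], se_right=pair.ses[1],
                    statistic=pair.statistic, p_value=pair.p_value,
                    chi2_statistic=chi2, chi2_df=df, chi2_p=p_chi,
                    direction=pair.direction, method=pair.method, flags=";".join(flags),
                )
                rows.append(row)

        for trait in shared["categorical"]:
            obs_left = _categorical_observations(left, trait)
            obs_right = _categorical_observations(right, trait)
            row = base_row(trait, "categorical")
            if not obs_left or not obs_right:
                row.update(method="randomization", flags="undefined", p_value=np.nan)
                rows.append(row)
                continue
            labels = [groups[0]] * len(obs_left) + [groups[1]] * len(obs_right)
            seed = _derive_seed(config.seed, contrast.name, trait)
            res = randomization_test(
                labels, obs_left + obs_right, B=config.B, seed=seed, trait=trait
            )
            overall = res["overall"]
            row.update(
                n_left=len(obs_left), n_right=len(obs_right),
                statistic=overall.statistic, p_value=overall.p_value,
                direction="none", method=overall.method,
                resamples=overall.resamples, seed=seed,
                less_extreme=overall.extra["less_extreme"], flags="",
            )
            rows.append(row)
            for level, lres in sorted(res["levels"].items()):
                gl, gr = lres.groups.index(groups[0]), lres.groups.index(groups[1])
                lrow = base_row(trait, "categorical", level=level)
                lrow.update(
                    n_left=lres.n_per_group[gl], n_right=lres.n_per_group[gr],
                    estimate_left=lres.estimates[gl], estimate_right=lres.estimates[gr],
                    se_left=lres.ses[gl], se_right=lres.ses[gr],
                    statistic=lres.statistic, p_value=lres.p_value,
                    direction=lres.direction, method=lres.method,
                    resamples=lres.resamples, seed=seed,
                    less_extreme=lres.extra["less_extreme"], flags="",
                )
                rows.append(lrow)

        for variable in shared["quantitative"]:
            x, y = _quant_values(left, variable), _quant_values(right, variable)
            row = base_row(variable, "quantitative")
            if len(x) < 2 or len(y) < 2:
                row.update(method="brunner_munzel", flags="undefined", p_value=np.nan)
                rows.append(row)
                continue
            res = bm_contrast(x, y, pair=groups)
            direction = "none"
            if res.p_hat > 0.5:
                direction = groups[1]
            elif res.p_hat < 0.5:
                direction = groups[0]
            row.update(
                n_left=len(x), n_right=len(y),
                estimate_left=float(np.mean(x)), estimate_right=float(np.mean(y)),
                relative_effect=res.p_hat, statistic=res.statistic, df=res.df,
                p_value=res.p_raw, direction=direction,
                method="brunner_munzel", flags=";".join(res.flags),
            )
            rows.append(row)

        if contrast.phylo and tree is not None:
            rows.extend(
                _phylo_rows(contrast, left, right, shared, tree, config, base_row)
            )

    results = pd.DataFrame(rows)
    if config.bh_adjust and "p_value" in results:
        mask = results["p_value"].notna() & (results["level"] == "")
        results.loc[mask, "p_value_bh"] = benjamini_hochberg(results.loc[mask, "p_value"].values)
    provenance = {
        "traitscope_version": __version__,
        "seed": config.seed,
        "B": config.B,
        "alpha": config.alpha,
        "thresholds": config.thresholds,
        "databases": config.databases,
        "tree": config.tree_path,
        "cohort_sizes": {name: len(db) for name, db in cohorts.items()},
        "contrasts": [c.name for c in config.contrasts],
    }
    return ReportBundle(results=results, provenance=provenance, cohorts=cohorts)


def _phylo_rows(contrast, left, right, shared, tree, config, base_row):
    """Naive vs phylogenetically corrected membership regressions per trait."""
    species, y = [], []
    seen = set()
    for db, label in ((left, 1), (right, 0)):
        for name in db.species_names:
            if name in seen:
                continue  # species present on both sides stays with the left cohort
            seen.add(name)
            species.append(name)
            y.append(label)
    y = np.array(y, dtype=float)
    merged = {**{s: right[s] for s in right.species_names},
              **{s: left[s] for s in left.species_names}}

    rows = []
    traits = (
        [(t, "binary") for t in shared["binary"]]
        + [(t, "substrate") for t in shared["substrate"]]
        + [(t, "categorical") for t in shared["categorical"]]
        + [(t, "quantitative") for t in shared["quantitative"]]
    )
    for trait, kind in traits:
        xs = []
        for s in species:
            rec = merged[s]
            if kind == "binary":
                state = rec.binary_traits.get(trait, "unknown")
                xs.append({"positive": 1.0, "negative": 0.0}.get(state))
            elif kind == "substrate":
                state = rec.substrate_use.get(trait, "unknown")
                xs.append({"positive": 1.0, "negative": 0.0}.get(state))
            elif kind == "categorical":
                levels = rec.categorical_traits.get(trait, set())
                # multi-level species have no single level to dummy-code; dropped
                xs.append(sorted(levels)[0] if len(levels) == 1 else None)
            else:
                xs.append(rec.quantitative_value(trait))
        xs = np.array(xs, dtype=object)
        row = base_row(trait, kind)
        row["method"] = "logistic_lrt"
        known = np.array([v is not None for v in xs])
        y_known = y[known]
        if known.sum() < 4 or len(set(y_known)) < 2:
            row.update(flags="undefined", p_value=np.nan)
            rows.append(row)
            continue
        if kind != "quantitative" and len({str(v) for v in xs[known]}) < 2:
            row.update(flags="constant_predictor", p_value=np.nan)
            rows.append(row)
            continue
        seed = _derive_seed(config.seed, contrast.name, trait, "phylo")
        try:
            fit_n = naive_logistic(y, xs)
            null_n = naive_logistic(y[known], None)
            stat_n, p_n = lrt(fit_n, null_n, df=len(fit_n.betas) - 1)
            sp_known = [s for s, k in zip(species, known) if k]
            fit_p, _, stat_p, p_p = phylo_lrt(
                y_known, xs[known], tree, sp_known, seed=seed, n_starts=1
            )
        except ValueError as exc:
            row.update(flags=f"degenerate:{exc}", p_value=np.nan)
            rows.append(row)
            continue
        row.update(
            n_left=int(y_known.sum()), n_right=int((1 - y_known).sum()),
            naive_beta1=fit_n.betas[1] if len(fit_n.betas) > 1 else np.nan,
            naive_loglik=fit_n.loglik, naive_lrt=stat_n, naive_p=p_n,
            phylo_beta1=fit_p.betas[1] if len(fit_p.betas) > 1 else np.nan,
            phylo_loglik=fit_p.loglik, phylo_lrt=stat_p, phylo_p=p_p,
            phylo_alpha=np.nan if fit_p.alpha is None else fit_p.alpha,
            phylo_sigma2=fit_p.sigma2, seed=seed,
            p_value=p_p,
            flags=";".join(sorted(set(fit_n.flags + fit_p.flags))),
        )
        rows.append(row)
    return rows


def summarize_tables(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    """Quantitative-means and trait-prevalence summary tables per cohort.

    Mirrors the style of a mean-trait table (one row per quantitative
    variable, one column pair per cohort) and a prevalence table (one row
    per binary trait / substrate / categorical level).
    """
    cohorts = bundle.cohorts
    quant_rows = []
    some_db = next(iter(cohorts.values()))
    for variable in some_db.schema.quantitative_variables:
        row = {"variable": variable}
        for name, db in cohorts.items():
            s = summarize_quantitative(db, None, variable)
            row[f"{name}_mean"] = np.nan if s.mean is None else s.mean
            row[f"{name}_sd"] = np.nan if s.sd is None else s.sd
            row[f"{name}_n"] = s.n
        quant_rows.append(row)

    prev_rows = []
    schema = some_db.schema
    items = (
        [(t, None) for t in schema.binary_traits]
        + [(t, None) for t in schema.substrate_names]
        + [(t, lvl) for t in schema.categorical_traits for lvl in schema.categorical_vocabularies[t]]
    )
    for trait, level in items:
        row = {"trait": trait, "level": "" if level is None else level}
        for name, db in cohorts.items():
            r = trait_prevalence(db, None, trait, level)
            row[f"{name}_proportion"] = np.nan if r.proportion is None else r.proportion
            row[f"{name}_k"] = r.k
            row[f"{name}_n"] = r.n
        prev_rows.append(row)
    return {
        "quantitative_means": pd.DataFrame(quant_rows),
        "trait_prevalence": pd.DataFrame(prev_rows),
    }
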