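"""Synthetic trait databases, abundance tables and phylogenies.

Every pipeline stage is exercised on generated data with known ground
truth.  The generator defaults emulate the statistical structure of the
study system: a skin-like cohort of 971 species compared against a larger
world-wide cohort, binary prevalences at the reported effect sizes (spore
formation 3% vs 22.5%, catalase 47% vs 57%, glucose use 91% ...),
categorical shifts (abundant skin taxa half as likely aerobic, favoring a
facultative strategy; clumps over chains), growth envelopes centred on the
reported means (pH maximum 7.97 vs 9.03, temperature optimum ~33 vs ~31 C)
and ~15% missing values per trait, missing completely at random.

Phylogenies are pure-birth (Yule) trees scaled to unit height; binary
traits evolve along them under a two-state Markov process, which produces
the clade-clumped trait patterns the phylogenetic regression must correct
for.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._schema import Schema
from .phylo import Phylogeny, ou_correlation
from .screening import SITE_CLASSES, AbundanceTable
from .traitdb import QuantRange, TaxonRecord, TraitDatabase

__all__ = [
    "BinaryTraitSpec",
    "CategoricalTraitSpec",
    "EnvelopeSpec",
    "SimulationSpec",
    "gen_tree",
    "sim_binary_trait_on_tree",
    "sim_logistic_on_tree",
    "gen_trait_database",
    "gen_abundance_table",
]

PHYLA = ("Actinobacteria", "Firmicutes", "Proteobacteria", "Bacteroidetes")


@dataclass
class BinaryTraitSpec:
    prevalence_a: float
    prevalence_b: float


@dataclass
class CategoricalTraitSpec:
    #: level -> probability, per group; probabilities sum to 1
    probs_a: dict[str, float]
    probs_b: dict[str, float]


@dataclass
class EnvelopeSpec:
    """Growth envelope: per-group means of the minimum and maximum, shared sd.

    Per species, min ~ N(min_mean, sd), range ~ N(max_mean - min_mean, sd)
    truncated positive, max = min + range, and the optimum sits at a jittered
    interior point, so min < optimum < max and range = max - min hold by
    construction.
    """

    min_mean: tuple[float, float]
    max_mean: tuple[float, float]
    sd: float = 1.0


def _default_binary() -> dict[str, BinaryTraitSpec]:
    return {
        "spore_formation": BinaryTraitSpec(0.03, 0.225),
        "pigment": BinaryTraitSpec(0.55, 0.68),
        "catalase": BinaryTraitSpec(0.47, 0.57),
        "oxidase": BinaryTraitSpec(0.25, 0.47),
        "nitrate_reduction": BinaryTraitSpec(0.40, 0.40),
    }


def _default_categorical() -> dict[str, CategoricalTraitSpec]:
    return {
        "oxygen_use": CategoricalTraitSpec(
            {"aerobic": 0.25, "facultative": 0.50, "anaerobic": 0.20, "microaerophilic": 0.05},
            {"aerobic": 0.50, "facultative": 0.25, "anaerobic": 0.20, "microaerophilic": 0.05},
        ),
        "aggregation": CategoricalTraitSpec(
            {"singly": 0.50, "chains": 0.15, "clumps": 0.35},
            {"singly": 0.50, "chains": 0.30, "clumps": 0.20},
        ),
    }


def _default_envelopes() -> dict[str, EnvelopeSpec]:
    return {
        "temperature": EnvelopeSpec((20.3, 18.3), (42.7, 40.7), sd=3.0),
        "ph": EnvelopeSpec((5.72, 5.65), (7.97, 9.03), sd=0.7),
        "nacl": EnvelopeSpec((1.09, 0.02), (2.23, 3.40), sd=0.5),
    }


def _default_substrates() -> dict[str, BinaryTraitSpec]:
    return {
        "glucose": BinaryTraitSpec(0.91, 0.80),
        "glutamate": BinaryTraitSpec(0.95, 0.85),
        "gelatin": BinaryTraitSpec(0.03, 0.20),
    }


@dataclass
class SimulationSpec:
    """Ground-truth parameters of a two-group trait-database simulation."""

    n_taxa: tuple[int, int] = (971, 3000)
    binary: dict[str, BinaryTraitSpec] = field(default_factory=_default_binary)
    categorical: dict[str, CategoricalTraitSpec] = field(default_factory=_default_categorical)
    envelopes: dict[str, EnvelopeSpec] = field(default_factory=_default_envelopes)
    gc_mean: tuple[float, float] = (51.7, 55.0)
    gc_sd: float = 8.0
    substrates: dict[str, BinaryTraitSpec] = field(default_factory=_default_substrates)
    missingness: float = 0.15
    #: per-group phylum weights (skin-like group is Actinobacteria-heavy)
    phylum_weights_a: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)
    phylum_weights_b: tuple[float, ...] = (0.20, 0.25, 0.40, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_taxa):
            raise ValueError("n_taxa must be >= 1 per group")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        for name, bt in {**self.binary, **self.substrates}.items():
            for p in (bt.prevalence_a, bt.prevalence_b):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}: prevalence {p} outside [0, 1]")
        for name, ct in self.categorical.items():
            for probs in (ct.probs_a, ct.probs_b):
                if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{name}: level probabilities must be >= 0 and sum to 1")
        for name, env in self.envelopes.items():
            if env.sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        if self.gc_sd < 0:
            raise ValueError("gc_sd must be >= 0")


# ---------------------------------------------------------------------------
# trees and traits on trees


def gen_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with uniquely named tips, scaled to unit height."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the process stops at the n-th split; extend pendant edges by the
    # waiting time to the next (unobserved) event so cherries have height
    tail = rng.expovariate(n_tips * 1.0)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    phy = Phylogeny(tree)
    return phy.scale_to_unit_height()


def sim_binary_trait_on_tree(
    tree: Phylogeny, rate01: float, rate10: float, seed: int
) -> dict[str, int]:
    """Two-state Markov trait evolution along branches.

    The root state is drawn from the stationary distribution
    pi_1 = rate01 / (rate01 + rate10); along a branch of length t the chain
    transitions with the usual two-state matrix exponential.  Low rates on a
    short tree leave tips clumped around the root state; high rates mix to
    stationarity.  Returns tip name -> 0/1.
    """
    if rate01 <= 0 or rate10 <= 0:
        raise ValueError("rates must be > 0")
    rng = np.random.default_rng(seed)
    total = rate01 + rate10
    pi1 = rate01 / total
    states: dict = {}
    root = tree.tree.seed_node
    states[root] = int(rng.random() < pi1)
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_state = states[node.parent_node]
        decay = math.exp(-total * t)
        p1 = pi1 + ((1.0 if parent_state == 1 else 0.0) - pi1) * decay
        states[node] = int(rng.random() < p1)
    return {leaf.taxon.label: states[leaf] for leaf in tree.tree.leaf_node_iter()}


def sim_logistic_on_tree(
    tree: Phylogeny,
    x,
    beta0: float,
    beta1: float,
    sigma2: float,
    alpha: float,
    seed: int,
) -> np.ndarray:
    """Bernoulli response with tree-structured latent correlation.

    logit P(y_i = 1) = beta0 + beta1 x_i + u_i with
    u ~ N(0, sigma2 * C(alpha)), the generating model of the corrected
    logistic regression.  Observations follow the tree's tip order.
    """
    x = np.asarray(x, dtype=float)
    order = tree.tip_names
    if len(x) != len(order):
        raise ValueError("x must have one value per tip")
    rng = np.random.default_rng(seed)
    scaled = tree.scale_to_unit_height()
    S, T = scaled.shared_depth_matrix(order)
    if sigma2 > 0:
        C = ou_correlation(S, T, alpha)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
        u = math.sqrt(sigma2) * (L @ rng.standard_normal(len(order)))
    else:
        u = np.zeros(len(order))
    eta = beta0 + beta1 * x + u
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(order)) < p).astype(int)


# ---------------------------------------------------------------------------
# trait databases


def _species_names(group: str, n: int) -> list[str]:
    return [f"Syntheticus {group.lower()}{i:04d}" for i in range(1, n + 1)]


def gen_trait_database(spec: SimulationSpec) -> tuple[TraitDatabase, TraitDatabase, dict]:
    """Generate two trait databases (groups A and B) plus the truth record.

    Databases conform to the trait-table schema (only the simulated columns
    are populated; the rest stay unknown), unknowns are injected completely
    at random at the missingness rate, and the returned truth dict stores
    every generating parameter.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    schema = Schema()
    dbs = []
    for gi, group in enumerate(("A", "B")):
        n = spec.n_taxa[gi]
        weights = np.asarray(
            spec.phylum_weights_a if gi == 0 else spec.phylum_weights_b, dtype=float
        )
        weights = weights / weights.sum()
        phyla = rng.choice(len(PHYLA), size=n, p=weights)
        records = []
        for i, name in enumerate(_species_names(group, n)):
            rec = TaxonRecord(species_name=name, phylum=PHYLA[phyla[i]])
            for trait, bt in spec.binary.items():
                prev = bt.prevalence_a if gi == 0 else bt.prevalence_b
                if rng.random() < spec.missingness:
                    rec.binary_traits[trait] = "unknown"
                else:
                    rec.binary_traits[trait] = "positive" if rng.random() < prev else "negative"
            for trait, ct in spec.categorical.items():
                probs = ct.probs_a if gi == 0 else ct.probs_b
                if rng.random() < spec.missingness:
                    rec.categorical_traits[trait] = set()
                else:
                    levels = list(probs)
                    lvl = levels[rng.choice(len(levels), p=np.array(list(probs.values())))]
                    rec.categorical_traits[trait] = {lvl}
            for substrate, bt in spec.substrates.items():
                prev = bt.prevalence_a if gi == 0 else bt.prevalence_b
                if rng.random() < spec.missingness:
                    rec.substrate_use[substrate] = "unknown"
                else:
                    rec.substrate_use[substrate] = (
                        "positive" if rng.random() < prev else "negative"
                    )
            if rng.random() >= spec.missingness:
                rec.gc_content = float(
                    np.clip(rng.normal(spec.gc_mean[gi], spec.gc_sd), 0.0, 100.0)
                )
            for env_name, env in spec.envelopes.items():
                if rng.random() < spec.missingness:
                    continue
                lo = rng.normal(env.min_mean[gi], env.sd)
                width = env.max_mean[gi] - env.min_mean[gi]
                rng_width = max(1e-6, rng.normal(width, env.sd))
                hi = lo + rng_width
                opt = lo + rng_width * rng.uniform(0.35, 0.65)
                qr = rec.envelope(env_name)
                qr.minimum, qr.maximum, qr.optimum = float(lo), float(hi), float(opt)
                qr.derive_range()
            records.append(rec)
        dbs.append(TraitDatabase(records, schema=schema))
    truth = {
        "n_taxa": spec.n_taxa,
        "binary": {k: (v.prevalence_a, v.prevalence_b) for k, v in spec.binary.items()},
        "categorical": {
            k: {"A": dict(v.probs_a), "B": dict(v.probs_b)} for k, v in spec.categorical.items()
        },
        "envelopes": {
            k: {"min_mean": v.min_mean, "max_mean": v.max_mean, "sd": v.sd}
            for k, v in spec.envelopes.items()
        },
        "gc": {"mean": spec.gc_mean, "sd": spec.gc_sd},
        "substrates": {k: (v.prevalence_a, v.prevalence_b) for k, v in spec.substrates.items()},
        "missingness": spec.missingness,
        "seed": spec.seed,
    }
    return dbs[0], dbs[1], truth


# ---------------------------------------------------------------------------
# abundance tables


def gen_abundance_table(
    n_taxa: int,
    n_samples: int,
    site_labels=None,
    abundant_fraction: float = 0.2,
    seed: int = 0,
    all_fraction: float = 1.0,
) -> tuple[AbundanceTable, dict]:
    """Log-normal abundance profiles with a designated abundant subset.

    A fraction ``abundant_fraction`` of taxa exceeds 0.1% of reads in at
    least one sample by construction; the remaining taxa stay strictly
    between 0.001% and 0.1% (or, for the ``1 - all_fraction`` tail, never
    exceed 0.001%, so they fall below even the permissive screen).  Returns
    the table and the truth dict with the designated member lists.
    """
    if not 0.0 <= abundant_fraction <= 1.0 or not 0.0 <= all_fraction <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    if n_taxa < 1 or n_samples < 1:
        raise ValueError("need >= 1 taxon and >= 1 sample")
    rng = np.random.default_rng(seed)
    taxa = [f"Syntheticus taxon{i:04d}" for i in range(1, n_taxa + 1)]
    samples = [f"S{j:03d}" for j in range(1, n_samples + 1)]
    if site_labels is None:
        site_labels = [SITE_CLASSES[j % len(SITE_CLASSES)] for j in range(n_samples)]
    n_abundant = int(round(abundant_fraction * n_taxa))
    n_detected = int(round(all_fraction * n_taxa))
    values = np.zeros((n_taxa, n_samples))
    # baseline noise well below the permissive threshold
    base = np.exp(rng.normal(math.log(1e-4), 0.5, size=(n_taxa, n_samples)))
    values += np.minimum(base, 9e-4)
    for i in range(n_taxa):
        if i < n_abundant:
            peak = rng.uniform(0.2, 5.0)  # percent of reads, clearly abundant
        elif i < n_detected:
            peak = rng.uniform(0.002, 0.09)  # detected but never abundant
        else:
            continue  # stays below 0.001% everywhere
        j = rng.integers(n_samples)
        values[i, j] = peak
    # guard the per-sample budget (values are percentages of reads)
    col_sums = values.sum(axis=0)
    if (col_sums > 100.0).any():
        raise ValueError("abundance budget exceeded; reduce n_taxa or peaks")
    table = AbundanceTable(
        pd.DataFrame(values, index=taxa, columns=samples),
        dict(zip(samples, site_labels)),
    )
    truth = {
        "abundant": set(taxa[:n_abundant]),
        "all": set(taxa[:n_detected]),
        "undetected": set(taxa[n_detected:]),
        "seed": seed,
    }
    return table, truth
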