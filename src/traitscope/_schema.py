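"""Schema configuration for trait tables.

A :class:`Schema` declares which columns of a trait table are binary,
categorical or quantitative, the controlled vocabulary of every categorical
trait, the substrate catalog with its chemical categories, and the alias map
that translates raw cell strings (``"+"``, ``"-"``, ``"v"``, ``"ND"`` ...)
into parsed states.  Schemas are plain data and can be loaded from YAML, so a
new trait class needs a config change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Raw-cell aliases for binary traits and substrate usage.  ``variable`` marks
#: documented strain-to-strain variation: the species is counted as unknown in
#: prevalence denominators but the trait is flagged on the record.
DEFAULT_BINARY_ALIASES: dict[str, str] = {
    "+": "positive",
    "positive": "positive",
    "pos": "positive",
    "1": "positive",
    "true": "positive",
    "yes": "positive",
    "-": "negative",
    "negative": "negative",
    "neg": "negative",
    "0": "negative",
    "false": "negative",
    "no": "negative",
    "v": "variable",
    "variable": "variable",
    "": "unknown",
    "nd": "unknown",
    "na": "unknown",
    "unknown": "unknown",
    "?": "unknown",
}

DEFAULT_BINARY_TRAITS: list[str] = [
    "spore_formation",
    "pigment",
    # enzyme activities
    "catalase",
    "oxidase",
    "urease",
    "alkaline_phosphatase",
    "acid_phosphatase",
    "gelatinase",
    "aesculin_hydrolysis",
    "alpha_galactosidase",
    "arylsulfatase",
    "pyrazinamidase",
    "tellurite_reductase",
    # gas production
    "methane",
    "h2s",
    "indole",
    "nitrate_reduction",
]

DEFAULT_CATEGORICAL_VOCABULARIES: dict[str, list[str]] = {
    "oxygen_use": ["aerobic", "facultative", "anaerobic", "microaerophilic"],
    "motility": ["none", "flagella", "gliding", "axial_filament", "other"],
    "shape": ["coccus", "coccobacillus", "bacillus", "spirillum", "other"],
    "gram_stain": ["positive", "negative", "variable"],
    "aggregation": ["singly", "chains", "clumps"],
}

#: Quantitative variables: GC content plus min/max/optimum/range triples for
#: growth temperature (degrees C), pH and NaCl concentration (% w/v).
QUANT_ENVELOPES: list[str] = ["temperature", "ph", "nacl"]
QUANT_PARTS: list[str] = ["min", "max", "optimum", "range"]

SUBSTRATE_CATEGORIES: list[str] = [
    "organic_acid",
    "amino_acid",
    "monosaccharide",
    "oligo_polysaccharide",
    "alcohol",
    "other",
]

DEFAULT_SUBSTRATES: dict[str, str] = {
    # organic acids
    "succinate": "organic_acid",
    "acetate": "organic_acid",
    "gluconate": "organic_acid",
    "2-ketogluconate": "organic_acid",
    "valerate": "organic_acid",
    "pyruvate": "organic_acid",
    "citrate": "organic_acid",
    "malonate": "organic_acid",
    "formate": "organic_acid",
    "aspartate": "organic_acid",
    # amino acids
    "glutamate": "amino_acid",
    "asparagine": "amino_acid",
    "serine": "amino_acid",
    "proline": "amino_acid",
    "alanine": "amino_acid",
    "leucine": "amino_acid",
    "glycine": "amino_acid",
    # monosaccharides
    "glucose": "monosaccharide",
    "xylose": "monosaccharide",
    "fructose": "monosaccharide",
    # oligo/polysaccharides
    "cellobiose": "oligo_polysaccharide",
    "starch": "oligo_polysaccharide",
    # alcohols
    "xylitol": "alcohol",
    "glycerol": "alcohol",
    # other
    "gelatin": "other",
    "urea": "other",
}


@dataclass
class Schema:
    """Column layout and vocabularies of a trait table."""

    binary_traits: list[str] = field(default_factory=lambda: list(DEFAULT_BINARY_TRAITS))
    categorical_vocabularies: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORICAL_VOCABULARIES.items()}
    )
    substrates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SUBSTRATES))
    binary_aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BINARY_ALIASES))
    #: separator for multi-valued categorical cells ("singly;clumps")
    multivalue_sep: str = ";"

    @property
    def categorical_traits(self) -> list[str]:
        return list(self.categorical_vocabularies)

    @property
    def quantitative_variables(self) -> list[str]:
        cols = ["gc_content"]
        for env in QUANT_ENVELOPES:
            cols.extend(f"{env}_{part}" for part in QUANT_PARTS)
        return cols

    @property
    def substrate_names(self) -> list[str]:
        return list(self.substrates)

    def columns(self) -> list[str]:
        """Full ordered column list of the TSV representation."""
        return (
            ["species", "phylum"]
            + self.binary_traits
            + self.categorical_traits
            + self.quantitative_variables
            + self.substrate_names
        )

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "binary_traits" in raw:
            kwargs["binary_traits"] = list(raw["binary_traits"])
        if "categorical_vocabularies" in raw:
            kwargs["categorical_vocabularies"] = {
                k: list(v) for k, v in raw["categorical_vocabularies"].items()
            }
        if "substrates" in raw:
            kwargs["substrates"] = dict(raw["substrates"])
        if "binary_aliases" in raw:
            aliases = dict(DEFAULT_BINARY_ALIASES)
            aliases.update({str(k).lower(): v for k, v in raw["binary_aliases"].items()})
            kwargs["binary_aliases"] = aliases
        if "multivalue_sep" in raw:
            kwargs["multivalue_sep"] = str(raw["multivalue_sep"])
        schema = cls(**kwargs)
        bad = set(schema.substrates.values()) - set(SUBSTRATE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown substrate categories: {sorted(bad)}")
        return schema

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "binary_traits": self.binary_traits,
                    "categorical_vocabularies": self.categorical_vocabularies,
                    "substrates": self.substrates,
                    "binary_aliases": self.binary_aliases,
                    "multivalue_sep": self.multivalue_sep,
                },
                fh,
                sort_keys=False,
            )
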