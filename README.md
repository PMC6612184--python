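# traitscope

Trait-based comparison of microbial communities. Given culture-derived
trait databases (one row per bacterial species: binary traits such as spore
formation and enzyme activities, categorical traits such as oxygen use and
cell shape, quantitative growth envelopes for temperature, pH and NaCl, and
per-substrate usage), `traitscope` answers the question that motivates
trait-based microbiome work: *which functional traits are over- or
under-represented in one community relative to another* — for instance,
abundant human-skin bacteria versus bacteria at large, or versus the rare
members of the same community — and *does the difference survive correction
for shared evolutionary history?*

It is written for microbial ecologists and biostatisticians who have a
species-by-trait table, a taxonomic classification summary with relative
abundances, and optionally a phylogeny, and who want the full comparison
workflow as reproducible, machine-readable tables.

## What it computes

- **Screening.** Species lists by abundance threshold: *detected* species
  exceed 0.001% of reads in at least one sample, *abundant* species exceed
  0.1% (strict inequalities); sets can be restricted to dry / moist /
  sebaceous skin sites and stratified by phylum. Unknown trait values are
  explicit and excluded from every denominator.
- **Binary traits.** Prevalence p̂ = k/n with binomial standard error
  √(p̂(1−p̂)/n), overall Pearson χ² on the 2×m positive/negative table, and
  pairwise contrasts z = (p̂₁−p̂₂)/√(se₁²+se₂²).
- **Categorical traits.** A randomization test of equal level proportions:
  group labels permuted (default B = 10⁵, seeded), per-level and overall
  (max-statistic) permutation p-values, exact enumeration for tiny samples.
- **Quantitative traits.** Nonparametric relative effects
  p = P(X < Y) + ½P(X = Y) via midranks, studentized with the
  Brunner–Munzel variance (Satterthwaite df), and all-pairs Tukey-type
  contrasts with joint equicoordinate multiplicity control.
- **Phylogenetic correction.** Naive logistic regression of group
  membership on each trait, and a corrected Bernoulli GLMM with
  tree-structured mean-reverting (Ornstein–Uhlenbeck) latent correlation,
  fit by Laplace-approximated maximum likelihood and screened against the
  intercept-only null by likelihood-ratio test — side by side, so
  phylogenetically driven "effects" are visible as such.
- **Synthetic data.** Generators for trait databases, abundance tables and
  Yule phylogenies with known ground truth, whose defaults encode the
  skin-vs-world study conditions (spore formation 3% vs 22.5%, glucose use
  91%, pH maximum 7.97 vs 9.03, ...), so the entire pipeline is testable
  without any downloads.

See `docs/methods.md` for the models, defaults and numerical decisions.

## Worked example

```python
from traitscope import (
    SimulationSpec, gen_trait_database, trait_prevalence,
    summarize_quantitative, pairwise_proportion_contrast, bm_contrast,
)

spec = SimulationSpec(seed=7)           # defaults = study-like conditions
skin, world, truth = gen_trait_database(spec)

spore_s = trait_prevalence(skin, None, "spore_formation")
spore_w = trait_prevalence(world, None, "spore_formation")
print(f"spore formation: skin {spore_s.k}/{spore_s.n} = {spore_s.proportion:.3f}, "
      f"world {spore_w.k}/{spore_w.n} = {spore_w.proportion:.3f}")
res = pairwise_proportion_contrast(spore_s.k, spore_s.n, spore_w.k, spore_w.n,
                                   groups=("skin", "world"))
print(f"z = {res.statistic:.2f}, p = {res.p_value:.3g}, "
      f"over-represented in: {res.direction}")

ph_s = summarize_quantitative(skin, None, "ph_max")
ph_w = summarize_quantitative(world, None, "ph_max")
print(f"pH maximum: skin mean {ph_s.mean:.2f} (n={ph_s.n}), "
      f"world mean {ph_w.mean:.2f} (n={ph_w.n})")
xs = [r.ph.maximum for r in skin.records.values() if r.ph.maximum is not None]
xw = [r.ph.maximum for r in world.records.values() if r.ph.maximum is not None]
bm = bm_contrast(xs, xw, pair=("skin", "world"))
print(f"relative effect P(skin < world) = {bm.p_hat:.3f}, "
      f"t = {bm.statistic:.2f}, p = {bm.p_raw:.3g}")
```

prints

```
spore formation: skin 28/820 = 0.034, world 586/2549 = 0.230
z = -18.69, p = 5.82e-78, over-represented in: world
pH maximum: skin mean 7.95 (n=830), world mean 9.03 (n=2557)
relative effect P(skin < world) = 0.781, t = 31.51, p = 8.62e-167
```

Spore formation is roughly seven-fold rarer in the skin-like cohort
(3.4% vs 23.0% of species with a known state — note the known-value
denominators), a difference the binomial contrast calls decisively. The
skin cohort tolerates less alkaline conditions: a randomly chosen skin
species has a lower pH maximum than a world species 78% of the time.

## Command line

```sh
traitscope simulate -o synthetic --seed 1      # synthetic study inputs
traitscope validate synthetic/group_a.tsv      # parse + invariant report
traitscope run -c config.yaml                  # full comparison workflow
traitscope summarize <output_dir>              # reprint summary tables
```

`run` consumes a YAML config naming the databases, cohorts (optionally
screened by abundance, site class or phylum), contrasts, thresholds and
test settings, and writes `results.tsv` (one row per trait × contrast,
plus per-level rows), summary tables, and a `provenance.json` with
versions, seeds and thresholds. Reruns with the same config and seed are
byte-identical. Exit codes: 0 ok, 1 validation error, 2 runtime error.

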