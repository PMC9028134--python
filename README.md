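# venomdelta

Comparative venom-gland transcriptomics for a two-species study design:
compositional differential-expression calling, ortholog pairing with pairwise
dN/dS, weighted coexpression modules, miRNA target prediction, and
transcriptome–proteome integration — exercised end to end on a synthetic
two-species cohort generator with known ground truth.

## Scientific problem

Closely related pit vipers can diverge sharply in venom composition even when
their genomes are nearly identical, because venom phenotype is dominated by
*expression* differences in a handful of toxin families (metalloproteinases,
serine proteases, phospholipases A2, C-type lectins, …). Asking "which toxins
changed?" from RNA-seq is harder than it looks:

- **Expression is compositional.** TPM values are constrained to a constant
  sum, so a real increase in one dominant family depresses every other value.
  venomdelta works in centered log-ratio (clr) space, where ratios — the only
  identifiable quantities — become differences.
- **There is no replication to speak of.** Venom-gland studies typically have
  two individuals per species. Instead of per-gene tests, venomdelta builds an
  empirical null from the thousands of *nontoxin* ortholog pairs: a total
  least squares line through nontoxin clr values plus a 99th-percentile band
  of orthogonal residuals. Toxins falling outside that band are called
  divergent, with a direction.
- **Expression divergence and sequence divergence are different questions.**
  Orthologs are paired by reciprocal best hit (BLOSUM62 global alignment with
  a k-mer prescreen), and each pair gets pairwise dS, dN, and ω by
  Nei–Gojobori (1986) counting with Jukes–Cantor correction, dS-range
  filters, and toxin-vs-nontoxin rank tests.
- **Regulation leaves multi-omic fingerprints.** Coexpression modules
  (WGCNA-style: |r|^β adjacency, topological overlap, average linkage),
  miRNA seed-site scanning (8mer/7mer-m8/7mer-A1/6mer), spectral-count
  translation efficiency, and a conjunctive filter that nominates
  (miRNA, toxin) repression candidates: miRNA enriched in one species, target
  translationally repressed in the same species, with a seed site in its
  3'UTR.

Because real studies at this scale are not statistically reproducible from
summary numbers, the package ships a **synthetic cohort generator** whose
defaults emulate the study conditions (two species × two individuals,
~3600 nontoxin orthologs, ~50 toxins in 10 families, planted expression
shifts, planted ω values, planted TE offsets and miRNA chains). Every
analysis stage is validated against that known ground truth.

## Worked example

```python
import numpy as np
from venomdelta.cohort import CohortConfig, generate_cohort
from venomdelta.outliers import interspecific_divergence
from venomdelta.evolution import rbh_pairs, pairwise_dnds

# a small cohort with one planted 6-fold expression shift and one
# positively selected toxin
cfg = CohortConfig(
    n_nontoxin_orthologs=300,
    toxin_family_plan=[("PLA2", 2), ("SVMP", 4)],
    toxin_family_percent={"PLA2": 30.0, "SVMP": 70.0},
    planted_expression_shifts=[("PLA2-1", "fonsecai", 6.0)],
    dnds_plan=[("PLA2-1", 0.05, 2.4)],
    rng_seed=7,
)
cohort = generate_cohort(cfg)

# expression divergence: toxins outside the nontoxin 99% band
pairs = [(f"{t}@cotiara", f"{t}@fonsecai")
         for t in cfg.toxin_ids() + cfg.nontoxin_ids()]
band, calls = interspecific_divergence(
    cohort.expression["cotiara"], cohort.expression["fonsecai"], pairs)
flagged = [(c.id, c.direction) for c in calls if c.is_outlier]
print(flagged)           # [('PLA2-1@cotiara', 'fonsecai')]

# sequence divergence: RBH orthologs -> pairwise dN/dS
orthologs, _, _ = rbh_pairs(cohort.cds["cotiara"], cohort.cds["fonsecai"])
res = {p.id_a: pairwise_dnds(p) for p in orthologs}
r = res["PLA2-1@cotiara"]
print(round(r.dS, 3), round(r.omega, 2))   # dS near 0.05, omega near 2.4
```

### Command line

```bash
# full pipeline on the default study-condition cohort
venomdelta run-all --seed 1 --out results/

# or from a config file (see tests/fixtures/run_all_config.yaml)
venomdelta run-all --config tests/fixtures/run_all_config.yaml --out results/

# individual stages
venomdelta simulate  --seed 3 --out cohort/
venomdelta normalize --expression cohort/expression_cotiara.tsv --out clr.tsv
venomdelta dnds --help
```

`run-all` writes a `report.json` plus per-stage TSVs (clr outlier calls,
dN/dS table, module assignments, translation efficiency, miRNA counts and
sites, repression candidates). Runs are byte-identical for a fixed seed.

## Reproduction

```bash
# full test suite, including the acceptance suite
# (tests/test_acceptance.py, one test per acceptance criterion)
python -m pytest -q tests/

# headline quantities of the default pipeline, as JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance suite validates each stage against independent oracles:
exhaustive codon-pathway enumeration for NG86 counting, brute-force
seed-site scanning, an independent sort-based TMM oracle, planted-truth
recovery for outlier calling, module detection, miRNA chains, and proteome
correlation, and byte-level determinism of `run-all`.

See `docs/methods.md` for the statistical methods, model assumptions, and
numerical design choices.
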