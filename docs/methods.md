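# Methods

Statistical methods, model assumptions, and numerical design choices of
venomdelta. Default parameter values are stated with their rationale; all of
them are overridable through `PipelineConfig` / the stage configs.

## 1. Compositional expression analysis

**clr transform.** TPM values are compositions (constant-sum), so all
analyses operate on centered log-ratios: `clr(x) = log x − mean(log x)` per
sample. Zeros are replaced multiplicatively by half the smallest nonzero
value in the sample before taking logs. Properties guaranteed (and
property-tested): columns sum to zero, scale invariance, and monotonicity
*with ties* — two distinct doubles can have exactly equal float64 logs, so
strict rank preservation is not attainable by any log-based transform; the
tests assert the tie-allowing version.

**TPM filter.** Transcripts must exceed (strictly) 1 TPM; scope `all`,
`per-species`, or a named species. Strict inequality makes the boundary
unambiguous.

**TMM normalization.** edgeR-style trimmed mean of M-values (trim 30% on M,
5% on A, precision weights, reference column = library whose 75th percentile
is closest to the mean). One deliberate departure: trimming is done by
*sort position* (drop `floor(n·trim)` entries from each end of a stable
argsort) rather than by average rank. The two rules coincide for distinct
values, but synthetic and deeply-normalized data contain large exact-tie
blocks whose average ranks can straddle both trim bounds, emptying the kept
set and silently degrading to an untrimmed mean. Sort-position trimming
drops interchangeable tied members instead, leaving the kept mean unchanged.

## 2. Divergence outlier calling

With two individuals per species there is no per-gene test. Instead the
thousands of nontoxin orthologs form an empirical null:

1. Fit a total least squares (orthogonal) line through nontoxin clr values
   (x = one individual/species, y = the other). TLS, not OLS, because both
   axes carry the same measurement noise; OLS would attenuate the slope and
   bias the band.
2. The null band is the 99th percentile of |orthogonal residuals| (or the
   signed 0.5th/99.5th percentiles in `signed` mode).
3. Toxins outside the band are outliers; the residual sign gives the
   direction (which species/individual is higher).

Intraspecific mode compares the two individuals of one species;
interspecific mode compares species-mean clr values over RBH ortholog pairs.

## 3. Ortholog pairing and dN/dS

**RBH.** Reciprocal best hits under Needleman–Wunsch global alignment
(BLOSUM62, gap open −10, extend −1), partitioned by class label so toxins
pair only with toxins of the same family. Partitions with more than 250,000
cross-pairs are prescreened by 4-mer Jaccard similarity computed as a sparse
incidence-matrix product, keeping the top 8 candidates per query in each
direction plus any reciprocal hits discovered the other way; the test suite
asserts prescreen == exhaustive on a mutated-ortholog cohort.

**NG86 counting.** Nei–Gojobori (1986): per-codon synonymous site fraction
from the 61 sense codons (stop-codon mutations excluded from the site count
denominator, so S + N = 3 per codon), pathway-averaged synonymous/
nonsynonymous difference counts over all orderings of 1–3 nucleotide
changes (pathways through stops discarded), Jukes–Cantor correction
`d = −3/4 · ln(1 − 4p/3)`. Codon tables are precomputed and cached; the
acceptance suite checks all 61×61 codon pairs against an independent
exhaustive enumeration oracle. Pairs with p ≥ 3/4 are saturated and return
NaN with an `undefined` flag.

**Filters and comparison.** The default dS window keeps 0.001 ≤ dS ≤ 0.10
(inclusive both ends): the lower bound removes pairs with no usable
synonymous signal, the upper bound removes saturation-inflated estimates.
Toxin vs nontoxin dS/dN/ω are compared by Mann–Whitney rank-sum (the
contrast is structurally two-sample); ω > the nontoxin 95th percentile and
ω > 1 are flagged.

## 4. Coexpression modules

WGCNA-style and deliberately minimal: log2(TPM+1), a lowess
variance-vs-mean trend filter (keep transcripts more variable than the
trend), adjacency `|pearson r|^β` with β = 10, topological overlap
similarity, average-linkage clustering on 1 − TOM, static cut at 0.25,
eigengene merging of modules below `min_module_size` (default 1, a no-op).
Notes:

- The adjacency is unsigned, so perfectly anti-correlated profiles merge by
  design (they share a regulatory axis).
- 1 − TOM can be −1e−16 by float error; distances are clipped at 0 before
  linkage.
- The filter output is tagged (`attrs["vst_filtered"]`) so applying it twice
  equals applying it once.
- With 4 samples (the study design) correlations are coarse; a warning is
  emitted below 8 samples, and partition-recovery validation uses synthetic
  cohorts with more samples.

## 5. miRNA toolkit

Read collapsing with ≤1 mismatch to known matures and a 3'-end length
window; novel-candidate detection from read pairs forming a duplex with
2-nt 3' overhangs and ≥14 paired positions (G:U allowed); canonical seed
sites (8mer, 7mer-m8, 7mer-A1, 6mer) by exact Watson–Crick complement to
miRNA positions 2–7/2–8 plus the A1 rule; a transparent gap-free duplex
score. Thermodynamic folding (miRanda/RNAhybrid internals) is intentionally
out of scope: the downstream analysis consumes only presence/absence of a
plausible site.

`integrate_candidates` nominates a (miRNA, toxin) repression pair only when
all three conditions hold: TMM-normalized miRNA log2 ratio ≥ 1 toward the
target species (with a +0.5 count stabilizer), target translation
efficiency in the lowest quartile for that species, and ≥1 seed site in the
target's 3'UTR. Conjunction keeps the false-positive rate at zero on
planted cohorts.

## 6. Proteome integration

Spectral counts are normalized to eUSC fractions and clr-transformed;
transcriptome–proteome agreement is reported as Spearman ρ plus a fitted
line (OLS by default — here the transcript axis is the natural predictor —
orthogonal by option). Translation efficiency is the clr difference
(protein − transcript) over shared transcripts; `low_te_set` takes the
lowest quartile per species.

## 7. Synthetic cohort generator

The generator's defaults emulate the study conditions: two species
(`cotiara`, `fonsecai`) × two individuals, ~3600 nontoxin orthologs, ~50
toxins in 10 families with realistic venom composition, planted 6-fold
PLA2 and SVMP/SVSP/CTL expression shifts, a dnds plan with one positively
selected toxin (ω = 2.41 at dS ≈ 0.05), TE offsets of −2 on two toxins with
matching planted miRNA chains, and species-specific TE noise (sd 1.4 vs
0.6). What it emulates: compositional structure, ortholog divergence at
realistic dS, the repression fingerprint. What it does not: read-level
noise, isoforms, mapping artifacts, genome structure.

Codon evolution proposes uniform single-nucleotide changes along each
branch, rejects stops, accepts nonsynonymous proposals with probability
min(1, ω) and synonymous with min(1, 1/max(ω, 1)), with a Poisson
synonymous quota calibrated to the target dS. Target dS values implying
p_S ≥ 0.70 are refused — the Jukes–Cantor correction domain ends at 3/4 and
estimates beyond ~0.70 are numerically explosive.

Proteome simulation draws multinomial spectral counts from expression-
derived abundances perturbed by planted TE offsets plus per-toxin TE noise
(offsets for the same toxin accumulate). All layers are deterministic given
`rng_seed`; pipeline runs are byte-identical for a fixed seed.

## 8. Testing strategy

- Independent oracles, not regression values: exhaustive codon-pathway
  enumeration (NG86), brute-force window scans (seed sites), a sort-based
  trimmed-mean oracle (TMM), closed-form expectations (clr, TLS, Spearman
  under a Gaussian copula).
- Planted ground truth: every detector is run on cohorts where the answer
  is known by construction (shifts, ω, modules, repression chains).
- Property tests (hypothesis, derandomized) for invariants: clr zero-sum /
  scale invariance / tie-allowing monotonicity, partition properties,
  alphabet invariance.
- `tests/test_acceptance.py` holds one test per acceptance criterion;
  `scripts/acceptance.py` recomputes the default pipeline's headline
  quantities as JSON.
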