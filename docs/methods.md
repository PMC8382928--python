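# Methods

## The quartet scan

The scan targets alleles driven to high frequency by whole-genome duplication
(WGD) rather than by local population history. Its unit of design is a
*quartet*: two diploid and two autotetraploid populations, giving six pairwise
contrasts — four interploidy (p1–p4) and two within-ploidy (dd between the
diploids, tt between the tetraploids).

Differentiation is Nei's Fst. Per SNP with population frequencies p₁, p₂:

    Hs = (2p₁q₁ + 2p₂q₂) / 2      Ht = 2 p̄ q̄,  p̄ = (p₁+p₂)/2
    Fst = 1 − Hs/Ht               (undefined when Ht = 0)

Windows (non-overlapping, anchored at scaffold coordinate 0, 1 kb by default)
and genes aggregate by ratio of sums, `Fst = 1 − ΣHs/ΣHt`, which weights SNPs
by their informativeness rather than averaging noisy per-SNP ratios. Windows
with fewer than `min_snps` SNPs (default 20; 5 per gene for the gene-level
scan) are marked ineligible but kept in the output.

The rank-sum step: (1) windows in the top `top_frac` (default 1%) of dd or tt
Fst are flagged and excluded — differentiation inside a cytotype cannot be a
WGD response; (2) eligible windows are ranked by Fst descending in each
interploidy contrast (average ranks on ties); (3) `R` is the sum of the four
ranks; (4) candidates are windows with `R` in the lowest `top_frac` quantile.
Whether exclusion precedes ranking is configurable (`exclusion_order`,
default `"before"`); the two orders differ only marginally because excluded
windows are rare.

Numerical choices: negative window Fst (Hs > Ht, common at low
differentiation) is clamped to 0 for ranking but reported raw; the dd/tt
outlier rule uses a strict `>` against the quantile so that a constant
within-ploidy Fst flags nothing; undefined Fst ranks as 0. Coordinates are
0-based half-open internally, converted at the VCF/GFF3 boundary only.

## Pool-seq allele frequencies

A replicate pool's frequency estimate is alt reads / total reads; the
population estimate is the unweighted mean over its replicates (replicates
with zero depth are ignored; a site with a fully missing population is
dropped and logged). Depth filters remove a site when any replicate pool is
below `min_dp` (default 10) or above `max_dp`; a flag switches to summed
per-population depth, since published pipelines rarely state which was used.
The `max_dp` cutoff can be derived as `1.6 x` the second local mode of the
per-site depth histogram — the first mode is a low-depth artifact, the second
is genuine coverage, and far-above-mode sites are collapsed paralogs.

## FineMAV

Each amino-acid substitution is scored `S = G x f_max x DAP`:

* `G` — Grantham (1974) physicochemical distance between the two residues
  (0 for identity, 5–215 otherwise; shipped as a validated data file);
* polarization — the minor allele, averaged over the two cytotype groups, is
  treated as derived (`d = f` or `1 − f`; an exact tie keeps the alternate);
* `f_max = max(d₂ₓ, d₄ₓ)`;
* `DAP = (max d / Σd)^A`, purity exponent `A = 3.5` by default: DAP → 1 when
  one cytotype carries all the derived allele, and decays quickly as the
  allele is shared.

Synonymous records and records with Σd = 0 score exactly 0 and are excluded
from the outlier quantile, which is taken over scored records only (ties at
the threshold expand the outlier set). An alternative amplification
`|d₄ₓ − d₂ₓ|` in place of `f_max` sits behind the `formula="afd"` flag.
Polarization uses cytotype groups, not individual populations; a
population-level variant would only sharpen purity at these sample sizes.

## Convergence tests

Candidates from two species are mapped to one reference namespace via a
five-rule cascade (single reference gene in the orthogroup; RBH within the
orthogroup; lowest-E-value orthogroup member; RBH outside; global best hit;
otherwise unassigned). Overlap between candidate lists is a two-sided Fisher
exact test on the 2x2 membership table over an explicit gene universe — the
universe is a required parameter, never inferred.

GO enrichment uses the elim algorithm: terms are tested most-specific-first
(depth = longest path to a root), each by one-sided Fisher; when a term's p
falls below `elim_cutoff` (default 0.01) its candidate genes are removed from
all ancestors' tallies before those are tested, suppressing redundant
enrichments along the hierarchy. Terms annotated to fewer than
`min_node_size` universe genes (default 150) are skipped; the gate uses
pre-elimination counts. `elim_cutoff = 0` reduces exactly to classic
per-term Fisher.

Network convergence counts species-A candidates with ≥ 1 (and > 1) direct
interaction-network edges to species-B candidates, at confidence
≥ `min_confidence` (default 400 on the 0–1000 scale, i.e. medium). The null
re-draws A-sized gene sets uniformly from the universe `n_perm` times
(default 1000) and the p-value uses the add-one rule
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so p is never 0 and floors at
1/1001. Only direct ("first shell") edges count; no transitive expansion.

## Meiotic stability

Spreads are banded by bivalent count — diploid: 8 stable, 7–6 partly stable,
5–4 partly unstable, <4 unstable; tetraploid: 16 / 14–12 / 10–8 / <8. The
tetraploid counts 15 and 11 fall between the published bands; the nearest
band is extended downward (15 → partly stable, 11 → partly unstable) with a
warning. Stability is summarized per individual (qualifying / scored cells,
under either the stable-only or the stable-plus-partly definition) and per
ploidy (unweighted over individuals). The ploidy contrast is a binomial GLM
on cell outcomes; the reported statistic is the deviance drop of the ploidy
term, which equals the 2x2 G-statistic `2ΣO·ln(O/E)` when cells are
aggregated, with a chi-square(1) reference. A saturated two-group fit
separates perfectly by construction; the deviance is still well-defined and
fit-time warnings are silenced.

## The synthetic-data generator

The generator's defaults are the study conditions of the empirical design it
emulates: 4 populations (2 diploid, 2 tetraploid), 25 individuals per pool, 3
replicate pools, mean replicate-pool depth 80, 50,000 SNPs over 4 scaffolds of
500 kb, per-branch drift `F = 0.05`, and 20 ploidy-associated plus 20
lineage-specific sweeps of frequency shift 0.8.

* Ancestral frequencies: Beta(0.5, 0.5) truncated to [0.05, 0.95] — U-shaped
  like a real site-frequency spectrum but kept polymorphic.
* Drift: Balding–Nichols, each population an independent branch with
  parameter `drift_fst`. Two populations drifted by `F` from a common
  ancestor then show pairwise Nei Fst `F/(2−F)` in expectation (at `F = 0.05`,
  about 0.026 — matching the modest genome-wide differentiation the design
  assumes).
* Sweeps: implanted as contiguous 1-kb regions chosen among regions holding
  at least `min_sweep_snps` (default 20) SNPs, so every implanted sweep is in
  principle detectable at the default window settings and recovery measures
  ranking behaviour rather than SNP-density luck. Ancestral frequencies at
  sweep loci are compressed below `1 − sweep_afd` so the shift fits in [0, 1].
  Ploidy sweeps shift both tetraploid populations in the same direction
  (one shared origin of the tetraploids); lineage sweeps shift exactly one
  population, cycling over all four.
* Pool reads, per replicate: chromosome counts `Binomial(ploidy x N, AF)`
  (tetraploid pools sample 4N chromosomes, diploid 2N — the dosage difference
  is the point of the design), depth `Poisson(mean_depth)` (negative binomial
  behind `depth_dispersion`), alt reads binomial at the realized pool
  fraction.
* Functional universes: a random GO DAG (each term 1–2 parents among earlier
  terms), gene annotations propagated to all ancestors, random interaction
  edges, and planted modules — fully wired bipartite gene sets (score 900)
  connecting designated species-A and species-B candidates. The two species'
  candidate lists are drawn independently so ortholog-level overlap behaves
  like its null.
* Meiotic counts: per cell, a stability category from a per-ploidy
  multinomial, then a bivalent count uniform within the category's band.

What the generator does **not** emulate: linkage (SNPs are independent given
population frequencies, so no haplotype structure or hitchhiking), demographic
history beyond a star phylogeny, sequencing error, mapping bias, and
overdispersed depth by default. Passing tests therefore demonstrate the
ranking, exclusion, calibration, and bookkeeping logic — not haplotype-based
power on real genomes.

Two accuracy notes derived from the model itself. First, pool-frequency
estimates have a finite-pool error floor: with 25 diploid individuals x 3
replicates, the pool-sampling stage alone leaves a per-population standard
error around `sqrt(pq/50)/sqrt(3)` no matter how deep the sequencing; tests
assert the corresponding bound (mean absolute error < 0.03 at depth 500) and
that the error keeps shrinking when pools grow. Second, at ~25 SNPs/kb a
50,000-SNP genome yields ~1,700 eligible windows, so a top-1% candidate list
holds 17–18 windows; with 20 implanted ploidy sweeps the attainable recovery
tops out near 85–90%.

## Calibration choices

The permutation-test null calibration runs 200 seeded null universes and
checks the p-values against uniformity (Kolmogorov–Smirnov). Because the
overlap statistic is integer-valued, a single fixed edge density makes the
add-one estimator visibly conservative (ties between observed and null
statistics); the calibration therefore sweeps edge density across runs —
still a null in every run (random edges, independent random candidates) —
so the p-value distribution is examined across the statistic's full range.
Calibration runs use `n_perm = 199` (p-granularity 1/200 suffices for a KS
check over 200 values); the planted-module floor check uses `n_perm = 1000`.

## Pipeline and reproducibility

`run_scan_pipeline` composes simulate/load → depth filter → allele
frequencies → six window tables → rank sum → gene annotation → gene-level
scan → FineMAV → contrast statistics → truth recovery, persisting every
intermediate and a removal log whose counts always sum (input → biallelic →
depth-filtered → analyzed). One configuration seed fans out to per-stage
child seeds through `numpy.random.SeedSequence` keyed on stage indices, so
every stage is independently reproducible and full runs are byte-identical
under a fixed seed. Reports are TSV/JSON plus a human-readable summary; no
plotting is required anywhere in the pipeline.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use five seeded full-scale
simulations (50,000 SNPs each) for the scan-recovery and FineMAV checks, 200
null universes (4,000 genes, 400-gene candidate lists) for permutation
calibration, exhaustive enumeration up to universe size 12 for Fisher
exactness, 1,000 random 2x2 tables for GLM/G-statistic equivalence, and toy
instances small enough to trace by hand for the elim schedule and the depth
filters.
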