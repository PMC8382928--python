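# wgdadapt

Genome scans and convergence tests for adaptation to whole-genome duplication
(WGD), built for replicated pool-seq designs contrasting diploid and
autotetraploid populations of the same species.

Young autopolyploids face immediate challenges — meiosis with four homologs,
altered ion homeostasis, changed cell physiology — and the genes that solve
them leave selective-sweep signatures that separate the cytotypes. `wgdadapt`
implements the full analysis chain for detecting and interpreting those
signatures, plus a synthetic-data generator with known ground truth so every
stage is testable without any external data:

* **Pool-seq input** (`wgdadapt.poolseq`): biallelic-SNP VCF reading with
  per-sample allelic depths, min/max depth filters (the max-depth cutoff is
  1.6 x the second mode of the depth histogram), and population allele
  frequencies as the unweighted mean over replicate pools.
* **Quartet divergence scan** (`wgdadapt.scan`): per-SNP Nei Fst
  (`Fst = 1 − Hs/Ht`, `Hs = (2p₁q₁ + 2p₂q₂)/2`, `Ht = 2p̄q̄`), windowed and
  per-gene Fst by ratio of sums (`1 − ΣHs/ΣHt`), and the quartet rank-sum
  statistic: windows are ranked by Fst in each of the four diploid–tetraploid
  contrasts, `R = Σ ranks`, and candidates are the lowest-`R` top fraction
  after excluding windows that are top outliers in the diploid–diploid or
  tetraploid–tetraploid contrasts (local history, not WGD).
* **FineMAV** (`wgdadapt.finemav`): amino-acid substitutions scored as
  `S = G x f_max x DAP`, with `G` the Grantham distance, `f_max` the larger
  derived-allele frequency of the two cytotypes, and
  `DAP = (max d / Σd)^A` the derived allele purity (default `A = 3.5`).
* **Convergence** (`wgdadapt.convergence`): orthogroup/RBH assignment cascade
  to a reference-species namespace, two-sided Fisher candidate-overlap tests,
  topology-aware GO enrichment (elim algorithm), and permutation tests on
  first-shell protein-interaction overlap between two species' candidates.
* **Meiotic stability** (`wgdadapt.meiosis`): bivalent-count scoring bands,
  per-individual stability proportions, and a binomial GLM whose deviance drop
  `D = 2ΣO·ln(O/E)` tests the ploidy difference.
* **Simulator** (`wgdadapt.simulate`): quartet allele frequencies under
  Balding–Nichols drift with implanted ploidy-associated and lineage-specific
  sweeps, two-stage pool sampling (individuals, then reads), coding
  substitutions, functional universes with planted convergent modules, and
  meiotic spread counts — all with truth tables.

## Worked example

`examples/01_quartet_scan.py` simulates 10,000 SNPs for two diploid and two
tetraploid populations (three replicate pools of 25 individuals each, mean
pool depth 80) with five ploidy-associated and five single-population sweeps,
and runs the scan:

```
candidate windows: 4 of 341 eligible
candidate genes overlapped: 1
ploidy-sweep recovery: 80%  (sweeps shared by both tetraploid populations that rank in the top 1%)
lineage-sweep false recovery: 0%  (single-population sweeps are excluded by the within-ploidy contrasts)

genome-wide differentiation (mean AFD / fixed diffs / mean Fst):
  p1: 0.123 / 0 / 0.041
  p2: 0.123 / 0 / 0.041
  p3: 0.121 / 0 / 0.039
  p4: 0.122 / 0 / 0.039
  dd: 0.116 / 0 / 0.034
  tt: 0.109 / 0 / 0.030
```

The four interploidy contrasts (p1–p4) show elevated differentiation relative
to the within-ploidy baselines (dd, tt) because the implanted ploidy sweeps
separate the cytotypes; the rank-sum candidates recover the ploidy sweeps
while the within-ploidy exclusion removes every single-population sweep.
The other example scripts cover FineMAV scoring, the convergence tests, and
the meiotic-stability contrast in the same style.

A thin CLI wraps the same functions
(`wgdadapt simulate|scan|finemav|converge|meiosis|all`); see
`wgdadapt --help`.

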