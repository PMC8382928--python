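"""Meiotic-stability scoring and the ploidy contrast.

Simulates bivalent counts for chromosome spreads of 4 diploid and 4
tetraploid individuals (tetraploids less stable), classifies each spread,
summarizes per-individual stability, and tests the ploidy difference with a
binomial GLM.
"""

from wgdadapt import ploidy_glm_test, simulate_meiosis_counts, stability_summary

probs = {
    2: {"stable": 0.55, "partly_stable": 0.25, "partly_unstable": 0.12, "unstable": 0.08},
    4: {"stable": 0.15, "partly_stable": 0.25, "partly_unstable": 0.30, "unstable": 0.30},
}
spreads = simulate_meiosis_counts(4, probs, n_cells=60, seed=3)

summary = stability_summary(spreads, mode="stable_plus_partly")
print(summary.per_individual.round(3).to_string(index=False))
for ploidy in (2, 4):
    print(
        f"{ploidy}x mean stability (stable + partly stable): "
        f"{summary.ploidy_means[ploidy]:.2f} over {summary.cell_counts[ploidy]} cells"
    )

d, df, p = ploidy_glm_test(spreads, mode="stable_plus_partly")
print(f"\nbinomial GLM, ploidy effect: D = {d:.1f}, df = {df}, p = {p:.2g}")
print("D is the deviance drop of the ploidy term; under equal stability it is"
      " chi-square(1), so large D means tetraploid meiosis is measurably less stable.")
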