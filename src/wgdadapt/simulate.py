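"""Synthetic quartet pool-seq data, functional universes, and meiotic counts.

The generator emulates the study design the downstream modules are built for:
two diploid and two autotetraploid populations of an outcrossing plant, each
sequenced as three replicate pools of 25 individuals.  Ancestral allele
frequencies are drawn from a truncated Beta(0.5, 0.5); each population drifts
independently under the Balding–Nichols model; ploidy-associated sweeps shift
both tetraploid populations in the same direction (a single shared origin of
the tetraploids), lineage sweeps shift exactly one population.  Pool reads are
sampled in two stages per replicate: chromosomes from the pool (2N per diploid
individual, 4N per tetraploid — the dosage difference is the point of the
design), then reads given a Poisson depth.

SNPs are independent given the population frequencies: no linkage or haplotype
structure is modelled, so recovery results measure ranking behaviour of the
scan, not haplotype-based power.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv

from wgdadapt.poolseq import AFTable, PoolReadCounts

_BASES = np.array(list("ACGT"))

# amino acids ordered as in the shipped Grantham matrix
_AA = list("SRLPTAVGIFYCHQNKDEMW")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the quartet simulator.

    Defaults mirror the empirical design: 4 populations (2 diploid, 2
    autotetraploid) x 3 replicate pools of 25 individuals, mean replicate-pool
    depth 80, modest genome-wide drift (Balding–Nichols F = 0.05 per branch),
    and 20 ploidy-associated plus 20 single-population sweeps of allele
    frequency shift 0.8.
    """

    n_scaffolds: int = 4
    scaffold_length: int = 500_000
    n_snps: int = 50_000
    n_genes: int = 400
    pop_labels: tuple[tuple[str, int], ...] = (
        ("LUZ", 2),
        ("VKR", 2),
        ("CEZ", 4),
        ("PIC", 4),
    )
    n_individuals_per_pool: int = 25
    n_replicates: int = 3
    mean_depth: float = 80.0
    drift_fst: float = 0.05
    n_sweeps_ploidy: int = 20
    n_sweeps_lineage: int = 20
    sweep_afd: float = 0.8
    seed: int = 0
    # ancestral AF distribution: Beta(a, b) truncated to bounds, keeps sites
    # polymorphic and SNP-like
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    ancestral_bounds: tuple[float, float] = (0.05, 0.95)
    # sweeps are implanted as contiguous regions of this span, chosen among
    # regions holding at least min_sweep_snps SNPs so every implanted sweep is
    # in principle detectable at the default window settings
    sweep_span_bp: int = 1000
    min_sweep_snps: int = 20
    # genic fraction of each scaffold used when tiling gene models
    genic_fraction: float = 0.5
    # negative-binomial depth overdispersion (None -> Poisson)
    depth_dispersion: float | None = None

    def __post_init__(self) -> None:
        ploidies = sorted(p for _, p in self.pop_labels)
        if len(self.pop_labels) != 4 or ploidies != [2, 2, 4, 4]:
            raise ValueError("pop_labels must name 4 populations, 2 diploid + 2 tetraploid")
        if not 0 <= self.drift_fst < 1:
            raise ValueError("drift_fst must be in [0, 1)")
        if not 0 < self.sweep_afd <= 1:
            raise ValueError("sweep_afd must be in (0, 1]")
        for name in (
            "n_scaffolds",
            "scaffold_length",
            "n_snps",
            "n_genes",
            "n_individuals_per_pool",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sweeps_ploidy < 0 or self.n_sweeps_lineage < 0:
            raise ValueError("sweep counts must be non-negative")

    @property
    def pops(self) -> list[str]:
        return [name for name, _ in self.pop_labels]

    @property
    def ploidy(self) -> dict[str, int]:
        return dict(self.pop_labels)

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]


def _truncated_beta(rng, a, b, lo, hi, size):
    u = rng.uniform(betainc(a, b, lo), betainc(a, b, hi), size=size)
    return betaincinv(a, b, u)


def _balding_nichols(rng, p, fst):
    """Drift allele frequencies p by one branch of divergence fst."""
    if fst == 0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def simulate_quartet_afs(config: SimulationConfig) -> tuple[AFTable, pd.DataFrame]:
    """Simulate true per-population allele frequencies with implanted sweeps.

    Returns the table of true (noise-free) population frequencies and a truth
    table with one row per SNP: locus_id (sweep id or "neutral"), class
    (ploidy_sweep / lineage_sweep / neutral), target populations, and true AFs.
    """
    rng = np.random.default_rng(config.seed)
    scaffolds = config.scaffold_names()
    per_scaf = np.full(config.n_scaffolds, config.n_snps // config.n_scaffolds)
    per_scaf[: config.n_snps % config.n_scaffolds] += 1

    scaf_col, pos_col = [], []
    for name, n in zip(scaffolds, per_scaf):
        pos = np.sort(rng.choice(config.scaffold_length, size=n, replace=False))
        scaf_col.append(np.full(n, name))
        pos_col.append(pos)
    scaffold = np.concatenate(scaf_col)
    pos = np.concatenate(pos_col)

    ref_idx = rng.integers(0, 4, config.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, config.n_snps)) % 4
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    a, b = config.ancestral_beta
    lo, hi = config.ancestral_bounds
    ancestral = _truncated_beta(rng, a, b, lo, hi, config.n_snps)

    # choose sweep regions among sweep_span_bp tiles dense enough to be seen
    n_sweeps = config.n_sweeps_ploidy + config.n_sweeps_lineage
    classes = np.full(config.n_snps, "neutral", dtype=object)
    locus_id = np.full(config.n_snps, "neutral", dtype=object)
    targets = np.full(config.n_snps, "", dtype=object)
    sweep_members: list[np.ndarray] = []
    if n_sweeps > 0:
        tile = pd.Series(
            scaffold + ":" + (pos // config.sweep_span_bp).astype(str)
        )
        counts = tile.value_counts()
        eligible = counts.index[counts >= config.min_sweep_snps]
        if n_sweeps > len(eligible):
            raise ValueError(
                f"cannot place {n_sweeps} sweeps: only {len(eligible)} regions hold "
                f">= {config.min_sweep_snps} SNPs (is n_snps large enough?)"
            )
        chosen = rng.choice(np.asarray(eligible, dtype=object), size=n_sweeps, replace=False)
        for t in chosen:
            sweep_members.append(np.flatnonzero(tile.values == t))

    dip = [p for p, k in config.pop_labels if k == 2]
    tet = [p for p, k in config.pop_labels if k == 4]
    pops = config.pops
    tet_idx = [pops.index(p) for p in tet]

    # constrain ancestral AF at sweep loci so the implanted shift fits in [0,1]
    afd = config.sweep_afd
    for members in sweep_members:
        span = max(1.0 - afd - lo, 0.0)
        ancestral[members] = lo + (ancestral[members] - lo) * span / max(hi - lo, 1e-12)

    af = np.column_stack(
        [_balding_nichols(rng, ancestral, config.drift_fst) for _ in pops]
    )

    lineage_targets = [pops[i % 4] for i in range(config.n_sweeps_lineage)]
    for k, members in enumerate(sweep_members):
        if k < config.n_sweeps_ploidy:
            sweep = f"ploidy_{k + 1}"
            for j in tet_idx:
                af[members, j] = np.clip(af[members, j] + afd, 0.0, 1.0)
            classes[members] = "ploidy_sweep"
            targets[members] = ",".join(tet)
        else:
            target = lineage_targets[k - config.n_sweeps_ploidy]
            sweep = f"lineage_{k - config.n_sweeps_ploidy + 1}"
            j = pops.index(target)
            af[members, j] = np.clip(af[members, j] + afd, 0.0, 1.0)
            classes[members] = "lineage_sweep"
            targets[members] = target
        locus_id[members] = sweep

    truth = sites[["scaffold", "pos"]].copy()
    truth.insert(0, "locus_id", locus_id)
    truth["class"] = classes
    truth["target_populations"] = targets
    for j, p in enumerate(pops):
        truth[f"true_af_{p}"] = af[:, j]

    table = AFTable(sites=sites, pops=pops, ploidy=config.ploidy, af=af)
    return table, truth


def simulate_pool_reads(
    true_afs: AFTable, config: SimulationConfig, seed: int | None = None
) -> PoolReadCounts:
    """Two-stage pool sampling: chromosomes from the pool, then reads.

    Per replicate: allele count k ~ Binomial(ploidy x n_individuals, AF), depth
    d ~ Poisson(mean_depth) (negative binomial if depth_dispersion is set),
    alt reads ~ Binomial(d, k / (ploidy x n_individuals)).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, n_pops = true_afs.af.shape
    n_rep = config.n_replicates
    chroms = np.array(
        [config.ploidy[p] * config.n_individuals_per_pool for p in true_afs.pops]
    )
    af = np.repeat(true_afs.af[:, :, None], n_rep, axis=2)
    k = rng.binomial(chroms[None, :, None], af)
    frac = k / chroms[None, :, None]
    if config.depth_dispersion is None:
        depth = rng.poisson(config.mean_depth, size=(n, n_pops, n_rep))
    else:
        r = config.depth_dispersion
        depth = rng.negative_binomial(r, r / (r + config.mean_depth), size=(n, n_pops, n_rep))
    alt = rng.binomial(depth, frac)
    return PoolReadCounts(
        sites=true_afs.sites.copy(),
        pops=list(true_afs.pops),
        ploidy=dict(true_afs.ploidy),
        ref=depth - alt,
        alt=alt,
    )


def _tile_genes(config: SimulationConfig) -> pd.DataFrame:
    """Evenly tiled gene models covering genic_fraction of each scaffold."""
    per_scaf = np.full(config.n_scaffolds, config.n_genes // config.n_scaffolds)
    per_scaf[: config.n_genes % config.n_scaffolds] += 1
    rows = []
    gid = 0
    for name, g in zip(config.scaffold_names(), per_scaf):
        if g == 0:
            continue
        slot = config.scaffold_length / g
        length = max(int(slot * config.genic_fraction), 1)
        for i in range(g):
            gid += 1
            start = int(i * slot + (slot - length) / 2)
            rows.append((f"gene{gid:05d}", name, start, start + length))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def write_synthetic_inputs(
    reads: PoolReadCounts,
    config: SimulationConfig,
    out_dir,
    truth: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write VCF (AD/DP per replicate pool), GFF3 gene models, sample map, truth TSV.

    Files round-trip losslessly through :func:`wgdadapt.poolseq.read_pool_vcf`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "pools.vcf"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "sample_map": os.path.join(out_dir, "samples.tsv"),
    }
    samples = reads.sample_names()
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in config.scaffold_names():
            fh.write(f"##contig=<ID={name},length={config.scaffold_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        sites = reads.sites
        ref = reads.ref.reshape(reads.n_snps, -1)
        alt = reads.alt.reshape(reads.n_snps, -1)
        for i in range(reads.n_snps):
            cells = [
                f"./.:{r},{a}:{r + a}" for r, a in zip(ref[i], alt[i])
            ]
            fh.write(
                f"{sites.scaffold.iloc[i]}\t{sites.pos.iloc[i] + 1}\t.\t"
                f"{sites.ref.iloc[i]}\t{sites.alt.iloc[i]}\t.\tPASS\t.\tGT:AD:DP\t"
                + "\t".join(cells)
                + "\n"
            )

    genes = _tile_genes(config)
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write(
                f"{row.scaffold}\twgdadapt_sim\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )

    with open(paths["sample_map"], "w") as fh:
        fh.write("sample\tpopulation\tploidy\treplicate\n")
        for p in reads.pops:
            for r in range(reads.n_replicates):
                fh.write(f"{p}_rep{r + 1}\t{p}\t{reads.ploidy[p]}\t{r + 1}\n")

    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.tsv")
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_substitutions(
    truth: pd.DataFrame,
    config: SimulationConfig,
    fraction: float = 0.05,
    high_grantham: int = 150,
    seed: int | None = None,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign amino-acid changes to a fraction of SNPs; sweep loci get radical ones.

    Each ploidy-sweep region receives one planted nonsynonymous substitution
    with Grantham distance >= ``high_grantham`` (column ``planted`` marks
    them); a random ``fraction`` of the remaining SNPs receive random
    amino-acid pairs.  Per-cytotype alternate-allele frequencies f2x/f4x are
    the means of the true population frequencies within each cytotype.
    """
    from wgdadapt.finemav import load_grantham

    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    matrix = load_grantham()
    if fraction == 0:
        return pd.DataFrame(
            columns=["gene", "scaffold", "pos", "aa_ref", "aa_alt", "f2x", "f4x", "planted", "locus_id"]
        )

    dip = [p for p, k in config.pop_labels if k == 2]
    tet = [p for p, k in config.pop_labels if k == 4]
    f2x = truth[[f"true_af_{p}" for p in dip]].mean(axis=1).to_numpy()
    f4x = truth[[f"true_af_{p}" for p in tet]].mean(axis=1).to_numpy()

    aa = np.array(_AA)
    high_pairs = [
        (a, b)
        for i, a in enumerate(_AA)
        for j, b in enumerate(_AA)
        if i < j and matrix.loc[a, b] >= high_grantham
    ]

    rows = []
    planted_idx = set()
    for sweep, grp in truth[truth["class"] == "ploidy_sweep"].groupby("locus_id"):
        i = int(grp.index[rng.integers(len(grp))])
        planted_idx.add(i)
        a, b = high_pairs[rng.integers(len(high_pairs))]
        rows.append((i, a, b, True))

    if fraction > 0:
        rest = np.setdiff1d(truth.index.to_numpy(), np.fromiter(planted_idx, dtype=int, count=len(planted_idx)))
        n_extra = int(round(fraction * len(truth)))
        extra = rng.choice(rest, size=min(n_extra, len(rest)), replace=False)
        for i in extra:
            a, b = aa[rng.integers(20)], aa[rng.integers(20)]
            rows.append((int(i), a, b, False))

    rows.sort()
    idx = [r[0] for r in rows]
    out = pd.DataFrame(
        {
            "scaffold": truth["scaffold"].to_numpy()[idx],
            "pos": truth["pos"].to_numpy()[idx],
            "aa_ref": [r[1] for r in rows],
            "aa_alt": [r[2] for r in rows],
            "f2x": f2x[idx],
            "f4x": f4x[idx],
            "planted": [r[3] for r in rows],
            "locus_id": truth["locus_id"].to_numpy()[idx],
        }
    )
    if genes is None:
        genes = _tile_genes(config)
    gene_col = np.full(len(out), "", dtype=object)
    for scaf, grp in out.groupby("scaffold"):
        g = genes[genes["scaffold"] == scaf]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        p = grp["pos"].to_numpy()
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        vals = np.where(ok, ids[np.clip(j, 0, None)], "")
        gene_col[grp.index.to_numpy()] = vals
    out.insert(0, "gene", gene_col)
    return out


@dataclass
class FunctionalUniverse:
    """Ortholog map, GO annotations + DAG, and interaction edges for both species."""

    genes: list[str]
    term_genes: dict[str, set[str]]  # ancestor-closed
    dag: "object"  # networkx.DiGraph, edges child -> parent
    edges: pd.DataFrame  # geneA, geneB, score in [0, 1000]
    ortholog_map: dict[str, str]
    candidates_a: list[str]
    candidates_b: list[str]
    module_genes_a: list[str]
    module_genes_b: list[str]


def simulate_functional_universe(
    n_genes: int = 2000,
    n_terms: int = 50,
    n_edges: int = 2000,
    planted_modules: int = 1,
    module_size: int = 20,
    n_candidates: int = 100,
    ortholog_dropout: float = 0.05,
    seed: int = 0,
) -> FunctionalUniverse:
    """Random GO DAG + annotations, random interaction edges, planted modules.

    Planted modules are fully wired bipartite gene sets connecting designated
    species-A and species-B candidate genes (score 900); background edges get
    uniform scores in [150, 999].  Annotations are propagated to all DAG
    ancestors.  The ortholog map is a permutation with ``ortholog_dropout``
    unassigned.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    terms = [f"T{i:04d}" for i in range(n_terms)]

    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for i in range(1, n_terms):
        for parent in rng.choice(i, size=min(i, rng.integers(1, 3)), replace=False):
            dag.add_edge(terms[i], terms[int(parent)])  # child -> parent

    term_genes: dict[str, set[str]] = {t: set() for t in terms}
    for g in genes:
        for t in rng.choice(n_terms, size=rng.integers(1, 4), replace=False):
            term = terms[int(t)]
            term_genes[term].add(g)
            for anc in nx.descendants(dag, term):  # ancestors along child->parent
                term_genes[anc].add(g)

    module_a: list[str] = []
    module_b: list[str] = []
    edge_rows: list[tuple[str, str, int]] = []
    if planted_modules > 0:
        picked = rng.choice(n_genes, size=2 * planted_modules * module_size, replace=False)
        half = planted_modules * module_size
        module_a = [genes[i] for i in picked[:half]]
        module_b = [genes[i] for i in picked[half:]]
        for m in range(planted_modules):
            ga = module_a[m * module_size : (m + 1) * module_size]
            gb = module_b[m * module_size : (m + 1) * module_size]
            edge_rows += [(x, y, 900) for x in ga for y in gb]
    if n_edges > 0:
        pairs = rng.integers(0, n_genes, size=(n_edges, 2))
        scores = rng.integers(150, 1000, size=n_edges)
        edge_rows += [
            (genes[i], genes[j], int(s)) for (i, j), s in zip(pairs, scores) if i != j
        ]
    edges = pd.DataFrame(edge_rows, columns=["geneA", "geneB", "score"])

    free = [g for g in genes if g not in set(module_a) | set(module_b)]
    n_extra_a = max(n_candidates - len(module_a), 0)
    n_extra_b = max(n_candidates - len(module_b), 0)
    if max(n_extra_a, n_extra_b) > len(free):
        raise ValueError("n_candidates too large for the gene universe")
    # the two species' lists are drawn independently, so they may overlap
    extra_a = rng.choice(len(free), size=n_extra_a, replace=False)
    extra_b = rng.choice(len(free), size=n_extra_b, replace=False)
    candidates_a = module_a + [free[i] for i in extra_a]
    candidates_b = module_b + [free[i] for i in extra_b]

    perm = rng.permutation(n_genes)
    keep = rng.random(n_genes) >= ortholog_dropout
    ortholog_map = {
        f"sp_{genes[i]}": genes[int(perm[i])] for i in range(n_genes) if keep[i]
    }

    return FunctionalUniverse(
        genes=genes,
        term_genes=term_genes,
        dag=dag,
        edges=edges,
        ortholog_map=ortholog_map,
        candidates_a=candidates_a,
        candidates_b=candidates_b,
        module_genes_a=module_a,
        module_genes_b=module_b,
    )


# bivalent-count bands per category: (lo, hi) inclusive
MEIOSIS_BANDS = {
    2: {"stable": (8, 8), "partly_stable": (6, 7), "partly_unstable": (4, 5), "unstable": (0, 3)},
    4: {"stable": (16, 16), "partly_stable": (12, 14), "partly_unstable": (8, 10), "unstable": (0, 7)},
}
MEIOSIS_CATEGORIES = ["stable", "partly_stable", "partly_unstable", "unstable"]


def simulate_meiosis_counts(
    n_individuals_per_ploidy: int,
    stability_probs: dict[int, dict[str, float]],
    n_cells: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bivalent counts per chromosome spread.

    ``stability_probs[ploidy]`` gives the multinomial over the four stability
    categories; per cell a category is drawn, then a bivalent count uniform in
    that category's band.  Returns one row per spread: individual, ploidy,
    n_bivalents.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ploidy in (2, 4):
        probs = np.array([stability_probs[ploidy][c] for c in MEIOSIS_CATEGORIES], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("stability_probs must be a probability vector per ploidy")
        bands = MEIOSIS_BANDS[ploidy]
        for i in range(n_individuals_per_ploidy):
            ind = f"{ploidy}x_ind{i + 1}"
            cats = rng.choice(len(MEIOSIS_CATEGORIES), size=n_cells, p=probs)
            for c in cats:
                lo, hi = bands[MEIOSIS_CATEGORIES[int(c)]]
                rows.append((ind, ploidy, int(rng.integers(lo, hi + 1))))
    return pd.DataFrame(rows, columns=["individual", "ploidy", "n_bivalents"])
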