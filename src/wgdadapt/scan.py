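"""Nei Fst genome scans with quartet rank-sum outlier detection.

Per SNP, differentiation between two populations with allele frequencies p1,
p2 is Nei's Fst = 1 - Hs/Ht with Hs = (2 p1 q1 + 2 p2 q2)/2 and
Ht = 2 p̄ q̄ at the pooled mean frequency p̄.  Windows (and genes) aggregate by
the ratio of sums: Fst = 1 - ΣHs/ΣHt over their SNPs.

The quartet design contrasts two diploid with two autotetraploid populations.
Windows are ranked by Fst in each of the four interploidy contrasts and the
rank sum over the four is the selection statistic; low sums mark windows that
are consistently differentiated between ploidies.  Windows that are top
outliers within a ploidy (diploid-diploid or tetraploid-tetraploid contrast)
are excluded — such differentiation reflects local population history, not
whole-genome duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from wgdadapt.poolseq import AFTable

INTERPLOIDY = ("p1", "p2", "p3", "p4")
WITHIN_PLOIDY = ("dd", "tt")
ALL_CONTRASTS = INTERPLOIDY + WITHIN_PLOIDY


@dataclass(frozen=True)
class QuartetDesign:
    """The six pairings of 2 diploid + 2 tetraploid populations.

    p1..p4 are the interploidy contrasts; dd and tt the within-ploidy ones.
    """

    contrasts: dict[str, tuple[str, str]]

    @classmethod
    def from_ploidy(cls, ploidy: dict[str, int]) -> "QuartetDesign":
        dips = sorted(p for p, k in ploidy.items() if k == 2)
        tets = sorted(p for p, k in ploidy.items() if k == 4)
        if len(dips) != 2 or len(tets) != 2 or len(ploidy) != 4:
            raise ValueError("quartet design needs exactly 2 diploid and 2 tetraploid populations")
        inter = [(d, t) for d in dips for t in tets]
        contrasts = {f"p{i + 1}": pair for i, pair in enumerate(inter)}
        contrasts["dd"] = (dips[0], dips[1])
        contrasts["tt"] = (tets[0], tets[1])
        return cls(contrasts=contrasts)

    def __post_init__(self) -> None:
        pops = sorted({p for pair in self.contrasts.values() for p in pair})
        expected = {tuple(sorted(c)) for c in combinations(pops, 2)}
        got = {tuple(sorted(pair)) for pair in self.contrasts.values()}
        if len(pops) != 4 or got != expected or set(self.contrasts) != set(ALL_CONTRASTS):
            raise ValueError("contrasts must be exactly the six pairings of four populations")


def snp_fst(p1, p2):
    """Per-SNP Nei Fst.  Returns (Hs, Ht, Fst); Fst is NaN where Ht = 0."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, 1.0 - hs / np.where(ht > 0, ht, 1.0), np.nan)
    return hs, ht, fst


def _pair_afs(table: AFTable, pair: tuple[str, str]):
    return table.af[:, table.pop_index(pair[0])], table.af[:, table.pop_index(pair[1])]


def window_fst(
    table: AFTable,
    pair: tuple[str, str],
    window_bp: int = 1000,
    min_snps: int = 20,
) -> pd.DataFrame:
    """Window Fst by ratio of sums over non-overlapping windows anchored at 0.

    Only windows containing at least one SNP are emitted; windows with fewer
    than ``min_snps`` SNPs are marked ineligible but kept in the output.
    Returns columns scaffold, start, end, n_snps, hs_sum, ht_sum, fst,
    eligible.
    """
    p1, p2 = _pair_afs(table, pair)
    hs, ht, _ = snp_fst(p1, p2)
    win = (table.sites["pos"].to_numpy() // window_bp).astype(np.int64)
    df = pd.DataFrame(
        {
            "scaffold": table.sites["scaffold"].to_numpy(),
            "win": win,
            "hs": hs,
            "ht": ht,
        }
    )
    agg = (
        df.groupby(["scaffold", "win"], sort=True)
        .agg(n_snps=("hs", "size"), hs_sum=("hs", "sum"), ht_sum=("ht", "sum"))
        .reset_index()
    )
    agg["start"] = agg["win"] * window_bp
    agg["end"] = agg["start"] + window_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["fst"] = np.where(
            agg["ht_sum"] > 0, 1.0 - agg["hs_sum"] / agg["ht_sum"].where(agg["ht_sum"] > 0, 1.0), np.nan
        )
    agg["eligible"] = agg["n_snps"] >= min_snps
    return agg[["scaffold", "start", "end", "n_snps", "hs_sum", "ht_sum", "fst", "eligible"]]


def _gene_fst(table: AFTable, pair, genes: pd.DataFrame, min_snps: int) -> pd.DataFrame:
    p1, p2 = _pair_afs(table, pair)
    hs, ht, _ = snp_fst(p1, p2)
    pos = table.sites["pos"].to_numpy()
    scaf = table.sites["scaffold"].to_numpy()
    rows = []
    for g in genes.itertuples():
        m = (scaf == g.scaffold) & (pos >= g.start) & (pos < g.end)
        n = int(m.sum())
        hs_sum, ht_sum = hs[m].sum(), ht[m].sum()
        fst = 1.0 - hs_sum / ht_sum if ht_sum > 0 else np.nan
        rows.append((g.gene_id, g.scaffold, g.start, g.end, n, hs_sum, ht_sum, fst, n >= min_snps))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "scaffold", "start", "end", "n_snps", "hs_sum", "ht_sum", "fst", "eligible"],
    )


def _rank_sum_core(
    wide: pd.DataFrame, top_frac: float, exclusion_order: str
) -> pd.DataFrame:
    """Shared rank-sum logic over a wide table with fst_<contrast> columns.

    Negative Fst (Hs > Ht) is clamped to 0 for ranking; the raw value is kept
    in the fst_* columns.  Ties get average ranks.
    """
    out = wide.copy()
    eligible = out["eligible"].to_numpy()
    clamped = {
        c: np.clip(np.nan_to_num(out[f"fst_{c}"].to_numpy(), nan=0.0), 0.0, 1.0)
        for c in ALL_CONTRASTS
    }
    for c in WITHIN_PLOIDY:
        flag = np.zeros(len(out), dtype=bool)
        if eligible.any():
            # strict > so a constant within-ploidy Fst flags nothing
            cut = np.quantile(clamped[c][eligible], 1.0 - top_frac)
            flag[eligible] = clamped[c][eligible] > cut
        out[f"{c}_outlier"] = flag
    excluded = out["dd_outlier"].to_numpy() | out["tt_outlier"].to_numpy()

    if exclusion_order == "before":
        pool = eligible & ~excluded
    elif exclusion_order == "after":
        pool = eligible
    else:
        raise ValueError("exclusion_order must be 'before' or 'after'")

    ranks = np.full((len(out), 4), np.nan)
    for j, c in enumerate(INTERPLOIDY):
        if pool.any():
            ranks[pool, j] = rankdata(-clamped[c][pool], method="average")
        out[f"rank_{c}"] = ranks[:, j]
    rank_sum = ranks.sum(axis=1)
    out["rank_sum"] = rank_sum

    candidate = np.zeros(len(out), dtype=bool)
    if pool.any():
        cut = np.quantile(rank_sum[pool], top_frac)
        candidate[pool] = rank_sum[pool] <= cut
    if exclusion_order == "after":
        candidate &= ~excluded
    out["candidate"] = candidate
    return out


def _merge_contrasts(tables: dict[str, pd.DataFrame], keys: list[str]) -> pd.DataFrame:
    names = set(tables)
    if names != set(ALL_CONTRASTS):
        raise ValueError(f"need window tables for contrasts {ALL_CONTRASTS}, got {sorted(names)}")
    base_cols = keys + ["n_snps", "eligible"]
    wide = tables["p1"][base_cols].copy()
    for c in ALL_CONTRASTS:
        t = tables[c]
        if len(t) != len(wide) or not (t[keys].to_numpy() == wide[keys].to_numpy()).all():
            raise ValueError("window grids differ between contrasts")
        wide[f"fst_{c}"] = t["fst"].to_numpy()
    return wide


def quartet_rank_sum(
    window_tables: dict[str, pd.DataFrame],
    top_frac: float = 0.01,
    exclusion_order: str = "before",
) -> pd.DataFrame:
    """Quartet scan: exclude within-ploidy outliers, rank-sum the interploidy Fst.

    ``window_tables`` maps contrast names (p1..p4, dd, tt) to identical-grid
    outputs of :func:`window_fst`.  Windows in the top ``top_frac`` of dd or tt
    Fst are flagged and excluded; remaining eligible windows are ranked by Fst
    (descending, average ties) in each interploidy contrast, and candidates are
    windows whose rank sum falls in the lowest ``top_frac`` quantile.  With
    ``exclusion_order="after"`` ranking precedes exclusion.
    """
    keys = ["scaffold", "start", "end"] if "start" in window_tables["p1"] else ["gene_id"]
    wide = _merge_contrasts(window_tables, keys)
    return _rank_sum_core(wide, top_frac, exclusion_order)


def gene_level_scan(
    table: AFTable,
    genes: pd.DataFrame,
    design: QuartetDesign,
    min_snps_per_gene: int = 5,
    top_frac: float = 0.01,
    exclusion_order: str = "before",
) -> pd.DataFrame:
    """SNP-by-SNP scan at gene granularity: per-gene ratio-of-sums Fst + rank sum."""
    tables = {
        name: _gene_fst(table, pair, genes, min_snps_per_gene)
        for name, pair in design.contrasts.items()
    }
    wide = _merge_contrasts(tables, ["gene_id"])
    return _rank_sum_core(wide, top_frac, exclusion_order)


def annotate_candidates(candidate_windows: pd.DataFrame, genes: pd.DataFrame) -> list[str]:
    """Gene IDs whose span overlaps any candidate window by >= 1 bp (each once)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        if g.end > g.start:
            trees.setdefault(g.scaffold, IntervalTree()).addi(g.start, g.end, g.gene_id)
    hits: set[str] = set()
    for w in candidate_windows.itertuples():
        tree = trees.get(w.scaffold)
        if tree is not None:
            hits.update(iv.data for iv in tree.overlap(w.start, w.end))
    return sorted(hits)


@dataclass(frozen=True)
class ContrastStats:
    """Genome-wide differentiation between one pair of populations."""

    mean_afd: float
    fixed_differences: int
    mean_fst: float  # mean of per-SNP Fst over sites where Ht > 0
    fst_ratio_of_sums: float  # genome-wide 1 - ΣHs/ΣHt
    n_snps: int


def genome_stats(table: AFTable, pair: tuple[str, str]) -> ContrastStats:
    """Mean |AFD|, fixed-difference count, and mean Fst for one contrast."""
    if table.n_snps == 0:
        raise ValueError("empty allele-frequency table")
    p1, p2 = _pair_afs(table, pair)
    afd = np.abs(p1 - p2)
    hs, ht, fst = snp_fst(p1, p2)
    defined = ~np.isnan(fst)
    return ContrastStats(
        mean_afd=float(afd.mean()),
        fixed_differences=int((afd >= 1.0 - 1e-9).sum()),
        mean_fst=float(fst[defined].mean()) if defined.any() else float("nan"),
        fst_ratio_of_sums=float(1.0 - hs.sum() / ht.sum()) if ht.sum() > 0 else float("nan"),
        n_snps=table.n_snps,
    )


def genic_fraction_check(
    windows: pd.DataFrame, genes: pd.DataFrame
) -> tuple[float, int]:
    """Pearson r between per-window genic bp fraction and window Fst.

    A strong correlation would mean the scan confounds genic density with
    differentiation.  Returns (r, n); r is NaN when either vector is constant.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        if g.end > g.start:
            trees.setdefault(g.scaffold, IntervalTree()).addi(g.start, g.end)
    fracs, fsts = [], []
    for w in windows.itertuples():
        if np.isnan(w.fst):
            continue
        overlap = 0
        tree = trees.get(w.scaffold)
        if tree is not None:
            for iv in tree.overlap(w.start, w.end):
                overlap += min(iv.end, w.end) - max(iv.begin, w.start)
        fracs.append(overlap / (w.end - w.start))
        fsts.append(w.fst)
    n = len(fracs)
    if n < 2 or np.std(fracs) == 0 or np.std(fsts) == 0:
        return float("nan"), n
    r, _ = pearsonr(fracs, fsts)
    return float(r), n
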