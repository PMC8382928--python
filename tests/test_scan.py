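import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_af_table
from wgdadapt import (
    QuartetDesign,
    annotate_candidates,
    gene_level_scan,
    genic_fraction_check,
    genome_stats,
    quartet_rank_sum,
    snp_fst,
    window_fst,
)

DESIGN = QuartetDesign.from_ploidy({"LUZ": 2, "VKR": 2, "CEZ": 4, "PIC": 4})

afs = st.floats(0.0, 1.0, allow_nan=False)


def brute_snp_fst(p1, p2):
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    return 1 - hs / ht if ht > 0 else float("nan")


class TestSnpFst:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(0.5, 0.5, 0.0), (0.0, 1.0, 1.0), (1.0, 0.0, 1.0)],
    )
    def test_known_values(self, p1, p2, expected):
        _, _, fst = snp_fst(p1, p2)
        assert fst == pytest.approx(expected)

    def test_hand_evaluated_formula(self):
        hs, ht, fst = snp_fst(0.2, 0.8)
        assert ht == pytest.approx(0.5)
        assert hs == pytest.approx(0.32)
        assert fst == pytest.approx(0.36)

    def test_monomorphic_site_is_undefined(self):
        _, ht, fst = snp_fst(0.0, 0.0)
        assert ht == 0.0 and np.isnan(fst)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            snp_fst(-0.1, 0.5)

    @settings(max_examples=100, derandomize=True)
    @given(afs, afs)
    def test_symmetric_and_relabel_invariant(self, p1, p2):
        from hypothesis import assume

        _, ht, a = snp_fst(p1, p2)
        assume(np.isnan(a) or ht > 1e-6)  # near-monomorphic Ht is numerically degenerate
        _, _, b = snp_fst(p2, p1)
        _, _, c = snp_fst(1 - p1, 1 - p2)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b, abs=1e-12)
            assert a == pytest.approx(c, abs=1e-9)


def test_fst_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(0)
    p1, p2 = rng.random(1000), rng.random(1000)
    _, _, fst = snp_fst(p1, p2)
    brute = np.array([brute_snp_fst(a, b) for a, b in zip(p1, p2)])
    assert np.nanmax(np.abs(fst - brute)) < 1e-12


class TestWindowFst:
    def test_no_differentiation_window(self):
        af = np.tile([[0.3, 0.3, 0.3, 0.3]], (25, 1))
        table = make_af_table(af, positions=np.arange(25))
        w = window_fst(table, ("LUZ", "VKR"), window_bp=1000, min_snps=20)
        assert len(w) == 1 and w.loc[0, "fst"] == pytest.approx(0.0)

    def test_ratio_of_sums_arithmetic(self):
        # SNP 1: (0.2, 0.8) -> Hs 0.32, Ht 0.5; SNP 2: (0, 1) -> Hs 0, Ht 0.5
        af = np.array([[0.2, 0.8, 0.5, 0.5], [0.0, 1.0, 0.5, 0.5]])
        table = make_af_table(af, positions=[0, 1])
        w = window_fst(table, ("LUZ", "VKR"), window_bp=1000, min_snps=1)
        assert w.loc[0, "fst"] == pytest.approx(1 - 0.32 / 1.0)

    def test_min_snps_marks_ineligible(self):
        af = np.random.default_rng(1).random((19, 4))
        table = make_af_table(af, positions=np.arange(19))
        w = window_fst(table, ("LUZ", "VKR"), window_bp=1000, min_snps=20)
        assert not w.loc[0, "eligible"] and w.loc[0, "n_snps"] == 19

    def test_single_snp_window_equals_snp_fst(self):
        af = np.array([[0.1, 0.7, 0.2, 0.9]])
        table = make_af_table(af, positions=[5])
        w = window_fst(table, ("LUZ", "CEZ"), window_bp=1000, min_snps=1)
        _, _, fst = snp_fst(0.1, 0.2)
        assert w.loc[0, "fst"] == pytest.approx(float(fst))

    def test_window_fst_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        af = rng.random((500, 4))
        pos = np.sort(rng.choice(10_000, 500, replace=False))
        table = make_af_table(af, positions=pos)
        w = window_fst(table, ("VKR", "PIC"), window_bp=1000, min_snps=1)
        j1, j2 = 1, 3
        for row in w.itertuples():
            m = (pos >= row.start) & (pos < row.end)
            hs = sum(
                (2 * a * (1 - a) + 2 * b * (1 - b)) / 2
                for a, b in zip(af[m, j1], af[m, j2])
            )
            ht = sum(
                2 * ((a + b) / 2) * (1 - (a + b) / 2)
                for a, b in zip(af[m, j1], af[m, j2])
            )
            assert row.fst == pytest.approx(1 - hs / ht, abs=1e-12)


def _window_tables(fst: dict[str, np.ndarray], n_snps=30) -> dict[str, pd.DataFrame]:
    n = len(next(iter(fst.values())))
    base = pd.DataFrame(
        {
            "scaffold": ["s1"] * n,
            "start": np.arange(n) * 1000,
            "end": np.arange(1, n + 1) * 1000,
            "n_snps": n_snps,
            "hs_sum": 0.0,
            "ht_sum": 1.0,
            "eligible": True,
        }
    )
    return {c: base.assign(fst=v) for c, v in fst.items()}


class TestQuartetRankSum:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.n = 300
        self.base = {c: rng.uniform(0, 0.2, self.n) for c in ["p1", "p2", "p3", "p4", "dd", "tt"]}

    def test_extreme_window_is_candidate_with_minimal_rank_sum(self):
        fst = {c: v.copy() for c, v in self.base.items()}
        for c in ["p1", "p2", "p3", "p4"]:
            fst[c][0] = 0.9
        res = quartet_rank_sum(_window_tables(fst))
        assert res.loc[0, "candidate"]
        assert res.loc[0, "rank_sum"] == 4.0

    def test_dd_outlier_is_excluded_even_if_top_ranked(self):
        fst = {c: v.copy() for c, v in self.base.items()}
        for c in ["p1", "p2", "p3", "p4", "dd"]:
            fst[c][0] = 0.9
        res = quartet_rank_sum(_window_tables(fst), exclusion_order="before")
        assert res.loc[0, "dd_outlier"] and not res.loc[0, "candidate"]
        res_after = quartet_rank_sum(_window_tables(fst), exclusion_order="after")
        assert not res_after.loc[0, "candidate"]

    def test_duplicated_contrasts_reduce_to_single_contrast_outliers(self):
        fst = {c: self.base["p1"] for c in ["p1", "p2", "p3", "p4"]}
        fst["dd"] = np.zeros(self.n)
        fst["tt"] = np.zeros(self.n)
        res = quartet_rank_sum(_window_tables(fst), top_frac=0.05)
        cut = np.quantile(self.base["p1"], 0.95)
        expected = self.base["p1"] >= cut
        # quantile interpolation can move the boundary by one window
        assert (res["candidate"].to_numpy() ^ expected).sum() <= 1

    def test_candidate_count_tracks_top_fraction(self):
        res = quartet_rank_sum(_window_tables(self.base), top_frac=0.05)
        eligible_pool = (~res["dd_outlier"] & ~res["tt_outlier"]).sum()
        assert abs(res["candidate"].sum() - 0.05 * eligible_pool) <= 2

    def test_mismatched_grids_rejected(self):
        tables = _window_tables(self.base)
        tables["tt"] = tables["tt"].iloc[:-1]
        with pytest.raises(ValueError, match="grid"):
            quartet_rank_sum(tables)

    def test_ineligible_windows_never_candidates(self):
        tables = _window_tables(self.base)
        tables = {c: t.assign(eligible=np.arange(self.n) % 2 == 0) for c, t in tables.items()}
        res = quartet_rank_sum(tables)
        assert not res.loc[~res["eligible"], "candidate"].any()


GENES = pd.DataFrame(
    {
        "gene_id": ["gA", "gB", "gC"],
        "scaffold": ["s1", "s1", "s2"],
        "start": [100, 2500, 0],
        "end": [1200, 3500, 500],
    }
)


class TestAnnotateCandidates:
    def test_window_inside_gene(self):
        w = pd.DataFrame({"scaffold": ["s1"], "start": [200], "end": [300]})
        assert annotate_candidates(w, GENES) == ["gA"]

    def test_window_spanning_two_genes(self):
        genes = GENES.copy()
        genes.loc[1, ["start", "end"]] = [1150, 2000]
        w = pd.DataFrame({"scaffold": ["s1"], "start": [1100], "end": [1200]})
        assert annotate_candidates(w, genes) == ["gA", "gB"]

    def test_no_overlap_empty(self):
        w = pd.DataFrame({"scaffold": ["s1"], "start": [2000], "end": [2100]})
        assert annotate_candidates(w, GENES) == []

    def test_gene_reported_once(self):
        w = pd.DataFrame({"scaffold": ["s1", "s1"], "start": [100, 500], "end": [200, 600]})
        assert annotate_candidates(w, GENES) == ["gA"]


class TestGenomeStats:
    def test_fixed_difference(self):
        table = make_af_table(np.array([[0.0, 1.0, 0.5, 0.5]]))
        s = genome_stats(table, ("LUZ", "VKR"))
        assert s.mean_afd == 1.0 and s.fixed_differences == 1 and s.mean_fst == 1.0

    def test_identical_populations(self):
        table = make_af_table(np.tile([[0.4, 0.4, 0.4, 0.4]], (5, 1)))
        s = genome_stats(table, ("LUZ", "VKR"))
        assert s.mean_afd == 0.0 and s.fixed_differences == 0 and s.mean_fst == 0.0

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(4)
        af = rng.random((10, 4))
        table = make_af_table(af)
        s = genome_stats(table, ("VKR", "CEZ"))
        afd = [abs(a - b) for a, b in zip(af[:, 1], af[:, 2])]
        fsts = [brute_snp_fst(a, b) for a, b in zip(af[:, 1], af[:, 2])]
        fsts = [f for f in fsts if not np.isnan(f)]
        assert s.mean_afd == pytest.approx(np.mean(afd))
        assert s.fixed_differences == sum(d >= 1 - 1e-9 for d in afd)
        assert s.mean_fst == pytest.approx(np.mean(fsts))

    def test_empty_table_rejected(self):
        table = make_af_table(np.empty((0, 4)), positions=[])
        with pytest.raises(ValueError):
            genome_stats(table, ("LUZ", "VKR"))


class TestGenicFraction:
    def test_constant_fst_undefined(self):
        w = pd.DataFrame(
            {"scaffold": ["s1"] * 3, "start": [0, 1000, 2000], "end": [1000, 2000, 3000], "fst": 0.2}
        )
        r, n = genic_fraction_check(w, GENES)
        assert np.isnan(r) and n == 3

    def test_perfect_correlation(self):
        # gene gA covers 90% of window 1 and 20% of window 2; fst set equal to
        # those fractions
        w = pd.DataFrame(
            {"scaffold": ["s1", "s1"], "start": [200, 1000], "end": [1200, 2000], "fst": [0.9, 0.2]}
        )
        r, n = genic_fraction_check(w, GENES)
        assert r == pytest.approx(1.0) and n == 2


def test_gene_level_scan_excludes_sparse_genes_and_finds_sweep():
    rng = np.random.default_rng(5)
    n = 400
    af = np.clip(rng.normal(0.5, 0.05, (n, 4)), 0, 1)
    pos = np.arange(n) * 10
    # gene spans: dense sweep gene, dense neutral gene, sparse gene (4 SNPs)
    genes = pd.DataFrame(
        {
            "gene_id": ["sweep", "neutral", "sparse"],
            "scaffold": ["s1"] * 3,
            "start": [0, 1000, 2000],
            "end": [1000, 2000, 2035],
        }
    )
    sweep_snps = pos < 1000
    af[sweep_snps, 2] = np.clip(af[sweep_snps, 2] + 0.9, 0, 1)
    af[sweep_snps, 3] = np.clip(af[sweep_snps, 3] + 0.9, 0, 1)
    table = make_af_table(af, positions=pos)
    res = gene_level_scan(table, genes, DESIGN, min_snps_per_gene=5, top_frac=0.5)
    res = res.set_index("gene_id")
    assert not res.loc["sparse", "eligible"]
    assert res.loc["sweep", "candidate"]
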