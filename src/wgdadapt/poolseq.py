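"""Pool-seq VCF input, site filtering, and replicate-averaged allele frequencies.

Pooled sequencing estimates a population allele frequency as the fraction of
reads carrying the alternate allele.  With replicated pools (several
independently pooled libraries per population) the population estimate is the
unweighted mean over replicate-pool frequencies, which averages out
library-level sampling noise.

Coordinates are 0-based half-open internally; conversion to/from the 1-based
VCF and GFF3 conventions happens only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


class SNPRecord(NamedTuple):
    """One biallelic SNP with per-sample read counts."""

    scaffold: str
    pos: int  # 0-based
    ref: str
    alt: str
    ref_reads: np.ndarray  # per sample
    alt_reads: np.ndarray


@dataclass
class PoolReadCounts:
    """Read counts for replicated population pools.

    ``ref`` and ``alt`` have shape (n_snps, n_pops, n_replicates); ``sites``
    has one row per SNP with columns scaffold, pos (0-based), ref, alt.
    """

    sites: pd.DataFrame
    pops: list[str]
    ploidy: dict[str, int]
    ref: np.ndarray
    alt: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    @property
    def n_replicates(self) -> int:
        return self.ref.shape[2]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def sample_names(self) -> list[str]:
        return [f"{p}_rep{r + 1}" for p in self.pops for r in range(self.n_replicates)]

    def take(self, mask: np.ndarray) -> "PoolReadCounts":
        return PoolReadCounts(
            sites=self.sites.loc[mask].reset_index(drop=True),
            pops=list(self.pops),
            ploidy=dict(self.ploidy),
            ref=self.ref[mask],
            alt=self.alt[mask],
        )


@dataclass
class AFTable:
    """Per-SNP, per-population allele frequencies with replicate provenance.

    ``af`` (n_snps, n_pops) holds the population frequencies; ``rep_af`` holds
    the per-replicate frequencies (NaN where a replicate had zero depth) and is
    None for tables of true simulated frequencies.  The population frequency
    always equals the mean of its non-missing replicate frequencies.
    """

    sites: pd.DataFrame
    pops: list[str]
    ploidy: dict[str, int]
    af: np.ndarray
    rep_af: np.ndarray | None = None
    depth: np.ndarray | None = None  # per population, summed over replicates

    def __post_init__(self) -> None:
        if np.any((self.af < 0) | (self.af > 1)):
            raise ValueError("allele frequencies outside [0, 1]")
        if self.rep_af is not None:
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(self.rep_af, axis=2)
            if not np.allclose(np.nan_to_num(mean), np.nan_to_num(self.af), atol=1e-12):
                raise ValueError("population AF must equal the mean of replicate AFs")

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def pops_with_ploidy(self, ploidy: int) -> list[str]:
        return [p for p in self.pops if self.ploidy[p] == ploidy]

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        for j, p in enumerate(self.pops):
            out[f"af_{p}"] = self.af[:, j]
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.DataFrame:
    """Read a ``sample<TAB>population<TAB>ploidy<TAB>replicate`` map."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    required = {"sample", "population", "ploidy", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample map missing columns: {sorted(missing)}")
    return df


def iter_pool_vcf(path, samples: Sequence[str]) -> Iterator[SNPRecord]:
    """Stream biallelic SNPs from a VCF, skipping indels and multiallelics.

    Requires a per-sample AD (ref,alt depth) FORMAT field.  Yields read counts
    in the column order of ``samples``.
    """
    for rec, _ in _iter_vcf_with_skips(path, samples):
        if rec is not None:
            yield rec


def _iter_vcf_with_skips(path, samples):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in samples if s not in vcf_samples]
    if missing:
        raise ValueError(f"samples not in VCF: {missing}")
    order = np.array([vcf_samples.index(s) for s in samples])
    for v in vcf:
        if len(v.ALT) != 1:
            yield None, "multiallelic"
            continue
        if not v.is_snp:
            yield None, "indel_or_other"
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"missing AD field at {v.CHROM}:{v.POS} for samples {samples!r}"
            )
        ad = np.asarray(ad)[order]
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as large negatives
        yield (
            SNPRecord(v.CHROM, v.POS - 1, v.REF, v.ALT[0], ad[:, 0], ad[:, 1]),
            None,
        )


def read_pool_vcf(path, sample_map: pd.DataFrame) -> tuple[PoolReadCounts, dict[str, int]]:
    """Read a pool-seq VCF into replicate read-count arrays.

    ``sample_map`` follows :func:`read_sample_map`.  Returns the counts plus a
    log of skipped records (multiallelic sites and indels are excluded, as the
    analysis is restricted to biallelic SNPs).
    """
    pops = list(dict.fromkeys(sample_map["population"]))
    ploidy = {
        p: int(sample_map.loc[sample_map["population"] == p, "ploidy"].iloc[0])
        for p in pops
    }
    # samples ordered population-major, replicate-minor
    ordered = sample_map.sort_values(
        by=["population", "replicate"],
        key=lambda c: c.map({p: i for i, p in enumerate(pops)}) if c.name == "population" else c,
    )
    samples = list(ordered["sample"])
    n_rep = len(samples) // len(pops)
    if n_rep * len(pops) != len(samples):
        raise ValueError("unequal replicate counts per population")

    rows, refs, alts = [], [], []
    skipped = {"multiallelic": 0, "indel_or_other": 0}
    for rec, reason in _iter_vcf_with_skips(path, samples):
        if rec is None:
            skipped[reason] += 1
            continue
        rows.append((rec.scaffold, rec.pos, rec.ref, rec.alt))
        refs.append(rec.ref_reads)
        alts.append(rec.alt_reads)
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    shape = (len(rows), len(pops), n_rep)
    counts = PoolReadCounts(
        sites=sites,
        pops=pops,
        ploidy=ploidy,
        ref=np.asarray(refs, dtype=np.int64).reshape(shape) if rows else np.zeros(shape, dtype=np.int64),
        alt=np.asarray(alts, dtype=np.int64).reshape(shape) if rows else np.zeros(shape, dtype=np.int64),
    )
    return counts, skipped


def depth_threshold_from_mode(depth_histogram, multiplier: float = 1.6) -> int:
    """Max-depth cutoff: ``multiplier`` x the second local mode of the depth histogram.

    The per-site depth histogram of pooled data typically shows a low-depth
    artifact mode and a main coverage mode; sites far above the main mode are
    collapsed repeats or paralogs.  ``depth_histogram`` maps depth -> site
    count (dict or array indexed by depth).  Modes are local maxima ordered by
    depth; the cutoff is the second one, scaled and rounded.
    """
    if isinstance(depth_histogram, Mapping):
        if not depth_histogram:
            raise ValueError("empty depth histogram")
        max_d = max(depth_histogram)
        counts = np.zeros(max_d + 1)
        for d, c in depth_histogram.items():
            counts[int(d)] = c
    else:
        counts = np.asarray(depth_histogram, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty depth histogram")
    # pad so boundary maxima count as modes
    padded = np.concatenate([[-1.0], counts, [-1.0]])
    peaks, _ = find_peaks(padded)
    modes = np.sort(peaks - 1)
    if len(modes) < 2:
        raise ValueError(
            "fewer than two local modes in the depth histogram; "
            "supply an explicit max-depth cutoff instead"
        )
    return int(np.rint(multiplier * modes[1]))


def filter_sites(
    reads: PoolReadCounts,
    min_dp: int = 10,
    max_dp: int | None = None,
    scope: str = "replicate",
) -> tuple[PoolReadCounts, pd.DataFrame]:
    """Apply min/max depth filters; returns retained counts and a removal log.

    scope="replicate" (default) removes a site if *any* replicate pool violates
    the depth bounds — the conservative reading.  scope="summed" applies the
    bounds to per-population depth summed over replicates.
    """
    if max_dp is not None and max_dp <= min_dp:
        raise ValueError("max_dp must exceed min_dp")
    if scope == "replicate":
        depth = reads.depth  # (n, pops, reps)
        low = (depth < min_dp).any(axis=(1, 2))
        high = (
            (depth > max_dp).any(axis=(1, 2))
            if max_dp is not None
            else np.zeros(reads.n_snps, dtype=bool)
        )
    elif scope == "summed":
        depth = reads.depth.sum(axis=2)
        low = (depth < min_dp).any(axis=1)
        high = (
            (depth > max_dp).any(axis=1)
            if max_dp is not None
            else np.zeros(reads.n_snps, dtype=bool)
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    removed = low | high
    reasons = np.where(low, "min_depth", np.where(high, "max_depth", ""))
    log = reads.sites.loc[removed, ["scaffold", "pos"]].copy()
    log["reason"] = reasons[removed]
    return reads.take(~removed), log.reset_index(drop=True)


def population_afs(reads: PoolReadCounts) -> tuple[AFTable, pd.DataFrame]:
    """Replicate AF = alt/(ref+alt); population AF = mean over replicates with data.

    Replicates with zero depth contribute NaN and are ignored in the mean.
    Sites where every replicate of some population has zero depth are dropped
    and logged.
    """
    depth = reads.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rep_af = np.where(depth > 0, reads.alt / np.where(depth > 0, depth, 1), np.nan)
    pop_has_data = (depth > 0).any(axis=2)
    keep = pop_has_data.all(axis=1)
    log = reads.sites.loc[~keep, ["scaffold", "pos"]].copy()
    log["reason"] = "zero_depth_population"
    rep_af = rep_af[keep]
    with np.errstate(invalid="ignore"):
        af = np.nanmean(rep_af, axis=2)
    table = AFTable(
        sites=reads.sites.loc[keep].reset_index(drop=True),
        pops=list(reads.pops),
        ploidy=dict(reads.ploidy),
        af=af,
        rep_af=rep_af,
        depth=reads.depth[keep].sum(axis=2),
    )
    return table, log.reset_index(drop=True)
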