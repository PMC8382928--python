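"""FineMAV scoring of amino-acid substitutions.

Fine-Mapping of Adaptive Variation ranks coding SNPs by combining a
physicochemical severity term with a population-genetic term:

    S = G(aa_ref, aa_alt) * f_max * DAP

where G is the Grantham distance between the two amino acids, f_max the
largest derived-allele frequency among the population groups (here the two
cytotypes: diploid and tetraploid), and DAP the derived allele purity

    DAP = (max(d) / sum(d)) ** A

with exponent A = 3.5 by default.  DAP measures how unequally the derived
allele is distributed among groups: a radical substitution at high frequency
in exactly one cytotype scores highest.  Minor alleles (averaged over the two
cytotypes) are treated as derived.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

MAX_GRANTHAM = 215

_matrix_cache: pd.DataFrame | None = None


def load_grantham() -> pd.DataFrame:
    """Load the published 20x20 Grantham distance matrix (one-letter codes).

    Validated at load: symmetric, zero diagonal, off-diagonal values within
    the published range [5, 215].
    """
    global _matrix_cache
    if _matrix_cache is None:
        with resources.files("wgdadapt").joinpath("data/grantham.tsv").open() as fh:
            m = pd.read_csv(fh, sep="\t", index_col=0)
        m.index.name = None
        if list(m.index) != list(m.columns) or len(m) != 20:
            raise ValueError("Grantham matrix must be 20x20 with matching row/column order")
        a = m.to_numpy()
        if not np.array_equal(a, a.T):
            raise ValueError("Grantham matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("Grantham diagonal must be zero")
        off = a[~np.eye(20, dtype=bool)]
        if off.min() < 5 or off.max() > 215:
            raise ValueError("Grantham off-diagonal values must lie in [5, 215]")
        _matrix_cache = m
    return _matrix_cache


def grantham(aa_ref: str, aa_alt: str) -> int:
    """Grantham distance between two amino acids (one-letter codes)."""
    m = load_grantham()
    try:
        return int(m.loc[aa_ref, aa_alt])
    except KeyError as exc:
        raise KeyError(f"unknown amino-acid code: {exc}") from None


def polarize_derived(f2x, f4x):
    """Derived-allele frequencies under the minor-allele-is-derived convention.

    If the alternate allele is the major one on average across cytotypes
    (mean(f2x, f4x) > 0.5), the reference allele is treated as derived and
    d = 1 - f; otherwise d = f.  An exact tie treats the alternate as derived.
    """
    f2x = np.asarray(f2x, dtype=float)
    f4x = np.asarray(f4x, dtype=float)
    if np.any((f2x < 0) | (f2x > 1) | (f4x < 0) | (f4x > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    flip = (f2x + f4x) / 2.0 > 0.5
    return np.where(flip, 1.0 - f2x, f2x), np.where(flip, 1.0 - f4x, f4x)


def dap(derived_freqs, exponent: float = 3.5) -> float:
    """Derived allele purity: (max(d) / sum(d)) ** exponent.  Requires sum(d) > 0."""
    d = np.asarray(derived_freqs, dtype=float)
    total = d.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("dap requires a positive total derived frequency")
    return (d.max(axis=-1) / total) ** exponent


def finemav_score(
    aa_ref: str,
    aa_alt: str,
    f2x: float,
    f4x: float,
    exponent: float = 3.5,
    formula: str = "purity",
) -> float:
    """FineMAV score for one substitution.

    formula="purity" (default) gives S = G * f_max * DAP; formula="afd" gives
    the alternative S = G * |d4x - d2x| * DAP.  Synonymous records
    (aa_ref == aa_alt) and records with zero total derived frequency score 0.
    """
    g = grantham(aa_ref, aa_alt)
    d2, d4 = polarize_derived(f2x, f4x)
    d2, d4 = float(d2), float(d4)
    if g == 0 or d2 + d4 == 0:
        return 0.0
    purity = dap([d2, d4], exponent)
    amp = max(d2, d4) if formula == "purity" else abs(d4 - d2)
    return float(g * amp * purity)


def score_table(
    subs: pd.DataFrame, exponent: float = 3.5, formula: str = "purity"
) -> pd.DataFrame:
    """Vectorized FineMAV over a substitution table.

    Requires columns aa_ref, aa_alt, f2x, f4x; adds grantham, d2x, d4x, dap,
    score.  Unknown amino-acid codes raise.
    """
    if formula not in ("purity", "afd"):
        raise ValueError("formula must be 'purity' or 'afd'")
    m = load_grantham()
    out = subs.copy()
    codes = {a: i for i, a in enumerate(m.index)}
    bad = sorted((set(out["aa_ref"]) | set(out["aa_alt"])) - set(codes))
    if bad:
        raise KeyError(f"unknown amino-acid code(s): {bad}")
    i = out["aa_ref"].map(codes).to_numpy(dtype=int)
    j = out["aa_alt"].map(codes).to_numpy(dtype=int)
    g = m.to_numpy()[i, j]
    d2, d4 = polarize_derived(out["f2x"].to_numpy(), out["f4x"].to_numpy())
    total = d2 + d4
    dmax = np.maximum(d2, d4)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, (dmax / np.where(total > 0, total, 1.0)) ** exponent, 0.0)
    amp = dmax if formula == "purity" else np.abs(d4 - d2)
    out["grantham"] = g
    out["d2x"] = d2
    out["d4x"] = d4
    out["dap"] = purity
    out["score"] = np.where((g > 0) & (total > 0), g * amp * purity, 0.0)
    return out


def top_fraction(scored: pd.DataFrame, frac: float = 0.01) -> pd.DataFrame:
    """Flag top-fraction FineMAV outliers among scored records.

    The quantile is computed over scored records only (nonsynonymous with a
    nonzero derived frequency, i.e. grantham > 0 and d2x + d4x > 0); ties at
    the threshold expand the outlier set.  Adds a boolean ``outlier`` column.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    out = scored.copy()
    in_scope = (out["grantham"].to_numpy() > 0) & (
        (out["d2x"].to_numpy() + out["d4x"].to_numpy()) > 0
    )
    outlier = np.zeros(len(out), dtype=bool)
    if in_scope.any():
        cut = np.quantile(out.loc[in_scope, "score"].to_numpy(), 1.0 - frac)
        outlier[in_scope] = out.loc[in_scope, "score"].to_numpy() >= cut
    out["outlier"] = outlier
    return out
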