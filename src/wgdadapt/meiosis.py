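"""Meiotic-stability scoring of chromosome spreads and the ploidy contrast.

In autopolyploids, multivalent chromosome associations at metaphase I
predispose to missegregation, so the number of bivalents per spread proxies
meiotic stability.  Spreads are classified into four bands by bivalent count
(diploids carry up to 8 bivalents, tetraploids up to 16), per-individual
stability is the fraction of qualifying cells, and the ploidy difference is
tested with a binomial GLM whose deviance drop D is chi-square(1) distributed
under the null of equal stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

CATEGORIES = ["stable", "partly_stable", "partly_unstable", "unstable"]

_MAX_BIVALENTS = {2: 8, 4: 16}


def _normalize_ploidy(ploidy) -> int:
    if isinstance(ploidy, str):
        ploidy = ploidy.rstrip("xX")
    ploidy = int(ploidy)
    if ploidy not in (2, 4):
        raise ValueError(f"ploidy must be 2 or 4, got {ploidy}")
    return ploidy


def classify_spread(ploidy, n_bivalents: int) -> str:
    """Stability category from (ploidy, bivalent count).

    Diploid: 8 stable, 7-6 partly stable, 5-4 partly unstable, <4 unstable.
    Tetraploid: 16 stable, 14-12 partly stable, 10-8 partly unstable, <8
    unstable.  Tetraploid counts 15 and 11 fall between the enumerated bands
    and are resolved by extending the nearest band downward (15 -> partly
    stable, 11 -> partly unstable), with a warning.
    """
    ploidy = _normalize_ploidy(ploidy)
    n = int(n_bivalents)
    if n < 0 or n > _MAX_BIVALENTS[ploidy]:
        raise ValueError(
            f"bivalent count {n} outside 0..{_MAX_BIVALENTS[ploidy]} for ploidy {ploidy}"
        )
    if ploidy == 2:
        if n == 8:
            return "stable"
        if n >= 6:
            return "partly_stable"
        if n >= 4:
            return "partly_unstable"
        return "unstable"
    if n == 16:
        return "stable"
    if n in (15, 11):
        warnings.warn(
            f"tetraploid bivalent count {n} falls between scoring bands; "
            "extending the nearest band downward",
            stacklevel=2,
        )
    if n >= 12:
        return "partly_stable"
    if n >= 8:
        return "partly_unstable"
    return "unstable"


def classify_table(spreads: pd.DataFrame) -> pd.DataFrame:
    """Add a ``category`` column to a spread table (individual, ploidy, n_bivalents)."""
    out = spreads.copy()
    out["category"] = [
        classify_spread(p, n) for p, n in zip(out["ploidy"], out["n_bivalents"])
    ]
    return out


def _qualifying(categories: pd.Series, mode: str) -> np.ndarray:
    if mode == "stable_only":
        return (categories == "stable").to_numpy()
    if mode == "stable_plus_partly":
        return categories.isin(["stable", "partly_stable"]).to_numpy()
    raise ValueError("mode must be 'stable_only' or 'stable_plus_partly'")


@dataclass(frozen=True)
class StabilitySummary:
    per_individual: pd.DataFrame  # individual, ploidy, n_cells, proportion
    ploidy_means: dict[int, float]  # unweighted mean over individuals
    cell_counts: dict[int, int]
    mode: str


def stability_summary(spreads: pd.DataFrame, mode: str = "stable_plus_partly") -> StabilitySummary:
    """Per-individual and per-ploidy stability proportions.

    The per-individual proportion is qualifying cells / scored cells; ploidy
    means are unweighted over individuals.
    """
    scored = spreads if "category" in spreads else classify_table(spreads)
    q = _qualifying(scored["category"], mode)
    per_ind = (
        scored.assign(q=q)
        .groupby(["individual", "ploidy"], sort=True)
        .agg(n_cells=("q", "size"), proportion=("q", "mean"))
        .reset_index()
    )
    per_ind["ploidy"] = [_normalize_ploidy(p) for p in per_ind["ploidy"]]
    means = per_ind.groupby("ploidy")["proportion"].mean().to_dict()
    counts = per_ind.groupby("ploidy")["n_cells"].sum().to_dict()
    return StabilitySummary(
        per_individual=per_ind,
        ploidy_means={int(k): float(v) for k, v in means.items()},
        cell_counts={int(k): int(v) for k, v in counts.items()},
        mode=mode,
    )


def ploidy_glm_test(
    spreads: pd.DataFrame, mode: str = "stable_plus_partly"
) -> tuple[float, int, float]:
    """Binomial GLM of cell outcome on ploidy: returns (deviance D, df, p).

    Each scored cell is a Bernoulli trial (qualifying vs not); D is the null
    deviance minus the residual deviance of the ploidy model, distributed
    chi-square with 1 df under the null.  For ploidy-aggregated counts D
    equals the 2x2 G-statistic 2 Σ O ln(O/E).
    """
    import statsmodels.api as sm

    scored = spreads if "category" in spreads else classify_table(spreads)
    y = _qualifying(scored["category"], mode).astype(float)
    ploidy = np.array([_normalize_ploidy(p) for p in scored["ploidy"]])
    present = set(ploidy)
    if present != {2, 4}:
        raise ValueError(f"both ploidies must have scored cells, got {sorted(present)}")
    x = sm.add_constant((ploidy == 4).astype(float))
    fit = _quiet_glm_fit(sm, y, x)
    d = float(fit.null_deviance - fit.deviance)
    p = float(chi2.sf(d, 1))
    return d, 1, p


def _quiet_glm_fit(sm, y, x):
    # a saturated 2-level binomial fit legitimately separates perfectly;
    # the deviance is still well-defined, so silence the fit-time warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, x, family=sm.families.Binomial()).fit()


def ploidy_glm_test_counts(table_2x2) -> tuple[float, int, float]:
    """Aggregated-counts variant: rows = (qualifying, non-qualifying) per ploidy.

    Fits the same binomial GLM on the 2x2 table directly and yields a deviance
    identical to the cell-level fit (and to the G-statistic 2 Σ O ln(O/E)).
    """
    import statsmodels.api as sm

    counts = np.asarray(table_2x2, dtype=float)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("both ploidies must have scored cells")
    x = sm.add_constant(np.array([0.0, 1.0]))
    fit = _quiet_glm_fit(sm, counts, x)
    d = float(fit.null_deviance - fit.deviance)
    return d, 1, float(chi2.sf(d, 1))
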