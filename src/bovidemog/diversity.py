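"""Per-population diversity and inbreeding statistics.

Observed heterozygosity Ho, Nei's sample-size-unbiased expected
heterozygosity He, the multilocus inbreeding coefficient
F_IS = 1 − Ho/He (ratio of locus means, not mean of per-locus ratios),
and Welch's unequal-variance t-test for comparing breed groups.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeDataset


def _pop_calls(ds: GenotypeDataset, population: str) -> np.ndarray:
    return ds.calls[ds.sample_indices(population)]


def observed_het(ds: GenotypeDataset, population: str) -> float:
    """Mean over variants of (heterozygous calls / non-missing calls).

    Variants with no non-missing call in the population are excluded.
    """
    calls = _pop_calls(ds, population)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    ok = n_called > 0
    if not ok.any():
        raise ValueError(f"{population}: no called genotypes")
    return float((n_het[ok] / n_called[ok]).mean())


def expected_het_unbiased(ds: GenotypeDataset, population: str) -> float:
    """Nei (1978) unbiased expected heterozygosity, averaged over variants.

    Per variant with k non-missing allele copies and alternate frequency p:
    he = k/(k−1) · (1 − p² − (1−p)²).  Variants with fewer than 2 diploid
    calls are excluded; monomorphic variants contribute 0 and are retained
    (the array panel is fixed across populations).
    """
    calls = _pop_calls(ds, population)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    ok = n_called >= 2
    if not ok.any():
        raise ValueError(f"{population}: no variant with >= 2 called genotypes")
    k = 2.0 * n_called[ok]
    alt = np.where(called, calls, 0).sum(axis=0)[ok]
    p = alt / k
    he = (k / (k - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    return float(he.mean())


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient F_IS = 1 − Ho/He; NaN when He = 0."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def diversity_table(ds: GenotypeDataset, min_n: int | None = None) -> pd.DataFrame:
    """One row per population (input order): n, ho, he, fis.

    ``min_n`` optionally drops populations with fewer sampled diploids
    (small breeds are a robustness check, not a different estimator).
    """
    rows = []
    for pop in ds.population_names():
        n = ds.sample_indices(pop).size
        if min_n is not None and n < min_n:
            continue
        ho = observed_het(ds, pop)
        he = expected_het_unbiased(ds, pop)
        rows.append({"population": pop, "n": n, "ho": ho, "he": he, "fis": fis(ho, he)})
    return pd.DataFrame(rows, columns=["population", "n", "ho", "he", "fis"])


# ---------------------------------------------------------------------------
# reference breed panel
# ---------------------------------------------------------------------------

def load_breed_panel() -> pd.DataFrame:
    """Published per-breed diversity summary for a 56-breed bovine SNP panel.

    Columns: abb (breed code), breed, tax (taurus / indicus / hybrid, or the
    outgroup species), n, ho (observed heterozygosity), fis.  Breeds with
    too few genotyped animals carry empty ho/fis cells.
    """
    ref = importlib.resources.files("bovidemog") / "data" / "breed_panel_diversity.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"abb": str})


def breed_group_means(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean Ho and F_IS per taxonomic group of the reference panel
    (rows with missing values excluded)."""
    if panel is None:
        panel = load_breed_panel()
    ok = panel.dropna(subset=["ho", "fis"])
    out = ok.groupby("tax", sort=False)[["ho", "fis"]].mean().reset_index()
    return out
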