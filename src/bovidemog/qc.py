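"""Quality-control filters on genotype datasets.

The merge-and-filter protocol for multi-chip SNP-array data: drop samples
below a call-rate threshold first, then SNPs below a call-rate threshold
computed on the remaining samples, then (for structure analyses) prune by
minor-allele frequency and sliding-window LD.
"""

from __future__ import annotations

import numpy as np

from .datatypes import MISSING, GenotypeDataset


class EmptyDatasetError(ValueError):
    """Every sample or variant was removed by a filter."""


def filter_call_rate(
    ds: GenotypeDataset,
    sample_min: float = 0.95,
    snp_min: float = 0.95,
) -> GenotypeDataset:
    """Keep samples with call rate >= sample_min, then SNPs with call rate
    >= snp_min over the remaining samples.

    The order is fixed — samples before SNPs — and matters: removing a
    badly-typed sample can rescue SNPs that would otherwise fail.  The
    input dataset is not modified.  Thresholds are "keep at >=".
    """
    for name, thr in (("sample_min", sample_min), ("snp_min", snp_min)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    called = ds.calls != MISSING
    sample_rate = called.mean(axis=1) if ds.n_variants else np.ones(ds.n_samples)
    keep_s = np.flatnonzero(sample_rate >= sample_min)
    if keep_s.size == 0:
        raise EmptyDatasetError("all samples filtered by call rate")
    snp_rate = called[keep_s].mean(axis=0) if keep_s.size else np.zeros(ds.n_variants)
    keep_v = np.flatnonzero(snp_rate >= snp_min)
    if keep_v.size == 0:
        raise EmptyDatasetError("all SNPs filtered by call rate")
    if keep_s.size == ds.n_samples and keep_v.size == ds.n_variants:
        return ds.subset()  # fresh copy, unchanged content
    return ds.subset(sample_idx=keep_s, variant_idx=keep_v)


def minor_allele_freq(ds: GenotypeDataset, subset: list[str] | None = None) -> np.ndarray:
    """Per-variant MAF = min(p, 1-p) over non-missing calls in ``subset``
    (default: all samples).  Variants with no non-missing call are NaN.
    """
    if subset is None:
        idx = np.arange(ds.n_samples)
    else:
        if not subset:
            raise ValueError("subset must be non-empty")
        pos = {s: i for i, s in enumerate(ds.samples)}
        unknown = [s for s in subset if s not in pos]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        idx = np.array([pos[s] for s in subset], dtype=int)
    calls = ds.calls[idx]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.minimum(p, 1.0 - p)


def _genotype_r2(calls: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of genotype codes, pairwise-complete."""
    ok = (calls[:, i] != MISSING) & (calls[:, j] != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = calls[ok, i].astype(float)
    y = calls[ok, j].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
    maf_min: float = 0.01,
) -> GenotypeDataset:
    """MAF + sliding-window LD pruning (PLINK --indep-pairwise analogue).

    Removes variants with MAF < maf_min, then slides a ``window_snps``-wide
    window in ``step_snps`` steps along each chromosome; within a window,
    for every pair with genotype r² > r2_max the later-positioned variant
    is removed.  Deterministic given input order; r² is computed on
    unphased genotype codes since pruning precedes phasing.
    """
    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")
    maf = minor_allele_freq(ds)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    ds2 = ds.subset(variant_idx=keep)

    kept = np.ones(ds2.n_variants, dtype=bool)
    chroms = ds2.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):  # preserve order
        cidx = np.flatnonzero(chroms == chrom)
        n = cidx.size
        start = 0
        while True:
            win = cidx[start : start + window_snps]
            alive = [int(v) for v in win if kept[v]]
            for a_pos in range(len(alive)):
                i = alive[a_pos]
                if not kept[i]:
                    continue
                for j in alive[a_pos + 1 :]:
                    if not kept[j]:
                        continue
                    if _genotype_r2(ds2.calls, i, j) > r2_max:
                        kept[j] = False  # drop the later-positioned variant
            if start + window_snps >= n:
                break
            start += step_snps
    return ds2.subset(variant_idx=np.flatnonzero(kept))
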