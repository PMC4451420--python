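"""Cross-population extended haplotype homozygosity (XP-EHH) from scratch.

EHH at a flanking position x is the probability that two haplotypes drawn
at random from the whole sample are identical over the interval from the
core SNP to x; iHH is the trapezoidal integral of the EHH decay curve over
physical distance on both sides of the core; XP-EHH is ln(iHH_A / iHH_B)
between two populations at the same SNP, standardized per chromosome, with
genome-wide 5 %/95 % quantile outlier flags.

The whole-sample (unpartitioned) EHH is the quantity XP-EHH integrates;
an allele-partitioned variant is kept for testing.  Curves are truncated
where EHH drops below a cutoff (default 0.05), at chromosome ends, and at
the last SNP before an inter-SNP gap larger than ``max_gap_bp`` (default
400 kb, matched to medium-density array spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HaplotypeSet

EHH_CUTOFF = 0.05
MAX_GAP_BP = 400_000


@dataclass
class EhhCurve:
    """EHH decay to one side of a core SNP.

    The first point is (core position, 1.0) — two haplotypes are trivially
    identical over a zero-length interval; each further point at x gives
    the probability of identity over the allele string core..x inclusive.
    """

    core_index: int
    direction: str  # "left" or "right"
    points: list[tuple[int, float]]


def _group_sizes_to_ehh(sizes: np.ndarray, n: int) -> float:
    """Sum of C(g,2) over identity groups divided by C(n,2)."""
    return float((sizes * (sizes - 1)).sum() / (n * (n - 1)))


def ehh(
    hapset: HaplotypeSet,
    core: int,
    direction: str,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: int = MAX_GAP_BP,
) -> EhhCurve:
    """Whole-sample EHH decay curve from ``core`` in one direction.

    Haplotype identity groups are refined one SNP at a time (equivalent to
    counting identical pairs over core..x); the curve stops before the
    first point with EHH < cutoff, at the chromosome end, or at the last
    SNP before a gap larger than ``max_gap_bp``.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if hapset.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    return _ehh_over_rows(
        hapset.haplotypes, hapset.positions(), core, direction, cutoff, max_gap_bp
    )


def ehh_partitioned(
    hapset: HaplotypeSet,
    core: int,
    allele: int,
    direction: str,
    cutoff: float = 0.0,
    max_gap_bp: int = MAX_GAP_BP,
) -> EhhCurve:
    """EHH restricted to carriers of ``allele`` at the core (the classic
    single-population form; used for testing, not by XP-EHH)."""
    carriers = np.flatnonzero(hapset.haplotypes[:, core] == allele)
    if carriers.size < 2:
        raise ValueError("need at least 2 carrier haplotypes")
    return _ehh_over_rows(hapset.haplotypes[carriers], hapset.positions(), core,
                          direction, cutoff, max_gap_bp)


def _ehh_over_rows(H, pos, core, direction, cutoff, max_gap_bp) -> EhhCurve:
    n = H.shape[0]
    step = 1 if direction == "right" else -1
    points = [(int(pos[core]), 1.0)]
    group = H[:, core].astype(np.int64)
    x = core
    prev_pos = pos[core]
    while True:
        x += step
        if x < 0 or x >= H.shape[1]:
            break
        if abs(int(pos[x]) - int(prev_pos)) > max_gap_bp:
            break
        group = group * 2 + H[:, x]
        _, group = np.unique(group, return_inverse=True)
        sizes = np.bincount(group).astype(np.float64)
        val = _group_sizes_to_ehh(sizes, n)
        if val < cutoff:
            break
        points.append((int(pos[x]), val))
        prev_pos = pos[x]
        if val == 0.0:
            break
    return EhhCurve(core_index=core, direction=direction, points=points)


def ihh(curve_left: EhhCurve, curve_right: EhhCurve) -> float:
    """Trapezoidal integral of EHH over physical distance, both sides.

    Linear in distance: doubling all inter-SNP gaps doubles iHH.
    """
    if curve_left.core_index != curve_right.core_index:
        raise ValueError("curves must share the core SNP")
    total = 0.0
    for curve in (curve_left, curve_right):
        pts = curve.points
        for (p0, e0), (p1, e1) in zip(pts, pts[1:]):
            total += 0.5 * (e0 + e1) * abs(p1 - p0)
    return total


def _ihh_at(hapset: HaplotypeSet, core: int, cutoff: float, max_gap_bp: int) -> float:
    return ihh(
        ehh(hapset, core, "left", cutoff, max_gap_bp),
        ehh(hapset, core, "right", cutoff, max_gap_bp),
    )


def _ihh_rightward(
    H: np.ndarray,
    pos: np.ndarray,
    cores: np.ndarray,
    cutoff: float,
    max_gap_bp: int,
) -> np.ndarray:
    """Rightward iHH for many cores at once.

    For every haplotype pair, ``nxt[:, c]`` is the first index >= c where
    the pair differs, so the pair is identical over core..x iff nxt > x and
    EHH(c, x) is a suffix count over nxt.  EHH is non-increasing in x, so
    the cutoff truncation point comes straight from an order statistic.
    Exactly equivalent to walking ``ehh()`` core by core, just O(pairs)
    instead of O(pairs x extent) per core.
    """
    n, m = H.shape
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    agree = H[iu] == H[ju]
    dtype = np.int16 if m < 32000 else np.int32
    nxt = np.empty((n_pairs, m), dtype=dtype)
    last = np.full(n_pairs, m, dtype=dtype)
    for c in range(m - 1, -1, -1):
        last = np.where(agree[:, c], last, c).astype(dtype)
        nxt[:, c] = last

    big_gap_idx = np.flatnonzero(np.diff(pos) > max_gap_bp)
    t = max(1, int(np.ceil(cutoff * n_pairs)))
    out = np.zeros(cores.size)
    for k, c in enumerate(cores):
        vals = np.sort(nxt[:, c])
        x_cut = int(vals[n_pairs - t]) - 1 if cutoff > 0 else m - 1
        j = np.searchsorted(big_gap_idx, c)
        x_gap = int(big_gap_idx[j]) if j < big_gap_idx.size else m - 1
        x_stop = min(x_cut, x_gap, m - 1)
        if x_stop <= c:
            continue
        xs = np.arange(c + 1, x_stop + 1)
        ehh_vals = (n_pairs - np.searchsorted(vals, xs, side="right")) / n_pairs
        y = np.concatenate(([1.0], ehh_vals))
        out[k] = np.trapezoid(y, pos[c : x_stop + 1])
    return out


def _ihh_all(
    hapset: HaplotypeSet, cores: np.ndarray, cutoff: float, max_gap_bp: int
) -> np.ndarray:
    """Left + right iHH at every core index (vectorized fast path)."""
    H = hapset.haplotypes
    pos = hapset.positions().astype(np.int64)
    m = H.shape[1]
    right = _ihh_rightward(H, pos, cores, cutoff, max_gap_bp)
    left = _ihh_rightward(
        H[:, ::-1], -pos[::-1], (m - 1 - cores)[::-1], cutoff, max_gap_bp
    )[::-1]
    return right + left


def xpehh(
    hapset_a: HaplotypeSet,
    hapset_b: HaplotypeSet,
    maf_min: float = 0.05,
    max_gap_bp: int = MAX_GAP_BP,
    cutoff: float = EHH_CUTOFF,
) -> pd.DataFrame:
    """Per-SNP raw XP-EHH = ln(iHH_A / iHH_B) between two populations.

    Both haplotype sets must share the variant map.  A SNP is ``tested``
    when its MAF is >= maf_min in both populations and both iHH are
    positive; untested SNPs carry NaN raw scores.  Positive scores mean
    longer haplotype homozygosity in population A.

    Returns a DataFrame with columns variant_id, chrom, pos_bp, ihh_a,
    ihh_b, raw, tested (z / outlier are added by the standardization and
    flagging steps).
    """
    va, vb = hapset_a.variants, hapset_b.variants
    if len(va) != len(vb) or not (
        (va["id"].to_numpy() == vb["id"].to_numpy()).all()
        and (va["pos_bp"].to_numpy() == vb["pos_bp"].to_numpy()).all()
    ):
        raise ValueError("haplotype sets must share the variant map")

    fa = hapset_a.allele_freqs()
    fb = hapset_b.allele_freqs()
    maf_ok = (np.minimum(fa, 1 - fa) >= maf_min) & (np.minimum(fb, 1 - fb) >= maf_min)

    m = len(va)
    ihh_a = np.full(m, np.nan)
    ihh_b = np.full(m, np.nan)
    raw = np.full(m, np.nan)
    tested = np.zeros(m, dtype=bool)
    cores = np.flatnonzero(maf_ok)
    if cores.size:
        ia = _ihh_all(hapset_a, cores, cutoff, max_gap_bp)
        ib = _ihh_all(hapset_b, cores, cutoff, max_gap_bp)
        ihh_a[cores] = ia
        ihh_b[cores] = ib
        ok = (ia > 0) & (ib > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw[cores[ok]] = np.log(ia[ok] / ib[ok])
        tested[cores[ok]] = True
    return pd.DataFrame(
        {
            "variant_id": va["id"].to_numpy(),
            "chrom": va["chrom"].to_numpy(),
            "pos_bp": va["pos_bp"].to_numpy(),
            "ihh_a": ihh_a,
            "ihh_b": ihh_b,
            "raw": raw,
            "tested": tested,
        }
    )


def standardize_by_chrom(records: pd.DataFrame) -> pd.DataFrame:
    """Add z = (raw − mean_chrom) / sd_chrom over tested records, each
    chromosome separately (sample sd); untested records get NaN z."""
    out = records.copy()
    out["z"] = np.nan
    for chrom, sub in out.groupby("chrom", sort=False):
        sel = sub.index[sub["tested"]]
        if len(sel) < 2:
            raise ValueError(f"chromosome {chrom}: fewer than 2 tested records")
        vals = out.loc[sel, "raw"].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        # tolerance absorbs the rounding residue of identical raw scores
        if sd <= 1e-12 * (1.0 + np.abs(vals).max()):
            raise ValueError(f"chromosome {chrom}: zero variance in raw scores")
        out.loc[sel, "z"] = (vals - vals.mean()) / sd
    return out


def flag_outliers(
    records: pd.DataFrame,
    q_low: float = 0.05,
    q_high: float = 0.95,
    per_chrom: bool = False,
) -> pd.DataFrame:
    """Flag z-score outliers at the q_low / q_high quantiles.

    Thresholds are linear-interpolation quantiles of z over all tested
    records (genome-wide by default; ``per_chrom`` recomputes them per
    chromosome); comparison is inclusive (z <= low → "low", z >= high →
    "high").  If the two thresholds coincide (degenerate distribution)
    nothing is flagged.
    """
    out = records.copy()
    out["outlier"] = "none"

    def _flag(idx: pd.Index) -> None:
        z = out.loc[idx, "z"].to_numpy(dtype=float)
        lo = np.quantile(z, q_low)
        hi = np.quantile(z, q_high)
        if lo >= hi:
            return
        out.loc[idx[z <= lo], "outlier"] = "low"
        out.loc[idx[z >= hi], "outlier"] = "high"

    tested_idx = out.index[out["tested"] & out["z"].notna()]
    if per_chrom:
        for _, sub in out.loc[tested_idx].groupby("chrom", sort=False):
            _flag(sub.index)
    elif len(tested_idx):
        _flag(tested_idx)
    return out
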