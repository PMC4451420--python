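"""Forward Wright–Fisher simulator of phased multi-population SNP data.

Emulates the structure SNP-array population data has after ascertainment:
a fixed panel of standing variants (no new mutation), multiple populations
connected by splits and two-parent admixture, piecewise-constant effective
sizes, uniform recombination at 1 cM/Mb, and optional hard sweeps with
additive fitness confined to named populations.

Time is counted in generations before present: the simulation starts at
the deepest breakpoint/split and runs forward to generation 0, where each
population is sampled without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, HaplotypeSet


@dataclass
class PopulationSpec:
    """Demography of one population.

    ne_schedule: (generations-before-present, diploid Ne) breakpoints;
    the size applies from that time forward (toward the present) until the
    next, more recent, breakpoint.  A root population has no parents; one
    parent = a clean split; two parents = an admixed founding where each
    founding haplotype comes from ``parents[0]`` with probability
    ``admixture_fraction``.
    """

    name: str
    ne_schedule: list[tuple[int, int]]
    parents: list[str] = field(default_factory=list)
    admixture_fraction: float | None = None
    split_generation: int | None = None

    def __post_init__(self) -> None:
        if not self.ne_schedule:
            raise ValueError(f"{self.name}: ne_schedule must be non-empty")
        if any(ne < 2 for _, ne in self.ne_schedule):
            raise ValueError(f"{self.name}: Ne must be >= 2 everywhere")
        if len(self.parents) not in (0, 1, 2):
            raise ValueError(f"{self.name}: 0, 1 or 2 parents allowed")
        if len(self.parents) == 2:
            # 1.0 is allowed as the degenerate "all from parent A" boundary
            if self.admixture_fraction is None or not 0 < self.admixture_fraction <= 1:
                raise ValueError(
                    f"{self.name}: admixture_fraction in (0,1] required with 2 parents"
                )
        elif self.admixture_fraction is not None:
            raise ValueError(f"{self.name}: admixture_fraction only valid with 2 parents")
        if self.parents and self.split_generation is None:
            raise ValueError(f"{self.name}: split_generation required with parents")
        self.ne_schedule = sorted(self.ne_schedule, key=lambda t: -t[0])

    def ne_at(self, t: int) -> int:
        """Diploid size at t generations before present (piecewise constant)."""
        ne = self.ne_schedule[0][1]
        for g, n in self.ne_schedule:
            if g >= t:
                ne = n
            else:
                break
        return ne


@dataclass
class SweepSpec:
    """A hard sweep: additive fitness 1, 1+s, 1+2s at the focal variant,
    active from ``start_generation`` (before present) in ``target_populations``.

    ``initial_freq`` optionally pins the focal variant's frequency in the
    ancestral standing variation (otherwise it is drawn like any other).
    """

    chrom: str
    pos_bp: int
    s: float
    start_generation: int
    target_populations: list[str]
    initial_freq: float | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient s must be > 0")


@dataclass
class SimConfig:
    chrom_length_bp: int = 50_000_000
    n_variants: int = 2000
    recomb_rate: float = 1e-8  # Morgans per bp == 1 cM/Mb
    populations: list[PopulationSpec] = field(default_factory=list)
    sweeps: list[SweepSpec] = field(default_factory=list)
    sample_sizes: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    n_chromosomes: int = 1
    init_freq_low: float = 0.05  # array-ascertainment-like bound
    init_freq_high: float = 0.95
    resample_until_established: bool = False
    established_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")
        if not self.populations:
            raise ValueError("at least one population required")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        known = set(names)
        for p in self.populations:
            for par in p.parents:
                if par not in known:
                    raise ValueError(f"{p.name}: unknown parent {par!r}")
        for pop, n in self.sample_sizes.items():
            if pop not in known:
                raise ValueError(f"sample_sizes: unknown population {pop!r}")
            spec = next(p for p in self.populations if p.name == pop)
            if n > spec.ne_at(0):
                raise ValueError(
                    f"{pop}: cannot sample {n} diploids from final Ne {spec.ne_at(0)}"
                )

    @property
    def horizon(self) -> int:
        gens = [g for p in self.populations for g, _ in p.ne_schedule]
        gens += [p.split_generation for p in self.populations if p.split_generation]
        gens += [sw.start_generation for sw in self.sweeps]
        return max(gens)


@dataclass
class SimTruth:
    """What actually happened: sweep allele-frequency trajectories and
    per-sweep establishment outcome (final frequency >= established_freq
    in every target population)."""

    sweep_trajectories: pd.DataFrame  # generation, population, chrom, pos_bp, freq
    sweep_established: dict[tuple[str, int], bool]
    resamples_used: int = 0

    def to_tsv(self, path: str) -> None:
        self.sweep_trajectories.to_csv(path, sep="\t", index=False)


def expected_het_decay(ne: int, generations: int, h0: float) -> float:
    """Closed-form heterozygosity decay under drift: h0·(1 − 1/(2Ne))^g.

    The analytic oracle the simulator is tested against.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    return h0 * (1.0 - 1.0 / (2.0 * ne)) ** generations


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _make_gametes(
    H: np.ndarray,
    parent_idx: np.ndarray,
    gpos: np.ndarray,
    map_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of parent_idx, drawn from diploid parents in H.

    Crossover count per gamete is Poisson(map_length); crossover points are
    uniform on the genetic map; the starting haplotype is fair-coin.
    """
    n_g = parent_idx.size
    m = H.shape[1]
    ks = rng.poisson(map_length, n_g)
    starts = rng.integers(0, 2, n_g)
    out = np.empty((n_g, m), dtype=np.uint8)
    no_x = ks == 0
    out[no_x] = H[2 * parent_idx[no_x] + starts[no_x]]
    recomb = np.flatnonzero(~no_x)
    if recomb.size:
        # all crossovers of the generation at once: per gamete, the parity
        # at SNP j is (start + number of crossovers left of j) mod 2
        k_sub = ks[recomb]
        gid = np.repeat(np.arange(recomb.size), k_sub)
        xs = rng.uniform(0.0, map_length, int(k_sub.sum()))
        idx = np.searchsorted(gpos, xs, side="right")
        delta = np.bincount(
            gid * (m + 1) + idx, minlength=recomb.size * (m + 1)
        ).reshape(recomb.size, m + 1)
        cnt = np.cumsum(delta[:, :m], axis=1)
        parity = (cnt + starts[recomb, None]) & 1
        rows = 2 * parent_idx[recomb]
        out[recomb] = np.where(parity == 0, H[rows], H[rows + 1])
    return out


def _fitness_weights(H: np.ndarray, col: int, s: float) -> np.ndarray:
    gt = H[0::2, col].astype(np.float64) + H[1::2, col]
    w = 1.0 + s * gt
    return w / w.sum()


def _simulate_one_chromosome(
    config: SimConfig, chrom: str, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Run the forward process for one chromosome.

    Returns final (unsampled) pools per population, the variant table, and
    the focal-variant frequency trajectories.
    """
    L_bp = config.chrom_length_bp
    m = config.n_variants
    pos = np.sort(rng.choice(np.arange(1, L_bp + 1), size=m, replace=False))
    variants = pd.DataFrame(
        {
            "id": [f"{chrom}_snp{j}" for j in range(m)],
            "chrom": chrom,
            "pos_bp": pos.astype(np.int64),
            "allele_ref": "A",
            "allele_alt": "B",
        }
    )
    gpos = pos * config.recomb_rate  # Morgans
    map_length = L_bp * config.recomb_rate

    freqs = rng.uniform(config.init_freq_low, config.init_freq_high, m)
    sweep_cols: dict[int, SweepSpec] = {}
    for sw in config.sweeps:
        if sw.chrom != chrom:
            continue
        hits = np.flatnonzero(pos == sw.pos_bp)
        if hits.size == 0:
            # snap to the nearest simulated variant so the sweep always sits
            # on an existing column of the panel
            hits = np.array([int(np.argmin(np.abs(pos - sw.pos_bp)))])
        col = int(hits[0])
        sweep_cols[col] = sw
        if sw.initial_freq is not None:
            freqs[col] = sw.initial_freq

    specs = {p.name: p for p in config.populations}
    roots = [p for p in config.populations if not p.parents]
    horizon = config.horizon

    pools: dict[str, np.ndarray] = {}
    for p in roots:
        n0 = p.ne_at(horizon)
        pools[p.name] = (rng.random((2 * n0, m)) < freqs).astype(np.uint8)

    traj_rows: list[tuple[int, str, str, int, float]] = []

    def record(t: int) -> None:
        for col, sw in sweep_cols.items():
            for name, H in pools.items():
                traj_rows.append(
                    (t, name, chrom, int(pos[col]), float(H[:, col].mean()))
                )

    record(horizon)
    for t in range(horizon, 0, -1):
        # found any population whose split time is t (parents are the
        # generation alive at time t)
        for p in config.populations:
            if p.parents and p.split_generation == t and p.name not in pools:
                n_child = p.ne_at(t - 1)
                if len(p.parents) == 1:
                    src = pools[p.parents[0]]
                    par = rng.integers(0, src.shape[0] // 2, 2 * n_child)
                    pools[p.name] = _make_gametes(src, par, gpos, map_length, rng)
                else:
                    a, b = (pools[q] for q in p.parents)
                    from_a = rng.random(2 * n_child) < p.admixture_fraction
                    par_a = rng.integers(0, a.shape[0] // 2, 2 * n_child)
                    par_b = rng.integers(0, b.shape[0] // 2, 2 * n_child)
                    g_a = _make_gametes(a, par_a, gpos, map_length, rng)
                    g_b = _make_gametes(b, par_b, gpos, map_length, rng)
                    pools[p.name] = np.where(from_a[:, None], g_a, g_b)
        # one generation of reproduction in every extant population
        for name in list(pools):
            spec = specs[name]
            if spec.split_generation is not None and spec.split_generation == t:
                continue  # just founded this tick
            H = pools[name]
            n_next = spec.ne_at(t - 1)
            weights = None
            for col, sw in sweep_cols.items():
                if name in sw.target_populations and t <= sw.start_generation:
                    w = _fitness_weights(H, col, sw.s)
                    weights = w if weights is None else weights * w
            if weights is not None:
                weights = weights / weights.sum()
            n_par = H.shape[0] // 2
            if weights is None:
                par = rng.integers(0, n_par, 2 * n_next)
            else:
                par = rng.choice(n_par, size=2 * n_next, p=weights)
            pools[name] = _make_gametes(H, par, gpos, map_length, rng)
        record(t - 1)

    traj = pd.DataFrame(
        traj_rows, columns=["generation", "population", "chrom", "pos_bp", "freq"]
    )
    return pools, variants, traj


def _run_once(
    config: SimConfig, seed: int
) -> tuple[GenotypeDataset, dict[str, list[HaplotypeSet]], SimTruth]:
    rng = np.random.default_rng(seed)
    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]

    all_variants: list[pd.DataFrame] = []
    all_traj: list[pd.DataFrame] = []
    hapsets: dict[str, list[HaplotypeSet]] = {
        p: [] for p in config.sample_sizes
    }
    geno_blocks: dict[str, list[np.ndarray]] = {p: [] for p in config.sample_sizes}

    for chrom in chrom_names:
        pools, variants, traj = _simulate_one_chromosome(config, chrom, rng)
        all_traj.append(traj)
        for pop, n_samp in config.sample_sizes.items():
            H = pools[pop]
            pick = np.sort(rng.choice(H.shape[0] // 2, n_samp, replace=False))
            rows = np.empty(2 * n_samp, dtype=int)
            rows[0::2] = 2 * pick
            rows[1::2] = 2 * pick + 1
            sub = H[rows].copy()
            samples = [f"{pop}_{i}" for i in range(n_samp)]
            hapsets[pop].append(
                HaplotypeSet(variants=variants.copy(), samples=samples, haplotypes=sub)
            )
            geno_blocks[pop].append(
                (sub[0::2].astype(np.int16) + sub[1::2]).astype(np.int8)
            )
        all_variants.append(variants)

    variants_all = pd.concat(all_variants, ignore_index=True)
    samples_all: list[str] = []
    populations: dict[str, str] = {}
    call_rows: list[np.ndarray] = []
    for pop, n_samp in config.sample_sizes.items():
        block = np.hstack(geno_blocks[pop])
        for i in range(n_samp):
            sid = f"{pop}_{i}"
            samples_all.append(sid)
            populations[sid] = pop
        call_rows.append(block)
    ds = GenotypeDataset(
        variants=variants_all,
        samples=samples_all,
        populations=populations,
        calls=np.vstack(call_rows),
    )

    traj_all = pd.concat(all_traj, ignore_index=True) if all_traj else pd.DataFrame(
        columns=["generation", "population", "chrom", "pos_bp", "freq"]
    )
    established: dict[tuple[str, int], bool] = {}
    for sw in config.sweeps:
        final = traj_all[
            (traj_all["generation"] == 0)
            & traj_all["population"].isin(sw.target_populations)
        ]
        key_rows = final[final["chrom"] == sw.chrom]
        ok = bool(len(key_rows)) and bool(
            (key_rows["freq"] >= config.established_freq).all()
        )
        established[(sw.chrom, sw.pos_bp)] = ok
    truth = SimTruth(sweep_trajectories=traj_all, sweep_established=established)
    return ds, hapsets, truth


def simulate(
    config: SimConfig,
) -> tuple[GenotypeDataset, dict[str, list[HaplotypeSet]], SimTruth]:
    """Run the forward simulation.

    Returns the sampled GenotypeDataset (all populations, all chromosomes),
    per-population per-chromosome HaplotypeSets, and the truth record.
    Identical config (including seed) gives bit-identical output.  A lost
    sweep is reported in the truth record, not raised — unless
    ``resample_until_established`` is set, in which case the whole run is
    retried with derived seeds (capped at 50 attempts).
    """
    attempts = 50 if config.resample_until_established and config.sweeps else 1
    seed = int(config.seed)
    for k in range(attempts):
        ds, haps, truth = _run_once(config, (seed + 1_000_003 * k) % (2**31 - 1))
        truth.resamples_used = k
        if all(truth.sweep_established.values()) or k == attempts - 1:
            if attempts > 1 and not all(truth.sweep_established.values()):
                warnings.warn("sweep not established after resampling cap")
            return ds, haps, truth
    raise AssertionError("unreachable")


def config_from_dict(d: dict[str, Any]) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping."""
    pops = [
        PopulationSpec(
            name=p["name"],
            ne_schedule=[tuple(x) for x in p["ne_schedule"]],
            parents=list(p.get("parents", [])),
            admixture_fraction=p.get("admixture_fraction"),
            split_generation=p.get("split_generation"),
        )
        for p in d["populations"]
    ]
    sweeps = [
        SweepSpec(
            chrom=str(s["chrom"]),
            pos_bp=int(s["pos_bp"]),
            s=float(s["s"]),
            start_generation=int(s["start_generation"]),
            target_populations=list(s["target_populations"]),
            initial_freq=s.get("initial_freq"),
        )
        for s in d.get("sweeps", [])
    ]
    return SimConfig(
        chrom_length_bp=int(d.get("chrom_length_bp", 50_000_000)),
        n_variants=int(d.get("n_variants", 2000)),
        recomb_rate=float(d.get("recomb_rate", 1e-8)),
        populations=pops,
        sweeps=sweeps,
        sample_sizes={k: int(v) for k, v in d.get("sample_sizes", {}).items()},
        seed=int(d.get("seed", 0)),
        n_chromosomes=int(d.get("n_chromosomes", 1)),
        init_freq_low=float(d.get("init_freq_low", 0.05)),
        init_freq_high=float(d.get("init_freq_high", 0.95)),
        resample_until_established=bool(d.get("resample_until_established", False)),
        established_freq=float(d.get("established_freq", 0.5)),
    )
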