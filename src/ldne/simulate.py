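"""Synthetic closed-herd generator with a known true effective size.

Three stages mirror the data-generating process the estimators assume:

1. :func:`simulate_base_population` — discrete Wright–Fisher reproduction of
   ``base_ne`` diploids with per-chromosome recombination and recurrent
   biallelic mutation, run long enough (default ``4 * base_ne`` generations)
   for drift–recombination linkage disequilibrium to equilibrate.  Because the
   burn-in is an explicit census-``base_ne`` population, the true Ne is known
   exactly and parameter recovery can be scored against it.
2. :func:`breeding_schedule` — an overlapping-generation herd: founders enter
   in year 0 and each subsequent year a small set of breeding males and
   females drawn from ages 1–5 produces the next cohort, with matings between
   animals sharing a parent or grandparent excluded.
3. :func:`gene_drop` — Mendelian transmission of founder haplotypes down the
   fixed pedigree, with Poisson crossover counts and uniform crossover
   placement (no interference), matching the Morgan/Mb conversion used by the
   LD-based estimator.

All stages are driven by one integer seed and are fully deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HaplotypePool, MarkerMap
from .pedigree_ne import Pedigree

logger = logging.getLogger(__name__)

BREEDING_AGES = (1, 2, 3, 4, 5)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic herd.

    Rates are Morgans per Mb (scalar, or one value per chromosome).  The
    mutation rate is per locus per gamete per generation; the default 2.5e-4
    keeps the population-scaled rate small (4 Ne mu = 0.05 at the default
    base_ne), so recurrent mutation maintains segregating candidates without
    visibly depressing linkage disequilibrium — the fitted mutation intercept
    of the equilibrium LD curve stays in the 1-2.5 range mutation theory
    predicts.  Marker loci are ascertained at ``ascertainment_maf`` (default
    0.05), emulating the common-variant bias of SNP genotyping chips; set it
    to 0 to keep every segregating locus.
    """

    n_founder_males: int = 4
    n_founder_females: int = 20
    n_years: int = 30
    target_generation_interval: float = 3.0
    litter_mean: float = 0.86  # offspring per mated female per year
    breeding_age_weights: tuple[float, ...] = (0.10, 0.25, 0.35, 0.20, 0.10)
    n_breeding_males: int = 4
    n_breeding_females: int = 20
    n_chromosomes: int = 6
    chromosome_length_mb: float = 100.0
    n_snps_per_chromosome: int = 200
    recomb_rate: float | tuple[float, ...] = 0.0076
    base_ne: int = 25
    burn_in_generations: int | None = None  # default 4 * base_ne
    mutation_rate: float = 2.5e-4
    candidate_factor: float = 10.0
    ascertainment_maf: float = 0.05
    genotyped_last_generations: int | None = None
    missing_rate: float = 0.0
    founding_year: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_founder_males": self.n_founder_males,
            "n_founder_females": self.n_founder_females,
            "n_breeding_males": self.n_breeding_males,
            "n_breeding_females": self.n_breeding_females,
            "n_chromosomes": self.n_chromosomes,
            "n_snps_per_chromosome": self.n_snps_per_chromosome,
            "base_ne": self.base_ne,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_years < 0:
            raise ValueError("n_years must be >= 0")
        for r in self.recomb_rates():
            if r < 0:
                raise ValueError("recombination rates must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.ascertainment_maf < 0.5:
            raise ValueError("ascertainment_maf must be in [0, 0.5)")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if len(self.breeding_age_weights) != len(BREEDING_AGES):
            raise ValueError(f"breeding_age_weights needs {len(BREEDING_AGES)} entries")

    def recomb_rates(self) -> tuple[float, ...]:
        r = self.recomb_rate
        if np.isscalar(r):
            return tuple(float(r) for _ in range(self.n_chromosomes))
        r = tuple(float(x) for x in r)
        if len(r) != self.n_chromosomes:
            raise ValueError("need one recombination rate per chromosome")
        return r

    @property
    def resolved_burn_in(self) -> int:
        return (
            self.burn_in_generations
            if self.burn_in_generations is not None
            else 4 * self.base_ne
        )

    @property
    def chromosome_names(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]

    @property
    def chromosome_length_bp(self) -> int:
        return int(round(self.chromosome_length_mb * 1e6))


def guadyerbas_preset(**overrides) -> SimulationConfig:
    """Closed Iberian-pig-herd-like configuration.

    24 founders (4 males, 20 females), 67 years of overlapping generations
    (~26 generations at a ~3-year generation interval), 18 autosomes, high LD
    from a small founder population (burn-in census 25), genotypes restricted
    to the last 6 generations.  Litter mean is calibrated so the pedigree
    totals ~1,180 animals.
    """
    cfg = SimulationConfig(
        n_founder_males=4,
        n_founder_females=20,
        n_years=67,
        target_generation_interval=3.0,
        litter_mean=0.86,
        n_breeding_males=4,
        n_breeding_females=20,
        n_chromosomes=18,
        chromosome_length_mb=130.0,
        n_snps_per_chromosome=200,
        recomb_rate=0.0076,
        base_ne=25,
        genotyped_last_generations=6,
        founding_year=1944,
        seed=0,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# Wright–Fisher burn-in
# ---------------------------------------------------------------------------

def _recombine(hap_a: np.ndarray, hap_b: np.ndarray, pos_bp: np.ndarray,
               length_morgans: float, length_bp: int, rng) -> np.ndarray:
    """One recombinant gamete from a pair of haplotypes.

    Crossover count ~ Poisson(length_morgans), positions uniform on the
    chromosome, no interference; the starting strand is fair.
    """
    n_x = rng.poisson(length_morgans)
    start = rng.integers(2)
    if n_x == 0:
        return (hap_a if start == 0 else hap_b).copy()
    cuts = np.sort(rng.integers(1, length_bp + 1, size=n_x))
    strand = (start + np.searchsorted(cuts, pos_bp, side="left")) % 2
    return np.where(strand == 0, hap_a, hap_b).astype(np.uint8)


def _wf_generation(state: list[np.ndarray], positions: list[np.ndarray],
                   lengths_m: list[float], length_bp: int,
                   mu: float, rng) -> list[np.ndarray]:
    """One discrete Wright-Fisher generation (monoecious random mating)."""
    n = state[0].shape[0] // 2
    parents = rng.integers(n, size=(n, 2))
    out = []
    for chrom, (haps, pos, lm) in enumerate(zip(state, positions, lengths_m)):
        new = np.empty_like(haps)
        for i in range(n):
            for k in (0, 1):
                p = parents[i, k]
                new[2 * i + k] = _recombine(
                    haps[2 * p], haps[2 * p + 1], pos, lm, length_bp, rng
                )
        if mu > 0:
            flips = rng.random(new.shape) < mu
            new ^= flips.astype(np.uint8)
        out.append(new)
    return out


def _init_state(config: SimulationConfig, rng) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Candidate loci and starting haplotypes (alleles drawn at p = 0.5)."""
    n_cand = int(math.ceil(config.candidate_factor * config.n_snps_per_chromosome))
    positions, state = [], []
    for _ in range(config.n_chromosomes):
        pos = np.sort(rng.choice(config.chromosome_length_bp, size=n_cand, replace=False)) + 1
        positions.append(pos.astype(np.int64))
        state.append(
            (rng.random((2 * config.base_ne, n_cand)) < 0.5).astype(np.uint8)
        )
    return state, positions


def _run_burn_in(config: SimulationConfig, rng) -> tuple[list[np.ndarray], list[np.ndarray]]:
    state, positions = _init_state(config, rng)
    lengths_m = [config.chromosome_length_mb * r for r in config.recomb_rates()]
    mu = config.mutation_rate
    for _ in range(config.resolved_burn_in):
        state = _wf_generation(
            state, positions, lengths_m, config.chromosome_length_bp, mu, rng
        )
    return state, positions


def _prune_to_segregating(state, positions, config) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Keep n_snps_per_chromosome chip-like loci (MAF >= ascertainment_maf)."""
    want = config.n_snps_per_chromosome
    maf = config.ascertainment_maf
    out_h, out_p = [], []
    for chrom, (haps, pos) in enumerate(zip(state, positions)):
        freq = haps.mean(axis=0)
        seg = np.flatnonzero((freq > max(0.0, maf - 1e-12)) & (freq < 1 - maf + 1e-12)) if maf > 0 else np.flatnonzero((freq > 0) & (freq < 1))
        if seg.size < want:
            raise SimulationError(
                f"chromosome {chrom + 1}: only {seg.size} of the required "
                f"{want} loci pass MAF >= {maf} after burn-in "
                f"(shortfall {want - seg.size}); raise candidate_factor or "
                "the mutation rate"
            )
        if seg.size > want:
            # evenly thin across the chromosome to preserve the density
            keep = seg[np.linspace(0, seg.size - 1, want).round().astype(int)]
            logger.info(
                "chromosome %d: thinned %d segregating loci to %d",
                chrom + 1, seg.size, want,
            )
        else:
            keep = seg
        out_h.append(haps[:, keep])
        out_p.append(pos[keep])
    return out_h, out_p


def simulate_base_population(config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> HaplotypePool:
    """Equilibrium founder haplotypes from an explicit Wright-Fisher burn-in.

    Returns ``2 * base_ne`` haplotypes per chromosome.  Loci fixed at the end
    of the burn-in are dropped; if fewer than ``n_snps_per_chromosome``
    segregate, a :class:`SimulationError` names the shortfall.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state, positions = _run_burn_in(config, rng)
    haps, pos = _prune_to_segregating(state, positions, config)
    return HaplotypePool(list(config.chromosome_names), haps, pos)


def wright_fisher_cohorts(
    config: SimulationConfig,
    n_individuals: int,
    n_replicates: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenotypeMatrix], MarkerMap]:
    """Replicate cohorts from consecutive generations of a constant-Ne population.

    After the burn-in the Wright-Fisher population is advanced
    ``n_replicates`` further generations; at each one, ``n_individuals``
    diploids are sampled and genotyped at the loci still segregating across
    the whole window.  This is the discrete-generation analogue of treating
    consecutive cohorts of a herd as temporal replicates.
    """
    if n_individuals > config.base_ne:
        raise ValueError("cannot sample more individuals than the census size")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state, positions = _run_burn_in(config, rng)
    lengths_m = [config.chromosome_length_mb * r for r in config.recomb_rates()]
    mu = config.mutation_rate
    snapshots = []
    for _ in range(n_replicates):
        state = _wf_generation(
            state, positions, lengths_m, config.chromosome_length_bp, mu, rng
        )
        snapshots.append([h.copy() for h in state])
    # loci kept: ascertained on the pooled window (chip-style common-SNP
    # selection from a discovery panel), thinned per chromosome
    pooled = [np.vstack([snap[c] for snap in snapshots]) for c in range(config.n_chromosomes)]
    maf = config.ascertainment_maf
    keep: list[np.ndarray] = []
    for c, hp in enumerate(pooled):
        freq = hp.mean(axis=0)
        if maf > 0:
            seg = np.flatnonzero((freq >= maf - 1e-12) & (freq <= 1 - maf + 1e-12))
        else:
            seg = np.flatnonzero((freq > 0) & (freq < 1))
        want = config.n_snps_per_chromosome
        if seg.size < want:
            raise SimulationError(
                f"chromosome {c + 1}: only {seg.size} of {want} loci pass "
                f"MAF >= {maf} across the replicate window (shortfall {want - seg.size})"
            )
        keep.append(seg[np.linspace(0, seg.size - 1, want).round().astype(int)])
    rows = []
    for c in range(config.n_chromosomes):
        for p in positions[c][keep[c]]:
            rows.append((f"snp_{c + 1}_{p}", str(c + 1), int(p)))
    marker_map = MarkerMap(pd.DataFrame(rows, columns=["locus", "chrom", "pos"]))
    cohorts = []
    for rep, snap in enumerate(snapshots):
        pick = rng.choice(config.base_ne, size=n_individuals, replace=False)
        per_chrom = []
        for c in range(config.n_chromosomes):
            h = snap[c][:, keep[c]]
            per_chrom.append(h[2 * pick] + h[2 * pick + 1])
        G = np.hstack(per_chrom).astype(np.int8)
        samples = [f"rep{rep}_ind{i}" for i in range(n_individuals)]
        cohorts.append(GenotypeMatrix(G, samples, list(marker_map.loci)))
    return cohorts, marker_map


# ---------------------------------------------------------------------------
# Overlapping-generation breeding schedule
# ---------------------------------------------------------------------------

def breeding_schedule(config: SimulationConfig,
                      seed: int | np.random.Generator | None = None) -> Pedigree:
    """Pedigree of a closed herd with overlapping generations.

    Each year ``n_breeding_males``/``n_breeding_females`` breeders are drawn
    from animals aged 1-5 (age-weighted), each selected female is mated to a
    selected male that does not share a parent or grandparent with her, and
    litter sizes are Poisson(``litter_mean``).  Founders are born in
    ``founding_year`` with unknown parents.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    y0 = config.founding_year
    records: list[tuple[str, str, str, str, int]] = []
    ancestry: dict[str, set[str]] = {}  # id -> {parents, grandparents}
    sex_of: dict[str, str] = {}
    born: dict[str, int] = {}
    counter = 0

    parents_of: dict[str, set[str]] = {}

    def add(sire: str, dam: str, sex: str, year: int) -> str:
        nonlocal counter
        counter += 1
        iid = str(counter)
        records.append((iid, sire, dam, sex, year))
        parents = {p for p in (sire, dam) if p != "0"}
        grandparents = set().union(*(parents_of[p] for p in parents)) if parents else set()
        ancestry[iid] = parents | grandparents
        parents_of[iid] = parents
        sex_of[iid] = sex
        born[iid] = year
        return iid
    for _ in range(config.n_founder_males):
        add("0", "0", "M", y0)
    for _ in range(config.n_founder_females):
        add("0", "0", "F", y0)

    ages = np.asarray(BREEDING_AGES)
    w = np.asarray(config.breeding_age_weights, dtype=float)
    w = w / w.sum()

    def select(candidates: list[str], k: int, year: int) -> list[str]:
        if not candidates:
            return []
        cw = np.array([w[year - born[c] - 1] for c in candidates])
        if cw.sum() == 0:
            cw = np.ones(len(candidates))
        cw = cw / cw.sum()
        k = min(k, len(candidates))
        return list(rng.choice(candidates, size=k, replace=False, p=cw))

    for year in range(y0 + 1, y0 + config.n_years + 1):
        males = [i for i in born if sex_of[i] == "M" and 1 <= year - born[i] <= 5]
        females = [i for i in born if sex_of[i] == "F" and 1 <= year - born[i] <= 5]
        sires = select(males, config.n_breeding_males, year)
        dams = select(females, config.n_breeding_females, year)
        matings = []
        for dam in dams:
            ok = [
                s for s in sires
                if not (ancestry[dam] & (ancestry[s] | {s}))
                and not (ancestry[s] & {dam})
            ]
            if ok:
                matings.append((dam, str(rng.choice(ok))))
        if not matings and (sires or dams):
            raise SimulationError(
                f"year {year}: no eligible mating pair among {len(sires)} "
                f"sires and {len(dams)} dams (bottleneck too severe)"
            )
        for dam, sire in matings:
            for _ in range(rng.poisson(config.litter_mean)):
                add(sire, dam, "M" if rng.random() < 0.5 else "F", year)

    return Pedigree(
        pd.DataFrame(records, columns=["id", "sire", "dam", "sex", "birth_year"])
    )


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def gene_drop(
    pedigree: Pedigree,
    founder_pool: HaplotypePool,
    recomb_rates: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    genotyped_ids=None,
    missing_rate: float = 0.0,
    chromosome_length_bp: int | None = None,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Drop founder haplotypes down the pedigree with recombination.

    Each founder receives two pool haplotypes without replacement (with
    replacement plus a warning if the pool is too small); every non-founder
    receives one recombinant gamete per parent.  Returns 0/1/2 genotype
    counts for ``genotyped_ids`` (default: everyone) plus the marker map.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(0 if seed is None else seed)
    )
    chroms = founder_pool.chromosomes
    if recomb_rates is None:
        recomb_rates = {c: 0.0076 for c in chroms}
    missing = [c for c in chroms if c not in recomb_rates]
    if missing:
        raise ValueError(f"no recombination rate for chromosomes {missing}")
    length_bp = chromosome_length_bp or int(max(p[-1] for p in founder_pool.positions))
    lengths_m = {c: (length_bp / 1e6) * recomb_rates[c] for c in chroms}

    ids = pedigree.ids
    sire_idx, dam_idx = pedigree.parent_indices()
    founder_rows = np.flatnonzero((sire_idx < 0) & (dam_idx < 0))
    n_pool = founder_pool.n_haplotypes
    need = 2 * founder_rows.size
    if need > n_pool:
        logger.warning(
            "founder pool has %d haplotypes for %d founder copies; resampling "
            "with replacement", n_pool, need,
        )
        assign = rng.integers(n_pool, size=need)
    else:
        assign = rng.permutation(n_pool)[:need]

    n = len(ids)
    haps = [np.zeros((2 * n, p.size), dtype=np.uint8) for p in founder_pool.positions]
    for k, row in enumerate(founder_rows):
        for c in range(len(chroms)):
            haps[c][2 * row] = founder_pool.haplotypes[c][assign[2 * k]]
            haps[c][2 * row + 1] = founder_pool.haplotypes[c][assign[2 * k + 1]]

    for row in range(n):
        si, di = sire_idx[row], dam_idx[row]
        if si < 0 and di < 0:
            continue
        if si < 0 or di < 0:
            raise SimulationError(f"individual {ids[row]} has exactly one known parent")
        if si >= row or di >= row:
            raise SimulationError("pedigree order violation: parent after offspring")
        for c, chrom in enumerate(chroms):
            pos = founder_pool.positions[c]
            haps[c][2 * row] = _recombine(
                haps[c][2 * si], haps[c][2 * si + 1], pos,
                lengths_m[chrom], length_bp, rng,
            )
            haps[c][2 * row + 1] = _recombine(
                haps[c][2 * di], haps[c][2 * di + 1], pos,
                lengths_m[chrom], length_bp, rng,
            )

    if genotyped_ids is None:
        rows = np.arange(n)
    else:
        rows = pedigree.index_of([str(i) for i in genotyped_ids])
    per_chrom = [h[2 * rows] + h[2 * rows + 1] for h in haps]
    G = np.hstack(per_chrom).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(G.shape) < missing_rate
        G[mask] = -1
    marker_map = founder_pool.marker_map()
    return GenotypeMatrix(G, [ids[r] for r in rows], list(marker_map.loci)), marker_map


def genotyped_window_ids(pedigree: Pedigree, generation_of: pd.Series,
                         last_k: int) -> list[str]:
    """Ids belonging to the ``last_k`` most recent generation indices."""
    gens = sorted(generation_of.unique())
    window = set(gens[-last_k:])
    return [i for i in pedigree.ids if generation_of.loc[i] in window]
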