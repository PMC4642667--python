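"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a SNP pair are maximum-likelihood estimates under
random mating obtained by EM on the 3x3 genotype table: only double
heterozygotes are phase-ambiguous, and the E-step splits them between the
coupling (AB/ab) and repulsion (Ab/aB) configurations in proportion to
``p_AB p_ab : p_Ab p_aB``.  LD is then the squared allelic correlation

    r^2 = D^2 / (p_A p_a p_B p_b),   D = p_AB - p_A p_B.

A vectorised EM over many pair tables at once backs the genome-scale paths
(:func:`pairwise_ld`, :func:`nonsyntenic_background`); the scalar
:func:`em_haplotype_freqs` is the reference implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFreqs:
    """EM haplotype frequencies for one SNP pair (alleles A/a and B/b)."""

    p_ab_coupling: float  # p_AB
    p_Ab: float
    p_aB: float
    p_ab: float  # p_ab (repulsion complement)
    n_used: int
    n_iter: int
    converged: bool

    @property
    def p_AB(self) -> float:
        return self.p_ab_coupling

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


class MonomorphicLocusError(ValueError):
    """r^2 is undefined when either locus is monomorphic in the joint sample."""


def allele_frequencies(genotypes: np.ndarray) -> tuple[float, float]:
    """(p_A, p_a) from a vector of 0/1/2 allele counts; missing = -1 ignored."""
    g = np.asarray(genotypes)
    used = g != MISSING
    n = int(used.sum())
    if n == 0:
        raise ValueError("all genotypes missing at locus")
    p = float(g[used].sum()) / (2.0 * n)
    return p, 1.0 - p


def pair_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 genotype count table over jointly non-missing individuals."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    used = (g1 != MISSING) & (g2 != MISSING)
    code = g1[used].astype(np.int64) * 3 + g2[used].astype(np.int64)
    return np.bincount(code, minlength=9).reshape(3, 3)


# Known haplotype counts contributed by each genotype cell (A-allele locus 1,
# B-allele locus 2).  Cell (i, j) = i copies of A, j copies of B; every cell
# except the double heterozygote (1, 1) has a unique phase resolution.
#   order: AB, Ab, aB, ab
_CELL_HAPS = np.zeros((3, 3, 4))
for _i in range(3):
    for _j in range(3):
        if (_i, _j) == (1, 1):
            continue  # ambiguous, handled by the E-step
        # locus-1 gametes carry A with multiplicity _i, locus-2 carry B with
        # multiplicity _j; with at most one heterozygous locus the pairing is
        # forced (index: 0=AB, 1=Ab, 2=aB, 3=ab).
        a_gam = [1] * _i + [0] * (2 - _i)
        b_gam = [1] * _j + [0] * (2 - _j)
        for ga, gb in zip(a_gam, b_gam):
            _CELL_HAPS[_i, _j, (1 - ga) * 2 + (1 - gb)] += 1


def _em_tables(tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Vectorised EM over P genotype tables of shape (P, 3, 3).

    Returns (freqs (P, 4) in order AB, Ab, aB, ab; n_iter (P,); converged (P,)).
    Initialisation is linkage equilibrium p_AB = p_A p_B, so the degenerate
    all-double-heterozygote table stays at the symmetric fixed point (r^2 = 0).
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    P = tables.shape[0]
    n = tables.sum(axis=(1, 2))
    if np.any(n == 0):
        raise ValueError("empty genotype table")
    two_n = 2.0 * n
    # fixed haplotype counts from unambiguous cells
    fixed = np.einsum("pij,ijk->pk", tables, _CELL_HAPS)
    n_dh = tables[:, 1, 1]
    # observed allele frequencies (margins are phase-invariant)
    p_a1 = tables.sum(axis=2) @ np.array([0.0, 1.0, 2.0]) / two_n  # p_A
    p_b1 = tables.sum(axis=1) @ np.array([0.0, 1.0, 2.0]) / two_n  # p_B
    f = np.stack(
        [p_a1 * p_b1, p_a1 * (1 - p_b1), (1 - p_a1) * p_b1, (1 - p_a1) * (1 - p_b1)],
        axis=1,
    )
    n_iter = np.zeros(P, dtype=np.int64)
    converged = np.zeros(P, dtype=bool)
    active = np.ones(P, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        fa = f[idx]
        coup = fa[:, 0] * fa[:, 3]
        rep = fa[:, 1] * fa[:, 2]
        tot = coup + rep
        w = np.where(tot > 0, np.divide(coup, tot, out=np.full_like(tot, 0.5), where=tot > 0), 0.5)
        counts = fixed[idx].copy()
        counts[:, 0] += n_dh[idx] * w
        counts[:, 3] += n_dh[idx] * w
        counts[:, 1] += n_dh[idx] * (1 - w)
        counts[:, 2] += n_dh[idx] * (1 - w)
        new = counts / two_n[idx, None]
        delta = np.abs(new - fa).max(axis=1)
        f[idx] = new
        n_iter[idx] = it
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    return f, n_iter, converged


def table_loglik(table: np.ndarray, p_ab_coupling: float) -> float:
    """Observed-data multinomial log-likelihood of a 3x3 table given p_AB.

    Margins (p_A, p_B) are taken from the table itself — they are determined
    by the single-locus counts whatever the phase.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_A = (table.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    p_B = (table.sum(axis=0) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    return float(_loglik_grid(table, p_A, p_B, np.array([p_ab_coupling]))[0])


def _loglik_grid(table, p_A, p_B, p_ab_vals):
    """Log-likelihood at each candidate p_AB (margins fixed). Vectorised."""
    p_ab_vals = np.asarray(p_ab_vals, dtype=float)
    pAB = p_ab_vals
    pAb = p_A - pAB
    paB = p_B - pAB
    pab = 1.0 - p_A - p_B + pAB
    h = np.stack([pAB, pAb, paB, pab], axis=1).clip(min=0.0)
    # genotype-cell probabilities under random union of gametes
    cell = np.empty((p_ab_vals.size, 3, 3))
    cell[:, 2, 2] = h[:, 0] ** 2
    cell[:, 2, 1] = 2 * h[:, 0] * h[:, 1]
    cell[:, 2, 0] = h[:, 1] ** 2
    cell[:, 1, 2] = 2 * h[:, 0] * h[:, 2]
    cell[:, 1, 1] = 2 * (h[:, 0] * h[:, 3] + h[:, 1] * h[:, 2])
    cell[:, 1, 0] = 2 * h[:, 1] * h[:, 3]
    cell[:, 0, 2] = h[:, 2] ** 2
    cell[:, 0, 1] = 2 * h[:, 2] * h[:, 3]
    cell[:, 0, 0] = h[:, 3] ** 2
    tab = np.asarray(table, dtype=float)
    mask = tab > 0
    with np.errstate(divide="ignore"):
        lp = np.where(cell[:, mask] > 0, np.log(cell[:, mask].clip(min=1e-300)), -np.inf)
    return (lp * tab[mask]).sum(axis=1)


def grid_search_p_ab(table: np.ndarray, step: float = 1e-6) -> float:
    """Independent likelihood maximiser over p_AB by grid search.

    Scans the feasible interval [max(0, p_A + p_B - 1), min(p_A, p_B)] at a
    coarse 1e-4 step, then refines around every coarse local maximum at
    ``step``.  Used as an oracle against the EM path.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_A = (table.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    p_B = (table.sum(axis=0) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    lo = max(0.0, p_A + p_B - 1.0)
    hi = min(p_A, p_B)
    if hi - lo < step:
        return 0.5 * (lo + hi)
    coarse_step = max(step, 1e-4)
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step).clip(lo, hi)
    ll = _loglik_grid(table, p_A, p_B, grid)
    # refine around every coarse local maximum (likelihood may be multimodal)
    peaks = [int(np.argmax(ll))]
    for k in range(1, len(ll) - 1):
        if ll[k] >= ll[k - 1] and ll[k] >= ll[k + 1]:
            peaks.append(k)
    best_p, best_ll = None, -np.inf
    for k in set(peaks):
        a = max(lo, grid[k] - 2 * coarse_step)
        b = min(hi, grid[k] + 2 * coarse_step)
        fine = np.arange(a, b + step / 2, step).clip(lo, hi)
        fll = _loglik_grid(table, p_A, p_B, fine)
        j = int(np.argmax(fll))
        if fll[j] > best_ll:
            best_ll, best_p = float(fll[j]), float(fine[j])
    return best_p


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeFreqs:
    """ML haplotype frequencies for one SNP pair from unphased genotypes."""
    table = pair_table(g1, g2)
    n = int(table.sum())
    if n == 0:
        raise ValueError("no jointly non-missing individuals")
    p_A = float(table.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    p_B = float(table.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise MonomorphicLocusError("monomorphic locus in the joint sample")
    f, n_iter, conv = _em_tables(table[None], tol=tol, max_iter=max_iter)
    if not conv[0]:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return HaplotypeFreqs(
        p_ab_coupling=float(f[0, 0]),
        p_Ab=float(f[0, 1]),
        p_aB=float(f[0, 2]),
        p_ab=float(f[0, 3]),
        n_used=n,
        n_iter=int(n_iter[0]),
        converged=bool(conv[0]),
    )


def r2_from_freqs(freqs: HaplotypeFreqs | np.ndarray) -> float:
    """r^2 = D^2 / (p_A p_a p_B p_b) with D = p_AB - p_A p_B."""
    h = freqs.as_array() if isinstance(freqs, HaplotypeFreqs) else np.asarray(freqs)
    p_A = h[0] + h[1]
    p_B = h[0] + h[2]
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    if denom <= 0:
        raise MonomorphicLocusError("allele frequency at 0 or 1: r^2 undefined")
    d = h[0] - p_A * p_B
    r2 = d * d / denom
    if r2 > 1.0 + 1e-9:
        raise ValueError(f"r^2 = {r2} exceeds 1 beyond floating error")
    return float(min(max(r2, 0.0), 1.0))


def syntenic_pairs(marker_map: MarkerMap, max_distance_bp: int) -> pd.DataFrame:
    """All within-chromosome locus-index pairs with 0 < distance <= max.

    Returns a DataFrame with columns i, j (column indices into the map/matrix,
    i < j), chrom, distance_bp.
    """
    out = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.indices_for_chrom(chrom)
        pos = marker_map.pos[idx]
        # upper bound per left locus via searchsorted on sorted positions
        hi = np.searchsorted(pos, pos + max_distance_bp, side="right")
        for a in range(len(idx)):
            for b in range(a + 1, hi[a]):
                out.append((idx[a], idx[b], chrom, int(pos[b] - pos[a])))
    return pd.DataFrame(out, columns=["i", "j", "chrom", "distance_bp"])


def _ld_for_pairs(
    genotypes: GenotypeMatrix, pairs_i: np.ndarray, pairs_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised r^2 for arbitrary locus-index pairs.

    Returns (r2, n_used, valid, freqs): ``valid`` is False where a locus is
    monomorphic in the joint sample (those pairs are to be skipped).
    """
    G = genotypes.genotypes
    P = len(pairs_i)
    if P == 0:
        empty = np.array([])
        return empty, empty.astype(int), empty.astype(bool), np.empty((0, 4))
    tables = np.zeros((P, 9), dtype=np.int64)
    # batch over pairs to bound memory at ~P*n ints per batch
    batch = max(1, int(5e7) // max(1, genotypes.n_samples))
    for s in range(0, P, batch):
        e = min(P, s + batch)
        g1 = G[:, pairs_i[s:e]].T  # (b, n)
        g2 = G[:, pairs_j[s:e]].T
        used = (g1 != MISSING) & (g2 != MISSING)
        code = g1 * 3 + g2
        offs = np.arange(e - s)[:, None] * 9
        flat = np.where(used, code + offs, -1).ravel()
        flat = flat[flat >= 0]
        tables[s:e] = np.bincount(flat, minlength=(e - s) * 9).reshape(e - s, 9)
    tables = tables.reshape(P, 3, 3)
    n_used = tables.sum(axis=(1, 2))
    two_n = 2.0 * np.maximum(n_used, 1)
    p_A = tables.sum(axis=2) @ np.array([0.0, 1.0, 2.0]) / two_n
    p_B = tables.sum(axis=1) @ np.array([0.0, 1.0, 2.0]) / two_n
    valid = (n_used > 0) & (p_A > 0) & (p_A < 1) & (p_B > 0) & (p_B < 1)
    freqs = np.full((P, 4), np.nan)
    r2 = np.full(P, np.nan)
    if valid.any():
        f, _, conv = _em_tables(tables[valid])
        if not conv.all():
            logger.warning("EM non-convergence on %d pairs", int((~conv).sum()))
        d = f[:, 0] - (f[:, 0] + f[:, 1]) * (f[:, 0] + f[:, 2])
        denom = (
            (f[:, 0] + f[:, 1])
            * (f[:, 2] + f[:, 3])
            * (f[:, 0] + f[:, 2])
            * (f[:, 1] + f[:, 3])
        )
        r2v = (d * d / denom).clip(0.0, 1.0)
        freqs[valid] = f
        r2[valid] = r2v
    return r2, n_used, valid, freqs


def pairwise_ld(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    max_distance_bp: int,
    min_distance_bp: int = 0,
) -> pd.DataFrame:
    """r^2 for every syntenic pair within (min, max] distance.

    Pairs with a monomorphic locus among jointly non-missing individuals are
    skipped (and counted in the log).  Columns: locus1, locus2, chrom,
    distance_bp, r2, n_used.
    """
    if list(marker_map.loci) != list(genotypes.loci):
        raise ValueError("genotypes and marker map do not share loci")
    pairs = syntenic_pairs(marker_map, max_distance_bp)
    if min_distance_bp > 0:
        pairs = pairs[pairs["distance_bp"] > min_distance_bp].reset_index(drop=True)
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    r2, n_used, valid, _ = _ld_for_pairs(genotypes, i, j)
    n_skip = int((~valid).sum()) if len(valid) else 0
    if n_skip:
        logger.info("skipped %d pairs with a monomorphic locus", n_skip)
    loci = np.asarray(genotypes.loci)
    out = pd.DataFrame(
        {
            "locus1": loci[i],
            "locus2": loci[j],
            "chrom": pairs["chrom"].to_numpy(),
            "distance_bp": pairs["distance_bp"].to_numpy(),
            "r2": r2,
            "n_used": n_used,
        }
    )
    return out[valid].reset_index(drop=True) if len(valid) else out


def nonsyntenic_background(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    per_chromosome: int = 30,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, int]:
    """Background LD from random non-syntenic SNP pairs.

    Selects ``per_chromosome`` polymorphic loci per chromosome uniformly at
    random and computes r^2 for all between-chromosome pairs; returns
    (mean r^2, SD, pair count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = genotypes.genotypes
    chosen: list[np.ndarray] = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.indices_for_chrom(chrom)
        poly = []
        for k in idx:
            g = G[:, k]
            used = g != MISSING
            if used.any():
                s = g[used].sum()
                if 0 < s < 2 * used.sum():
                    poly.append(k)
        if len(poly) < per_chromosome:
            raise ValueError(
                f"chromosome {chrom} has only {len(poly)} polymorphic loci; "
                f"{per_chromosome} required"
            )
        chosen.append(rng.choice(np.asarray(poly), size=per_chromosome, replace=False))
    sel = np.concatenate(chosen)
    sel_chrom = np.repeat(np.arange(len(chosen)), per_chromosome)
    ii, jj = np.triu_indices(len(sel), k=1)
    between = sel_chrom[ii] != sel_chrom[jj]
    pi, pj = sel[ii[between]], sel[jj[between]]
    r2, _, valid, _ = _ld_for_pairs(genotypes, pi, pj)
    r2 = r2[valid]
    return float(np.mean(r2)), float(np.std(r2, ddof=1)), int(between.sum())


DEFAULT_BIN_SCHEME: list[tuple[float, float, float]] = [
    (0.0, 2.0, 0.05),
    (2.0, 5.0, 0.20),
    (5.0, 50.0, 5.00),
]


def bin_ld(
    ld_records: pd.DataFrame,
    scheme: list[tuple[float, float, float]] = DEFAULT_BIN_SCHEME,
) -> pd.DataFrame:
    """Distance-binned LD summary (mean r^2, count, 5th/95th percentiles).

    ``scheme`` is an ordered list of (range_start_mb, range_stop_mb, width_mb)
    with non-overlapping ranges; bins are left-closed right-open.  Empty bins
    are reported with count 0 and NaN statistics.
    """
    edges_list = []
    prev_stop = None
    for start, stop, width in scheme:
        if prev_stop is not None and start < prev_stop:
            raise ValueError("bin scheme ranges overlap")
        prev_stop = stop
        n_bins = int(np.ceil((stop - start) / width - 1e-12))
        for k in range(n_bins):
            lo = start + k * width
            hi = min(start + (k + 1) * width, stop)
            edges_list.append((lo, hi))
    d_mb = ld_records["distance_bp"].to_numpy() / 1e6
    r2 = ld_records["r2"].to_numpy()
    rows = []
    for lo, hi in edges_list:
        m = (d_mb >= lo) & (d_mb < hi)
        cnt = int(m.sum())
        if cnt:
            vals = r2[m]
            rows.append(
                (lo, hi, cnt, float(vals.mean()),
                 float(np.percentile(vals, 5)), float(np.percentile(vals, 95)))
            )
        else:
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["bin_lo_mb", "bin_hi_mb", "n_pairs", "mean_r2", "p5", "p95"]
    )


def segregating_filter(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    max_locus_missing: float = 0.04,
    max_sample_missing: float = 0.04,
) -> tuple[GenotypeMatrix, MarkerMap | None]:
    """Drop non-segregating (MAF = 0) loci and high-missingness loci/samples.

    Sample filtering runs first (mirroring a per-sample call-rate cut), then
    per-locus missingness, then the MAF = 0 cut on the retained samples.
    """
    G = genotypes.genotypes
    miss = G == MISSING
    keep_s = miss.mean(axis=1) <= max_sample_missing
    G2 = G[keep_s]
    miss2 = G2 == MISSING
    keep_missing = miss2.mean(axis=0) <= max_locus_missing
    n_used = (~miss2).sum(axis=0)
    s = np.where(miss2, 0, G2).sum(axis=0)
    seg = (n_used > 0) & (s > 0) & (s < 2 * n_used)
    keep_l = keep_missing & seg
    out = genotypes.subset_samples(keep_s).subset_loci(keep_l)
    out_map = marker_map.subset(keep_l) if marker_map is not None else None
    logger.info(
        "segregating_filter: kept %d/%d samples, %d/%d loci",
        out.n_samples, genotypes.n_samples, out.n_loci, genotypes.n_loci,
    )
    return out, out_map
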