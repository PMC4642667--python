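"""Two-locus EM, r², pair enumeration, binning and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldne import ld_engine as le
from ldne.containers import MISSING

from conftest import make_genotypes


def random_genotype_pair(rng, n):
    """Two genotype vectors drawn from random haplotype frequencies."""
    pA, pB = rng.uniform(0.15, 0.85, 2)
    lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
    pab = rng.uniform(lo, hi)
    h = np.array([pab, pA - pab, pB - pab, 1 - pA - pB + pab]).clip(min=0)
    haps = rng.choice(4, size=(n, 2), p=h / h.sum())
    g1 = (haps < 2).sum(axis=1)  # haplotypes 0 (AB), 1 (Ab) carry A
    g2 = ((haps == 0) | (haps == 2)).sum(axis=1)  # 0 (AB), 2 (aB) carry B
    return g1, g2


def test_allele_frequencies():
    assert le.allele_frequencies([2, 2, 2]) == (1.0, 0.0)
    assert le.allele_frequencies([0, 1, 2]) == (0.5, 0.5)
    # missing entries excluded from the denominator
    p, q = le.allele_frequencies([2, 1, 0, 1, MISSING])
    assert p == 0.5 and q == 0.5
    with pytest.raises(ValueError):
        le.allele_frequencies([MISSING, MISSING])


def test_em_without_double_heterozygotes_is_gamete_counting():
    # genotypes (2,1): haplotypes AB + Ab; (0,0): ab + ab; etc.
    g1 = np.array([2, 2, 0, 0])
    g2 = np.array([1, 2, 0, 1])
    f = le.em_haplotype_freqs(g1, g2)
    assert f.n_iter <= 2
    # direct count: AB x3, Ab x1, ab x3, aB x1 over 8 gametes
    np.testing.assert_allclose(f.as_array(), [3 / 8, 1 / 8, 1 / 8, 3 / 8], atol=1e-12)


def test_em_all_double_heterozygotes_stays_symmetric():
    g = np.ones(10, dtype=int)
    f = le.em_haplotype_freqs(g, g)
    np.testing.assert_allclose(f.as_array(), [0.25] * 4, atol=1e-12)
    assert le.r2_from_freqs(f) == 0.0


def test_em_matches_grid_search_on_coupling_table():
    # {(2,2): 4, (1,1): 4, (0,0): 4}: near-complete coupling LD
    g1 = np.array([2] * 4 + [1] * 4 + [0] * 4)
    g2 = np.array([2] * 4 + [1] * 4 + [0] * 4)
    f = le.em_haplotype_freqs(g1, g2)
    p_grid = le.grid_search_p_ab(le.pair_table(g1, g2))
    assert abs(f.p_AB - p_grid) < 1e-4
    assert le.r2_from_freqs(f) > 0.9


@pytest.mark.parametrize("seed", range(8))
def test_em_matches_grid_search_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(5):
        g1, g2 = random_genotype_pair(rng, int(rng.integers(10, 50)))
        try:
            f = le.em_haplotype_freqs(g1, g2)
        except le.MonomorphicLocusError:
            continue
        if f.n_iter <= 1 or not f.converged:
            continue  # symmetric fixed point or flagged boundary case
        p_grid = le.grid_search_p_ab(le.pair_table(g1, g2))
        assert abs(f.p_AB - p_grid) < 1e-4


def test_em_loglik_nondecreasing():
    rng = np.random.default_rng(42)
    for _ in range(10):
        g1, g2 = random_genotype_pair(rng, 30)
        table = le.pair_table(g1, g2)
        pA = table.sum(axis=1) @ np.array([0, 1, 2]) / (2 * table.sum())
        pB = table.sum(axis=0) @ np.array([0, 1, 2]) / (2 * table.sum())
        if pA in (0, 1) or pB in (0, 1):
            continue
        # re-run EM step by step and track the observed-data log-likelihood
        lls = []
        f = None
        for it in range(1, 60):
            f, n_iter, conv = le._em_tables(table, max_iter=it)
            lls.append(le.table_loglik(table, f[0, 0]))
            if conv[0]:
                break
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_r2_hand_arithmetic():
    # complete LD
    f = le.HaplotypeFreqs(0.5, 0.0, 0.0, 0.5, 10, 1, True)
    assert le.r2_from_freqs(f) == pytest.approx(1.0)
    # equilibrium
    f = le.HaplotypeFreqs(0.25, 0.25, 0.25, 0.25, 10, 1, True)
    assert le.r2_from_freqs(f) == 0.0
    # p_A=0.6, p_B=0.5, p_AB=0.35 -> D=0.05, r2=0.05^2/(0.6*0.4*0.5*0.5)
    f = le.HaplotypeFreqs(0.35, 0.25, 0.15, 0.25, 10, 1, True)
    assert le.r2_from_freqs(f) == pytest.approx(0.05 ** 2 / 0.06, rel=1e-12)


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_r2_symmetry_under_swaps_and_relabels(seed):
    """Swapping loci or flipping allele labels leaves r² unchanged."""
    rng = np.random.default_rng(seed)
    g1, g2 = random_genotype_pair(rng, 25)
    try:
        base = le.r2_from_freqs(le.em_haplotype_freqs(g1, g2))
    except le.MonomorphicLocusError:
        return
    swapped = le.r2_from_freqs(le.em_haplotype_freqs(g2, g1))
    flipped = le.r2_from_freqs(le.em_haplotype_freqs(2 - g1, g2))
    assert swapped == pytest.approx(base, abs=1e-6)
    assert flipped == pytest.approx(base, abs=1e-6)


def test_vectorised_em_agrees_with_scalar():
    rng = np.random.default_rng(9)
    pairs = [random_genotype_pair(rng, 30) for _ in range(20)]
    tables = np.stack([le.pair_table(a, b) for a, b in pairs])
    keep = []
    for t in tables:
        pA = t.sum(axis=1) @ np.array([0, 1, 2]) / (2 * t.sum())
        pB = t.sum(axis=0) @ np.array([0, 1, 2]) / (2 * t.sum())
        keep.append(0 < pA < 1 and 0 < pB < 1)
    tables = tables[np.array(keep)]
    f_vec, _, _ = le._em_tables(tables)
    for t, fv in zip(tables, f_vec):
        g1 = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], t.ravel())
        g2 = np.repeat([0, 1, 2, 0, 1, 2, 0, 1, 2], t.ravel())
        fs = le.em_haplotype_freqs(g1, g2)
        np.testing.assert_allclose(fv, fs.as_array(), atol=1e-10)


def test_syntenic_pairs_oracle():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(40_000_000, size=100, replace=False)) + 1
    _, mm = make_genotypes(np.zeros((2, 100)), positions=list(pos))
    got = le.syntenic_pairs(mm, 15_000_000)
    # brute-force double loop
    expected = {
        (i, j)
        for i in range(100)
        for j in range(i + 1, 100)
        if 0 < pos[j] - pos[i] <= 15_000_000
    }
    assert set(zip(got["i"], got["j"])) == expected
    assert le.syntenic_pairs(mm, 0).empty


def test_pairwise_ld_duplicate_locus_r2_one():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, size=40)
    G = np.stack([col, col], axis=1)
    gm, mm = make_genotypes(G, positions=[1000, 1001])
    ld = le.pairwise_ld(gm, mm, 10_000)
    assert len(ld) == 1
    assert ld["r2"].iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_independent_loci_mean_r2_near_sampling_floor():
    """For unlinked loci, mean EM r² sits near the 1/n sampling level."""
    rng = np.random.default_rng(7)
    n = 100
    n_pairs = 1200
    r2s = []
    for _ in range(n_pairs):
        p, q = rng.uniform(0.2, 0.8, 2)
        g1 = rng.binomial(2, p, size=n)
        g2 = rng.binomial(2, q, size=n)
        try:
            r2s.append(le.r2_from_freqs(le.em_haplotype_freqs(g1, g2)))
        except le.MonomorphicLocusError:
            pass
    mean = np.mean(r2s)
    assert 0.3 / n < mean < 3.0 / n


def test_nonsyntenic_background_pair_counts():
    # 2 chromosomes x 2 polymorphic SNPs -> 4 between-chromosome pairs
    rng = np.random.default_rng(2)
    G = rng.integers(0, 3, size=(30, 4))
    gm, mm = make_genotypes(G, chroms=["1", "1", "2", "2"],
                            positions=[1000, 2000, 1000, 2000])
    mean, sd, count = le.nonsyntenic_background(gm, mm, per_chromosome=2, seed=0)
    assert count == 4
    assert 0 <= mean <= 1 and sd >= 0
    with pytest.raises(ValueError, match="polymorphic"):
        le.nonsyntenic_background(gm, mm, per_chromosome=5, seed=0)


def test_default_bin_scheme_counts_and_edges():
    records = pd.DataFrame(
        {"distance_bp": [10_000, 50_000, 1_999_999, 2_000_000, 5_000_000],
         "r2": [0.5, 0.4, 0.3, 0.2, 0.1]}
    )
    bins = le.bin_ld(records)
    assert len(bins) == 40 + 15 + 9  # 0.05-Mb, 0.2-Mb and 5-Mb bins
    # right-open rule: 50 kb starts the second bin; 2 Mb starts the 2-5 range
    first = bins.iloc[0]
    assert first["n_pairs"] == 1 and first["mean_r2"] == 0.5
    assert bins.iloc[1]["n_pairs"] == 1
    assert bins.iloc[39]["n_pairs"] == 1  # 1.999999 Mb in [1.95, 2.0)
    assert bins.iloc[40]["n_pairs"] == 1  # exactly 2 Mb in [2.0, 2.2)
    assert bins.iloc[55]["n_pairs"] == 1  # exactly 5 Mb in [5, 10)
    # empty bins are reported with count 0 and undefined mean
    assert (bins["n_pairs"] == 0).sum() == 64 - 5
    assert bins.loc[bins["n_pairs"] == 0, "mean_r2"].isna().all()


def test_bin_assignment_matches_bruteforce_at_edges():
    rng = np.random.default_rng(4)
    d = np.concatenate([rng.uniform(0, 50e6, 200),
                        np.array([0.05e6, 2e6, 5e6, 49.999999e6])])
    records = pd.DataFrame({"distance_bp": d, "r2": rng.uniform(0, 1, d.size)})
    bins = le.bin_ld(records)
    total = bins["n_pairs"].sum()
    in_range = ((d / 1e6 >= 0) & (d / 1e6 < 50)).sum()
    assert total == in_range
    for rec in bins.itertuples():
        m = (d / 1e6 >= rec.bin_lo_mb) & (d / 1e6 < rec.bin_hi_mb)
        assert rec.n_pairs == m.sum()


def test_segregating_filter_planted_truth():
    rng = np.random.default_rng(11)
    G = rng.integers(0, 3, size=(20, 10))
    G[:, 3] = 2  # monomorphic
    G[:, 7] = 0  # monomorphic
    G[:, 5] = 1  # one heterozygote column stays polymorphic
    gm, mm = make_genotypes(G)
    out, out_map = le.segregating_filter(gm, mm)
    assert set(out.loci) == set(gm.loci) - {"l3", "l7"}
    # a locus with a single heterozygote is retained
    assert "l5" in out.loci
    # high-missingness locus removed
    G2 = G.copy()
    G2[:10, 0] = MISSING
    gm2, mm2 = make_genotypes(G2)
    out2, _ = le.segregating_filter(gm2, mm2, max_locus_missing=0.04,
                                    max_sample_missing=1.0)
    assert "l0" not in out2.loci
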