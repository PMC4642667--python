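import numpy as np
import pandas as pd
import pytest

from ldne.containers import GenotypeMatrix, MarkerMap
from ldne.pedigree_ne import Pedigree


def make_pedigree(rows):
    """Pedigree from (id, sire, dam, sex, birth_year) tuples."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year"])
    )


@pytest.fixture
def trio_pedigree():
    return make_pedigree(
        [
            ("s", 0, 0, "M", 0),
            ("d", 0, 0, "F", 0),
            ("j", "s", "d", "M", 1),
        ]
    )


@pytest.fixture
def founder_only_pedigree():
    rows = [(f"f{i}", 0, 0, "M" if i < 4 else "F", 0) for i in range(24)]
    return make_pedigree(rows)


def random_pedigree(rng, n=30, n_founders=6, n_years=6):
    """Random valid pedigree: founders in year 0, later animals get random
    earlier-born parents of the right sex (or unknown with small probability)."""
    rows = []
    males, females = [], []
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        rows.append((f"i{i}", 0, 0, sex, 0))
        (males if sex == "M" else females).append((f"i{i}", 0))
    for i in range(n_founders, n):
        year = int(rng.integers(1, n_years + 1))
        elig_m = [m for m, y in males if y < year]
        elig_f = [f for f, y in females if y < year]
        sire = rng.choice(elig_m) if elig_m and rng.random() > 0.1 else 0
        dam = rng.choice(elig_f) if elig_f and rng.random() > 0.1 else 0
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((f"i{i}", sire, dam, sex, year))
        (males if sex == "M" else females).append((f"i{i}", year))
    return make_pedigree(rows)


def make_genotypes(G, chroms=None, positions=None):
    """GenotypeMatrix + MarkerMap from a raw array (one chromosome default)."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    if chroms is None:
        chroms = ["1"] * m
    if positions is None:
        positions = []
        seen = {}
        for c in chroms:
            seen[c] = seen.get(c, 0) + 1
            positions.append(seen[c] * 1000)
    loci = [f"l{k}" for k in range(m)]
    gm = GenotypeMatrix(G, [f"s{i}" for i in range(n)], loci)
    mm = MarkerMap(
        pd.DataFrame({"locus": loci, "chrom": chroms, "pos": positions})
    )
    return gm, mm
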