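"""Pedigree-based effective population size from long-term genetic contributions.

The benchmark track of the analysis: for a closed herd with a complete
genealogy, the long-term genetic contribution ``c_i`` of ancestor *i* is its
ultimate proportional contribution to a distant reference cohort.  The rate of
inbreeding per generation is ``dF = (sum c_i^2) / 4`` taken over the members of
one generation, and the effective size at that generation is
``Ne = 2 / (sum c_i^2)`` (equivalently ``Ne = 1 / (2 dF)``).

The generation interval *L* is the gene-turnover time: the span of birth years
over which the contributions of entering ancestors sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = 0  # parent code for "unknown" in pedigree files

_SEX_CODES = {"M": "M", "F": "F", "U": "U", "1": "M", "2": "F", "0": "U"}


@dataclass
class Pedigree:
    """Validated directed-acyclic pedigree with birth years.

    ``records`` holds one row per individual with columns
    ``id, sire, dam, sex, birth_year``; parent value ``0`` means unknown.
    Rows are stored sorted by (birth_year, id), which is a topological order
    because parents are required to be born strictly before their offspring.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["id", "sire", "dam", "sex", "birth_year"]
        if list(self.records.columns[:5]) != req:
            missing = set(req) - set(self.records.columns)
            if missing:
                raise ValueError(f"pedigree missing columns {sorted(missing)}")
            self.records = self.records[req]
        t = self.records.copy()
        for col in ("id", "sire", "dam"):
            t[col] = t[col].astype(str)
        t["sex"] = [_SEX_CODES.get(str(s).upper(), "U") for s in t["sex"]]
        t["birth_year"] = t["birth_year"].astype(int)
        dup = t["id"].duplicated()
        if dup.any():
            raise ValueError(f"duplicated id {t.loc[dup, 'id'].iloc[0]!r}")
        if (t["id"] == str(UNKNOWN)).any():
            raise ValueError("id 0 is reserved for unknown parents")
        t = t.sort_values(["birth_year", "id"], kind="stable").reset_index(drop=True)
        year = dict(zip(t["id"], t["birth_year"]))
        sex = dict(zip(t["id"], t["sex"]))
        for _, row in t.iterrows():
            for which, parent in (("sire", row["sire"]), ("dam", row["dam"])):
                if parent == str(UNKNOWN):
                    continue
                if parent == row["id"]:
                    raise ValueError(f"cycle: {row['id']!r} is its own {which}")
                if parent not in year:
                    raise ValueError(f"{which} {parent!r} of {row['id']!r} not in pedigree")
                if year[parent] >= row["birth_year"]:
                    raise ValueError(
                        f"{which} {parent!r} (born {year[parent]}) not older than "
                        f"offspring {row['id']!r} (born {row['birth_year']})"
                    )
                expected = "M" if which == "sire" else "F"
                if sex[parent] not in (expected, "U"):
                    raise ValueError(
                        f"{which} {parent!r} of {row['id']!r} has sex {sex[parent]}"
                    )
        self.records = t
        self._index = {i: k for k, i in enumerate(t["id"])}

    # -- accessors ---------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy()

    @property
    def birth_years(self) -> np.ndarray:
        return self.records["birth_year"].to_numpy()

    @property
    def founding_year(self) -> int:
        return int(self.records["birth_year"].min())

    def __len__(self) -> int:
        return len(self.records)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per individual (-1 where unknown)."""
        sire = np.array(
            [self._index.get(s, -1) for s in self.records["sire"]], dtype=np.int64
        )
        dam = np.array(
            [self._index.get(d, -1) for d in self.records["dam"]], dtype=np.int64
        )
        return sire, dam

    def index_of(self, ids) -> np.ndarray:
        out = []
        for i in ids:
            i = str(i)
            if i not in self._index:
                raise KeyError(f"id {i!r} not in pedigree")
            out.append(self._index[i])
        return np.asarray(out, dtype=np.int64)

    def founders(self) -> np.ndarray:
        """Ids of individuals with both parents unknown."""
        m = (self.records["sire"] == str(UNKNOWN)) & (self.records["dam"] == str(UNKNOWN))
        return self.records.loc[m, "id"].to_numpy()

    def latest_cohort(self) -> np.ndarray:
        """Ids born in the most recent birth year."""
        last = self.records["birth_year"].max()
        return self.records.loc[self.records["birth_year"] == last, "id"].to_numpy()


@dataclass
class ContributionVector:
    """Long-term genetic contributions of every pedigree member to a cohort."""

    pedigree: Pedigree
    reference_cohort: list[str]
    contributions: pd.Series  # index = id, value = c_i

    @property
    def n_reference(self) -> int:
        return len(self.reference_cohort)

    def for_ids(self, ids) -> np.ndarray:
        return self.contributions.loc[[str(i) for i in ids]].to_numpy()


@dataclass
class PedigreeNeSeries:
    """Per-generation rate of inbreeding and effective size.

    ``table`` columns: generation, n_individuals, sum_c2, delta_f, ne
    (``ne`` is NaN where all contributions in the generation are zero).
    """

    table: pd.DataFrame


def read_pedigree(path) -> Pedigree:
    """Read a comma/whitespace-delimited pedigree file with a header.

    Expected columns ``id,sire,dam,sex,birth_year``; parent 0 = unknown.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree(df)


def genetic_contributions(pedigree: Pedigree, reference_cohort) -> pd.DataFrame:
    """Expected gene-flow fraction g(ancestor, cohort member).

    Implements the recursion g(a, a) = 1 and
    g(a, j) = 1/2 g(a, sire(j)) + 1/2 g(a, dam(j)), with 0 through unknown
    parents.  Returns a DataFrame indexed by ancestor id with one column per
    cohort member.  Computed per cohort member by a reverse sweep in
    topological order, so cost is O(|cohort| * |pedigree|).
    """
    cohort = [str(i) for i in reference_cohort]
    if not cohort:
        raise ValueError("reference cohort is empty")
    n = len(pedigree)
    cohort_idx = pedigree.index_of(cohort)
    sire, dam = pedigree.parent_indices()
    out = np.zeros((n, len(cohort)))
    for k, j in enumerate(cohort_idx):
        v = out[:, k]
        v[j] = 1.0
        # rows are sorted topologically; walk descendants-to-ancestors
        for row in range(j, -1, -1):
            w = v[row]
            if w == 0.0:
                continue
            if sire[row] >= 0:
                v[sire[row]] += 0.5 * w
            if dam[row] >= 0:
                v[dam[row]] += 0.5 * w
    return pd.DataFrame(out, index=pd.Index(pedigree.ids, name="ancestor"), columns=cohort)


def long_term_contributions(pedigree: Pedigree, reference_cohort=None) -> ContributionVector:
    """Long-term contribution c_i = mean over the cohort of g(i, j).

    ``reference_cohort`` defaults to the most recent birth-year cohort.
    A single reverse topological sweep accumulates the cohort-summed gene
    flow for every ancestor at once.
    """
    if reference_cohort is None:
        reference_cohort = pedigree.latest_cohort()
    cohort = [str(i) for i in reference_cohort]
    if not cohort:
        raise ValueError("reference cohort is empty")
    cohort_idx = pedigree.index_of(cohort)
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    w = np.zeros(n)
    w[cohort_idx] += 1.0
    for row in range(n - 1, -1, -1):
        if w[row] == 0.0:
            continue
        if sire[row] >= 0:
            w[sire[row]] += 0.5 * w[row]
        if dam[row] >= 0:
            w[dam[row]] += 0.5 * w[row]
    c = pd.Series(w / len(cohort), index=pd.Index(pedigree.ids, name="id"))
    return ContributionVector(pedigree, cohort, c)


def ne_from_contributions(
    contrib: ContributionVector, generation_of: dict[str, int] | pd.Series
) -> PedigreeNeSeries:
    """Per-generation dF = (sum c_i^2)/4 and Ne = 2/(sum c_i^2).

    ``generation_of`` maps every pedigree id to a generation index (see
    :func:`partition_generations`).  Generations whose members all have zero
    contribution get ``ne = NaN`` (undefined, not infinite).
    """
    gen = pd.Series(generation_of)
    gen.index = gen.index.astype(str)
    c = contrib.contributions
    missing = set(c.index) - set(gen.index)
    if missing:
        raise ValueError(f"{len(missing)} ids missing a generation assignment")
    rows = []
    for g, ids in c.groupby(gen.reindex(c.index)).groups.items():
        cg = c.loc[ids]
        s2 = float(np.sum(cg.to_numpy() ** 2))
        delta_f = s2 / 4.0
        ne = 2.0 / s2 if s2 > 0 else math.nan
        rows.append((int(g), len(ids), s2, delta_f, ne))
    table = pd.DataFrame(
        rows, columns=["generation", "n_individuals", "sum_c2", "delta_f", "ne"]
    ).sort_values("generation").reset_index(drop=True)
    return PedigreeNeSeries(table)


def generation_interval(contrib: ContributionVector) -> float:
    """Generation interval L: mean time for entering contributions to sum to 1.

    For each start year *y* the smallest window width *w* (whole years,
    linearly interpolated within the final year) is found such that the
    contributions of individuals born in [y, y + w) sum to at least one; L is
    the mean of *w* over start years with a feasible window.
    """
    years = contrib.pedigree.birth_years
    c = contrib.contributions.to_numpy()
    per_year = pd.Series(c).groupby(pd.Series(years)).sum()
    year_grid = np.arange(per_year.index.min(), per_year.index.max() + 1)
    yearly = per_year.reindex(year_grid, fill_value=0.0).to_numpy()
    total = yearly.sum()
    if total < 1.0 - 1e-9:
        raise ValueError(
            f"total long-term contribution {total:.6f} < 1; "
            "pedigree and reference cohort are inconsistent"
        )
    widths = []
    for start in range(len(yearly)):
        cum = np.cumsum(yearly[start:])
        hit = np.flatnonzero(cum >= 1.0)
        if hit.size == 0:
            continue
        k = int(hit[0])  # window covers k+1 whole years
        before = cum[k - 1] if k > 0 else 0.0
        frac = (1.0 - before) / yearly[start + k] if yearly[start + k] > 0 else 1.0
        widths.append(k + frac)
    if not widths:
        raise ValueError("no feasible start year for the unit-contribution window")
    return float(np.mean(widths))


def partition_generations(pedigree: Pedigree, L: float) -> pd.Series:
    """Assign each id a generation index from birth-year blocks of width round(L).

    generation = floor((birth_year - founding_year) / round(L)); founders are
    generation 0.  Well-defined under overlapping generations, where pedigree
    depth is ambiguous.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    width = max(1, int(round(L)))
    idx = (pedigree.birth_years - pedigree.founding_year) // width
    return pd.Series(idx.astype(int), index=pd.Index(pedigree.ids, name="id"))
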