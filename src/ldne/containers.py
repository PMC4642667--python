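"""Shared in-memory containers: genotype matrices and marker maps.

Genotypes are stored as diploid allele counts (0/1/2) with ``-1`` marking a
missing call, one row per individual and one column per locus.  Marker
positions are 1-based base pairs, the VCF convention, and are kept sorted by
(chromosome, position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class MarkerMap:
    """Locus id -> (chromosome, 1-based bp position), sorted within chromosome.

    Parameters
    ----------
    table:
        DataFrame with columns ``locus`` (str), ``chrom`` (str), ``pos`` (int).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locus", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        t = self.table.reset_index(drop=True).copy()
        t["locus"] = t["locus"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["pos"] = t["pos"].astype(np.int64)
        if (t["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        for chrom, grp in t.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        if t["locus"].duplicated().any():
            dup = t.loc[t["locus"].duplicated(), "locus"].iloc[0]
            raise ValueError(f"duplicate locus id {dup!r}")
        self.table = t

    @property
    def loci(self) -> np.ndarray:
        return self.table["locus"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.table["chrom"]))

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def indices_for_chrom(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == str(chrom))


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of diploid allele counts with missing = -1."""

    genotypes: np.ndarray
    samples: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        if g.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype shape {g.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        legal = np.isin(g, (MISSING, 0, 1, 2))
        if not legal.all():
            bad = np.argwhere(~legal)[0]
            raise ValueError(
                f"illegal genotype value {g[tuple(bad)]} at "
                f"sample {self.samples[bad[0]]}, locus {self.loci[bad[1]]}"
            )
        self.genotypes = g
        self.samples = [str(s) for s in self.samples]
        self.loci = [str(l) for l in self.loci]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.genotypes[:, idx], list(self.samples), [self.loci[i] for i in idx]
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.genotypes[idx, :], [self.samples[i] for i in idx], list(self.loci)
        )


@dataclass
class HaplotypePool:
    """Binary founder haplotypes per chromosome plus marker positions.

    ``haplotypes[c]`` is a (2 * n_individuals) x n_loci 0/1 matrix for
    chromosome ``chromosomes[c]``; ``positions[c]`` the matching strictly
    increasing 1-based bp coordinates.
    """

    chromosomes: list[str]
    haplotypes: list[np.ndarray]
    positions: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.chromosomes) == len(self.haplotypes) == len(self.positions)):
            raise ValueError("per-chromosome lists must have equal length")
        n_hap = None
        for c, (h, p) in enumerate(zip(self.haplotypes, self.positions)):
            h = np.asarray(h, dtype=np.uint8)
            p = np.asarray(p, dtype=np.int64)
            if h.ndim != 2 or h.shape[1] != p.shape[0]:
                raise ValueError(f"haplotype/position shape mismatch on chrom index {c}")
            if not np.isin(h, (0, 1)).all():
                raise ValueError("haplotype entries must be 0/1")
            if p.size and not np.all(np.diff(p) > 0):
                raise ValueError("positions must be strictly increasing")
            if n_hap is None:
                n_hap = h.shape[0]
            elif h.shape[0] != n_hap:
                raise ValueError("all chromosomes must carry the same haplotype count")
            self.haplotypes[c] = h
            self.positions[c] = p

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes[0].shape[0] if self.haplotypes else 0

    @property
    def n_loci(self) -> int:
        return int(sum(p.size for p in self.positions))

    def marker_map(self) -> MarkerMap:
        rows = []
        for chrom, pos in zip(self.chromosomes, self.positions):
            for p in pos:
                rows.append((f"snp_{chrom}_{p}", chrom, int(p)))
        return MarkerMap(pd.DataFrame(rows, columns=["locus", "chrom", "pos"]))
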