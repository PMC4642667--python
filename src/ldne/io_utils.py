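"""File formats, Mendelian-consistency checks and pipeline orchestration.

Genotypes travel as VCF (unphased GT, one contig per chromosome) or a
PLINK-style ``.ped``/``.map`` text dialect (alleles written ``A``/``B``,
missing ``0``); pedigrees as comma-delimited text with header
``id,sire,dam,sex,birth_year`` (0 = unknown parent).  Coordinates are 1-based
bp throughout, the VCF convention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerMap
from . import ld_engine, ne_from_ld, pedigree_ne as pne, simulate as sim

logger = logging.getLogger(__name__)

LOCUS_INCONSISTENCY_THRESHOLD = 9  # loci with more are dropped


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: pne.Pedigree, path) -> None:
    pedigree.records.to_csv(path, index=False)


def write_vcf(genotypes: GenotypeMatrix, marker_map: MarkerMap, path,
              chromosome_length_bp: int | None = None) -> None:
    """Minimal unphased biallelic VCF (REF=A, ALT=G)."""
    path = Path(path)
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldne\n")
        for chrom in marker_map.chromosomes:
            idx = marker_map.indices_for_chrom(chrom)
            length = chromosome_length_bp or int(marker_map.pos[idx].max())
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        G = genotypes.genotypes
        for k in range(len(marker_map)):
            gts = "\t".join(code[int(g)] for g in G[:, k])
            fh.write(
                f"{marker_map.chrom[k]}\t{marker_map.pos[k]}\t{marker_map.loci[k]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_plink(genotypes: GenotypeMatrix, marker_map: MarkerMap, prefix) -> None:
    """PLINK-style text dialect: ``.map`` + ``.ped`` with alleles A/B."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for k in range(len(marker_map)):
            fh.write(
                f"{marker_map.chrom[k]}\t{marker_map.loci[k]}\t0\t{marker_map.pos[k]}\n"
            )
    allele_pairs = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        G = genotypes.genotypes
        for i, s in enumerate(genotypes.samples):
            row = " ".join(allele_pairs[int(g)] for g in G[i])
            fh.write(f"FAM {s} 0 0 0 -9 {row}\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read unphased (or phased; phase ignored) biallelic SNPs from VCF.

    Multi-allelic sites are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", v.CHROM, v.POS)
            continue
        gt = np.asarray(v.genotypes, dtype=object)
        counts = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(gt):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            counts[i] = (a > 0) + (b > 0)
        rows.append((v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS))
        cols.append(counts)
    if not cols:
        raise ValueError(f"no biallelic records in {path}")
    marker_map = MarkerMap(pd.DataFrame(rows, columns=["locus", "chrom", "pos"]))
    G = np.stack(cols, axis=1)
    gm = GenotypeMatrix(G, samples, list(marker_map.loci))
    return _sort_by_map(gm, marker_map)


def read_plink(prefix) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read the PLINK-style .ped/.map text dialect written by write_plink."""
    prefix = Path(prefix)
    m = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "locus", "cm", "pos"], dtype={"chrom": str, "locus": str},
    )
    marker_map = MarkerMap(m[["locus", "chrom", "pos"]])
    samples, rows = [], []
    n_loci = len(marker_map)
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_loci} "
                    f"fields, found {len(parts)}"
                )
            samples.append(parts[1])
            alleles = parts[6:]
            g = np.empty(n_loci, dtype=np.int8)
            for k in range(n_loci):
                a, b = alleles[2 * k], alleles[2 * k + 1]
                if a == "0" or b == "0":
                    g[k] = MISSING
                else:
                    g[k] = (a == "B") + (b == "B")
            rows.append(g)
    gm = GenotypeMatrix(np.vstack(rows), samples, list(marker_map.loci))
    return _sort_by_map(gm, marker_map)


def read_genotypes(path, fmt: str | None = None) -> tuple[GenotypeMatrix, MarkerMap]:
    """Dispatch on format: 'vcf' or 'plink' (prefix of .ped/.map)."""
    p = Path(path)
    if fmt is None:
        fmt = "vcf" if p.suffix == ".vcf" else "plink"
    if fmt == "vcf":
        return read_vcf(p)
    if fmt == "plink":
        return read_plink(p.with_suffix("") if p.suffix in (".ped", ".map") else p)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _sort_by_map(gm: GenotypeMatrix, marker_map: MarkerMap):
    """Order loci by (chromosome, position), keeping chromosome-first-seen order."""
    order = np.lexsort(
        (marker_map.pos,
         pd.Categorical(marker_map.chrom, categories=marker_map.chromosomes).codes)
    )
    if np.array_equal(order, np.arange(len(order))):
        return gm, marker_map
    mm = MarkerMap(marker_map.table.iloc[order].reset_index(drop=True))
    return gm.subset_loci(order), mm


def read_rates(path) -> dict[str, float]:
    """Per-chromosome recombination rates: columns chromosome, morgans_per_mb."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    df.columns = [c.strip().lower() for c in df.columns]
    rates = dict(zip(df["chromosome"].astype(str), df["morgans_per_mb"].astype(float)))
    for c, r in rates.items():
        if r <= 0:
            raise ValueError(f"rate for chromosome {c} must be > 0, got {r}")
    return rates


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

@dataclass
class MendelReport:
    """Counts of genotype configurations impossible under Mendelian inheritance."""

    per_locus: pd.Series  # locus id -> inconsistency count
    per_sample: pd.Series  # offspring id -> inconsistency count
    n_trios: int
    locus_threshold: int = LOCUS_INCONSISTENCY_THRESHOLD

    @property
    def total(self) -> int:
        return int(self.per_locus.sum())

    def failing_loci(self) -> list[str]:
        return list(self.per_locus[self.per_locus > self.locus_threshold].index)

    def failing_samples(self, threshold: int) -> list[str]:
        return list(self.per_sample[self.per_sample > threshold].index)


def trio_inconsistent(child: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Elementwise Mendelian-impossibility mask for genotype-count vectors.

    Handles missing (-1) entries: a parent with a missing genotype imposes no
    constraint; opposite-homozygote rules apply per known parent.
    """
    c, s, d = (np.asarray(x) for x in (child, sire, dam))
    known_c = c != MISSING
    ks, kd = s != MISSING, d != MISSING
    bad = np.zeros(c.shape, dtype=bool)
    # child homozygous vs either known parent being the opposite homozygote
    bad |= known_c & (c == 0) & ((ks & (s == 2)) | (kd & (d == 2)))
    bad |= known_c & (c == 2) & ((ks & (s == 0)) | (kd & (d == 0)))
    # heterozygous child with both parents the same homozygote
    bad |= known_c & (c == 1) & ks & kd & (s == d) & ((s == 0) | (s == 2))
    return bad


def mendel_check(genotypes: GenotypeMatrix, pedigree: pne.Pedigree,
                 locus_threshold: int = LOCUS_INCONSISTENCY_THRESHOLD) -> MendelReport:
    """Count Mendelian inconsistencies for every genotyped offspring/locus."""
    sample_row = {s: i for i, s in enumerate(genotypes.samples)}
    G = genotypes.genotypes
    per_locus = np.zeros(genotypes.n_loci, dtype=np.int64)
    per_sample: dict[str, int] = {}
    n_trios = 0
    sire_idx, dam_idx = pedigree.parent_indices()
    ids = pedigree.ids
    for row, iid in enumerate(ids):
        if iid not in sample_row:
            continue
        si, di = sire_idx[row], dam_idx[row]
        sire_id = ids[si] if si >= 0 else None
        dam_id = ids[di] if di >= 0 else None
        if sire_id not in sample_row and dam_id not in sample_row:
            continue
        c = G[sample_row[iid]]
        s = G[sample_row[sire_id]] if sire_id in sample_row else np.full_like(c, MISSING)
        d = G[sample_row[dam_id]] if dam_id in sample_row else np.full_like(c, MISSING)
        bad = trio_inconsistent(c, s, d)
        per_locus += bad
        per_sample[iid] = int(bad.sum())
        n_trios += 1
    return MendelReport(
        per_locus=pd.Series(per_locus, index=genotypes.loci),
        per_sample=pd.Series(per_sample, dtype=np.int64),
        n_trios=n_trios,
        locus_threshold=locus_threshold,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration."""

    out_dir: str
    seed: int = 0
    preset_overrides: dict = field(default_factory=dict)
    models: tuple[str, ...] = ("a", "b", "c", "d", "e", "f")
    min_mb: float = 2.5
    max_mb: float = 15.0
    step_mb: float = 0.2
    per_chromosome_background: int = 30
    min_pairs_per_category: int = ne_from_ld.MIN_PAIRS_PER_CATEGORY
    max_locus_missing: float = 0.04
    max_sample_missing: float = 0.04
    locus_inconsistency_threshold: int = LOCUS_INCONSISTENCY_THRESHOLD

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in ne_from_ld.ModelSpec.all_models():
                raise ValueError(f"unknown model {m!r}")
        if not (0 < self.min_mb < self.max_mb and self.step_mb > 0):
            raise ValueError("need 0 < min_mb < max_mb and step_mb > 0")
        for name in ("max_locus_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a herd, then run both Ne tracks and the comparison table.

    Writes pedigree, VCF, per-stage TSVs and a manifest into ``out_dir`` and
    returns the in-memory results bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim_cfg = sim.guadyerbas_preset(seed=config.seed, **config.preset_overrides)

    pool = sim.simulate_base_population(sim_cfg, rng)
    pedigree = sim.breeding_schedule(sim_cfg, rng)
    contrib = pne.long_term_contributions(pedigree)
    L = pne.generation_interval(contrib)
    generation_of = pne.partition_generations(pedigree, L)
    ne_series = pne.ne_from_contributions(contrib, generation_of)

    window = sim_cfg.genotyped_last_generations or 6
    geno_ids = sim.genotyped_window_ids(pedigree, generation_of, window)
    rates = {c: r for c, r in zip(sim_cfg.chromosome_names, sim_cfg.recomb_rates())}
    genotypes, marker_map = sim.gene_drop(
        pedigree, pool, rates, rng, genotyped_ids=geno_ids,
        missing_rate=sim_cfg.missing_rate,
        chromosome_length_bp=sim_cfg.chromosome_length_bp,
    )

    write_pedigree(pedigree, out / "pedigree.csv")
    write_vcf(genotypes, marker_map, out / "genotypes.vcf",
              chromosome_length_bp=sim_cfg.chromosome_length_bp)

    mendel = mendel_check(genotypes, pedigree, config.locus_inconsistency_threshold)
    keep = ~np.isin(genotypes.loci, mendel.failing_loci())
    genotypes = genotypes.subset_loci(keep)
    marker_map = marker_map.subset(keep)
    genotypes, marker_map = ld_engine.segregating_filter(
        genotypes, marker_map, config.max_locus_missing, config.max_sample_missing
    )

    bins = ld_engine.bin_ld(
        ld_engine.pairwise_ld(genotypes, marker_map,
                              int(50e6 if sim_cfg.chromosome_length_mb >= 50 else
                                  sim_cfg.chromosome_length_bp))
    )
    bg_mean, bg_sd, bg_n = ld_engine.nonsyntenic_background(
        genotypes, marker_map, config.per_chromosome_background, rng
    )

    categories = ne_from_ld.make_distance_categories(
        config.min_mb, config.max_mb, config.step_mb
    )
    # replicates: one per generation index in the genotyped window
    gens = sorted({generation_of.loc[s] for s in genotypes.samples})
    trajectories = []
    for g in gens:
        members = [s for s in genotypes.samples if generation_of.loc[s] == g]
        if len(members) < 2:
            continue
        cohort = genotypes.subset_samples(np.isin(genotypes.samples, members))
        cohort, cohort_map = ld_engine.segregating_filter(cohort, marker_map, 1.0, 1.0)
        ld_pairs = ne_from_ld.pairwise_ld_for_categories(cohort, cohort_map, categories)
        ld_pairs = ne_from_ld.attach_linkage_distance(ld_pairs, rates)
        for m in config.models:
            spec = ne_from_ld.ModelSpec.from_letter(m)
            try:
                traj = ne_from_ld.ne_trajectory(
                    cohort, cohort_map, rates, spec, categories,
                    min_pairs=config.min_pairs_per_category,
                    replicate=f"gen{g}", ld=ld_pairs,
                )
            except (ValueError, RuntimeError) as exc:
                logger.warning("model %s, generation %s failed: %s", m, g, exc)
                continue
            trajectories.append(traj)
    trajectory = pd.concat(trajectories, ignore_index=True) if trajectories else pd.DataFrame()
    summary = (
        ne_from_ld.replicate_summary(trajectory)
        if not trajectory.empty and trajectory["replicate"].nunique() >= 2
        else pd.DataFrame()
    )

    comparison = _comparison_table(summary, ne_series, generation_of)

    contrib_table = pd.DataFrame(
        {"id": contrib.contributions.index, "c": contrib.contributions.to_numpy()}
    )
    ne_series.table.to_csv(out / "pedigree_ne.tsv", sep="\t", index=False)
    contrib_table.to_csv(out / "contributions.tsv", sep="\t", index=False)
    bins.to_csv(out / "ld_bins.tsv", sep="\t", index=False)
    trajectory.to_csv(out / "ne_trajectory.tsv", sep="\t", index=False)
    if not summary.empty:
        summary.to_csv(out / "ne_summary.tsv", sep="\t", index=False)
    if not comparison.empty:
        comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "simulation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim_cfg).items()
        },
        "generation_interval_years": L,
        "n_pedigree": len(pedigree),
        "n_genotyped": genotypes.n_samples,
        "n_loci_after_qc": genotypes.n_loci,
        "mendel_total_inconsistencies": mendel.total,
        "background_r2_mean": bg_mean,
        "background_r2_sd": bg_sd,
        "background_pairs": bg_n,
        "models": list(config.models),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "pedigree": pedigree,
        "contributions": contrib,
        "generation_interval": L,
        "pedigree_ne": ne_series,
        "genotypes": genotypes,
        "marker_map": marker_map,
        "mendel": mendel,
        "ld_bins": bins,
        "background": (bg_mean, bg_sd, bg_n),
        "trajectory": trajectory,
        "summary": summary,
        "comparison": comparison,
        "manifest": manifest,
    }


def _comparison_table(summary: pd.DataFrame, ne_series: pne.PedigreeNeSeries,
                      generation_of: pd.Series) -> pd.DataFrame:
    """LD-based Ne(t) against pedigree Ne at the nearest generation back."""
    if summary.empty:
        return pd.DataFrame()
    ped = ne_series.table
    last_gen = int(generation_of.max())
    ped = ped.assign(t_ago=last_gen - ped["generation"])
    rows = []
    for rec in summary.itertuples():
        k = (ped["t_ago"] - rec.mean_t).abs().idxmin()
        rows.append(
            (rec.model, rec.mean_t, rec.mean_ne, rec.sd_ne,
             int(ped.loc[k, "t_ago"]), float(ped.loc[k, "ne"]))
        )
    return pd.DataFrame(
        rows,
        columns=["model", "t", "ld_ne_mean", "ld_ne_sd", "pedigree_t", "pedigree_ne"],
    )
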