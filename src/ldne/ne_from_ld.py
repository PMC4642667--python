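"""Historical effective population size from the decay of r² with distance.

For a pair of loci at linkage distance ``c`` Morgans, drift, mutation and
finite sampling give the expectation

    E[r²] = (α + 4 Ne c)⁻¹ + 1/N,

where α is 1 without mutation, 2 with mutation (or estimated from the data),
and the 1/N term absorbs the spurious association in a finite sample (N = n
diploids for unphased data, 2n when haplotypes are known without error).
Inverting at the mean r² of pairs a distance ``d`` apart dates the estimate:
pairs at linkage distance ``c`` reflect drift about t = 1/(2c) generations
ago, so

    Ne(t) = (4d)⁻¹ [ (r²_d − 1/N)⁻¹ − α ].

Six model variants (α estimated or fixed at 2, crossed with a sample-size
correction of 0, 1/(2n) or 1/n) are supported; α, where estimated, comes from
one global nonlinear least-squares fit over all distance categories and is
then reused in every per-category inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import GenotypeMatrix, MarkerMap
from . import ld_engine

logger = logging.getLogger(__name__)

ALPHA_FIXED_DEFAULT = 2.0
MIN_PAIRS_PER_CATEGORY = 10

# default per-chromosome linkage map density when no table is supplied:
# 2.5 Mb <-> 0.019 Morgans
DEFAULT_RATE_M_PER_MB = 0.0076


@dataclass(frozen=True)
class ModelSpec:
    """One of the six mutation x sample-size model variants."""

    alpha_mode: str  # "estimated" | "fixed"
    sample_correction: str  # "none" | "half_2n" | "inv_n"
    alpha_fixed_value: float = ALPHA_FIXED_DEFAULT

    _LETTERS = {
        "a": ("estimated", "none"),
        "b": ("estimated", "half_2n"),
        "c": ("estimated", "inv_n"),
        "d": ("fixed", "none"),
        "e": ("fixed", "half_2n"),
        "f": ("fixed", "inv_n"),
    }

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("estimated", "fixed"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.sample_correction not in ("none", "half_2n", "inv_n"):
            raise ValueError(f"unknown sample_correction {self.sample_correction!r}")

    @classmethod
    def from_letter(cls, letter: str) -> "ModelSpec":
        try:
            mode, corr = cls._LETTERS[letter.lower()]
        except KeyError:
            raise ValueError(
                f"unknown model {letter!r}; expected one of {sorted(cls._LETTERS)}"
            ) from None
        return cls(mode, corr)

    @classmethod
    def all_models(cls) -> dict[str, "ModelSpec"]:
        return {k: cls.from_letter(k) for k in cls._LETTERS}

    @property
    def letter(self) -> str:
        for k, v in self._LETTERS.items():
            if v == (self.alpha_mode, self.sample_correction):
                return k
        return "?"

    def correction_term(self, n: int) -> float:
        if self.sample_correction == "none":
            return 0.0
        if n < 1:
            raise ValueError("sample size n >= 1 required for the correction")
        return 1.0 / (2 * n) if self.sample_correction == "half_2n" else 1.0 / n


class UndefinedEstimateError(ValueError):
    """Raised when mean r² does not exceed the sampling floor 1/N."""


def physical_to_linkage(distance_bp, chromosome: str,
                        rates: dict[str, float]) -> float:
    """Morgans = (distance in Mb) x (chromosome rate in Morgans/Mb)."""
    chromosome = str(chromosome)
    if chromosome not in rates:
        raise KeyError(f"no recombination rate for chromosome {chromosome!r}")
    return (np.asarray(distance_bp, dtype=float) / 1e6) * rates[chromosome]


def generations_ago(d) -> float:
    """Pairs at linkage distance d Morgans date Ne about t = 1/(2d) back."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("linkage distance must be positive")
    out = 1.0 / (2.0 * d)
    return float(out) if out.ndim == 0 else out


def expected_r2(ne, c, model: ModelSpec, n: int | None = None,
                alpha: float | None = None):
    """E[r²] = 1/(α + 4 Ne c) + sample-size correction."""
    if alpha is None:
        if model.alpha_mode != "fixed":
            raise ValueError("alpha must be supplied when the model estimates it")
        alpha = model.alpha_fixed_value
    corr = model.correction_term(n) if model.sample_correction != "none" else 0.0
    ne = np.asarray(ne, dtype=float)
    c = np.asarray(c, dtype=float)
    out = 1.0 / (alpha + 4.0 * ne * c) + corr
    return float(out) if out.ndim == 0 else out


def invert_ne(mean_r2: float, mean_d: float, model: ModelSpec,
              n: int | None = None, alpha: float | None = None) -> float:
    """Ne(t) = (4d)⁻¹ [(r²_d − 1/N)⁻¹ − α]; exact inverse of expected_r2."""
    if alpha is None:
        if model.alpha_mode != "fixed":
            raise ValueError("alpha must be supplied when the model estimates it")
        alpha = model.alpha_fixed_value
    if mean_d <= 0:
        raise ValueError("mean linkage distance must be positive")
    corr = model.correction_term(n) if model.sample_correction != "none" else 0.0
    adj = mean_r2 - corr
    if adj <= 0:
        raise UndefinedEstimateError(
            f"mean r² {mean_r2:.4g} does not exceed the sampling floor {corr:.4g}"
        )
    ne = (1.0 / adj - alpha) / (4.0 * mean_d)
    return ne


@dataclass(frozen=True)
class DistanceCategorySet:
    """Contiguous left-closed right-open physical-distance categories (Mb)."""

    start: float
    stop: float
    step: float
    categories: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.categories)


def make_distance_categories(start: float = 2.5, stop: float = 15.0,
                             step: float = 0.2) -> DistanceCategorySet:
    """Consecutive [s, s+step) categories from start up to stop.

    The default 2.5-15.0 Mb interval at 0.2 Mb spacing yields 63 categories
    (the last one truncated at stop).
    """
    if not (start < stop and step > 0):
        raise ValueError("need start < stop and step > 0")
    cats = []
    k = 0
    while True:
        lo = start + k * step
        if lo >= stop - 1e-12:
            break
        cats.append((round(lo, 10), round(min(lo + step, stop), 10)))
        k += 1
    return DistanceCategorySet(start, stop, step, tuple(cats))


@dataclass
class AlphaFit:
    """Global (Ne, α) nonlinear least-squares fit over distance categories."""

    alpha: float
    ne: float
    cost: float
    converged: bool
    alpha_se: float
    ne_se: float
    n_categories: int


def _category_means(ld: pd.DataFrame, categories: DistanceCategorySet,
                    min_pairs: int) -> pd.DataFrame:
    """Mean r², mean linkage distance and pair count per physical category."""
    d_mb = ld["distance_bp"].to_numpy() / 1e6
    rows = []
    for lo, hi in categories.categories:
        m = (d_mb >= lo) & (d_mb < hi)
        cnt = int(m.sum())
        if cnt < min_pairs:
            if cnt:
                logger.info("category [%.1f, %.1f) dropped: %d pairs", lo, hi, cnt)
            continue
        rows.append(
            (lo, hi, cnt, float(ld.loc[m, "r2"].mean()), float(ld.loc[m, "d_morgans"].mean()))
        )
    return pd.DataFrame(rows, columns=["lo_mb", "hi_mb", "n_pairs", "mean_r2", "mean_d"])


def fit_alpha(category_means: pd.DataFrame, model: ModelSpec, n: int) -> AlphaFit:
    """Estimate (Ne, α) by nonlinear least squares on per-category mean r².

    Minimises Σ [mean_r² − (1/(α + 4 Ne d) + corr)]² over Ne ∈ (0, 1e6],
    α ∈ (0, 10] from a fixed multi-start grid (α ∈ {1, 2} x Ne ∈ {10, 100}).
    """
    if model.alpha_mode != "estimated":
        raise ValueError("fit_alpha requires a model with alpha_mode='estimated'")
    if len(category_means) < 10:
        raise ValueError(
            f"only {len(category_means)} populated distance categories; >= 10 required"
        )
    r2 = category_means["mean_r2"].to_numpy()
    d = category_means["mean_d"].to_numpy()
    corr = model.correction_term(n) if model.sample_correction != "none" else 0.0

    def resid(theta):
        ne, alpha = theta
        return 1.0 / (alpha + 4.0 * ne * d) + corr - r2

    best = None
    for ne0 in (10.0, 100.0):
        for a0 in (1.0, 2.0):
            sol = least_squares(
                resid, x0=[ne0, a0],
                bounds=([1e-12, 1e-12], [1e6, 10.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
    if best is None or not best.success:
        raise RuntimeError(
            "nonlinear least-squares fit failed from every start "
            f"(status {getattr(best, 'status', None)})"
        )
    # asymptotic SEs from the Jacobian at the optimum
    m, p = len(r2), 2
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        ne_se, alpha_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        ne_se = alpha_se = float("nan")
    return AlphaFit(
        alpha=float(best.x[1]), ne=float(best.x[0]), cost=float(best.cost),
        converged=bool(best.success), alpha_se=alpha_se, ne_se=ne_se,
        n_categories=len(r2),
    )


def attach_linkage_distance(ld: pd.DataFrame,
                            rates: dict[str, float]) -> pd.DataFrame:
    """Add a d_morgans column from per-chromosome Morgans/Mb rates."""
    out = ld.copy()
    rate = out["chrom"].astype(str).map(lambda c: rates[str(c)])
    if rate.isna().any():
        bad = sorted(set(out.loc[rate.isna(), "chrom"]))
        raise KeyError(f"no recombination rate for chromosomes {bad}")
    out["d_morgans"] = out["distance_bp"] / 1e6 * rate
    return out


def ne_trajectory(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    rates: dict[str, float],
    model: ModelSpec,
    categories: DistanceCategorySet | None = None,
    min_pairs: int = MIN_PAIRS_PER_CATEGORY,
    replicate: str = "0",
    ld: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ne(t) per distance category for one replicate cohort.

    Pairs are assigned to categories by physical distance; the inversion uses
    the arithmetic mean linkage distance of the pairs in the category.  For
    α-estimating models the global (Ne, α) fit across all categories supplies
    α̂, reused in every per-category inversion.  Categories whose mean r² is
    at or below the sampling floor are omitted (logged), as are categories
    with fewer than ``min_pairs`` pairs.

    A precomputed pair-level table (``ld``) can be passed to avoid repeating
    the EM step when several models run on the same cohort.
    """
    categories = categories or make_distance_categories()
    n = genotypes.n_samples
    if ld is None:
        ld = pairwise_ld_for_categories(genotypes, marker_map, categories)
    ld = ld if "d_morgans" in ld.columns else attach_linkage_distance(ld, rates)
    means = _category_means(ld, categories, min_pairs)
    if means.empty:
        raise ValueError("no distance category has enough pairs")
    if model.alpha_mode == "estimated":
        fit = fit_alpha(means, model, n)
        alpha = fit.alpha
    else:
        fit, alpha = None, model.alpha_fixed_value
    rows = []
    for rec in means.itertuples():
        t = generations_ago(rec.mean_d)
        try:
            ne = invert_ne(rec.mean_r2, rec.mean_d, model, n, alpha=alpha)
        except UndefinedEstimateError:
            logger.info(
                "category [%.1f, %.1f): r² below sampling floor; omitted",
                rec.lo_mb, rec.hi_mb,
            )
            continue
        if not np.isfinite(ne) or ne <= 0:
            logger.info(
                "category [%.1f, %.1f): non-positive Ne estimate omitted",
                rec.lo_mb, rec.hi_mb,
            )
            continue
        rows.append(
            (model.letter, replicate, rec.lo_mb, rec.hi_mb, rec.n_pairs,
             rec.mean_r2, rec.mean_d, t, ne, alpha)
        )
    return pd.DataFrame(
        rows,
        columns=["model", "replicate", "lo_mb", "hi_mb", "n_pairs",
                 "mean_r2", "mean_d", "t", "ne", "alpha"],
    )


def pairwise_ld_for_categories(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    categories: DistanceCategorySet,
) -> pd.DataFrame:
    """Pair-level r² restricted to the categories' physical-distance window."""
    max_bp = int(round(categories.stop * 1e6))
    min_bp = int(round(categories.start * 1e6))
    ld = ld_engine.pairwise_ld(genotypes, marker_map, max_bp)
    return ld[ld["distance_bp"] >= min_bp].reset_index(drop=True)


def replicate_summary(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Cross-replicate mean ± SD of Ne per (model, category).

    SD uses the sample (n−1) convention and is computed only over replicates
    with a valid estimate in the category.
    """
    reps = trajectories["replicate"].nunique()
    if reps < 2:
        raise ValueError("need >= 2 replicates to summarise")
    g = trajectories.groupby(["model", "lo_mb", "hi_mb"], sort=True)
    out = g.agg(
        mean_t=("t", "mean"),
        mean_ne=("ne", "mean"),
        sd_ne=("ne", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan),
        n_replicates=("ne", "size"),
    ).reset_index()
    return out
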