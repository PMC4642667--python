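# Methods

`ldne` estimates the effective population size (Ne) of a small closed
population with overlapping generations along two independent tracks — a
pedigree track based on long-term genetic contributions and a molecular track
based on the decay of linkage disequilibrium (LD) with map distance — and
ships a synthetic herd generator with a known true Ne so that both tracks can
be validated end to end without external data.

## Pedigree track

The long-term genetic contribution `c_i` of ancestor *i* to a reference
cohort is the expected fraction of the cohort's genome descending from *i*.
It is computed by the gene-flow recursion

    g(a, a) = 1,   g(a, j) = ½ g(a, sire(j)) + ½ g(a, dam(j)),

with unknown parents contributing zero (a closed herd has no immigrants), and
`c_i` is the mean of `g(i, j)` over the cohort.  The implementation runs one
reverse sweep per cohort member over the birth-year-sorted pedigree, so cost
is O(|cohort| · |pedigree|); a brute-force enumeration of all
ancestor-to-descendant paths weighted (½)^length serves as the test oracle.

Squared contributions give the rate of inbreeding and the effective size per
generation:

    ΔF_t = (Σ_{i∈t} c_i²) / 4,     Ne(t) = 2 / Σ_{i∈t} c_i² = 1 / (2 ΔF_t).

For a closed population the contributions of any complete ancestral
generation sum to one; the suite checks this to 1e-9 (the recursion is exact
arithmetic in halves, so only floating error accumulates).

The generation interval L is the gene-turnover time: for each start year, the
smallest window of birth years whose contributions sum to 1 (linearly
interpolated inside the final year); L is the mean window width over feasible
start years.  Generations under overlapping reproduction are then defined as
birth-year blocks of width round(L) — well-defined where pedigree depth is
not — and individuals are assigned to blocks by birth year.  Individuals with
no descendants in the cohort stay in their generation with c = 0; they add
nothing to Σc².

## LD track

For two biallelic loci, haplotype frequencies are estimated from unphased
genotypes by an EM algorithm on the 3×3 genotype table under random mating.
Only double heterozygotes are phase-ambiguous; the E-step assigns them to the
coupling configuration with weight p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB), the
M-step re-estimates the four frequencies from expected gamete counts.  EM is
initialised at linkage equilibrium (p_AB = p_A p_B) and iterated until the
largest frequency change is below 1e-8 (at most 1000 iterations).  LD is

    r² = D² / (p_A p_a p_B p_b),   D = p_AB − p_A p_B.

Numerical notes, established against a 1e-6-step likelihood grid search over
p_AB (margins are fixed by the single-locus counts whatever the phase):

- A table made only of double heterozygotes carries no phase information;
  the equilibrium start is a stationary point and EM stays at r² = 0.  This
  is deliberate: such data cannot distinguish coupling from repulsion.
  Generic random tables can, rarely, also make the start an exact fixed
  point; these are detected (convergence at iteration 1) and carry no
  maximum-likelihood comparison.
- When the likelihood maximum lies on the boundary of the feasible region
  (one haplotype frequency → 0), EM converges sublinearly and is flagged
  non-converged at the iteration cap rather than silently reported.
- The observed-data log-likelihood is non-decreasing along the EM path
  (asserted in tests).

The random-mating assumption inside EM is retained even though a small herd
is inbred: the estimator is used exactly as its field implementations use it,
and the sample-size corrections below absorb part of the residual error.

Pairs with a locus monomorphic among jointly non-missing individuals are
skipped and counted, not set to zero.  Missing genotypes are handled
pairwise-complete, so the sample size n varies per pair.  Background LD is
measured on a seeded random selection of loci per chromosome (default 30),
crossing all between-chromosome pairs.  Distance-binned summaries use
left-closed right-open bins on 1-based bp positions; the default scheme is
0.05-Mb bins to 2 Mb, 0.2-Mb bins to 5 Mb and 5-Mb bins to 50 Mb (64 bins).

The genome-scale path vectorises the EM over all pair tables simultaneously;
a scalar reference implementation backs it and both are cross-checked.

## From LD decay to an Ne trajectory

With mutation and finite sampling, the expectation of r² at linkage distance
c Morgans is

    E[r²] = (α + 4 Ne c)⁻¹ + 1/N,

where α = 1 without mutation, 2 with mutation (or estimated from the data)
and 1/N is the sampling inflation: N = n diploids for unphased data, 2n for
known haplotypes.  Six model variants cross α ∈ {estimated, fixed at 2} with
a correction of 0, 1/(2n) or 1/n (letters a–f).  Pairs at linkage distance c
reflect drift about t = 1/(2c) generations ago, so inverting at the mean r²
of pairs a distance d apart dates the estimate:

    Ne(t) = (4d)⁻¹ [ (r²_d − 1/N)⁻¹ − α ],   t = 1/(2d).

Physical distances (Mb) convert to Morgans by per-chromosome rates
(Morgans/Mb) from an external map table; the package-wide default is
0.0076 M/Mb, the value that makes 2.5 Mb correspond to 0.019 Morgans and
hence to roughly 26 generations, with "the present" (t = 1) at about 66 Mb.
The working window is 2.5–15.0 Mb split into 63 contiguous 0.2-Mb categories.

Design choices where the procedure was genuinely open:

- α, where estimated, comes from one global nonlinear least-squares fit of
  (Ne, α) over all populated categories and is reused in every per-category
  inversion.  Per-category two-parameter fits on a single mean r² are
  under-determined; the global-α reading makes every category estimable.
  The fit is unweighted, bounded (Ne ∈ (0, 1e6], α ∈ (0, 10]) and multi-
  started from α ∈ {1, 2} × Ne ∈ {10, 100} for determinism; asymptotic
  standard errors come from the Jacobian at the optimum.
- Pairs are assigned to categories by physical distance (the scheme is
  stated in Mb), while the inversion uses the arithmetic mean of the pairs'
  linkage distances — pairs from chromosomes with different rates land in
  the same physical category at different map distances.
- Categories with fewer than 10 pairs (configurable), with mean r² at or
  below the sampling floor, or yielding a non-positive Ne are omitted and
  logged rather than reported as zero or infinity.
- Replicates are consecutive generations of the same population (each
  genotyped generation is one replicate); cross-replicate SD uses the
  sample (n−1) convention.  Because consecutive generations share most of
  their drift history, this SD measures between-generation and sampling
  noise, not the full between-population error — a caveat inherited from
  the replicate design itself.

## Synthetic herd generator

The generator is first-class, tested code, and its defaults are the study
conditions, fixed once:

- **Burn-in** (`simulate_base_population`): an explicit discrete
  Wright–Fisher population of `base_ne` diploids (monoecious random mating)
  with per-chromosome recombination (Poisson crossover counts, uniform
  placement, no interference) and recurrent biallelic mutation, run for
  4·`base_ne` generations by default so drift–recombination LD reaches
  equilibrium.  True Ne is the census by construction, which is what makes
  parameter recovery scorable.  The per-locus mutation rate default,
  2.5e-4, was calibrated against the generator's own contract: the fitted
  intercept α of the equilibrium r²(c) curve (with Ne known) must lie in
  the 1–2.5 range mutation theory allows.  Much higher rates (population-
  scaled θ ≈ 1 per locus) visibly depress LD and push the fitted α to ~7,
  which no mutation model justifies.
- **Marker ascertainment**: kept loci must have pooled minor-allele
  frequency ≥ `ascertainment_maf` (default 0.05), emulating the
  common-variant bias of SNP genotyping chips.  Without it, rare-variant
  pairs inflate mean r² beyond what any of the 1/N corrections absorb, a
  regime chip data never enters.  Setting it to 0 keeps every segregating
  locus.  Loci fixed at the end of the burn-in are always dropped; if fewer
  loci than requested qualify, the failure names the shortfall.
- **Breeding schedule** (`breeding_schedule`): founders (default 4 males,
  20 females) enter in year 0; each year a fixed number of breeding males
  and females is drawn from animals aged 1–5 with age weights chosen to
  realise a ~3-year generation interval; each selected female is mated to a
  selected male that shares no parent or grandparent with her (the herd's
  "avoidance of matings between relatives", formalised); litter sizes are
  Poisson.  The herd-like preset (`guadyerbas_preset`) runs 67 years with a
  litter mean calibrated so the complete pedigree totals ≈ 1,180 animals —
  calibrated to total pedigree size, not asserted as any herd's true
  demography — and restricts genotypes to the 6 most recent generations.
- **Gene dropping** (`gene_drop`): founders draw two pool haplotypes
  without replacement (with replacement plus a warning if the pool is
  small); every non-founder receives one recombinant gamete per parent
  under the same crossover model as the burn-in.  Uncorrupted output is
  Mendelian-consistent by construction, and the trio-rule checker verifies
  exactly zero inconsistencies.
- **Missingness**: optional uniform random masking (default 0); real
  missingness patterns are structured in ways this does not emulate.

What the generator does **not** emulate: genotyping error beyond random
masking, selection, X chromosomes, interference, chip-specific QC metrics
(those filters are represented as documented no-ops), age-structured
mortality beyond the 1–5 breeding window, and the frequency-spectrum
distortions of real ascertainment panels.  Passing tests therefore show that
the estimators recover truth under the model's own assumptions at desk
scale; they do not certify behaviour on real chip data.

## Validation scale and known limitations

The parameter-recovery study runs at a deliberately reduced problem size —
6 chromosomes of 100 Mb with 300 ascertained SNPs each, true Ne = 50, five
replicate cohorts of 40 diploids — chosen so the whole suite completes on a
single CPU in well under a minute per run.  At this scale:

- Model b (α estimated, 1/(2n) correction) is consistently the least biased
  of the six variants, and the measured finite-sample inflation of EM-based
  r² (≈ 0.009–0.012 at n = 40) indeed sits near 1/(2n) rather than 1/n —
  the package reproduces the qualitative model ranking.
- The cross-replicate SD of the foundation-era estimate is *not* reliably
  larger for fixed-α models than for α-estimating ones.  With only six
  chromosomes the per-replicate α̂ carries substantial error, and the
  (4d)⁻¹ factor amplifies it exactly at the smallest distances; with more
  genome (and stronger LD) α̂ is pinned tightly and the fixed-α models'
  unabsorbed r² fluctuations dominate instead.  The SD ordering is thus
  scale-dependent, and the corresponding check in the acceptance suite
  documents this as an expected failure at reduced scale.
- Estimates a few generations back need pairs beyond ~15 Mb, where
  background (non-syntenic) LD becomes comparable to the signal; the
  trajectory is therefore truncated at the 2.5–15 Mb window (t ≈ 4–26
  generations at the default rate).

Determinism: every stochastic step takes a `numpy` Generator or integer
seed; identical seeds give byte-identical pedigrees, haplotype pools,
genotype files and pipeline manifests.
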