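# Methods

This note documents the models implemented in `fusesweep`, the numerical
choices behind them, and what the synthetic-data generator does and does
not emulate.

## The question and the data summary

Chromosome fissions and fusions are usually underdominant — heterozygotes
risk mis-segregation at meiosis — so their fixation is classically
attributed to drift in small populations. The alternative is that they
fix because they are positively selected. The package implements both
sides of the argument for resequencing data from small samples: a
composite-likelihood hard-sweep scan around rearrangement breakpoints,
and analytic calculators bounding what drift alone could have fixed.

The data summary for sweep inference is the *blockwise site frequency
spectrum* (bSFS). The genome is cut into blocks containing a fixed number
`l` of callable, non-exonic sites; `l` is chosen so the average block
holds 1.5 segregating sites (for a per-site `θ = 4 N_e μ` of 0.0058 this
gives `l = 113`, since E[S] = θ·l·H₅ with H₅ = 1 + ½ + … + ⅕). With four
unphased diploids, every choice of three diploids gives a sample of six
genomes; all four leave-one-out subsets are used, so each block yields
four observations. Because ancestral states cannot be polarized, counts
are folded: a site with `c` alternate alleles among six contributes to
class `min(c, 6 − c)` ∈ {1 (singleton), 2 (doubleton), 3 (tripleton)}.
Class counts per block are recorded exactly up to `k_max = 2`, larger
counts collapsing into an overflow category, giving 4³ = 64 possible
block configurations.

## Genealogy model and probability computation

Conditional on a genealogy, the three folded class counts are independent
Poisson variables with means `(θ/2)·L_c`, where `L_c` is the total branch
length (in units of 2·N_e generations) whose descendant class folds to
`c`. Configuration probabilities are expectations of the capped Poisson
product over genealogies. These expectations are computed by Monte Carlo.
Because the class lengths depend on the tree only through the multiset of
descendant counts, the Kingman coalescent is simulated on the space of
integer partitions of 6 (eleven states), which makes sampling 10⁵
genealogies essentially free.

A hard sweep that completed `T_a`·2·N_e generations ago is modelled as a
discrete event inserted into the neutral coalescent: each lineage alive
at `T_a` escapes independently with probability
`p_esc(d) = 1 − exp(−α·d)`, where `d` is the block's distance from the
sweep centre in bases and `α = (r/s)·ln(2 N_e s)` is the per-base ratio of
recombination to sweep strength; all caught lineages merge
instantaneously and the coalescent then continues. No coalescence among
escaping lineages during the event is allowed, and the sweep's duration
is ignored (the star-like approximation).

The expensive part — genealogy sampling — is independent of `d` and `α`.
The package therefore precomputes a **Φ table** for each `T_a`: M
genealogies truncated at `T_a`, each completed once for every possible
number of escapees `e ∈ {0..k}` (one uniformly chosen escape subset per
`(record, e)`; unbiased by exchangeability). Sweep probabilities at any
`(θ, α, d)` are then binomial mixtures over the table's `(k, e)` groups,
so one table serves an entire likelihood surface at fixed `T_a`.

**Common random numbers.** The neutral reference used for the likelihood
difference `Δln CL` is evaluated on the *same* Φ table: the rows with
`e = k` are exact neutral genealogies. This removes first-order
Monte-Carlo noise from `Δln CL` (which would otherwise be ~√(1/M) per
observation and swamp small differences) and makes the sweep family nest
the neutral model by construction, so `Δln CL ≥ 0`.

## Fitting

- **Neutral model**: 1-D bounded maximization of the composite
  log-likelihood over `θ ∈ [10⁻³, 10]` (Brent, `xatol` 10⁻⁴).
- **Sweep model**: for each `T_a` on a default 8-point geometric grid in
  (0.05, 1], a dense 15-point scan of `log₁₀ α` at the neutral `θ̂`, a
  coarse 5 × 8 grid in (θ, log₁₀ α), then Nelder–Mead refinement of
  (θ, log₁₀ α) from the best grid point (evaluated on a 10⁻³ lattice so
  per-θ and per-α caches are reused). `T̂_a` is reported at its grid
  value. `Δln CL` is normalized by the number of block observations
  (physical blocks × four subsets).
- **log₁₀ α bounds**: [−5.7, 0]. The upper bound lies where `α·d ≫ 1`
  for every block in a megabase window, so the family contains an
  effectively neutral member; the lower bound corresponds to footprints
  wider than the window. Both are configurable.
- **Local-θ model**: blocks within `d_extent` of the centre take a
  separate rate `θ_local`; `d_extent` runs over a 25 kb grid up to
  500 kb, with (θ, θ_local) maximized jointly at each value. This is the
  alternative explanation (a local mutation/diversity deficit) to
  compare against a sweep.
- Probabilities are floored at 10⁻¹² before logs; floored counts are
  logged. Parameters within 10⁻³ of a bound (relative to its span) are
  flagged.

Biological conversions follow `N_e = θ/(4 μ l)`,
`T = T_a · 2 N_e` generations, and `s` from `α = (r/s) ln(2 N_e s)`
solved on the strong-selection branch `2 N_e s > e` (the weak root is a
mathematical artefact of the log). The root is found by bracketed Brent
iteration and verified by back-substitution.

## Scans, classification, enrichment

Chromosome scans fit neutral + sweep models at evenly spaced test points
(default 100 kb) using blocks within ±500 kb; fusion intervals wider than
5 kb are sampled every 5 kb and summarized by the best point. A fit is
classified as a plausible sweep when `log₁₀ α̂ < −4` **and**
`Δln CL > 0.002` per block — thresholds calibrated so that constant-size
neutral simulations essentially never qualify.

The enrichment test resamples, without replacement within species, as
many background scan points as that species has fusions (100,000 sample
sets by default), comparing the summed `Δln CL` and the count of
classified sweeps. One-tailed p-values are the proportion of resamples
*strictly* exceeding the observed statistic, with an add-one correction
so p is never exactly zero.

## The synthetic-data generator

Two generators are provided, sharing scenario definitions:

- `simulate_blockset` draws one explicit eight-haplotype genealogy per
  block (independent across blocks) and projects it onto the four
  three-diploid subsets, so subset observations carry the same
  dependence as real data while matching the inference model exactly.
  Neutral, discrete-event sweep, and piecewise-constant-N_e histories
  are supported; piecewise histories use exact time rescaling of the
  coalescence hazard. This generator round-trips exactly through the VCF
  fixture writer and the block-building pipeline.
- `simulate_linked_blockset` / `simulate_linked_variants` delegate to
  msprime and simulate whole recombining sequences (the sweep kind uses
  msprime's genic-selection sweep model sandwiched between neutral
  phases). Linked data are what the calibration experiments use, because
  real sequence is linked: blocks share genealogies, within-block
  recombination exists, and local diversity fluctuates along the
  chromosome.

Default scenario conditions: strong sweep `s = 0.005`,
`N_e = 5 × 10⁵`, completed 250,000 generations ago (`T_a = 0.25`);
neutral `N_e = 5 × 10⁵`; both with `μ = r = 2.9 × 10⁻⁹` per site per
generation, 1 Mb regions, four diploids, block length 113 (so the true
per-block θ is 0.66). The demographic scenario ships a deliberately
simple transient ten-fold crash in `N_e` 40–60 k generations ago; it
reproduces the *direction* of demography-induced false sweep support but
is not the study species' fitted history (which involved interspecific
gene flow and is not reproduced here).

A caution discovered during development: re-blocking the
block-independent generator's output on a *shifted* block lattice splices
two independent genealogies into single blocks and violates the
one-genealogy-per-block assumption, which can manufacture spurious sweep
signals. Scans over synthetic data should therefore use the linked
generator (any blocking phase is equally valid there), and the
block-independent generator only with its own aligned lattice.

## Calibration experiments and problem sizes

`power_experiment` replicates the simulation calibration: per replicate,
a 1 Mb linked sequence for four diploids is simulated, blocks are built
at `l = 113`, and neutral + sweep models are fitted at the region centre.
Under the strong-sweep conditions the per-block `Δln CL` is always
positive with median ≈ 0.018, `θ̂` is slightly downward-biased (quartiles
≈ 0.63/0.64/0.66 against a truth of 0.66), `T̂_a` is slightly
overestimated and `α̂` slightly underestimated in strength. Under
neutrality the median per-block `Δln CL` is of order 10⁻⁵–10⁻⁴ and the
maximum stays below 0.002, motivating the classification thresholds.

The shipped experiments use 30 replicates (up to 100 for the neutral
calibration, whose median is the noisiest summary) and Φ tables of
M = 2 × 10⁴ genealogies, with larger tables (10⁵) recommended for
production fits of real data; all experiments expose `--replicates`-style
and `phi_m` knobs. Under neutrality the median per-block `Δln CL` is a
heavy-tailed, near-boundary statistic whose replicate-to-replicate
dispersion spans a factor of a few even at these sizes.

## Drift calculators

- **ROH probability**: an unbroken homozygous tract of expected length
  ≥ L requires pairwise coalescence within `t* = 1/(2 r L)` generations;
  `P = 1 − exp(−t*/(2 N_e))`. Tract-length variance is deliberately
  ignored (order-of-magnitude argument). Genome-wide,
  `1 − (1 − p)ⁿ` over n independent windows.
- **ROH caller**: a maximal interval is a ROH if no 100 kb stretch
  inside it holds more than five heterozygous calls and the interval is
  at least 100 kb; `F_roh` is the genome fraction covered. This is a
  simple density rule, not a re-implementation of PLINK's genotype-count
  windowing.
- **Underdominant fixation**: Kimura's diffusion with heterozygote
  fitness 1 − s and equal homozygotes, `u = ∫₀^{p₀} G / ∫₀¹ G`,
  `G(x) = exp(4 N_e s x (1 − x))`, `p₀ = 1/(2N)`. The integrand is
  rescaled by its maximum e^{N_e s} for numerical stability; adaptive
  quadrature at relative tolerance 10⁻¹⁰. (Since `1 − 4x(1−x) = (1−2x)²`
  the integrals have an erf closed form, used as an independent oracle
  in the tests.) The maximum-underdominance bound solves
  `2 N μ_genome · u(s) = observed rate` by bracketed root-finding on
  `log₁₀ s`, with the bracket capped so `N_e·s ≤ ~650`.
- **Finite-island model**: n_d demes of diploid size N, per-generation
  migration probability m, re-meeting probability 1/(n_d − 1). Within-
  individual heterozygosity `H = 4 N n_d μ` (independent of m);
  `d_xy = H + μ (n_d − 1)/m`; the expected ROH fraction `W_roh` is the
  probability that a within-individual pair coalesces before `t*`,
  computed from the 3-state chain (same deme, different demes,
  coalesced) by matrix exponential. The inverse fit solves H for
  `N·n_d`, `d_xy − H` for `(n_d − 1)/m`, and pins n_d by 1-D
  root-finding on `W_roh` (monotone along that path). n_d and N are
  robust to ~5 % observation noise; m inherits the noise of the small
  difference `d_xy − H` and is typically only good to a factor ~2.
- **Rearrangement substitution rate**: summed fixed rearrangements over
  summed branch lengths in generations.

## Known limitations

- Sweep probabilities are Monte-Carlo estimates; very small
  configuration probabilities (< ~10/M) are noisy, and small Φ tables
  can let the optimizer fit table noise near likelihood boundaries.
- The star-like discrete-event family is conservative on neutral data:
  for roughly half of neutral replicates its likelihood supremum over
  (θ, α, T_a) is numerically indistinguishable from the neutral maximum,
  so the neutral-calibration median `Δln CL` is only order-of-magnitude
  comparable across implementations of the sweep model.
- Composite likelihoods multiply over non-independent blocks and
  subsets; `Δln CL` is a relative-support measure calibrated by
  simulation, not a likelihood-ratio test statistic.
- The unfolded spectrum, soft/partial/recurrent sweeps, selfing, and
  selection during the flanking neutral phases are out of scope.
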