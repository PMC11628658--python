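"""Analytic calculators for the drift-versus-selection arguments.

These are the back-of-envelope but quantitative pieces of the analysis:

* how surprising long runs of homozygosity (ROH) are in a large panmictic
  population, and a simple density-based ROH caller;
* the diffusion fixation probability of an underdominant rearrangement
  (heterozygote fitness 1 - s, both homozygotes equal) and the maximum s
  compatible with an observed rearrangement substitution rate;
* expectations of within-individual heterozygosity H, between-deme
  divergence d_xy and the expected ROH fraction W_roh under a finite-island
  metapopulation, plus the inverse fit of (n_d, N, m) to observed values;
* the rearrangement substitution rate per genome per generation from
  phylogenetic branch counts and lengths.

All calculators are pure functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, linalg, optimize

__all__ = [
    "RohResult",
    "IslandParams",
    "IslandStats",
    "DriftInputs",
    "roh_window_prob",
    "roh_genome_prob",
    "detect_roh",
    "underdominant_fix_prob",
    "solve_max_underdominance",
    "island_stats",
    "fit_island",
    "rearrangement_rate",
]


@dataclass
class RohResult:
    """Runs of homozygosity for one individual."""

    intervals: list  # (chrom, start, end)
    f_roh: float  # summed ROH length / genome length


@dataclass(frozen=True)
class IslandParams:
    """Finite-island model: n_d demes of diploid size N, migration rate m."""

    n_d: float
    N: float
    m: float

    def __post_init__(self):
        if self.n_d < 1 or self.N <= 0 or not 0 < self.m < 1:
            raise ValueError("require n_d >= 1, N > 0, 0 < m < 1")


@dataclass(frozen=True)
class IslandStats:
    H: float
    d_xy: float
    W_roh: float


@dataclass(frozen=True)
class DriftInputs:
    """Inputs for the underdominance fixation-rate bound."""

    N_e: float
    N: float
    r: float
    mu_genome: float  # de novo rearrangements per genome per generation
    observed_rate: float  # rearrangement substitutions per genome per generation


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------


def roh_window_prob(N_e: float, r: float, L: float) -> float:
    """P(a length-L window lies inside a ROH) in a panmictic population.

    An unbroken homozygous tract of expected length >= L requires the two
    haplotypes to share an ancestor within t* = 1/(2 r L) generations;
    with pairwise coalescence rate 1/(2 N_e) that probability is
    1 - exp(-t* / (2 N_e)).  Tract-length variance is ignored, in keeping
    with the order-of-magnitude purpose of the calculation.
    """
    if N_e <= 0 or r <= 0 or L <= 0:
        raise ValueError("N_e, r and L must be positive")
    t_star = 1.0 / (2.0 * r * L)
    return float(-np.expm1(-t_star / (2.0 * N_e)))


def roh_genome_prob(p_window: float, n_windows: int) -> float:
    """P(at least one of n independent windows lies in a ROH)."""
    if not 0 <= p_window <= 1 or n_windows < 1:
        raise ValueError("require 0 <= p <= 1 and n >= 1")
    return float(1.0 - (1.0 - p_window) ** n_windows)


def detect_roh(
    het_positions: dict,
    chrom_lengths: dict,
    min_length: int = 100_000,
    max_het_per_100kb: int = 5,
    window: int = 100_000,
) -> RohResult:
    """Density-based ROH caller for one individual.

    A region is ROH-compatible if no length-``window`` stretch inside it
    contains more than ``max_het_per_100kb`` heterozygous sites;
    equivalently, any ``max_het_per_100kb + 1`` consecutive heterozygous
    calls spanning less than ``window`` bases break a ROH.  Maximal
    compatible intervals of at least ``min_length`` are reported.  This is
    a deliberately simple density rule, not a reimplementation of the
    sliding-window genotype-calling heuristics of variant-QC tools.
    """
    intervals = []
    total = 0
    genome = sum(chrom_lengths.values())
    k = max_het_per_100kb
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.asarray(het_positions.get(chrom, []), dtype=np.int64))
        # spans of k+1 consecutive hets tighter than the window are "dense"
        bad = []
        if len(pos) > k:
            left, right = pos[:-k], pos[k:]
            tight = (right - left) < window
            for a, b in zip(left[tight], right[tight]):
                if bad and a <= bad[-1][1]:
                    bad[-1][1] = max(bad[-1][1], b)
                else:
                    bad.append([int(a), int(b)])
        cur = 0
        for a, b in bad + [[length, length]]:
            if a - cur >= min_length:
                intervals.append((chrom, int(cur), int(a)))
                total += a - cur
            cur = b
    return RohResult(intervals=intervals, f_roh=total / genome if genome else 0.0)


# ---------------------------------------------------------------------------
# underdominant fixation
# ---------------------------------------------------------------------------


def underdominant_fix_prob(N_e: float, N: float, s: float) -> float:
    """Diffusion fixation probability of a new underdominant mutation.

    Heterozygote fitness 1 - s, both homozygotes equal; initial frequency
    p0 = 1/(2N).  u = int_0^p0 G / int_0^1 G with G(x) =
    exp(4 N_e s x (1 - x)).  The integrand is rescaled by its maximum
    exp(N_e s) so the adaptive quadrature stays stable for strong
    underdominance.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    p0 = 1.0 / (2.0 * N)
    if s == 0:
        return p0
    y = N_e * s
    if y > 700:
        raise OverflowError("N_e * s too large for stable quadrature")

    def g(x):  # G(x) / exp(y); equals exp(-y (1 - 2x)^2)
        return np.exp(4.0 * y * x * (1.0 - x) - y)

    num, _ = integrate.quad(g, 0.0, p0, epsrel=1e-10, epsabs=0)
    den, _ = integrate.quad(g, 0.0, 1.0, epsrel=1e-10, epsabs=0,
                            points=[0.5])
    return float(num / den)


def solve_max_underdominance(
    observed_rate: float, mu_genome: float, N_e: float, N: float
) -> float:
    """Largest heterozygote disadvantage consistent with an observed rate.

    Solves 2 N mu_genome * u(N_e, N, s) = observed_rate for s, where u is
    the underdominant fixation probability; the substitution rate is the
    de novo input rate times the fixation probability.  Bracketed
    root-finding on log10(s).
    """
    if observed_rate <= 0 or mu_genome <= 0:
        raise ValueError("rates must be positive")
    neutral_rate = 2.0 * N * mu_genome * underdominant_fix_prob(N_e, N, 0.0)
    if observed_rate > neutral_rate:
        raise ValueError(
            f"observed rate {observed_rate:g} exceeds the neutral substitution "
            f"rate {neutral_rate:g}; no underdominance required"
        )

    def f(log10_s):
        s = 10.0**log10_s
        return np.log(2.0 * N * mu_genome * underdominant_fix_prob(N_e, N, s)) \
            - np.log(observed_rate)

    lo = -8.0
    hi = min(0.0, np.log10(650.0 / N_e))
    if f(lo) < 0:
        return 0.0  # already below the observed rate at negligible s
    if f(hi) > 0:
        raise ValueError("no sign change: observed rate unreachable in bracket")
    root = optimize.brentq(f, lo, hi, xtol=1e-12)
    return float(10.0**root)


# ---------------------------------------------------------------------------
# finite-island model
# ---------------------------------------------------------------------------


def _within_coal_cdf(params: IslandParams, t: float) -> float:
    """P(two lineages in one individual coalesce before t generations).

    Three-state chain: same deme (coalescence rate 1/(2N), separation
    rate 2m), different demes (reunion rate 2m/(n_d - 1)), coalesced.
    Each lineage migrates independently at rate m and re-meets a specific
    deme with probability 1/(n_d - 1).
    """
    n_d, N, m = params.n_d, params.N, params.m
    if n_d <= 1:
        return float(-np.expm1(-t / (2.0 * N)))
    a = 1.0 / (2.0 * N)
    b = 2.0 * m
    c = 2.0 * m / (n_d - 1.0)
    Q = np.array([[-(a + b), b, a], [c, -c, 0.0], [0.0, 0.0, 0.0]])
    P = linalg.expm(Q * t)
    return float(P[0, 2])


def island_stats(
    params: IslandParams, mu: float, r: float, L_roh: float = 1_000_000
) -> IslandStats:
    """Expected (H, d_xy, W_roh) under the finite-island model.

    H = 4 N n_d mu (within-deme pairwise coalescence time is 2 N n_d
    generations, independently of m); d_xy adds the migration waiting
    time; W_roh is the probability that a within-individual pair
    coalesces before t* = 1/(2 r L_roh) generations.
    """
    n_d, N, m = params.n_d, params.N, params.m
    H = 4.0 * N * n_d * mu
    if n_d > 1:
        d_xy = H + 2.0 * mu * (n_d - 1.0) / (2.0 * m)
    else:
        d_xy = H
    t_star = 1.0 / (2.0 * r * L_roh)
    W = _within_coal_cdf(params, t_star)
    return IslandStats(H=float(H), d_xy=float(d_xy), W_roh=float(W))


def fit_island(
    H_obs: float,
    dxy_obs: float,
    Wroh_obs: float,
    mu: float,
    r: float,
    L_roh: float = 1_000_000,
) -> tuple[IslandParams, dict]:
    """Invert the finite-island expectations for (n_d, N, m).

    H fixes the product N * n_d; d_xy - H fixes (n_d - 1)/m; the
    remaining degree of freedom is pinned by W_roh via 1-D root-finding
    over n_d.  Returns the parameters and the residuals of the three
    moment equations.
    """
    if dxy_obs < H_obs:
        raise ValueError("d_xy must be >= H")
    Nn = H_obs / (4.0 * mu)
    if dxy_obs == H_obs:
        params = IslandParams(n_d=1.0, N=Nn, m=0.5)
        st = island_stats(params, mu, r, L_roh)
        return params, {"H": st.H - H_obs, "d_xy": st.d_xy - dxy_obs,
                        "W_roh": st.W_roh - Wroh_obs}
    ratio = (dxy_obs - H_obs) / (2.0 * mu)  # = (n_d - 1) / (2 m)

    def params_at(n_d):
        return IslandParams(n_d=n_d, N=Nn / n_d,
                            m=(n_d - 1.0) / (2.0 * ratio))

    def f(log_nd):
        n_d = np.exp(log_nd)
        return _within_coal_cdf(params_at(n_d),
                                1.0 / (2.0 * r * L_roh)) - Wroh_obs

    # keep m = (n_d - 1)/(2*ratio) inside (0, 1)
    nd_max = min(1e7, 1.0 + 2.0 * ratio * 0.999)
    lo, hi = np.log(1.0 + 1e-9), np.log(nd_max)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no island solution in bounds: residuals at n_d extremes "
            f"({flo:.3g}, {fhi:.3g})"
        )
    root = optimize.brentq(f, lo, hi, xtol=1e-12)
    params = params_at(float(np.exp(root)))
    st = island_stats(params, mu, r, L_roh)
    resid = {"H": st.H - H_obs, "d_xy": st.d_xy - dxy_obs,
             "W_roh": st.W_roh - Wroh_obs}
    return params, resid


# ---------------------------------------------------------------------------
# rearrangement substitution rate
# ---------------------------------------------------------------------------


def rearrangement_rate(
    branch_event_counts,
    branch_lengths_years,
    generation_time: float = 1.0,
) -> tuple[float, float]:
    """Substitutions per genome per generation, and its reciprocal.

    Total fixed rearrangements along a set of phylogenetic branches
    divided by the summed branch lengths in generations.
    """
    counts = np.asarray(branch_event_counts, dtype=float)
    lengths = np.asarray(branch_lengths_years, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have equal length")
    if np.any(lengths <= 0) or generation_time <= 0:
        raise ValueError("branch lengths and generation time must be positive")
    gens = lengths.sum() / generation_time
    rate = counts.sum() / gens
    return float(rate), float(np.inf if rate == 0 else 1.0 / rate)
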