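"""Composite-likelihood inference of hard selective sweeps from the folded
six-lineage blockwise SFS.

Models
------
* Neutral: a single per-block mutation rate theta = 4*Ne*mu*l.
* Sweep: a discrete hard-sweep event at scaled time T_a with strength
  alpha = (r/s) * ln(2*Ne*s) per base; a block at distance d from the
  sweep centre escapes per lineage with probability 1 - exp(-alpha*d).
* Local-theta: a neutral model in which blocks within d_extent of a centre
  have a separate (reduced) rate theta_local — an alternative explanation
  for locally depressed diversity.

All model probabilities are Monte-Carlo averages over sampled genealogies.
The sweep likelihood uses a :class:`~fusesweep.coalescent.PhiTable`, whose
rows are grouped by (k lineages at the event, e escapees), so a single
table serves every (theta, alpha) for a fixed T_a.  The neutral reference
used for the per-block likelihood difference (delta ln CL) is evaluated on
the *same* table (rows with e = k are exact neutral genealogies); this
common-random-numbers choice removes first-order Monte-Carlo noise from
delta ln CL and preserves model nesting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, e as _EULER_E

import numpy as np
from scipy import optimize

from .coalescent import (
    CONFIGS,
    N_CONFIGS,
    PhiTable,
    build_phi_table,
    capped_poisson_components,
    sample_neutral_class_lengths,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralModel",
    "SweepModel",
    "LocalThetaModel",
    "FitResult",
    "BiologicalParams",
    "get_phi_table",
    "get_neutral_lengths",
    "neutral_config_probs",
    "sweep_config_probs",
    "config_prob",
    "composite_loglik",
    "fit_neutral",
    "fit_sweep",
    "fit_local_theta",
    "alpha_to_s",
    "to_biological",
    "DEFAULT_THETA_BOUNDS",
    "DEFAULT_LOG10_ALPHA_BOUNDS",
    "DEFAULT_TA_GRID",
]

#: optimizer bounds for theta per block
DEFAULT_THETA_BOUNDS = (1e-3, 10.0)
#: optimizer bounds for log10(alpha); alpha is per base.  The upper bound
#: sits where alpha*d >> 1 for every block in a 1 Mb window, so the family
#: contains an effectively neutral member and nests the neutral model.
DEFAULT_LOG10_ALPHA_BOUNDS = (-5.7, 0.0)
#: default grid of scaled sweep times (units of 2*Ne generations)
DEFAULT_TA_GRID = tuple(np.round(np.geomspace(0.05, 1.0, 8), 6))
#: floor applied to model probabilities before taking logs
PROB_EPS = 1e-12


@dataclass(frozen=True)
class NeutralModel:
    theta_block: float


@dataclass(frozen=True)
class SweepModel:
    theta_block: float
    log10_alpha: float
    T_a: float

    @property
    def alpha(self) -> float:
        return 10.0**self.log10_alpha


@dataclass(frozen=True)
class LocalThetaModel:
    theta_block: float
    theta_local: float
    d_extent: float


@dataclass
class FitResult:
    """Maximum composite-likelihood fit of one model at one test point."""

    model: str
    params: dict
    lnCL: float
    lnCL_neutral: float
    delta_lnCL_per_block: float
    n_observations: int
    boundary_flags: list = field(default_factory=list)
    converged: bool = True
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BiologicalParams:
    """Sweep parameters converted to biological scales."""

    N_e: float
    s: float
    T_generations: float
    two_Ne_s: float
    mu: float
    r: float


# ---------------------------------------------------------------------------
# genealogy-table caches
# ---------------------------------------------------------------------------

_PHI_CACHE: dict = {}
_NEUTRAL_CACHE: dict = {}


def get_phi_table(
    T_a: float,
    M: int = 100_000,
    seed: int = 0,
    n: int = 6,
    cache_dir=None,
) -> PhiTable:
    """Build (or fetch from cache) the Phi table for a sweep at time T_a."""
    key = (n, round(float(T_a), 10), int(M), int(seed))
    if key in _PHI_CACHE:
        return _PHI_CACHE[key]
    path = None
    if cache_dir is not None:
        from pathlib import Path

        path = Path(cache_dir) / f"phi_n{n}_Ta{key[1]}_M{M}_s{seed}.npz"
        if path.exists():
            tab = PhiTable.load(path)
            _PHI_CACHE[key] = tab
            return tab
    tab = build_phi_table(n=n, T_a=T_a, M=M, seed=seed)
    _PHI_CACHE[key] = tab
    if path is not None:
        path.parent.mkdir(parents=True, exist_ok=True)
        tab.save(path)
    return tab


def get_neutral_lengths(M: int = 50_000, seed: int = 0, n: int = 6) -> np.ndarray:
    """Neutral genealogy table: (M, n//2) folded-class lengths."""
    key = (n, int(M), int(seed))
    if key not in _NEUTRAL_CACHE:
        rng = np.random.default_rng(seed)
        _NEUTRAL_CACHE[key] = sample_neutral_class_lengths(n, rng, size=M)
    return _NEUTRAL_CACHE[key]


# ---------------------------------------------------------------------------
# configuration probabilities
# ---------------------------------------------------------------------------


def _probs64(L: np.ndarray, theta: float, weights=None) -> np.ndarray:
    """Average capped-Poisson configuration probabilities over genealogies."""
    lam = 0.5 * theta * L
    A = capped_poisson_components(lam[:, 0])
    B = capped_poisson_components(lam[:, 1])
    C = capped_poisson_components(lam[:, 2])
    if weights is not None:
        A = A * weights[:, None]
    T = np.einsum("ri,rj,rk->ijk", A, B, C)
    out = T.reshape(N_CONFIGS)
    if weights is None:
        out = out / len(L)
    return out


def neutral_config_probs(lengths: np.ndarray, theta: float) -> np.ndarray:
    """(64,) configuration probabilities under the neutral model."""
    return _probs64(lengths, theta)


def _phi_group_probs(phi: PhiTable, theta: float) -> np.ndarray:
    """S[g, c]: summed capped-Poisson products per (k, e) group, / M."""
    lam = 0.5 * theta * phi.row_L
    A = capped_poisson_components(lam[:, 0])
    B = capped_poisson_components(lam[:, 1])
    C = capped_poisson_components(lam[:, 2])
    AB = np.einsum("ri,rj->rij", A, B).reshape(len(A), 16)
    G = len(phi.group_k)
    S = np.empty((G, N_CONFIGS))
    for g in range(G):
        sl = slice(phi.group_start[g], phi.group_end[g])
        S[g] = (AB[sl].T @ C[sl]).reshape(N_CONFIGS)
    return S / phi.M


def _powers(x: np.ndarray, emax: int) -> np.ndarray:
    """x ** (0..emax) via cumulative products; shape (len(x), emax + 1)."""
    out = np.empty((len(x), emax + 1))
    out[:, 0] = 1.0
    for e in range(1, emax + 1):
        np.multiply(out[:, e - 1], x, out=out[:, e])
    return out


def _binom_weights(phi: PhiTable, p_esc: np.ndarray) -> np.ndarray:
    """W[i, g] = Binom(e_g; k_g, p_esc[i]) for each observation i."""
    emax = int(phi.group_k.max())
    pe = _powers(p_esc, emax)
    qe = _powers(1.0 - p_esc, emax)
    coef = np.array([comb(int(k), int(e)) for k, e in zip(phi.group_k, phi.group_e)])
    return coef * pe[:, phi.group_e] * qe[:, phi.group_k - phi.group_e]


def sweep_config_probs(
    phi: PhiTable, theta: float, log10_alpha: float, d: np.ndarray
) -> np.ndarray:
    """(len(d), 64) configuration probabilities under the sweep model.

    d is the distance (bases) of each block from the sweep centre.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    S = _phi_group_probs(phi, theta)
    p_esc = -np.expm1(-(10.0**log10_alpha) * d)
    W = _binom_weights(phi, p_esc)
    return W @ S


def config_prob(config, d: float, model, phi: PhiTable | None = None, *,
                neutral_lengths: np.ndarray | None = None) -> float:
    """Probability of one folded configuration at distance d under a model.

    For :class:`SweepModel` a Phi table with matching T_a is required; for
    :class:`NeutralModel` a neutral genealogy table is used (drawn with
    default size/seed when not supplied).
    """
    idx = int(config[0]) * 16 + int(config[1]) * 4 + int(config[2])
    if isinstance(model, NeutralModel):
        if neutral_lengths is None:
            neutral_lengths = get_neutral_lengths()
        return float(neutral_config_probs(neutral_lengths, model.theta_block)[idx])
    if isinstance(model, SweepModel):
        if phi is None:
            raise ValueError("SweepModel requires a PhiTable")
        if abs(phi.T_a - model.T_a) > 1e-9:
            raise ValueError(
                f"PhiTable T_a={phi.T_a} does not match model T_a={model.T_a}"
            )
        return float(
            sweep_config_probs(phi, model.theta_block, model.log10_alpha,
                               np.array([d]))[0, idx]
        )
    raise TypeError(f"unsupported model type {type(model)!r}")


# ---------------------------------------------------------------------------
# composite log-likelihoods
# ---------------------------------------------------------------------------


def _log_floor(p: np.ndarray) -> np.ndarray:
    n_floored = int((p < PROB_EPS).sum())
    if n_floored:
        logger.warning("floored %d block probabilities at %g", n_floored, PROB_EPS)
    return np.log(np.maximum(p, PROB_EPS))


class _NeutralLik:
    """Neutral composite likelihood; probabilities from a fixed table."""

    def __init__(self, blocks, lengths: np.ndarray):
        self.counts = np.bincount(blocks.config_idx, minlength=N_CONFIGS)
        self.lengths = lengths
        self.n_obs = int(self.counts.sum())

    def lnCL(self, theta: float) -> float:
        p = neutral_config_probs(self.lengths, theta)
        return float(self.counts @ _log_floor(p))


class _SweepLik:
    """Sweep composite likelihood over a Phi table.

    Also exposes the same-table neutral likelihood (e = k rows), which is
    the alpha*d -> infinity closure of the sweep family.  ``w_cache`` may
    be shared between instances built on tables with the same (k, e)
    grouping and the same observations: the binomial escape weights do
    not depend on the sampled genealogies.
    """

    def __init__(self, blocks, phi: PhiTable, w_cache: dict | None = None):
        self.phi = phi
        self.d = np.asarray(blocks.distance, dtype=float)
        self.cfg = np.asarray(blocks.config_idx, dtype=np.int64)
        self.counts = np.bincount(self.cfg, minlength=N_CONFIGS)
        self.n_obs = len(self.cfg)
        # pure-neutral rows (e = k): the alpha*d -> inf closure of the family
        mask = phi.row_e == phi.row_k
        self._neutral_L = phi.row_L[mask]
        self._S_cache: dict[float, np.ndarray] = {}
        self._groups_key = (tuple(phi.group_k), tuple(phi.group_e))
        self._W_cache = w_cache if w_cache is not None else {}

    def _Sg(self, theta: float) -> np.ndarray:
        """S gathered at the observed configs: (n_obs, G); cached per theta."""
        if theta not in self._S_cache:
            if len(self._S_cache) > 8:
                self._S_cache.clear()
            S = _phi_group_probs(self.phi, theta)
            self._S_cache[theta] = np.ascontiguousarray(S[:, self.cfg].T)
        return self._S_cache[theta]

    def _W(self, log10_alpha: float) -> np.ndarray:
        key = (self._groups_key, log10_alpha)
        if key not in self._W_cache:
            if len(self._W_cache) > 48:
                self._W_cache.clear()
            p_esc = -np.expm1(-(10.0**log10_alpha) * self.d)
            self._W_cache[key] = _binom_weights(self.phi, p_esc)
        return self._W_cache[key]

    def lnCL(self, theta: float, log10_alpha: float) -> float:
        P = np.einsum("ng,ng->n", self._W(log10_alpha), self._Sg(theta))
        return float(_log_floor(P).sum())

    def lnCL_neutral(self, theta: float) -> float:
        p = _probs64(self._neutral_L, theta)
        return float(self.counts @ _log_floor(p))


def composite_loglik(blocks, model, phi: PhiTable | None = None, *,
                     neutral_lengths: np.ndarray | None = None) -> float:
    """Sum of per-observation log configuration probabilities."""
    if blocks.n_observations == 0:
        raise ValueError("empty block set")
    if isinstance(model, NeutralModel):
        if neutral_lengths is None:
            neutral_lengths = get_neutral_lengths()
        return _NeutralLik(blocks, neutral_lengths).lnCL(model.theta_block)
    if isinstance(model, SweepModel):
        if phi is None or abs(phi.T_a - model.T_a) > 1e-9:
            raise ValueError("SweepModel requires a PhiTable with matching T_a")
        return _SweepLik(blocks, phi).lnCL(model.theta_block, model.log10_alpha)
    if isinstance(model, LocalThetaModel):
        if neutral_lengths is None:
            neutral_lengths = get_neutral_lengths()
        return _local_theta_lnCL(
            blocks, neutral_lengths, model.theta_block, model.theta_local,
            model.d_extent,
        )
    raise TypeError(f"unsupported model type {type(model)!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _flag_bounds(value: float, bounds, name: str, flags: list, tol=1e-3) -> None:
    lo, hi = bounds
    span = hi - lo
    if value - lo <= tol * span:
        flags.append(f"{name}_low")
    elif hi - value <= tol * span:
        flags.append(f"{name}_high")


def _maximize_theta(fun, bounds=DEFAULT_THETA_BOUNDS, xatol=1e-4):
    """1-D bounded maximization over theta (fun returns lnCL)."""
    res = optimize.minimize_scalar(
        lambda t: -fun(t), bounds=bounds, method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun), bool(res.success)


def fit_neutral(blocks, *, neutral_m: int = 50_000, neutral_seed: int = 0,
                theta_bounds=DEFAULT_THETA_BOUNDS) -> FitResult:
    """Fit the single-theta neutral model by bounded 1-D maximization."""
    lengths = get_neutral_lengths(neutral_m, neutral_seed)
    lik = _NeutralLik(blocks, lengths)
    if lik.n_obs == 0:
        raise ValueError("empty block set")
    theta, lnCL, ok = _maximize_theta(lik.lnCL, theta_bounds)
    flags: list = []
    _flag_bounds(theta, theta_bounds, "theta", flags)
    return FitResult(
        model="neutral",
        params={"theta_block": theta},
        lnCL=lnCL,
        lnCL_neutral=lnCL,
        delta_lnCL_per_block=0.0,
        n_observations=lik.n_obs,
        boundary_flags=flags,
        converged=ok,
    )


def fit_sweep(
    blocks,
    *,
    ta_grid=DEFAULT_TA_GRID,
    log10_alpha_grid=None,
    n_theta: int = 5,
    phi_m: int = 100_000,
    phi_seed: int = 0,
    refine: bool = True,
    theta_bounds=DEFAULT_THETA_BOUNDS,
    log10_alpha_bounds=DEFAULT_LOG10_ALPHA_BOUNDS,
    cache_dir=None,
) -> FitResult:
    """Fit the hard-sweep model by grid search plus local refinement.

    The search is a coarse (theta x log10 alpha x T_a) grid with one Phi
    table per T_a value, followed by Nelder-Mead refinement of
    (theta, log10 alpha) at the best T_a.  delta ln CL per block is the
    likelihood gain over the best same-table neutral fit, normalized by
    the number of block observations (blocks x diploid subsets).
    """
    alpha_dense = np.linspace(*log10_alpha_bounds, 15)
    if log10_alpha_grid is None:
        # coarse grid = every other dense value, so weight caches are shared
        log10_alpha_grid = alpha_dense[::2]
    # multiplicative grid around the same-table neutral theta-hat; includes
    # 1.0 so a weak sweep can keep the neutral diversity level
    theta_factors = np.geomspace(0.8, 2.0, n_theta) if n_theta != 5 else \
        np.array([0.8, 1.0, 1.25, 1.6, 2.0])

    best = None  # (gain, T_a, theta, log10a, lnCL, lnCL0, lik)
    per_ta = {}
    w_cache: dict = {}
    for T_a in ta_grid:
        phi = get_phi_table(T_a, M=phi_m, seed=phi_seed, cache_dir=cache_dir)
        lik = _SweepLik(blocks, phi, w_cache=w_cache)
        theta0, lnCL0, _ = _maximize_theta(lik.lnCL_neutral, theta_bounds, xatol=1e-3)
        ta_best = (lnCL0, theta0, log10_alpha_bounds[1])  # neutral closure
        # dense alpha scan at the neutral theta (cheap: S(theta0) is cached),
        # then the coarse theta x alpha grid
        for log10a in alpha_dense:
            ll = lik.lnCL(theta0, log10a)
            if ll > ta_best[0]:
                ta_best = (ll, theta0, log10a)
        for theta in np.clip(theta0 * theta_factors, *theta_bounds):
            for log10a in log10_alpha_grid:
                ll = lik.lnCL(theta, log10a)
                if ll > ta_best[0]:
                    ta_best = (ll, theta, log10a)
        ll, theta, log10a = ta_best
        per_ta[float(T_a)] = (ll - lnCL0) / lik.n_obs
        if best is None or ll - lnCL0 > best[0]:
            best = (ll - lnCL0, float(T_a), theta, log10a, ll, lnCL0, lik)

    gain, T_a, theta, log10a, lnCL, lnCL0, lik = best
    converged = True
    if refine:
        tlo, thi = theta_bounds
        alo, ahi = log10_alpha_bounds

        def neg(x):
            # evaluate on a 1e-3 lattice so the S/W caches are reused
            thc = float(np.clip(x[0], tlo, thi))
            lac = float(np.clip(x[1], alo, ahi))
            pen = 1e4 * ((x[0] - thc) ** 2 + (x[1] - lac) ** 2)
            return -lik.lnCL(round(thc, 3), round(lac, 3)) + pen

        simplex = np.array(
            [
                [theta, log10a],
                [theta * 1.05, log10a],
                [theta, max(alo, log10a - 0.3)],
            ]
        )
        if simplex[2, 1] == log10a:  # already at the lower alpha bound
            simplex[2, 1] = log10a + 0.3
        res = optimize.minimize(
            neg, x0=[theta, log10a], method="Nelder-Mead",
            options={"maxfev": 60, "xatol": 1e-3, "fatol": 1e-4,
                     "initial_simplex": simplex},
        )
        if -res.fun > lnCL:
            theta = float(np.clip(res.x[0], tlo, thi))
            log10a = float(np.clip(res.x[1], alo, ahi))
            lnCL = float(-res.fun)
        converged = bool(res.success) or -res.fun >= lnCL

    delta = (lnCL - lnCL0) / lik.n_obs
    flags: list = []
    _flag_bounds(theta, theta_bounds, "theta", flags)
    _flag_bounds(log10a, log10_alpha_bounds, "log10_alpha", flags)
    if T_a == ta_grid[0]:
        flags.append("T_a_low")
    elif T_a == ta_grid[-1]:
        flags.append("T_a_high")
    return FitResult(
        model="sweep",
        params={"theta_block": theta, "log10_alpha": log10a, "T_a": T_a},
        lnCL=lnCL,
        lnCL_neutral=lnCL0,
        delta_lnCL_per_block=float(delta),
        n_observations=lik.n_obs,
        boundary_flags=flags,
        converged=converged,
        extras={"delta_by_Ta": per_ta},
    )


def _local_theta_lnCL(blocks, lengths, theta, theta_local, d_extent) -> float:
    d = np.asarray(blocks.distance, dtype=float)
    cfg = np.asarray(blocks.config_idx, dtype=np.int64)
    inside = d <= d_extent
    c_in = np.bincount(cfg[inside], minlength=N_CONFIGS)
    c_out = np.bincount(cfg[~inside], minlength=N_CONFIGS)
    ll = 0.0
    if c_out.sum():
        ll += float(c_out @ _log_floor(neutral_config_probs(lengths, theta)))
    if c_in.sum():
        ll += float(c_in @ _log_floor(neutral_config_probs(lengths, theta_local)))
    return ll


def fit_local_theta(
    blocks,
    *,
    d_grid=None,
    neutral_m: int = 50_000,
    neutral_seed: int = 0,
    theta_bounds=DEFAULT_THETA_BOUNDS,
) -> FitResult:
    """Fit a locally reduced mutation rate around the test point.

    d_extent runs over a 25 kb grid between 25 and 500 kb; at each value
    (theta, theta_local) are maximized jointly by Nelder-Mead.
    """
    if d_grid is None:
        d_grid = np.arange(25_000, 500_001, 25_000)
    lengths = get_neutral_lengths(neutral_m, neutral_seed)
    base = fit_neutral(blocks, neutral_m=neutral_m, neutral_seed=neutral_seed,
                       theta_bounds=theta_bounds)
    theta0 = base.params["theta_block"]
    tlo, thi = theta_bounds

    best = None
    for d_extent in d_grid:
        def neg(x, d_extent=d_extent):
            th = float(np.clip(x[0], tlo, thi))
            tl = float(np.clip(x[1], tlo, thi))
            pen = 1e4 * ((x[0] - th) ** 2 + (x[1] - tl) ** 2)
            return -_local_theta_lnCL(blocks, lengths, th, tl, d_extent) + pen

        res = optimize.minimize(
            neg, x0=[theta0, 0.7 * theta0], method="Nelder-Mead",
            options={"maxfev": 120, "xatol": 1e-3, "fatol": 1e-4},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, float(d_extent), res.x)

    lnCL, d_extent, x = best
    theta = float(np.clip(x[0], tlo, thi))
    theta_local = float(np.clip(x[1], tlo, thi))
    flags: list = []
    _flag_bounds(theta, theta_bounds, "theta", flags)
    _flag_bounds(theta_local, theta_bounds, "theta_local", flags)
    if d_extent == d_grid[0]:
        flags.append("d_extent_low")
    elif d_extent == d_grid[-1]:
        flags.append("d_extent_high")
    return FitResult(
        model="local_theta",
        params={"theta_block": theta, "theta_local": theta_local,
                "d_extent": d_extent},
        lnCL=lnCL,
        lnCL_neutral=base.lnCL,
        delta_lnCL_per_block=float((lnCL - base.lnCL) / base.n_observations),
        n_observations=base.n_observations,
        boundary_flags=flags,
    )


# ---------------------------------------------------------------------------
# biological conversions
# ---------------------------------------------------------------------------


def alpha_to_s(alpha: float, N_e: float, r: float) -> float:
    """Solve alpha = (r/s) * ln(2*Ne*s) for s on the strong-selection branch.

    With y = 2*Ne*s the equation reads ln(y)/y = alpha / (2*Ne*r); on
    y > e the left side decreases monotonically, giving a unique root
    corresponding to strong selection.
    """
    if alpha <= 0 or N_e <= 0 or r <= 0:
        raise ValueError("alpha, N_e and r must be positive")
    a = alpha / (2.0 * N_e * r)
    f = lambda y: np.log(y) / y - a
    if f(_EULER_E) <= 0:
        raise ValueError(
            f"no strong-selection root: alpha/(2*Ne*r) = {a:.4g} >= 1/e"
        )
    y_hi = 10.0
    while f(y_hi) > 0:
        y_hi *= 10.0
        if y_hi > 1e300:
            raise ValueError("failed to bracket root")
    y = optimize.brentq(f, _EULER_E, y_hi, xtol=1e-12, rtol=1e-14)
    return y / (2.0 * N_e)


def to_biological(fit: FitResult, mu: float, r: float,
                  block_length_l: int) -> BiologicalParams:
    """Convert a sweep fit to (N_e, s, T in generations, 2*Ne*s)."""
    if mu <= 0 or r <= 0:
        raise ValueError("mu and r must be positive")
    theta = fit.params["theta_block"]
    N_e = theta / (4.0 * mu * block_length_l)
    T_a = fit.params.get("T_a")
    T_gen = T_a * 2.0 * N_e if T_a is not None else float("nan")
    log10a = fit.params.get("log10_alpha")
    s = alpha_to_s(10.0**log10a, N_e, r) if log10a is not None else float("nan")
    return BiologicalParams(
        N_e=N_e, s=s, T_generations=T_gen, two_Ne_s=2.0 * N_e * s, mu=mu, r=r
    )
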