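"""Genealogy sampling for folded branch-class lengths under neutral and
discrete-sweep coalescent models.

The quantity of interest for blockwise-SFS inference is not the full tree
but the total branch length carried by each *folded mutation class*: for a
sample of n lineages, a branch with i descendants contributes to class
min(i, n - i).  For n = 6 there are three classes (singleton, doubleton,
tripleton).  Because these lengths depend on the genealogy only through the
multiset of descendant counts, the Kingman coalescent can be simulated on
the (small) space of integer partitions of n, which makes drawing very
large numbers of genealogies cheap.

Time is measured in units of 2*Ne generations throughout, so a pair of
lineages coalesces at rate 1 and the expected number of mutations on a
branch of length t is (theta/2)*t with theta = 4*Ne*mu*l per block.

A hard selective sweep that completed T_a (scaled) time units ago is
treated as a discrete event: lineages present at T_a either escape the
sweep (via recombination) independently with probability
p_esc(d) = 1 - exp(-alpha*d) at distance d from the sweep centre, or are
caught and merge instantaneously into a single ancestor.  The
:class:`PhiTable` pre-computes, for M sampled genealogies truncated at
T_a, the completed class lengths for *every* possible number of escapees
e, so that sweep probabilities at any (theta, alpha, d) reduce to a
binomial mixture over the table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np

__all__ = [
    "KMAX",
    "N_CONFIGS",
    "CONFIGS",
    "MORE",
    "ClassLengths",
    "PhiTable",
    "sample_neutral_class_lengths",
    "build_phi_table",
    "config_poisson_product",
    "capped_poisson_components",
    "total_length_expectation",
]

# Folded mutation-class cap: counts 0, 1, 2 are recorded exactly, anything
# larger collapses into the overflow category MORE.
KMAX = 2
MORE = KMAX + 1  # sentinel/encoded value for "> KMAX"
N_CLASS_VALUES = KMAX + 2  # {0, 1, 2, MORE}
N_CONFIGS = N_CLASS_VALUES**3  # 64 for six lineages

#: All (n1, n2, n3) configurations, row i encodes i = n1*16 + n2*4 + n3.
CONFIGS = np.array(
    [(a, b, c) for a in range(4) for b in range(4) for c in range(4)], dtype=np.int64
)


def config_index(n1: int, n2: int, n3: int) -> int:
    """Flat index of a folded configuration (values in {0, 1, 2, MORE=3})."""
    return int(n1) * 16 + int(n2) * 4 + int(n3)


@dataclass(frozen=True)
class ClassLengths:
    """Total branch length per folded class for one n = 6 genealogy."""

    L1: float
    L2: float
    L3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3])


# ---------------------------------------------------------------------------
# Partition-state machinery
# ---------------------------------------------------------------------------


def _partitions(n: int):
    """All integer partitions of n as descending tuples."""

    def gen(remaining, maxpart):
        if remaining == 0:
            yield ()
            return
        for p in range(min(remaining, maxpart), 0, -1):
            for rest in gen(remaining - p, p):
                yield (p,) + rest

    return list(gen(n, n))


@lru_cache(maxsize=None)
def _state_space(n: int):
    """Precompute the partition chain for a sample of n lineages.

    Returns (states, index, K, CLASSC, TRANS) where ``states`` lists the
    partitions, ``K[s]`` the number of lineages, ``CLASSC[s]`` the vector of
    folded-class branch counts (classes 1..n//2) and ``TRANS[s]`` a pair
    (targets, cumulative probabilities) for a single coalescence step.
    """
    states = _partitions(n)
    index = {p: i for i, p in enumerate(states)}
    n_cls = n // 2
    K = np.array([len(p) for p in states], dtype=np.int64)
    classc = np.zeros((len(states), n_cls))
    for i, parts in enumerate(states):
        for p in parts:
            c = min(p, n - p)
            if c >= 1:
                classc[i, c - 1] += 1
    trans = []
    for i, parts in enumerate(states):
        k = len(parts)
        if k < 2:
            trans.append((np.array([i]), np.array([1.0])))
            continue
        agg: dict[int, float] = {}
        total = comb(k, 2)
        # merge one pair of parts; count multiplicities by size
        from collections import Counter

        cnt = Counter(parts)
        sizes = sorted(cnt)
        for ai, a in enumerate(sizes):
            for b in sizes[ai:]:
                if a == b:
                    ways = comb(cnt[a], 2)
                else:
                    ways = cnt[a] * cnt[b]
                if ways == 0:
                    continue
                new = list(parts)
                new.remove(a)
                new.remove(b)
                new.append(a + b)
                j = index[tuple(sorted(new, reverse=True))]
                agg[j] = agg.get(j, 0.0) + ways / total
        targets = np.array(sorted(agg))
        probs = np.array([agg[t] for t in targets])
        trans.append((targets, np.cumsum(probs)))
    return states, index, K, classc, trans


def _step_states(st: np.ndarray, trans, rng: np.random.Generator) -> np.ndarray:
    """One coalescence transition for each state index in ``st``."""
    new = np.empty_like(st)
    for s in np.unique(st):
        rows = st == s
        targets, cum = trans[s]
        u = rng.random(int(rows.sum()))
        new[rows] = targets[np.searchsorted(cum, u, side="right")]
    return new


def _evolve(
    states: np.ndarray,
    n: int,
    rng: np.random.Generator,
    t_cap: float | None = None,
):
    """Run the partition chain, accumulating folded-class lengths.

    If ``t_cap`` is given the chain is frozen at that time and the state
    reached is returned; otherwise it runs to the MRCA.

    Returns (lengths (m, n//2), final_states, t_final).
    """
    _, _, K, classc, trans = _state_space(n)
    m = len(states)
    states = states.copy()
    lengths = np.zeros((m, n // 2))
    t = np.zeros(m)
    active = K[states] > 1
    while active.any():
        idx = np.nonzero(active)[0]
        st = states[idx]
        k = K[st]
        rate = k * (k - 1) / 2.0
        wait = rng.exponential(1.0 / rate)
        if t_cap is None:
            dt = wait
            crossed = np.zeros(len(idx), dtype=bool)
        else:
            remaining = t_cap - t[idx]
            crossed = wait >= remaining
            dt = np.minimum(wait, remaining)
        lengths[idx] += classc[st] * dt[:, None]
        t[idx] += dt
        move = idx[~crossed]
        if len(move):
            states[move] = _step_states(states[move], trans, rng)
        if t_cap is not None:
            active[idx[crossed]] = False
        active[move] = K[states[move]] > 1
    return lengths, states, t


def sample_neutral_class_lengths(
    n: int = 6,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
):
    """Draw folded-class branch lengths under the neutral coalescent.

    With ``size=None`` a single :class:`ClassLengths` is returned (n = 6
    only); otherwise an array of shape (size, n//2).
    """
    if not 2 <= n <= 8:
        raise ValueError("n must be between 2 and 8")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    _, index, _, _, _ = _state_space(n)
    start = index[(1,) * n]
    m = 1 if size is None else size
    lengths, _, _ = _evolve(np.full(m, start, dtype=np.int64), n, rng)
    if size is None:
        if n != 6:
            return lengths[0]
        return ClassLengths(*lengths[0])
    return lengths


def total_length_expectation(n: int) -> float:
    """E[total branch length] = 2 * sum_{i<n} 1/i in units of 2*Ne generations."""
    return 2.0 * sum(1.0 / i for i in range(1, n))


# ---------------------------------------------------------------------------
# Phi table: genealogy decomposition around a discrete sweep event
# ---------------------------------------------------------------------------


@dataclass
class PhiTable:
    """Monte-Carlo decomposition of sweep genealogies at event time T_a.

    Rows are (record, e) pairs: record m was truncated at T_a with
    ``k`` surviving lineages; for each possible number of escapees
    e in 0..k a completed genealogy was drawn (the k - e caught lineages
    merge instantaneously, then the chain continues to the MRCA).
    ``row_L[r]`` holds the completed folded-class lengths of row r.

    Rows are sorted by (k, e); ``group_k/group_e/group_start/group_end``
    delimit the contiguous groups so that likelihood code can aggregate
    per (k, e) and apply binomial escape weights afterwards.
    """

    n: int
    T_a: float
    M: int
    seed: int
    row_k: np.ndarray
    row_e: np.ndarray
    row_L: np.ndarray
    group_k: np.ndarray
    group_e: np.ndarray
    group_start: np.ndarray
    group_end: np.ndarray
    k_counts: np.ndarray = field(default=None)  # records per k (diagnostics)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            n=self.n,
            T_a=self.T_a,
            M=self.M,
            seed=self.seed,
            row_k=self.row_k,
            row_e=self.row_e,
            row_L=self.row_L,
            group_k=self.group_k,
            group_e=self.group_e,
            group_start=self.group_start,
            group_end=self.group_end,
            k_counts=self.k_counts,
        )

    @classmethod
    def load(cls, path) -> "PhiTable":
        z = np.load(path)
        return cls(
            n=int(z["n"]),
            T_a=float(z["T_a"]),
            M=int(z["M"]),
            seed=int(z["seed"]),
            row_k=z["row_k"],
            row_e=z["row_e"],
            row_L=z["row_L"],
            group_k=z["group_k"],
            group_e=z["group_e"],
            group_start=z["group_start"],
            group_end=z["group_end"],
            k_counts=z["k_counts"],
        )


@lru_cache(maxsize=None)
def _escape_luts(n: int):
    """For each (state, e): new-state index for every e-subset of lineages.

    Escaped lineages keep their descendant counts; the remaining ones merge
    into a single lineage carrying the complement.  Choosing a uniform
    random e-subset of exchangeable lineages is choosing a uniform entry of
    the returned array.
    """
    states, index, K, _, _ = _state_space(n)
    luts: dict[tuple[int, int], np.ndarray] = {}
    for s, parts in enumerate(states):
        k = len(parts)
        for e in range(k + 1):
            out = []
            for chosen in itertools.combinations(range(k), e):
                if k - e <= 1:
                    out.append(s)
                    continue
                esc = [parts[i] for i in chosen]
                merged = n - sum(esc)
                new = tuple(sorted(esc + [merged], reverse=True))
                out.append(index[new])
            luts[(s, e)] = np.array(out, dtype=np.int64)
    return luts


def build_phi_table(
    n: int = 6, T_a: float = 0.25, M: int = 10_000, seed: int = 0
) -> PhiTable:
    """Sample M genealogies truncated at T_a and complete them for every e.

    T_a is the sweep time in units of 2*Ne generations; larger values give
    genealogies that mostly coalesce before the event (the sweep then has
    no effect).  Reproducible: identical (n, T_a, M, seed) give an
    identical table.
    """
    if T_a <= 0:
        raise ValueError("T_a must be positive")
    rng = np.random.default_rng(seed)
    _, index, K, _, _ = _state_space(n)
    start = index[(1,) * n]
    pre, state_at, _ = _evolve(np.full(M, start, dtype=np.int64), n, rng, t_cap=T_a)
    k_at = K[state_at]

    counts = k_at + 1
    row_m = np.repeat(np.arange(M), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    row_e = np.arange(counts.sum()) - np.repeat(offsets, counts)
    row_state = state_at[row_m]
    row_k = k_at[row_m]

    # apply the event: choose a uniform e-subset of escapees per row
    luts = _escape_luts(n)
    new_states = np.empty_like(row_state)
    key = row_state * 16 + row_e  # unique small key
    for kv in np.unique(key):
        rows = key == kv
        s, e = int(kv) // 16, int(kv) % 16
        lut = luts[(s, e)]
        pick = rng.integers(0, len(lut), size=int(rows.sum()))
        new_states[rows] = lut[pick]

    post, _, _ = _evolve(new_states, n, rng)
    row_L = pre[row_m] + post

    order = np.lexsort((row_e, row_k))
    row_k, row_e, row_L = row_k[order], row_e[order], row_L[order]
    # contiguous (k, e) groups
    gkey = row_k * 16 + row_e
    change = np.nonzero(np.diff(gkey))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(gkey)]])
    group_k = row_k[starts]
    group_e = row_e[starts]
    k_counts = np.bincount(k_at, minlength=n + 1)
    return PhiTable(
        n=n,
        T_a=float(T_a),
        M=M,
        seed=seed,
        row_k=row_k,
        row_e=row_e,
        row_L=row_L,
        group_k=group_k,
        group_e=group_e,
        group_start=starts,
        group_end=ends,
        k_counts=k_counts,
    )


# ---------------------------------------------------------------------------
# Capped Poisson mutation layer
# ---------------------------------------------------------------------------


def capped_poisson_components(lam: np.ndarray) -> np.ndarray:
    """P(count = 0), P(1), P(2), P(> 2) for Poisson mean(s) ``lam``.

    Shape (..., 4); the four entries sum to one.
    """
    lam = np.asarray(lam, dtype=float)
    out = np.empty(lam.shape + (4,))
    p0 = np.exp(-lam, out=out[..., 0])
    np.multiply(lam, p0, out=out[..., 1])
    np.multiply(0.5 * lam, out[..., 1], out=out[..., 2])
    np.subtract(1.0, out[..., :3].sum(axis=-1), out=out[..., 3])
    np.clip(out[..., 3], 0.0, 1.0, out=out[..., 3])
    return out


def config_poisson_product(config, lengths, theta_block: float) -> float:
    """P(folded configuration | genealogy) under independent Poisson classes.

    Conditional on class lengths (L1, L2, L3), the counts of folded
    singletons/doubletons/tripletons are independent Poisson with mean
    (theta_block / 2) * L_c; counts above KMAX collapse into MORE.
    """
    if isinstance(lengths, ClassLengths):
        lengths = lengths.as_array()
    lengths = np.asarray(lengths, dtype=float)
    if theta_block < 0:
        raise ValueError("theta_block must be non-negative")
    comp = capped_poisson_components(0.5 * theta_block * lengths)
    out = 1.0
    for c, nc in enumerate(config):
        out *= comp[c, int(nc)]
    return float(out)
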