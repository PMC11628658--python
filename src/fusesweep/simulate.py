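"""Synthetic block observations and VCF/BED fixtures under the inference model.

The default generator draws, for each block, one explicit eight-haplotype
(four diploid) coalescent genealogy and projects it onto the four
three-diploid subsets, so the four observations per block carry the same
statistical dependence as in real data while blocks remain independent of
one another — exactly the composite-likelihood setting of the inference
machinery.  Three scenario kinds are supported:

* ``neutral`` — constant-size coalescent;
* ``sweep`` — a discrete hard-sweep event ``sweep_time_generations`` ago:
  lineages alive at the event escape independently with probability
  1 - exp(-alpha*d) (alpha = (r/s) ln(2*Ne*s), d = distance from the
  sweep centre in bases) and all caught lineages merge instantaneously;
* ``demographic`` — a single population with piecewise-constant N_e
  (used to probe sweep false positives caused by population-size change).

An optional linked mode delegates to msprime and simulates whole
recombining sequences instead of independent blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import N_SUBSETS, BlockSet, expected_block_length
from .coalescent import MORE

__all__ = [
    "Scenario",
    "SiteTable",
    "PowerSummary",
    "strong_sweep_scenario",
    "neutral_scenario",
    "bottleneck_scenario",
    "simulate_blockset",
    "simulate_linked_blockset",
    "write_fixture_vcf",
    "power_experiment",
]

_N_HAP = 8
_POP = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)
#: subset j uses the six haplotypes excluding diploid j (haplotypes 2j, 2j+1)
_SUBSET_MASKS = np.array([0xFF & ~(0b11 << (2 * j)) for j in range(N_SUBSETS)],
                         dtype=np.uint8)


@dataclass(frozen=True)
class Scenario:
    """Study conditions for one simulation scenario.

    ``epochs`` lists (start_generation, N_e) pairs backwards in time,
    starting at 0; a single epoch is the constant-size model.  The sweep
    kind requires ``s`` and ``sweep_time_generations`` and uses the first
    epoch's N_e.
    """

    kind: str
    N_e: float
    mu: float = 2.9e-9
    r: float = 2.9e-9
    s: float | None = None
    sweep_time_generations: float | None = None
    region_length: int = 1_000_000
    n_diploids: int = 4
    epochs: tuple = ()

    def __post_init__(self):
        if self.kind not in ("neutral", "sweep", "demographic"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "sweep":
            if not (self.s and self.s > 0) or not self.sweep_time_generations:
                raise ValueError("sweep scenario needs s > 0 and a sweep time")
        if self.kind == "demographic" and len(self.epochs) < 1:
            raise ValueError("demographic scenario needs at least one epoch")
        if self.n_diploids != 4:
            raise ValueError("the six-lineage bSFS machinery expects 4 diploids")

    @property
    def effective_epochs(self) -> tuple:
        return self.epochs if self.epochs else ((0.0, self.N_e),)

    @property
    def theta_site(self) -> float:
        return 4.0 * self.N_e * self.mu

    @property
    def alpha(self) -> float:
        y = 2.0 * self.N_e * self.s
        return (self.r / self.s) * np.log(y)

    @property
    def T_a(self) -> float:
        """Sweep time in units of 2*N_e generations."""
        return self.sweep_time_generations / (2.0 * self.N_e)


def strong_sweep_scenario(**kw) -> Scenario:
    """s = 0.005, sweep 250,000 generations ago, N_e = 5e5 (T_a = 0.25)."""
    kw.setdefault("N_e", 5e5)
    kw.setdefault("s", 0.005)
    kw.setdefault("sweep_time_generations", 250_000)
    return Scenario(kind="sweep", **kw)


def neutral_scenario(**kw) -> Scenario:
    kw.setdefault("N_e", 5e5)
    return Scenario(kind="neutral", **kw)


def bottleneck_scenario(**kw) -> Scenario:
    """Transient tenfold crash in N_e 40-60 k generations ago.

    A deliberately simple piecewise history (not a fitted demography) whose
    burst of excess coalescence mimics an old sweep and inflates sweep
    support at neutral loci.
    """
    kw.setdefault("N_e", 5e5)
    kw.setdefault("epochs", ((0.0, 5e5), (40_000.0, 5e4), (60_000.0, 5e5)))
    return Scenario(kind="demographic", **kw)


# ---------------------------------------------------------------------------
# vectorized eight-haplotype coalescent
# ---------------------------------------------------------------------------


def _piecewise_wait(t0, rate_scale, epochs, rng):
    """Waiting time to coalescence with hazard rate_scale / (2*N(t)).

    ``epochs`` is ((start_gen, N), ...); the last epoch extends to
    infinity.  Vectorized over rows.
    """
    E = rng.exponential(size=t0.shape)
    t = t0.astype(float).copy()
    rem = E
    for i, (lo, N) in enumerate(epochs):
        hi = epochs[i + 1][0] if i + 1 < len(epochs) else np.inf
        lam = rate_scale / (2.0 * N)
        base = np.maximum(t, lo)
        seg = np.clip(hi - base, 0.0, None)
        cap = lam * seg
        act = (rem > 0) & (t < hi)
        use = np.minimum(rem, cap)
        dt = np.where(lam > 0, use / lam, 0.0)
        t = np.where(act, base + dt, t)
        rem = np.where(act, rem - use, rem)
    return t - t0


class _SimState:
    """Mutable state of B simultaneous 8-haplotype genealogies."""

    def __init__(self, B: int, rng: np.random.Generator, record_sites: bool):
        self.B = B
        self.rng = rng
        self.bm = np.zeros((B, _N_HAP), dtype=np.uint8)
        self.bm[:] = 1 << np.arange(_N_HAP, dtype=np.uint8)
        self.k = np.full(B, _N_HAP, dtype=np.int64)
        self.t = np.zeros(B)
        self.acc = np.zeros((B, N_SUBSETS, 3), dtype=np.int64)
        self.record = record_sites
        self.site_block: list[np.ndarray] = []
        self.site_bm: list[np.ndarray] = []

    def _mutate(self, rows, dt, mut_rate):
        """Poisson mutations on every active lineage over exposure dt."""
        bmr = self.bm[rows]
        slot = np.arange(_N_HAP) < self.k[rows, None]
        lam = mut_rate * dt[:, None] * slot
        muts = self.rng.poisson(lam)
        if not muts.any():
            return
        for j in range(N_SUBSETS):
            cnt = _POP[bmr & _SUBSET_MASKS[j]]
            fold = np.minimum(cnt, 6 - cnt)
            for cls in (1, 2, 3):
                self.acc[rows, j, cls - 1] += (muts * (fold == cls)).sum(axis=1)
        if self.record:
            nz = muts > 0
            reps = muts[nz]
            self.site_block.append(np.repeat(np.broadcast_to(rows[:, None],
                                                             muts.shape)[nz], reps))
            self.site_bm.append(np.repeat(bmr[nz], reps))

    def _coalesce(self, rows):
        ks = self.k[rows]
        i = self.rng.integers(0, ks)
        j = self.rng.integers(0, ks - 1)
        j = j + (j >= i)
        self.bm[rows, i] |= self.bm[rows, j]
        self.bm[rows, j] = self.bm[rows, ks - 1]
        self.bm[rows, ks - 1] = 0
        self.k[rows] -= 1

    def run(self, epochs, mut_rate, t_cap=None):
        """Evolve until the MRCA (or until t_cap; rows reaching it freeze)."""
        while True:
            act = self.k > 1
            if t_cap is not None:
                act &= self.t < t_cap
            rows = np.nonzero(act)[0]
            if not len(rows):
                break
            ks = self.k[rows]
            wait = _piecewise_wait(self.t[rows], ks * (ks - 1) / 2.0, epochs,
                                   self.rng)
            if t_cap is None:
                dt = wait
                crossed = np.zeros(len(rows), dtype=bool)
            else:
                remaining = t_cap - self.t[rows]
                crossed = wait >= remaining
                dt = np.minimum(wait, remaining)
            self._mutate(rows, dt, mut_rate)
            self.t[rows] += dt
            move = rows[~crossed]
            if len(move):
                self._coalesce(move)

    def sweep_event(self, p_esc):
        """Discrete sweep: per-lineage escape, caught lineages merge."""
        slot = np.arange(_N_HAP) < self.k[:, None]
        esc = (self.rng.random((self.B, _N_HAP)) < p_esc[:, None]) & slot
        caught = slot & ~esc
        merged = np.bitwise_or.reduce(np.where(caught, self.bm, 0), axis=1)
        order = np.argsort(~esc, axis=1, kind="stable")
        newbm = np.take_along_axis(np.where(esc, self.bm, 0), order, axis=1)
        nesc = esc.sum(axis=1)
        has = caught.any(axis=1)
        newbm[has, nesc[has]] = merged[has].astype(np.uint8)
        self.bm = newbm
        self.k = nesc + has


def _blockset_from_counts(acc, scenario, block_length_l, test_point, chrom):
    B = acc.shape[0]
    capped = np.minimum(acc, MORE)
    cfg = capped[:, :, 0] * 16 + capped[:, :, 1] * 4 + capped[:, :, 2]
    starts = np.arange(B, dtype=np.int64) * block_length_l
    ends = starts + block_length_l
    mids = 0.5 * (starts + ends)
    return BlockSet(
        chrom=chrom,
        test_point=float(test_point),
        block_length_l=int(block_length_l),
        subset_id=np.repeat(np.arange(N_SUBSETS), B),
        start=np.tile(starts, N_SUBSETS),
        end=np.tile(ends, N_SUBSETS),
        midpoint=np.tile(mids, N_SUBSETS),
        distance=np.abs(np.tile(mids, N_SUBSETS) - float(test_point)),
        config_idx=cfg.T.reshape(-1),
    )


@dataclass
class SiteTable:
    """Individual simulated mutations: block index and haplotype bitmask."""

    block: np.ndarray
    bitmask: np.ndarray


def simulate_blockset(
    scenario: Scenario,
    n_blocks: int | None = None,
    block_length_l: int | None = None,
    test_point: float | None = None,
    seed: int = 0,
    *,
    chrom: str = "chr_sim",
    record_sites: bool = False,
):
    """Draw independent per-block genealogies and emit all four subsets.

    Returns a :class:`~fusesweep.blocks.BlockSet`; with
    ``record_sites=True`` also a :class:`SiteTable` for fixture writing.
    """
    if block_length_l is None:
        block_length_l = expected_block_length(scenario.theta_site)
    if n_blocks is None:
        n_blocks = scenario.region_length // block_length_l
    if test_point is None:
        test_point = scenario.region_length / 2.0
    rng = np.random.default_rng(seed)
    mut_rate = scenario.mu * block_length_l  # per lineage per generation
    mids = (np.arange(n_blocks) + 0.5) * block_length_l
    epochs = scenario.effective_epochs

    state = _SimState(n_blocks, rng, record_sites)
    if scenario.kind == "sweep":
        d = np.abs(mids - test_point)
        p_esc = -np.expm1(-scenario.alpha * d)
        state.run(epochs, mut_rate, t_cap=scenario.sweep_time_generations)
        state.sweep_event(p_esc)
        state.run(epochs, mut_rate)
    else:
        state.run(epochs, mut_rate)

    blocks = _blockset_from_counts(state.acc, scenario, block_length_l,
                                   test_point, chrom)
    if record_sites:
        if state.site_block:
            sites = SiteTable(np.concatenate(state.site_block),
                              np.concatenate(state.site_bm))
        else:
            sites = SiteTable(np.array([], dtype=np.int64),
                              np.array([], dtype=np.uint8))
        return blocks, sites
    return blocks


# ---------------------------------------------------------------------------
# linked-sequence mode (msprime adapter)
# ---------------------------------------------------------------------------


def _linked_genotypes(scenario: Scenario, seed: int):
    """msprime backend: genotype matrix (S, 8) and float positions."""
    import msprime

    L = scenario.region_length
    epochs = scenario.effective_epochs
    demography = msprime.Demography.isolated_model([epochs[0][1]])
    for start, N in epochs[1:]:
        demography.add_population_parameters_change(time=start, initial_size=N)

    kw = dict(
        samples=scenario.n_diploids,
        demography=demography,
        sequence_length=L,
        recombination_rate=scenario.r,
        random_seed=int(seed) % (2**31 - 1) + 1,
    )
    if scenario.kind == "sweep":
        N0 = epochs[0][1]
        sweep = msprime.SweepGenicSelection(
            position=L / 2,
            start_frequency=1.0 / (2 * N0),
            end_frequency=1.0 - 1.0 / (2 * N0),
            s=scenario.s,
            dt=1e-6,
        )
        kw["model"] = [
            msprime.StandardCoalescent(duration=scenario.sweep_time_generations),
            sweep,
            msprime.StandardCoalescent(),
        ]
    ts = msprime.sim_ancestry(**kw)
    ts = msprime.sim_mutations(
        ts, rate=scenario.mu, random_seed=int(seed) % (2**31 - 1) + 7,
        model=msprime.BinaryMutationModel(), discrete_genome=False,
    )
    G = ts.genotype_matrix()  # (S, 8)
    pos = np.array([s.position for s in ts.sites()])
    return G, pos


def simulate_linked_variants(scenario: Scenario, seed: int = 1,
                             chrom: str = "chr_sim"):
    """Simulate a recombining sequence and return per-site subset counts.

    Returns a :class:`~fusesweep.blocks.VariantTable` suitable for
    :func:`~fusesweep.blocks.build_blocks`, chromosome scans and fusion
    fits.  Continuous mutation positions are floored to integer base
    coordinates; the rare collisions are dropped.
    """
    from .blocks import VariantTable

    G, pos = _linked_genotypes(scenario, seed)
    ipos = np.floor(pos).astype(np.int64)
    keep = np.concatenate([[True], np.diff(ipos) > 0])
    G, ipos = G[keep], ipos[keep]
    counts = np.empty((len(ipos), N_SUBSETS), dtype=np.int64)
    for j in range(N_SUBSETS):
        hap = np.delete(np.arange(_N_HAP), [2 * j, 2 * j + 1])
        counts[:, j] = G[:, hap].sum(axis=1)
    return VariantTable(np.array([chrom] * len(ipos), dtype=object),
                        ipos + 1, counts)


def simulate_linked_blockset(
    scenario: Scenario,
    block_length_l: int | None = None,
    seed: int = 1,
    *,
    chrom: str = "chr_sim",
) -> BlockSet:
    """Simulate one recombining sequence with msprime and block it.

    Unlike :func:`simulate_blockset`, blocks here share genealogies
    through linkage, as in real data.  The sweep kind uses msprime's
    genic-selection sweep model sandwiched between neutral phases, an
    approximation to the discrete-event model used for inference.
    """
    if block_length_l is None:
        block_length_l = expected_block_length(scenario.theta_site)
    L = scenario.region_length
    G, pos = _linked_genotypes(scenario, seed)
    n_blocks = L // block_length_l
    acc = np.zeros((n_blocks, N_SUBSETS, 3), dtype=np.int64)
    block_of = (pos // block_length_l).astype(np.int64)
    keep = block_of < n_blocks
    G, block_of = G[keep], block_of[keep]
    for j in range(N_SUBSETS):
        hap = np.delete(np.arange(_N_HAP), [2 * j, 2 * j + 1])
        cnt = G[:, hap].sum(axis=1)
        fold = np.minimum(cnt, 6 - cnt)
        for cls in (1, 2, 3):
            np.add.at(acc[:, j, cls - 1], block_of[fold == cls], 1)
    return _blockset_from_counts(acc, scenario, block_length_l, L / 2.0, chrom)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_fixture_vcf(
    blocks: BlockSet,
    sites: SiteTable,
    vcf_path,
    mask_bed_path,
    exon_bed_path=None,
    *,
    region_length: int | None = None,
    sample_names=("dip0", "dip1", "dip2", "dip3"),
    decoy_exons=(),
    seed: int = 0,
) -> None:
    """Write a simulated block set as a plain-text VCF plus BED tracks.

    Mutations are placed at distinct positions inside their block, so
    re-reading the fixture through the block-building pipeline reproduces
    the generating configurations exactly.  ``decoy_exons`` optionally
    adds (position, genotype-bitmask) SNPs inside the exon track, which a
    correct loader must remove.
    """
    rng = np.random.default_rng(seed)
    l = blocks.block_length_l
    region_length = region_length or int(blocks.end.max())
    chrom = blocks.chrom

    pos_list, bm_list = [], []
    order = np.argsort(sites.block, kind="stable")
    sblock, sbm = sites.block[order], sites.bitmask[order]
    for b in np.unique(sblock):
        rows = sblock == b
        nmut = int(rows.sum())
        offs = rng.choice(l, size=min(nmut, l), replace=False)
        offs.sort()
        pos_list.append(b * l + offs)
        bm_list.append(sbm[rows][: len(offs)])
    pos = np.concatenate(pos_list) if pos_list else np.array([], dtype=np.int64)
    bm = np.concatenate(bm_list) if bm_list else np.array([], dtype=np.uint8)

    exon_iv = [(int(a), int(b)) for a, b, *_ in decoy_exons] if decoy_exons else []
    decoy_rows = []
    for iv in decoy_exons:
        a, b, mask = int(iv[0]), int(iv[1]), int(iv[2]) if len(iv) > 2 else 0b01010101
        p = (a + b) // 2
        decoy_rows.append((p, np.uint8(mask)))

    allpos = np.concatenate([pos, np.array([p for p, _ in decoy_rows], dtype=np.int64)])
    allbm = np.concatenate([bm, np.array([m for _, m in decoy_rows], dtype=np.uint8)])
    o = np.argsort(allpos, kind="stable")
    allpos, allbm = allpos[o], allbm[o]

    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=region_length,
                                    samples="\t".join(sample_names)))
        for p, m in zip(allpos, allbm):
            gts = []
            for dip in range(4):
                a = (int(m) >> (2 * dip)) & 1
                b = (int(m) >> (2 * dip + 1)) & 1
                gts.append(f"{a}/{b}")
            fh.write(f"{chrom}\t{p + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t" +
                     "\t".join(gts) + "\n")

    with open(mask_bed_path, "w") as fh:
        fh.write(f"{chrom}\t0\t{region_length}\n")
    if exon_bed_path is not None:
        with open(exon_bed_path, "w") as fh:
            for a, b in exon_iv:
                fh.write(f"{chrom}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# power / false-positive experiments
# ---------------------------------------------------------------------------


@dataclass
class PowerSummary:
    """Per-replicate sweep fits for one scenario plus aggregates."""

    scenario: Scenario
    table: pd.DataFrame
    aggregates: dict = field(default_factory=dict)

    def recompute_aggregates(self) -> dict:
        t = self.table
        q = np.percentile(t["theta_hat"], [25, 50, 75])
        agg = {
            "median_delta": float(t["delta"].median()),
            "max_delta": float(t["delta"].max()),
            "min_delta": float(t["delta"].min()),
            "theta_quartiles": (float(q[0]), float(q[1]), float(q[2])),
            "median_Ta": float(t["Ta_hat"].median()),
            "median_log10_alpha": float(t["log10_alpha_hat"].median()),
            "frac_classified": float(t["classified"].mean()),
            "n_nonconverged": int((~t["converged"]).sum()),
        }
        return agg


_SCENARIOS = {
    "strong_sweep": strong_sweep_scenario,
    "neutral": neutral_scenario,
    "demographic": bottleneck_scenario,
}


def power_experiment(
    scenario="strong_sweep",
    n_replicates: int = 100,
    seed: int = 0,
    *,
    block_length_l: int | None = None,
    phi_m: int = 100_000,
    neutral_m: int = 50_000,
    ta_grid=None,
    linked: bool = True,
) -> PowerSummary:
    """Replicate the simulation-calibration experiment for one scenario.

    Each replicate simulates a region (1 Mb by default) for four diploids,
    fits the neutral and sweep models at the region centre and records the
    estimates; aggregates summarize power (sweep scenario) or the
    false-positive calibration (neutral / demographic scenarios).  By
    default replicates are linked recombining sequences (msprime), as in
    the original calibration; ``linked=False`` instead draws independent
    per-block genealogies from the inference model itself.
    """
    from .scan import classify_sweep
    from .sweep import DEFAULT_TA_GRID, fit_neutral, fit_sweep

    if isinstance(scenario, str):
        scenario = _SCENARIOS[scenario]()
    if ta_grid is None:
        ta_grid = DEFAULT_TA_GRID
    ss = np.random.SeedSequence(seed)
    phi_seed = int(ss.generate_state(1)[0] % 2**31)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_replicates)]

    rows = []
    for i, rs in enumerate(rep_seeds):
        if linked:
            blocks = simulate_linked_blockset(scenario, block_length_l, seed=rs)
        else:
            blocks = simulate_blockset(scenario, block_length_l=block_length_l,
                                       seed=rs)
        f0 = fit_neutral(blocks, neutral_m=neutral_m, neutral_seed=phi_seed)
        f1 = fit_sweep(blocks, ta_grid=ta_grid, phi_m=phi_m, phi_seed=phi_seed)
        rows.append(
            {
                "replicate": i,
                "seed": rs,
                "theta_hat": f1.params["theta_block"],
                "log10_alpha_hat": f1.params["log10_alpha"],
                "Ta_hat": f1.params["T_a"],
                "delta": f1.delta_lnCL_per_block,
                "lnCL_neutral": f0.lnCL,
                "lnCL_sweep": f1.lnCL,
                "theta_neutral_hat": f0.params["theta_block"],
                "classified": classify_sweep(f1),
                "converged": f1.converged and f0.converged,
                "n_observations": f1.n_observations,
            }
        )
    table = pd.DataFrame(rows)
    summary = PowerSummary(scenario=scenario, table=table)
    summary.aggregates = summary.recompute_aggregates()
    return summary
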