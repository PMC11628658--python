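"""Build folded six-lineage mutation configurations from variant data.

The unit of observation is a *block*: a run of exactly ``l`` callable sites
(fixed callable length, not fixed physical span, so blocks are robust to
masked gaps).  For four unphased diploids there are four ways to sample
three diploids (= six genomes); each block therefore yields four
observations, one per leave-one-out subset.  Within a subset a SNP with
alternate-allele count c (0..6) belongs to folded class min(c, 6 - c);
per-block class counts are capped at k_max = 2, larger counts collapsing
into the overflow category MORE ("3+" in the tabular output).

Coordinates: BED inputs are 0-based half-open; VCF positions are 1-based.
All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import CONFIGS, KMAX, MORE

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "BlockSet",
    "Intervals",
    "load_bed",
    "exons_from_gff",
    "load_filtered_sites",
    "choose_block_length",
    "expected_block_length",
    "build_blocks",
    "N_SUBSETS",
]

#: leave-one-out subsets of four diploids; subset j excludes diploid j
N_SUBSETS = 4
_N_LINEAGES = 6

#: harmonic number H_{n-1} for n = 6: E[S per block] = theta_site * l * H_5
_H5 = sum(1.0 / i for i in range(1, _N_LINEAGES))


# ---------------------------------------------------------------------------
# interval tracks
# ---------------------------------------------------------------------------


class Intervals:
    """Sorted, merged, 0-based half-open intervals keyed by chromosome."""

    def __init__(self, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self._by_chrom = by_chrom or {}

    @classmethod
    def from_records(cls, records) -> "Intervals":
        """records: iterable of (chrom, start, end)."""
        acc: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            acc.setdefault(str(chrom), []).append((int(start), int(end)))
        by_chrom = {}
        for chrom, ivs in acc.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.array(merged, dtype=np.int64).reshape(-1, 2)
            by_chrom[chrom] = (arr[:, 0], arr[:, 1])
        return cls(by_chrom)

    def pad(self, pad: int) -> "Intervals":
        recs = []
        for chrom, (s, e) in self._by_chrom.items():
            for a, b in zip(s, e):
                recs.append((chrom, max(0, a - pad), b + pad))
        return Intervals.from_records(recs)

    def contains(self, chrom: str, pos0) -> np.ndarray:
        """Membership of 0-based positions (vectorized)."""
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        if chrom not in self._by_chrom:
            return np.zeros(len(pos0), dtype=bool)
        starts, ends = self._by_chrom[chrom]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < ends[idx[ok]]
        return ok

    def positions(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """All covered 0-based positions within [lo, hi)."""
        if chrom not in self._by_chrom:
            return np.array([], dtype=np.int64)
        starts, ends = self._by_chrom[chrom]
        chunks = []
        for s, e in zip(starts, ends):
            a, b = max(s, lo), min(e, hi)
            if a < b:
                chunks.append(np.arange(a, b, dtype=np.int64))
        if not chunks:
            return np.array([], dtype=np.int64)
        return np.concatenate(chunks)

    def chroms(self):
        return list(self._by_chrom)

    def span(self, chrom: str) -> tuple[int, int]:
        s, e = self._by_chrom[chrom]
        return int(s[0]), int(e[-1])


def load_bed(path) -> Intervals:
    """Read a BED file (first three columns) into an interval track."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return Intervals.from_records(df.itertuples(index=False))

def exons_from_gff(path) -> Intervals:
    """Extract exon intervals from a GFF3 file (optional exon source)."""
    recs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 5 and f[2].lower() == "exon":
                # GFF is 1-based closed; convert to 0-based half-open
                recs.append((f[0], int(f[3]) - 1, int(f[4])))
    return Intervals.from_records(recs)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Filtered biallelic SNPs with per-subset alternate-allele counts.

    ``alt_counts[i, j]`` is the number of alternate alleles among the six
    genomes of subset j (the three diploids excluding diploid j) at site i.
    Positions are 1-based, strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    alt_counts: np.ndarray  # (n_sites, 4), values 0..6
    n_dropped_missing: int = 0
    n_dropped_multiallelic: int = 0

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        if self.alt_counts.min(initial=0) < 0 or self.alt_counts.max(initial=0) > 6:
            raise ValueError("alt counts must lie in [0, 6]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def for_chromosome(self, chrom: str) -> "VariantTable":
        m = self.chrom == chrom
        return VariantTable(self.chrom[m], self.pos[m], self.alt_counts[m])


def load_filtered_sites(
    vcf_path,
    sample_ids,
    exclude_track: Intervals | None = None,
    callable_mask: Intervals | None = None,
    *,
    exon_pad: int = 10,
    chrom: str | None = None,
    max_het_frac: float | None = None,
) -> VariantTable:
    """Read biallelic SNPs for four diploids from a VCF, applying filters.

    Retains sites that are biallelic SNPs, genotyped in all four diploids,
    inside ``callable_mask`` and outside ``exclude_track`` padded by
    ``exon_pad`` bases (exonic sequence plus a margin; variation is then
    intronic or intergenic only).  Sites with a missing genotype are
    dropped and counted; ``max_het_frac`` optionally re-applies the
    upstream excess-heterozygosity filter (off by default, as production
    VCFs arrive with it already applied).
    """
    from cyvcf2 import VCF

    sample_ids = list(sample_ids)
    if len(sample_ids) != 4:
        raise ValueError("exactly four diploid sample ids are required")
    vcf = VCF(str(vcf_path), gts012=False)
    missing = [s for s in sample_ids if s not in vcf.samples]
    if missing:
        raise ValueError(f"samples missing from VCF: {missing}")
    cols = [vcf.samples.index(s) for s in sample_ids]
    excl = exclude_track.pad(exon_pad) if exclude_track is not None else None

    chroms, poss, counts = [], [], []
    n_missing = n_multi = 0
    for v in vcf:
        if chrom is not None and v.CHROM != chrom:
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            n_multi += 1
            continue
        pos0 = v.POS - 1
        if callable_mask is not None and not callable_mask.contains(v.CHROM, pos0)[0]:
            continue
        if excl is not None and excl.contains(v.CHROM, pos0)[0]:
            continue
        gts = v.genotypes
        dip = np.empty(4, dtype=np.int64)
        ok = True
        n_het = 0
        for j, c in enumerate(cols):
            a, b = gts[c][0], gts[c][1]
            if a < 0 or b < 0:
                ok = False
                break
            dip[j] = a + b
            n_het += a != b
        if not ok:
            n_missing += 1
            continue
        if max_het_frac is not None and n_het / 4 > max_het_frac:
            continue
        total = dip.sum()
        chroms.append(v.CHROM)
        poss.append(v.POS)
        counts.append(total - dip)  # subset j excludes diploid j
    if n_missing:
        logger.info("dropped %d sites with missing genotypes", n_missing)
    tab = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(counts, dtype=np.int64).reshape(-1, 4),
        n_dropped_missing=n_missing,
        n_dropped_multiallelic=n_multi,
    )
    tab.validate()
    return tab


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------


def choose_block_length(
    total_segsites: int, total_callable: int, target_segsites: float = 1.5
) -> int:
    """Block length so that the average block holds ``target_segsites`` SNPs."""
    if total_callable <= 0:
        raise ValueError("total_callable must be positive")
    if total_segsites <= 0:
        raise ValueError("monomorphic region: cannot size blocks")
    return max(1, round(target_segsites * total_callable / total_segsites))


def expected_block_length(theta_site: float, target_segsites: float = 1.5) -> int:
    """Block length from the per-site mutation rate via E[S] = theta*l*H_5."""
    if theta_site <= 0:
        raise ValueError("theta_site must be positive")
    return max(1, round(target_segsites / (theta_site * _H5)))


@dataclass
class BlockSet:
    """Folded block configurations around a test point.

    One row per (subset, block); ``config_idx`` encodes the capped folded
    configuration (n1, n2, n3) as n1*16 + n2*4 + n3 with MORE = 3.
    ``distance`` is |block midpoint - test_point| in bases.
    """

    chrom: str
    test_point: float
    block_length_l: int
    subset_id: np.ndarray
    start: np.ndarray
    end: np.ndarray
    midpoint: np.ndarray
    distance: np.ndarray
    config_idx: np.ndarray

    @property
    def n_observations(self) -> int:
        return len(self.config_idx)

    @property
    def n_blocks(self) -> int:
        return int(self.n_observations // N_SUBSETS)

    def configs(self) -> np.ndarray:
        """(n_observations, 3) folded class counts with MORE encoded as 3."""
        return CONFIGS[self.config_idx]

    def segregating_sites(self) -> np.ndarray:
        """Lower bound on segregating sites per observation (MORE counts as 3)."""
        return self.configs().sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        cfg = self.configs().astype(object)
        cfg[cfg == MORE] = f"{KMAX}+"
        return pd.DataFrame(
            {
                "subset_id": self.subset_id,
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "midpoint": self.midpoint,
                "distance": self.distance,
                "n1": cfg[:, 0],
                "n2": cfg[:, 1],
                "n3": cfg[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#chrom={self.chrom}\t#test_point={self.test_point}\t"
                     f"#block_length={self.block_length_l}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BlockSet":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(kv.lstrip("#").split("=") for kv in header.split("\t"))
            df = pd.read_csv(fh, sep="\t")

        def decode(col):
            return np.where(df[col].astype(str) == f"{KMAX}+", MORE,
                            pd.to_numeric(df[col], errors="coerce")).astype(np.int64)

        n1, n2, n3 = decode("n1"), decode("n2"), decode("n3")
        return cls(
            chrom=meta["chrom"],
            test_point=float(meta["test_point"]),
            block_length_l=int(meta["block_length"]),
            subset_id=df["subset_id"].to_numpy(),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            midpoint=df["midpoint"].to_numpy(dtype=float),
            distance=df["distance"].to_numpy(dtype=float),
            config_idx=n1 * 16 + n2 * 4 + n3,
        )


def build_blocks(
    variants: VariantTable,
    callable_mask: Intervals,
    test_point: float,
    block_length_l: int,
    window: int = 1_000_000,
    *,
    exclude_track: Intervals | None = None,
    exon_pad: int = 10,
    chrom: str | None = None,
) -> BlockSet:
    """Cut the window around a test point into fixed-callable-length blocks.

    Blocks are consecutive runs of exactly ``block_length_l`` callable
    (and non-excluded) sites; the trailing partial run is discarded.  Each
    block yields one observation per diploid subset.
    """
    if block_length_l < 1:
        raise ValueError("block_length_l must be >= 1")
    if chrom is None:
        uniq = np.unique(variants.chrom)
        if len(uniq) > 1:
            raise ValueError("multiple chromosomes present; pass chrom=")
        chrom = str(uniq[0]) if len(uniq) else callable_mask.chroms()[0]

    lo = int(test_point - window / 2)
    hi = int(test_point + window / 2)
    if lo < 0:
        logger.warning("window truncated at chromosome start")
        lo = 0
    excl = exclude_track.pad(exon_pad) if exclude_track is not None else None
    positions = callable_mask.positions(chrom, lo, hi)
    if excl is not None and len(positions):
        positions = positions[~excl.contains(chrom, positions)]
    n_blocks = len(positions) // block_length_l
    if n_blocks == 0:
        raise ValueError("window contains no complete block")
    used = positions[: n_blocks * block_length_l].reshape(n_blocks, block_length_l)
    starts = used[:, 0]
    ends = used[:, -1] + 1
    mids = 0.5 * (starts + ends)

    # assign retained SNPs to blocks via their rank among callable positions
    vt = variants.for_chromosome(chrom)
    inw = (vt.pos - 1 >= lo) & (vt.pos - 1 < hi)
    pos0 = vt.pos[inw] - 1
    alt = vt.alt_counts[inw]
    rank = np.searchsorted(positions, pos0)
    onmask = (rank < len(positions)) & (positions[np.minimum(rank, len(positions) - 1)] == pos0)
    if not np.all(onmask):
        logger.info("%d SNPs fall outside callable/non-excluded sites; skipped",
                    int((~onmask).sum()))
    rank, alt = rank[onmask], alt[onmask]
    block_of = rank // block_length_l
    keep = block_of < n_blocks
    block_of, alt = block_of[keep], alt[keep]

    counts = np.zeros((n_blocks, N_SUBSETS, 3), dtype=np.int64)
    folded = np.minimum(alt, _N_LINEAGES - alt)  # (S, 4)
    for cls in (1, 2, 3):
        for j in range(N_SUBSETS):
            np.add.at(counts[:, j, cls - 1], block_of[folded[:, j] == cls], 1)
    capped = np.minimum(counts, MORE)
    cfg = capped[:, :, 0] * 16 + capped[:, :, 1] * 4 + capped[:, :, 2]  # (B, 4)

    subset_id = np.repeat(np.arange(N_SUBSETS), n_blocks)
    return BlockSet(
        chrom=chrom,
        test_point=float(test_point),
        block_length_l=int(block_length_l),
        subset_id=subset_id,
        start=np.tile(starts, N_SUBSETS),
        end=np.tile(ends, N_SUBSETS),
        midpoint=np.tile(mids, N_SUBSETS),
        distance=np.abs(np.tile(mids, N_SUBSETS) - float(test_point)),
        config_idx=cfg.T.reshape(-1),
    )
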