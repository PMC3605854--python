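"""Summary statistics computed identically on observed and simulated data.

The panel mirrors the usual population-genetic diversity table: for mtDNA,
haplotype counts/diversity, nucleotide diversity, mean pairwise differences,
segregating sites, Tajima's D and pairwise Hudson F_ST; for microsatellites,
allele counts, allelic range, the Garza-Williamson M ratio, unbiased gene
diversity / expected heterozygosity, pairwise Weir-Cockerham F_ST and the
Goldstein (δμ)² distance.

Missing-data conventions: alignment sites containing any non-ACGT symbol are
excluded per pair (pairwise deletion) for distance-based statistics and
excluded completely (complete deletion) for segregating sites and Tajima's
D; STR alleles coded -1 are missing and dropped per locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DatasetBundle, PopPartition, SequenceAlignment, STRDataset

__all__ = [
    "UndefinedStatisticError",
    "haplotype_stats",
    "pairwise_diff_stats",
    "segregating_sites",
    "tajimas_d",
    "pairwise_fst_seq",
    "str_locus_stats",
    "delta_mu_sq",
    "pairwise_fst_str",
    "SummaryConfig",
    "summary_vector",
    "summary_table",
]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for the given input (too few copies, no
    segregating sites, ...)."""


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

def _pair_distances(aln: SequenceAlignment) -> np.ndarray:
    """Hamming distances over all unordered pairs (pairwise deletion)."""
    m = aln.matrix
    n = m.shape[0]
    valid = m < 4
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        vi = valid[i]
        mi = m[i]
        both = vi & valid[i + 1 :]
        diff = (mi != m[i + 1 :]) & both
        out[k : k + n - 1 - i] = diff.sum(axis=1)
        k += n - 1 - i
    return out


def haplotype_stats(aln: SequenceAlignment) -> tuple[int, float]:
    """Number of distinct haplotypes and unbiased haplotype diversity
    H = n(1 - Σ p_i²)/(n - 1)."""
    n = aln.n
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs >= 2 copies")
    from collections import Counter

    counts = np.array(
        list(Counter(aln.matrix[i].tobytes() for i in range(n)).values())
    )
    p = counts / n
    H = n * (1.0 - np.sum(p**2)) / (n - 1)
    return int(len(counts)), float(H)


def pairwise_diff_stats(aln: SequenceAlignment) -> tuple[float, float]:
    """Mean pairwise differences Π and nucleotide diversity π = Π/L."""
    if aln.n < 2:
        raise UndefinedStatisticError("pairwise differences need >= 2 copies")
    d = _pair_distances(aln)
    pi_count = float(d.mean())
    return pi_count, pi_count / aln.n_sites


def segregating_sites(aln: SequenceAlignment) -> int:
    """Number of segregating sites under complete deletion of non-ACGT sites."""
    m = aln.matrix
    keep = (m < 4).all(axis=0)
    mm = m[:, keep]
    if mm.shape[0] < 2:
        raise UndefinedStatisticError("segregating sites need >= 2 copies")
    return int(np.sum((mm != mm[0]).any(axis=0)))


def tajimas_d(aln: SequenceAlignment) -> float:
    """Tajima's (1989) D from Π and S with the standard constants.

    Raises UndefinedStatisticError when S = 0 (the variance term vanishes).
    """
    n = aln.n
    if n < 4:
        raise UndefinedStatisticError("Tajima's D needs >= 4 copies")
    m = aln.matrix
    keep = (m < 4).all(axis=0)
    mm = m[:, keep]
    S = int(np.sum((mm != mm[0]).any(axis=0)))
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined with no segregating sites")
    # Π on the completely-deleted alignment, consistent with S
    sub = SequenceAlignment(aln.names, aln.pops, mm)
    Pi = float(_pair_distances(sub).mean())
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((Pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


def pairwise_fst_seq(alnA: SequenceAlignment, alnB: SequenceAlignment) -> float:
    """Hudson-style sequence F_ST = 1 - Hw/Hb.

    Hw is the mean of the two within-population mean pairwise differences,
    Hb the mean between-population pairwise difference; returns 0 when
    Hb = 0 (identical monomorphic populations).
    """
    if alnA.n < 2 or alnB.n < 2:
        raise UndefinedStatisticError("sequence F_ST needs >= 2 copies per population")
    hw = 0.5 * (_pair_distances(alnA).mean() + _pair_distances(alnB).mean())
    a, b = alnA.matrix, alnB.matrix
    va, vb = a < 4, b < 4
    total = 0.0
    for i in range(a.shape[0]):
        both = va[i] & vb
        total += float(((a[i] != b) & both).sum())
    hb = total / (a.shape[0] * b.shape[0])
    if hb == 0:
        return 0.0
    return float(1.0 - hw / hb)


# ---------------------------------------------------------------------------
# Microsatellite statistics
# ---------------------------------------------------------------------------

def _locus_columns(block: np.ndarray):
    """Yield per-locus allele vectors with missing (-1) entries dropped."""
    for j in range(block.shape[1]):
        col = block[:, j]
        yield col[col >= 0]


@dataclass
class STRPopStats:
    mean_n_alleles: float
    sd_n_alleles: float
    mean_allelic_range: float
    sd_allelic_range: float
    garza_williamson: float
    sd_garza_williamson: float
    mean_genic_diversity: float
    sd_genic_diversity: float
    expected_heterozygosity: float
    sd_expected_heterozygosity: float
    n_polymorphic_loci: int


def str_locus_stats(dataset: STRDataset, population: str) -> STRPopStats:
    """Per-population means/SDs of the per-locus microsatellite panel.

    Per locus: allele count k, allelic range r = max - min (repeat units),
    Garza-Williamson M = k/(r + 1) and unbiased gene diversity
    n(1 - Σ p_i²)/(n - 1).  Means are over ALL typed loci (monomorphic loci
    included; M = 1 and diversity 0 there); expected heterozygosity averages
    gene diversity over polymorphic loci only.  The polymorphic-locus count
    is reported separately.
    """
    block = dataset.by_population(population)
    if block.shape[0] < 2:
        raise UndefinedStatisticError(
            f"STR statistics need >= 2 gene copies in population {population!r}"
        )
    ks, ranges, Ms, divs = [], [], [], []
    for col in _locus_columns(block):
        if col.size < 2:
            continue
        vals, counts = np.unique(col, return_counts=True)
        k = len(vals)
        r = int(vals.max() - vals.min())
        nn = col.size
        p = counts / nn
        div = nn * (1.0 - np.sum(p**2)) / (nn - 1)
        ks.append(k)
        ranges.append(r)
        Ms.append(k / (r + 1.0))
        divs.append(div)
    if not ks:
        raise UndefinedStatisticError("no typed loci")
    ks = np.array(ks, float)
    ranges = np.array(ranges, float)
    Ms = np.array(Ms)
    divs = np.array(divs)
    poly = ks > 1
    het = float(divs[poly].mean()) if poly.any() else 0.0
    sd_het = float(divs[poly].std(ddof=1)) if poly.sum() > 1 else 0.0
    sd = lambda x: float(x.std(ddof=1)) if x.size > 1 else 0.0
    return STRPopStats(
        mean_n_alleles=float(ks.mean()),
        sd_n_alleles=sd(ks),
        mean_allelic_range=float(ranges.mean()),
        sd_allelic_range=sd(ranges),
        garza_williamson=float(Ms.mean()),
        sd_garza_williamson=sd(Ms),
        mean_genic_diversity=float(divs.mean()),
        sd_genic_diversity=sd(divs),
        expected_heterozygosity=het,
        sd_expected_heterozygosity=sd_het,
        n_polymorphic_loci=int(poly.sum()),
    )


def delta_mu_sq(dataset: STRDataset, pop1: str, pop2: str) -> float:
    """Goldstein (δμ)²: mean over shared loci of the squared difference in
    mean allele size."""
    b1 = dataset.by_population(pop1)
    b2 = dataset.by_population(pop2)
    vals = []
    for j in range(dataset.n_loci):
        c1 = b1[:, j]
        c2 = b2[:, j]
        c1 = c1[c1 >= 0]
        c2 = c2[c2 >= 0]
        if c1.size == 0 or c2.size == 0:
            continue
        vals.append((c1.mean() - c2.mean()) ** 2)
    if not vals:
        raise UndefinedStatisticError("no shared typed loci")
    return float(np.mean(vals))


def pairwise_fst_str(dataset: STRDataset, pop1: str, pop2: str) -> float:
    """Weir-Cockerham-style F_ST over loci for gene-copy (haploid) data.

    Per allele per locus, variance components between (MSP) and within
    (MSG) populations are accumulated; the estimator is the multi-locus
    ratio of sums θ = Σ(MSP - MSG) / Σ(MSP + (n_c - 1) MSG).  Returns 0
    when the total variance is 0 (identical monomorphic populations).
    """
    b1 = dataset.by_population(pop1)
    b2 = dataset.by_population(pop2)
    if b1.shape[0] < 2 or b2.shape[0] < 2:
        raise UndefinedStatisticError("STR F_ST needs >= 2 copies per population")
    num = 0.0
    den = 0.0
    r = 2
    for j in range(dataset.n_loci):
        c1 = b1[:, j]
        c2 = b2[:, j]
        c1 = c1[c1 >= 0]
        c2 = c2[c2 >= 0]
        n1, n2 = c1.size, c2.size
        if n1 < 2 or n2 < 2:
            continue
        ntot = n1 + n2
        nc = (ntot - (n1**2 + n2**2) / ntot) / (r - 1)
        alleles = np.unique(np.concatenate([c1, c2]))
        for al in alleles:
            p1 = np.mean(c1 == al)
            p2 = np.mean(c2 == al)
            pbar = (n1 * p1 + n2 * p2) / ntot
            msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - r)
            num += msp - msg
            den += msp + (nc - 1) * msg
    if den == 0:
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------------
# Summary vectors for ABC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryConfig:
    """Which statistics enter the ABC summary vector.

    ``per_pop_mt`` / ``per_pop_str`` are statistic names computed for every
    population; ``pairwise_mt`` / ``pairwise_str`` for every population
    pair.  The default subset spans the diversity table: haplotype counts,
    mean pairwise differences, segregating sites and Tajima's D for mtDNA;
    allele counts, expected heterozygosity, allelic range and the
    Garza-Williamson M for STRs; plus pairwise F_ST (both markers) and
    (δμ)².
    """

    per_pop_mt: tuple[str, ...] = ("n_haplotypes", "mean_pairwise_diff", "seg_sites", "tajimas_d")
    per_pop_str: tuple[str, ...] = (
        "mean_n_alleles",
        "expected_heterozygosity",
        "mean_allelic_range",
        "garza_williamson",
    )
    pairwise_mt: tuple[str, ...] = ("fst_mt",)
    pairwise_str: tuple[str, ...] = ("fst_str", "delta_mu_sq")
    populations: tuple[str, ...] | None = None  # None = all, sorted
    pairs: tuple[tuple[str, str], ...] | None = None  # None = all pairs
    tajima_undefined_value: float = 0.0
    """Value recorded when Tajima's D is undefined (monomorphic sample) so
    simulated vectors keep a fixed length."""

    def names(self, populations: Sequence[str], pairs: Sequence[tuple[str, str]]) -> list[str]:
        out = []
        for p in populations:
            out += [f"{s}[{p}]" for s in self.per_pop_mt]
        for p in populations:
            out += [f"{s}[{p}]" for s in self.per_pop_str]
        for a, b in pairs:
            out += [f"{s}[{a},{b}]" for s in self.pairwise_mt]
        for a, b in pairs:
            out += [f"{s}[{a},{b}]" for s in self.pairwise_str]
        return out


_MT_SINGLE = {"n_haplotypes", "haplotype_diversity", "mean_pairwise_diff",
              "nucleotide_diversity", "seg_sites", "tajimas_d"}
_STR_SINGLE = {"mean_n_alleles", "mean_allelic_range", "garza_williamson",
               "mean_genic_diversity", "expected_heterozygosity", "n_polymorphic_loci"}


def _mt_single(aln: SequenceAlignment, stat: str, cfg: SummaryConfig) -> float:
    if stat == "n_haplotypes":
        return float(haplotype_stats(aln)[0])
    if stat == "haplotype_diversity":
        return haplotype_stats(aln)[1]
    if stat == "mean_pairwise_diff":
        return pairwise_diff_stats(aln)[0]
    if stat == "nucleotide_diversity":
        return pairwise_diff_stats(aln)[1]
    if stat == "seg_sites":
        return float(segregating_sites(aln))
    if stat == "tajimas_d":
        try:
            return tajimas_d(aln)
        except UndefinedStatisticError:
            return cfg.tajima_undefined_value
    raise KeyError(stat)


def _str_single(stats_: STRPopStats, stat: str) -> float:
    return float(getattr(stats_, stat if stat != "n_polymorphic_loci" else "n_polymorphic_loci"))


def summary_vector(
    bundle: DatasetBundle,
    partition: PopPartition | None = None,
    config: SummaryConfig | None = None,
) -> pd.Series:
    """The ordered, named summary-statistic vector for one dataset.

    Deterministic: the same bundle + config always yields the same names in
    the same order and the same values.
    """
    config = config or SummaryConfig()
    if partition is None:
        pops = (
            list(config.populations)
            if config.populations
            else sorted(set(bundle.mt.pops) | set(bundle.strs.pops))
        )
        partition = PopPartition.from_labels(pops)
        if config.pairs is not None:
            partition.pairs = [tuple(p) for p in config.pairs]
    pops = list(partition.labels)
    pairs = list(partition.pairs)

    for s in config.per_pop_mt:
        if s not in _MT_SINGLE:
            raise KeyError(f"unknown mtDNA statistic {s!r}")
    for s in config.per_pop_str:
        if s not in _STR_SINGLE:
            raise KeyError(f"unknown STR statistic {s!r}")
    for s in config.pairwise_mt:
        if s != "fst_mt":
            raise KeyError(f"unknown pairwise mtDNA statistic {s!r}")
    for s in config.pairwise_str:
        if s not in ("fst_str", "delta_mu_sq"):
            raise KeyError(f"unknown pairwise STR statistic {s!r}")

    values: list[float] = []
    mt_by_pop = {p: bundle.mt.by_population(p) for p in pops} if config.per_pop_mt or config.pairwise_mt else {}
    for p in pops:
        for s in config.per_pop_mt:
            values.append(_mt_single(mt_by_pop[p], s, config))
    str_stats = {}
    if config.per_pop_str:
        for p in pops:
            str_stats[p] = str_locus_stats(bundle.strs, p)
        for p in pops:
            for s in config.per_pop_str:
                values.append(_str_single(str_stats[p], s))
    # reorder: per-pop str values were appended pop-major above already
    for a, b in pairs:
        for s in config.pairwise_mt:
            values.append(pairwise_fst_seq(mt_by_pop[a], mt_by_pop[b]))
    for a, b in pairs:
        for s in config.pairwise_str:
            if s == "fst_str":
                values.append(pairwise_fst_str(bundle.strs, a, b))
            else:
                values.append(delta_mu_sq(bundle.strs, a, b))
    names = config.names(pops, pairs)
    return pd.Series(values, index=names, dtype=float)


def summary_table(bundle: DatasetBundle, populations: Sequence[str] | None = None) -> pd.DataFrame:
    """Human-readable per-population diversity table (the full panel)."""
    pops = sorted(set(bundle.mt.pops) | set(bundle.strs.pops)) if populations is None else list(populations)
    rows = {}
    for p in pops:
        aln = bundle.mt.by_population(p)
        row: dict[str, float] = {}
        if aln.n >= 2:
            nh, hd = haplotype_stats(aln)
            Pi, pi = pairwise_diff_stats(aln)
            row.update(
                mt_gene_copies=aln.n,
                n_haplotypes=nh,
                haplotype_diversity=hd,
                mean_pairwise_diff=Pi,
                nucleotide_diversity=pi,
                seg_sites=segregating_sites(aln),
            )
            try:
                row["tajimas_d"] = tajimas_d(aln)
            except UndefinedStatisticError:
                row["tajimas_d"] = float("nan")
        strb = bundle.strs.by_population(p)
        if strb.shape[0] >= 2:
            st = str_locus_stats(bundle.strs, p)
            row.update(
                str_gene_copies=strb.shape[0],
                mean_n_alleles=st.mean_n_alleles,
                mean_allelic_range=st.mean_allelic_range,
                garza_williamson=st.garza_williamson,
                mean_genic_diversity=st.mean_genic_diversity,
                expected_heterozygosity=st.expected_heterozygosity,
                n_polymorphic_loci=st.n_polymorphic_loci,
            )
        rows[p] = row
    return pd.DataFrame(rows).T
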