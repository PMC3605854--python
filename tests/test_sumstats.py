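import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalisle.containers import DatasetBundle, STRDataset
from coalisle.sumstats import (
    SummaryConfig,
    UndefinedStatisticError,
    delta_mu_sq,
    haplotype_stats,
    pairwise_diff_stats,
    pairwise_fst_seq,
    pairwise_fst_str,
    segregating_sites,
    str_locus_stats,
    summary_vector,
    tajimas_d,
)
from tests.conftest import aln_from_strings


# ---------------------------------------------------------------------------
# Brute-force oracles (independent re-implementations used only here)
# ---------------------------------------------------------------------------

def brute_hamming(a: str, b: str) -> int:
    return sum(
        x != y for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
    )


def brute_mean_pairwise(seqs):
    pairs = list(itertools.combinations(seqs, 2))
    return sum(brute_hamming(a, b) for a, b in pairs) / len(pairs)


def brute_haplotype_diversity(seqs):
    n = len(seqs)
    freqs = {}
    for s in seqs:
        freqs[s] = freqs.get(s, 0) + 1
    return n * (1 - sum((k / n) ** 2 for k in freqs.values())) / (n - 1)


def brute_tajimas_d(seqs):
    n = len(seqs)
    L = len(seqs[0])
    S = sum(len({s[j] for s in seqs}) > 1 for j in range(L))
    Pi = brute_mean_pairwise(seqs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (Pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def brute_hudson_fst(popA, popB):
    hw = (brute_mean_pairwise(popA) + brute_mean_pairwise(popB)) / 2
    cross = [brute_hamming(a, b) for a in popA for b in popB]
    hb = sum(cross) / len(cross)
    return 1 - hw / hb if hb else 0.0


def brute_wc_fst_haploid(c1, c2):
    """Weir-Cockerham theta for gene-copy data, two populations, one locus."""
    n1, n2 = len(c1), len(c2)
    ntot = n1 + n2
    r = 2
    nc = (ntot - (n1**2 + n2**2) / ntot) / (r - 1)
    num = den = 0.0
    for al in set(c1) | set(c2):
        p1 = sum(x == al for x in c1) / n1
        p2 = sum(x == al for x in c2) / n2
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - r)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num / den if den else 0.0


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

def test_haplotype_stats_examples():
    aln = aln_from_strings(["AAAA", "AAAA", "TTAA", "GGAA"])  # X,X,Y,Z
    nh, H = haplotype_stats(aln)
    assert nh == 3
    assert H == pytest.approx((4 / 3) * (1 - 0.375), abs=1e-12)

    mono = aln_from_strings(["ACGT"] * 5)
    assert haplotype_stats(mono) == (1, 0.0)

    distinct = aln_from_strings(["AAAA", "AAAT", "AATT", "ATTT", "TTTT"])
    assert haplotype_stats(distinct)[1] == pytest.approx(1.0, abs=1e-12)

    with pytest.raises(UndefinedStatisticError):
        haplotype_stats(aln_from_strings(["AAAA"]))


def test_pairwise_diff_examples(toy_alignment):
    Pi, pi = pairwise_diff_stats(toy_alignment)
    assert Pi == pytest.approx(4 / 3, abs=1e-12)
    assert pi == pytest.approx(1 / 3, abs=1e-12)

    same = aln_from_strings(["ACGT", "ACGT"])
    assert pairwise_diff_stats(same) == (0.0, 0.0)

    opposite = aln_from_strings(["AAAA", "TTTT"])
    assert pairwise_diff_stats(opposite) == (4.0, 1.0)


def test_tajimas_d_matches_oracle():
    seqs = ["AAAAA", "AATAA", "AATGA", "CATGA", "AAAAA"]
    aln = aln_from_strings(seqs)
    assert tajimas_d(aln) == pytest.approx(brute_tajimas_d(seqs), abs=1e-10)


def test_tajimas_d_undefined_without_variation():
    with pytest.raises(UndefinedStatisticError):
        tajimas_d(aln_from_strings(["AAAA"] * 6))


def test_tajimas_d_neutral_mean_near_zero(rng):
    """Under the neutral constant-size coalescent, E[D] is close to 0."""
    from coalisle.coalsim import evolve_sequences, single_population_genealogy
    from coalisle.demography import MutationModelMt

    model = MutationModelMt(
        kappa=2.0, gamma_shape=1.0, prop_invariant=0.0,
        mu_site=5e-6, length=565, n_categories=1,
    )
    vals = []
    while len(vals) < 2_000:
        g = single_population_genealogy(15, [(0.0, 1_000.0)], 1.0, rng)
        aln = evolve_sequences(g, model, rng)
        try:
            vals.append(tajimas_d(aln))
        except UndefinedStatisticError:
            continue
    assert abs(np.mean(vals)) < 0.15


def test_hudson_fst_examples():
    a = aln_from_strings(["AAAA", "AAAT"])
    b = aln_from_strings(["TTTT", "TTTA"])
    assert pairwise_fst_seq(a, b) == pytest.approx(1 - 1 / 3.5, abs=1e-12)
    assert pairwise_fst_seq(a, b) == pytest.approx(
        brute_hudson_fst(["AAAA", "AAAT"], ["TTTT", "TTTA"]), abs=1e-10
    )
    mono = aln_from_strings(["CCCC", "CCCC"])
    assert pairwise_fst_seq(mono, mono) == 0.0
    fixed_a = aln_from_strings(["AAAA", "AAAA"])
    fixed_t = aln_from_strings(["TTTT", "TTTT"])
    assert pairwise_fst_seq(fixed_a, fixed_t) == 1.0


def test_non_acgt_sites_excluded():
    # N at a differing site removes it from the pairwise comparison
    a = aln_from_strings(["ANAA", "AAAA"])
    assert pairwise_diff_stats(a)[0] == 0.0
    # complete deletion for S: column with any N is dropped entirely
    b = aln_from_strings(["ANTA", "AATA", "AACA"])
    assert segregating_sites(b) == 1


# ---------------------------------------------------------------------------
# STR statistics
# ---------------------------------------------------------------------------

def test_str_locus_examples():
    ds = STRDataset(
        [f"c{i}" for i in range(5)],
        ["p"] * 5,
        np.array([[10], [12], [14], [16], [19]]),
    )
    st_ = str_locus_stats(ds, "p")
    assert st_.mean_n_alleles == 5
    assert st_.mean_allelic_range == 9
    assert st_.garza_williamson == pytest.approx(0.5, abs=1e-12)

    mono = STRDataset(["a", "b", "c", "d"], ["p"] * 4, np.array([[7]] * 4))
    sm = str_locus_stats(mono, "p")
    assert sm.garza_williamson == 1.0
    assert sm.mean_genic_diversity == 0.0
    assert sm.n_polymorphic_loci == 0

    two = STRDataset(
        ["a", "b", "c", "d"], ["p"] * 4, np.array([[10], [10], [12], [12]])
    )
    assert str_locus_stats(two, "p").mean_genic_diversity == pytest.approx(
        (4 / 3) * 0.5, abs=1e-12
    )


def test_delta_mu_examples():
    ds = STRDataset(
        ["a", "b", "c", "d"],
        ["p1", "p1", "p2", "p2"],
        np.array([[10, 10], [10, 12], [13, 12], [13, 14]]),
    )
    # locus 1: means 10 vs 13 -> 9; locus 2: 11 vs 13 -> 4; mean 6.5
    assert delta_mu_sq(ds, "p1", "p2") == pytest.approx(6.5, abs=1e-12)
    assert delta_mu_sq(ds, "p1", "p1") == 0.0


def test_wc_fst_examples_and_oracle(toy_str_dataset):
    mono = STRDataset(
        ["a", "b", "c", "d"],
        ["p1", "p1", "p2", "p2"],
        np.array([[10], [10], [10], [10]]),
    )
    assert pairwise_fst_str(mono, "p1", "p2") == 0.0

    fixed = STRDataset(
        ["a", "b", "c", "d"],
        ["p1", "p1", "p2", "p2"],
        np.array([[10], [10], [12], [12]]),
    )
    assert pairwise_fst_str(fixed, "p1", "p2") == pytest.approx(1.0, abs=1e-12)

    # {10:3, 12:1} vs {12:4} on one locus
    ds = STRDataset(
        [f"c{i}" for i in range(8)],
        ["p1"] * 4 + ["p2"] * 4,
        np.array([[10], [10], [10], [12], [12], [12], [12], [12]]),
    )
    expected = brute_wc_fst_haploid([10, 10, 10, 12], [12, 12, 12, 12])
    assert pairwise_fst_str(ds, "p1", "p2") == pytest.approx(expected, abs=1e-10)


def test_missing_alleles_excluded():
    ds = STRDataset(
        ["a", "b", "c", "d"],
        ["p"] * 4,
        np.array([[10], [-1], [12], [12]]),
    )
    st_ = str_locus_stats(ds, "p")
    assert st_.mean_n_alleles == 2  # the missing copy is dropped


def test_gene_diversity_estimates_heterozygosity(rng):
    """Mean unbiased gene diversity over coalescent replicates matches the
    strict-SMM expected heterozygosity 1 - 1/sqrt(1+2*theta) (<2% bias)."""
    from coalisle.coalsim import evolve_strs, single_population_genealogy
    from coalisle.demography import MutationModelStr

    N, c, rate = 1_000.0, 1.0, 1e-3
    theta = 2 * c * N * rate  # 2.0 -> H = 1 - 1/sqrt(5) = 0.5528
    model = MutationModelStr(
        mean_rate=rate, locus_rate_shape=1e9, p_geom=1.0, n_loci=1,
        range_states=None,
    )
    vals = []
    for _ in range(1_500):
        g = single_population_genealogy(10, [(0.0, N)], c, rng, pop_label="p")
        ds = evolve_strs([g], model, rng)
        vals.append(str_locus_stats(ds, "p").mean_genic_diversity)
    expected = 1 - 1 / np.sqrt(1 + 2 * theta)
    assert abs(np.mean(vals) - expected) / expected < 0.02


# ---------------------------------------------------------------------------
# Summary vectors
# ---------------------------------------------------------------------------

def _small_bundle(rng):
    from coalisle.coalsim import SamplingDesign, simulate_dataset
    from coalisle.demography import (
        default_priors,
        default_template,
        draw_parameters,
        enumerate_colonization_scenarios,
    )

    scenario = enumerate_colonization_scenarios(default_template())[0]
    draw = draw_parameters(scenario, default_priors(), rng)
    design = SamplingDesign(
        n_mt={"a": 5, "b": 5}, n_str={"a": 6, "b": 6}
    )
    return simulate_dataset(scenario, draw, design, rng)


def test_summary_vector_shape_and_determinism(rng):
    bundle = _small_bundle(rng)
    cfg = SummaryConfig()
    v1 = summary_vector(bundle, config=cfg)
    v2 = summary_vector(bundle, config=cfg)
    assert list(v1.index) == list(v2.index)
    assert np.array_equal(v1.to_numpy(), v2.to_numpy())
    # 2 pops x (4 mt + 4 str) + 1 pair x (1 mt + 2 str) = 19
    assert len(v1) == 19


def test_summary_vector_empty_config(rng):
    bundle = _small_bundle(rng)
    cfg = SummaryConfig(per_pop_mt=(), per_pop_str=(), pairwise_mt=(), pairwise_str=())
    assert len(summary_vector(bundle, config=cfg)) == 0


def test_summary_vector_unknown_statistic(rng):
    bundle = _small_bundle(rng)
    with pytest.raises(KeyError):
        summary_vector(bundle, config=SummaryConfig(per_pop_mt=("bogus",)))


def test_statistics_invariant_to_row_order(rng):
    bundle = _small_bundle(rng)
    v1 = summary_vector(bundle)
    perm = rng.permutation(bundle.mt.n)
    perm_str = rng.permutation(bundle.strs.n)
    shuffled = DatasetBundle(
        mt=bundle.mt.subset(perm),
        strs=STRDataset(
            [bundle.strs.names[i] for i in perm_str],
            [bundle.strs.pops[i] for i in perm_str],
            bundle.strs.matrix[perm_str],
            bundle.strs.locus_names,
        ),
    )
    v2 = summary_vector(shuffled)
    assert np.allclose(v1.to_numpy(), v2.to_numpy(), atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_fst_and_diversity_bounds(data):
    """Hudson FST <= 1, diversity in [0,1], Pi >= pi*L - eps, on random
    two-population alignments."""
    n1 = data.draw(st.integers(2, 6))
    n2 = data.draw(st.integers(2, 6))
    L = data.draw(st.integers(4, 12))
    make = lambda n: [
        "".join(data.draw(st.sampled_from("ACGT")) for _ in range(L))
        for _ in range(n)
    ]
    a = aln_from_strings(make(n1))
    b = aln_from_strings(make(n2))
    fst = pairwise_fst_seq(a, b)
    assert fst <= 1.0 + 1e-12
    _, H = haplotype_stats(a)
    assert 0.0 <= H <= 1.0 + 1e-12
    Pi, pi = pairwise_diff_stats(a)
    assert Pi >= pi * L - 1e-9
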