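import numpy as np
import pytest
from scipy import stats

from coalisle.coalsim import (
    GeneGenealogy,
    SamplingDesign,
    UsageError,
    discrete_gamma_rates,
    evolve_sequences,
    evolve_strs,
    hky_rate_matrix,
    simulate_dataset,
    simulate_genealogy,
    single_population_genealogy,
)
from coalisle.demography import (
    MutationModelMt,
    MutationModelStr,
    default_priors,
    default_template,
    draw_parameters,
    enumerate_colonization_scenarios,
)


@pytest.fixture(scope="module")
def scenario():
    return enumerate_colonization_scenarios(default_template())[0]


@pytest.fixture(scope="module")
def draw(scenario):
    return draw_parameters(scenario, default_priors(), 42)


def test_pair_coalescence_mean_is_cN(rng):
    """E[T2] = c*N for pair-coalescence rate 1/(c*N)."""
    N, c, reps = 1_000.0, 2.0, 10_000
    t = np.array(
        [single_population_genealogy(2, [(0.0, N)], c, rng).tmrca for _ in range(reps)]
    )
    se = t.std(ddof=1) / np.sqrt(reps)
    assert abs(t.mean() - c * N) < 3 * se


def test_genealogy_is_ultrametric_and_structured(scenario, draw, rng):
    g = simulate_genealogy(scenario, draw, {"a": 5, "A": 5}, "mt", rng)
    assert g.n_tips == 10
    # tips at time zero, root oldest
    assert np.all(g.time[:10] == 0)
    assert g.tmrca == g.time.max()
    # parent times strictly exceed child times
    for node in range(len(g.time) - 1):
        assert g.time[g.parent[node]] > g.time[node]


def test_interpopulation_coalescence_respects_colonization_time(scenario, draw, rng):
    """Nodes ancestral to copies from both the island and its lineage cannot
    be younger than the island's colonization time."""
    t_col = draw.times["t4"]  # scenario 0 (order a,b,c,d): island a colonizes at t4
    for _ in range(20):
        g = simulate_genealogy(scenario, draw, {"a": 4, "A": 4}, "mt", rng)
        pops = np.array([p for p, _ in g.tip_labels])
        n = g.n_tips
        desc = [set() for _ in range(2 * n - 1)]
        for tip in range(n):
            desc[tip] = {pops[tip]}
        for node in range(n, 2 * n - 1):
            c0, c1 = g.children[node]
            desc[node] = desc[c0] | desc[c1]
            if len(desc[node]) > 1:
                assert g.time[node] > t_col


def test_bottleneck_prunes_lineages(scenario):
    """A severe founder bottleneck leaves fewer distinct lineages at the
    colonization time than no bottleneck."""
    from coalisle.demography import ParameterDraw

    times = {
        "t1": 1_000.0, "t2": 2_000.0, "t3": 3_000.0, "t4": 5_000.0,
        "t5": 400e3, "t6": 500e3, "t7": 600e3, "t8": 700e3,
    }
    # island a: huge present size (no drift before the bottleneck window)
    base_sizes = {
        "N_A": 10_000.0, "N1": 1e6, "N2": 1e4, "N3": 1e4, "N4": 1e4,
        "N5": 2.0, "N6": 100.0, "N7": 100.0, "N8": 100.0,
    }

    def lineages_at_colonization(n5, seed):
        d = ParameterDraw(times=times, sizes={**base_sizes, "N5": n5}, db=50.0)
        g = simulate_genealogy(scenario, d, {"a": 10}, "mt", seed)
        internal_times = g.time[g.n_tips:]
        return g.n_tips - int(np.sum(internal_times <= times["t4"]))

    reps = 1_500
    with_b = np.array([lineages_at_colonization(2.0, 1_000 + i) for i in range(reps)])
    without = np.array([lineages_at_colonization(1e6, 1_000 + i) for i in range(reps)])
    se = np.sqrt(with_b.var() / reps + without.var() / reps)
    assert with_b.mean() < without.mean() - 3 * se


def test_tmrca_distribution_matches_msprime(rng):
    """Cross-check: TMRCA of a 10-copy sample in a constant-size population
    agrees in distribution with msprime's coalescent (KS at alpha=0.01)."""
    import msprime

    N, c, n, reps = 1_000.0, 2.0, 10, 1_500
    mine = np.array(
        [single_population_genealogy(n, [(0.0, N)], c, rng).tmrca for _ in range(reps)]
    )
    # msprime with ploidy=1 and population_size M has pair-coalescence rate
    # 1/M; M = c*N matches our rate 1/(c*N)
    theirs = np.array(
        [
            msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=c * N, random_seed=10_000 + i
            ).max_root_time
            for i in range(reps)
        ]
    )
    p = stats.ks_2samp(mine, theirs).pvalue
    assert p > 0.01, f"TMRCA distributions differ (KS p={p:.2e})"


def test_sampling_from_source_is_an_error(scenario, draw):
    with pytest.raises(UsageError):
        simulate_genealogy(scenario, draw, {"U": 2}, "mt", 0)


def test_newick_export_parses(scenario, draw):
    import dendropy

    g = simulate_genealogy(scenario, draw, {"a": 4, "b": 3}, "mt", 5)
    tree = dendropy.Tree.get(data=g.newick(), schema="newick")
    assert len(tree.leaf_nodes()) == 7


# ---------------------------------------------------------------------------
# HKY sequence evolution
# ---------------------------------------------------------------------------

def _star_genealogy(n, height=0.0):
    """Manually built caterpillar with all internal nodes at `height`."""
    parent = np.full(2 * n - 1, -1, np.int64)
    time = np.zeros(2 * n - 1)
    children = np.full((2 * n - 1, 2), -1, np.int64)
    lineages = list(range(n))
    nxt = n
    while len(lineages) > 1:
        a, b = lineages[0], lineages[1]
        parent[a] = parent[b] = nxt
        children[nxt] = (a, b)
        time[nxt] = height
        lineages = lineages[2:] + [nxt]
        nxt += 1
    return GeneGenealogy([("p", i) for i in range(n)], parent, time, children)


def test_zero_height_tree_gives_identical_sequences(rng):
    g = _star_genealogy(6, height=0.0)
    aln = evolve_sequences(g, MutationModelMt(length=100), rng)
    assert np.all(aln.matrix == aln.matrix[0])


def test_hky_matrix_properties():
    Q = hky_rate_matrix(2.0, (0.1, 0.2, 0.3, 0.4))
    assert np.allclose(Q.sum(axis=1), 0)
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    assert np.isclose(-np.sum(pi * np.diag(Q)), 1.0)  # mean rate 1
    # detailed balance pi_i q_ij = pi_j q_ji
    for i in range(4):
        for j in range(4):
            assert np.isclose(pi[i] * Q[i, j], pi[j] * Q[j, i])


def test_discrete_gamma_rates_mean_one():
    for shape in (0.5, 2.0, 10.0):
        r = discrete_gamma_rates(shape, 4)
        assert np.isclose(r.mean(), 1.0)
        assert np.all(np.diff(r) > 0)


def test_kappa_one_reduces_to_jukes_cantor(rng):
    """With kappa=1 and equal frequencies, ~1/3 of observed differences at
    small divergence are transitions."""
    model = MutationModelMt(
        kappa=1.0, gamma_shape=1.0, prop_invariant=0.0,
        mu_site=1e-3, length=20_000, n_categories=1,
    )
    g = _star_genealogy(2, height=5.0)  # 2*mu*t = 0.01 per site
    n_ts = n_diff = 0
    for _ in range(30):
        aln = evolve_sequences(g, model, rng)
        a, b = aln.matrix
        diff = a != b
        n_diff += int(diff.sum())
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        n_ts += sum((int(x), int(y)) in transitions for x, y in zip(a[diff], b[diff]))
    assert n_diff > 3_000
    frac = n_ts / n_diff
    se = np.sqrt(frac * (1 - frac) / n_diff)
    assert abs(frac - 1 / 3) < 4 * se + 0.01


def test_small_distance_pairwise_differences(rng):
    """Two tips at divergence T with mu*T = 0.005 and 10% invariant sites:
    E[diffs/site] ~ 2*mu*T*0.9 in the small-distance regime."""
    mu, T, pinv, L = 1e-4, 50.0, 0.1, 565
    model = MutationModelMt(
        kappa=2.0, gamma_shape=2.0, prop_invariant=pinv, mu_site=mu, length=L
    )
    g = _star_genealogy(2, height=T)
    reps = 1_000
    diffs = np.empty(reps)
    for i in range(reps):
        aln = evolve_sequences(g, model, rng)
        diffs[i] = (aln.matrix[0] != aln.matrix[1]).sum()
    expected = 2 * mu * T * (1 - pinv) * L
    se = diffs.std(ddof=1) / np.sqrt(reps)
    assert abs(diffs.mean() - expected) < 3 * se + 0.05


def test_mean_pairwise_diff_matches_theta(rng):
    """Panmictic constant size: E[pairwise differences] = 2*c*N*mu_locus."""
    N, c, mu, L, reps = 500.0, 1.0, 2e-6, 565, 10_000
    model = MutationModelMt(
        kappa=2.0, gamma_shape=1.0, prop_invariant=0.0,
        mu_site=mu, length=L, n_categories=1,
    )
    diffs = np.empty(reps)
    for i in range(reps):
        g = single_population_genealogy(2, [(0.0, N)], c, rng)
        aln = evolve_sequences(g, model, rng)
        diffs[i] = (aln.matrix[0] != aln.matrix[1]).sum()
    theta = 2 * c * N * mu * L  # = 1.13
    assert abs(diffs.mean() - theta) / theta < 0.05


def test_constant_size_mismatch_is_geometric(rng):
    """Pairwise difference counts from a constant-size coalescent follow the
    geometric equilibrium law F_i = theta^i/(1+theta)^(i+1)."""
    N, c, mu, L = 500.0, 1.0, 2e-6, 2_000
    theta = 2 * c * N * mu * L  # 4.0
    model = MutationModelMt(
        kappa=2.0, gamma_shape=1.0, prop_invariant=0.0,
        mu_site=mu, length=L, n_categories=1,
    )
    reps = 4_000
    counts = np.zeros(200, int)
    for _ in range(reps):
        g = single_population_genealogy(2, [(0.0, N)], c, rng)
        aln = evolve_sequences(g, model, rng)
        d = int((aln.matrix[0] != aln.matrix[1]).sum())
        counts[min(d, 199)] += 1
    i = np.arange(200)
    expected = theta**i / (1 + theta) ** (i + 1.0)
    expected[-1] = 1 - expected[:-1].sum()
    # pool the tail so expected counts stay >= 5
    k = int(np.searchsorted(np.cumsum(expected) * reps, reps - 5))
    obs = np.concatenate([counts[:k], [counts[k:].sum()]])
    exp = np.concatenate([expected[:k], [expected[k:].sum()]]) * reps
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = stats.chi2.sf(chi2, len(obs) - 1)
    assert p > 0.01


# ---------------------------------------------------------------------------
# STR evolution
# ---------------------------------------------------------------------------

def test_str_zero_rate_keeps_ancestral(rng):
    g = [single_population_genealogy(8, [(0.0, 500.0)], 2.0, rng) for _ in range(3)]
    model = MutationModelStr(mean_rate=0.0, n_loci=3)
    ds = evolve_strs(g, model, rng)
    assert np.all(ds.matrix == model.ancestral_allele)


def test_strict_smm_parity(rng):
    """With p_geom = 1 every mutation is a single step, so allele offsets
    have the parity of the mutation count; offsets stay within the window."""
    model = MutationModelStr(
        mean_rate=5e-3, p_geom=1.0, n_loci=1, range_states=None
    )
    g = [single_population_genealogy(10, [(0.0, 500.0)], 2.0, rng)]
    ds = evolve_strs(g, model, rng)
    assert ds.matrix.shape == (10, 1)
    assert np.all(ds.matrix > 0)


def test_str_branch_mutation_count_is_poisson(rng):
    """Mutation count on one branch of length L has mean rate*L."""
    L, rate = 10_000.0, 1e-3
    model = MutationModelStr(
        mean_rate=rate, locus_rate_shape=1e9, p_geom=1.0, n_loci=1,
        range_states=None,
    )
    # two tips joined at height L/2: total path length L between them;
    # for +-1 steps Var(net tip offset difference) = E[mutation count] = rate*L
    g = _star_genealogy(2, height=L / 2)
    reps = 5_000
    net = np.empty(reps)
    for i in range(reps):
        ds = evolve_strs([g], model, rng)
        net[i] = ds.matrix[0, 0] - ds.matrix[1, 0]
    expected = rate * L
    assert abs(net.var() - expected) / expected < 0.1


def test_str_heterozygosity_increases_with_rate(rng):
    """Expected heterozygosity is monotone in the mutation rate."""
    from coalisle.containers import STRDataset
    from coalisle.sumstats import str_locus_stats

    rates = [1e-5, 5e-5, 2e-4, 1e-3, 5e-3]
    het = []
    for rate in rates:
        model = MutationModelStr(mean_rate=rate, n_loci=2)
        vals = []
        for _ in range(2_000):
            gs = [single_population_genealogy(6, [(0.0, 500.0)], 2.0, rng,
                                              pop_label="p") for _ in range(2)]
            ds = evolve_strs(gs, model, rng)
            vals.append(str_locus_stats(ds, "p").mean_genic_diversity)
        het.append(np.mean(vals))
    assert list(het) == sorted(het)  # strictly monotone -> Spearman rho = 1
    assert stats.spearmanr(rates, het).statistic > 0.9999


def test_str_locus_count_mismatch_raises(rng):
    g = [single_population_genealogy(4, [(0.0, 100.0)], 2.0, rng)]
    with pytest.raises(UsageError):
        evolve_strs(g, MutationModelStr(n_loci=2), rng)


# ---------------------------------------------------------------------------
# Dataset composition
# ---------------------------------------------------------------------------

def test_dataset_shape_matches_design(scenario, draw, rng):
    design = SamplingDesign(
        n_mt={"a": 22, "b": 29, "c": 30, "d": 16}, n_str={}
    )
    bundle = simulate_dataset(scenario, draw, design, rng)
    assert bundle.mt.n == 97
    assert bundle.mt.n_sites == 565
    assert bundle.strs.n == 0


def test_dataset_determinism(scenario, draw):
    design = SamplingDesign(n_mt={"a": 5, "b": 5}, n_str={"a": 6, "b": 6})
    b1 = simulate_dataset(scenario, draw, design, 99)
    b2 = simulate_dataset(scenario, draw, design, 99)
    assert np.array_equal(b1.mt.matrix, b2.mt.matrix)
    assert np.array_equal(b1.strs.matrix, b2.strs.matrix)


def test_duplicate_str_copies_mode(scenario, draw):
    design = SamplingDesign(n_mt={"a": 4}, n_str={"a": 8}, duplicate_str_copies=True)
    bundle = simulate_dataset(scenario, draw, design, 3)
    m = bundle.strs.matrix
    assert m.shape[0] == 8
    assert np.array_equal(m[0::2], m[1::2])  # consecutive copies identical
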