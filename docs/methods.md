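# Methods

## Demographic model

Nine populations: an unsampled source `U`, four "world" lineages `A–D`, and
four island populations `a–d` paired one-to-one with the lineages. Looking
backward in time, each island's gene copies transfer into its parent
lineage at its colonization time, and each lineage's copies transfer into
`U` at its coalescence time. The event times obey

    t8 > t6, t7 > t6, t6 > t4, t5 > t4, t4 > t3 > t2 > t1,

so diversification proceeds `U > A/D > B/C` (the relative order within
{t8, t7} and within {t6, t5} is deliberately unconstrained) and the four
colonizations are strictly ordered. Candidate scenarios are the 24
permutations of the colonization order; the permutation determines only
which island receives which time parameter (earliest colonizer → t4,
latest → t1). Scenario ids are assigned in lexicographic order of the
permutation so results are referenceable across runs.

Sizes: `N_A` for `U`; one shared present-day size per lineage/island pair
(`N1`–`N4`, A/a → N1 … D/d → N4); island founder-bottleneck sizes `N5`–`N8`
(a → N5 … d → N8, a fixed mapping — the *times* are permuted, the
bottleneck-size labels are not). During the window (t_col − db, t_col)
backward from the present an island's size is its bottleneck size; `db`
defaults to a fixed 5 generations, optionally drawable from U(1, 100).

Priors are independent uniforms: colonization times U(1,000, 250,000) and
lineage coalescences U(10,000, 1,000,000) generations. The size priors are
not pinned down by the sources available to this package, so defaults are
explicit and configurable: `N_A`, `N1`–`N4` ~ U(100, 100,000) individuals,
`N5`–`N8` ~ U(2, 1,000). Order constraints are imposed by rejection
(vectorized, capped at 10,000 candidate draws so impossible bounds fail
fast); rejection preserves the uniform law restricted to the constraint
polytope, which the test suite verifies against order-statistic marginals.

## Coalescent simulator

A standard structured Kingman coalescent with piecewise-constant sizes:
within a population of size N each lineage pair coalesces at rate 1/(c·N).
The ploidy factor c is 2 for nuclear loci and 0.5 for mtDNA by default.
The mtDNA scaling for an androdioecious, highly selfing species is genuinely
ambiguous (selfing collapses the usual dioecious N/4 argument), so c is an
explicit per-locus-kind configuration rather than a hidden constant.

Mutations are overlaid after the genealogy is drawn:

* **mtDNA** — HKY with transition/transversion ratio κ (default 2), base
  frequencies (default equal), discrete-Gamma rate heterogeneity with
  4 equal-probability categories (mean-of-bin rates; shape default 2), and
  an exact 10% fraction of invariant sites chosen uniformly once per
  simulation. Each site's state at a branch's end is sampled from the exact
  transition matrix P(t) = exp(Qμrt), computed from the spectral
  decomposition of the reversible generator — exact for any branch length
  and O(sites) per branch. The rate is scaled so a
  rate-1 site accumulates `mu_site` expected substitutions per generation;
  `mu_site` defaults to the measured 7.6e-8 for the 565-bp fragment.
* **microsatellites** — generalized stepwise model: per-locus rate drawn
  once from Gamma(shape 2, mean `mean_rate`), Poisson mutation counts per
  branch, step sizes ±k with k ~ Geometric(p, default 0.22; p = 1 recovers
  the strict SMM). Allele sizes reflect off a 40-state window centred on
  the ancestral allele (configurable off) to prevent unbounded drift.

Near-isogenic selfing strains are modelled by simulating one haploid
lineage per strain and emitting two identical STR gene copies (matching
the observed doubling of STR versus mtDNA gene-copy counts); a
fully-diploid mode simulates every copy independently.

The default `mean_rate` of 1e-5 per locus per generation is an *effective*
rate chosen on θ grounds: the collection shows high mtDNA haplotype
diversity (0.76–0.95) but only moderate STR gene diversity (0.36–0.64) in
the same populations, and with a shared effective size per population pair
(set near the upper size prior to reproduce the mtDNA magnitudes) the STR
θ = 4·N·rate implied by the observed heterozygosities corresponds to a
rate around 1e-5, far below per-generation lab estimates for outcrossing
microsatellites — consistent with near-complete selfing suppressing the
effective microsatellite diversity. The synthetic-data generator's default
draw uses colonization times of 133,000–191,000 and lineage coalescences of
391,000–691,000 generations (the regime the real analysis inferred), sizes
60,000–90,000, bottlenecks of a few hundred at db = 5.

What the generator does *not* emulate: admixed strains (excluded from the
real subset by design), geographic structure within islands, recombination,
STR allele-frequency spectra of the real loci, and missing data. Tests that
pass on synthetic data therefore validate the inference machinery, not the
historical conclusions for the real collection.

## Summary statistics

The panel mirrors the standard diversity table: per population — haplotype
count, unbiased haplotype diversity n(1−Σp²)/(n−1), mean pairwise
differences Π and nucleotide diversity π, segregating sites S, Tajima's D
(1989 constants); per population for STRs — mean allele count, allelic
range, Garza–Williamson M = k/(r+1), unbiased gene diversity; pairwise —
Hudson F_ST = 1 − Hw/Hb for sequences, Weir–Cockerham variance-components
F_ST in the haploid (gene-copy) form for STRs, and Goldstein's (δμ)².
Two deliberate conventions: "mean genic diversity" averages gene diversity
over *all* typed loci while "expected heterozygosity" averages over
polymorphic loci only (the two rows in the observed table differ, and this
is the simplest reading consistent with both); sites containing non-ACGT
symbols are deleted pairwise for distance statistics but completely for S
and Tajima's D. Monomorphic loci give M = 1 by the formula, not an error.
Tajima's D is undefined at S = 0; inside ABC summary vectors (where a fixed
vector length is required) that case is recorded as 0, elsewhere it raises.

The default ABC statistic subset spans the panel (per-population: mt
haplotype count, Π, S, D; STR allele count, expected heterozygosity,
allelic range, M; pairwise: both F_STs and (δμ)²) and is fully
configurable, including restriction of the pair list.

## ABC machinery

* Scale factors are robust SDs (1.4826×MAD, SD fallback) computed over the
  whole reference table; zero-spread statistics are dropped with a logged
  warning. Heavy-tailed summaries under wide time priors make the plain SD
  a poor normalizer.
* Rejection keeps ceil(tolerance × rows) rows by normalized Euclidean
  distance; ties break by row index, so results are reproducible up to row
  order.
* Scenario choice: multinomial logistic regression of scenario label on
  summary deviations over the retained set, evaluated at zero deviation,
  with a small fixed ridge penalty (C = 10) because perfect separation is
  routine with few retained rows. A retained set from a single scenario
  short-circuits to probability 1.
* Parameter estimation: Epanechnikov-weighted local-linear regression
  (bandwidth = largest retained distance) of log-parameters on summary
  deviations, back-transformed; the log scale enforces positivity across
  priors spanning orders of magnitude. The regression is lightly
  ridge-regularized (α = 0.01 per retained row): with retained counts of
  the same order as the statistic dimension an unpenalized fit interpolates
  and collapses the adjusted sample to a point, which destroys interval
  coverage. Constant columns (e.g. fixed db) pass through unadjusted; a
  singular design falls back to the raw rejection sample with a warning.
  Posterior summaries (mean, median, quartiles, 90% interval) are
  weighted-sample quantities.
* Validation: PCA pre-evaluation projects the observed vector into the
  scaled simulation cloud and reports convex-hull membership in the first
  two components; model checking simulates posterior predictive datasets
  and reports per-statistic tail probabilities (flagged within 0.025 of 0
  or 1); confidence in choice and bias/precision run pods from the priors
  through the full pipeline.

"250,000 simulations each" in the source protocol is read as per scenario
per run and is configurable; the staged 12+12 → top-6 mode exists but the
default is a single joint analysis over all 24 scenarios.

## Mismatch-distribution analysis

The sudden-expansion closed form above is the primary model: the source
protocol names a "spatial" expansion but defines exactly the θ₀/θ₁/τ
parameterization of the sudden-expansion model, so that is what is
implemented (the migration-parameterized variant is left as an extension
point). The frequencies are truncated at the observed maximum difference
class and renormalized. Numerical notes: the series is evaluated through
Poisson pmfs in the stable form e^{−τ(θ₁+1)/θ₁}τ^j/j! = Pois(j; τ)·e^{−τ/θ₁};
θ₁ = ∞ is supported as a flag (Poisson limit); θ₁ = 0 and τ = 0 short-circuit
to the appropriate equilibrium.

Fitting minimizes SSD = Σ(x_i − F_i)² by bounded Nelder–Mead from 20 starts
(θ ∈ [0, 100], τ ∈ [0, 50]); the surface is multimodal, so the start list
combines a vectorized coarse-grid optimum, moment-based guesses (τ near the
observed mean), and seeded random points; ties go to the lowest τ.
Bootstrap replicates are refit from the grid optimum with one short polish
— on bootstrap-smooth distributions this lands on the same optimum as the
full multi-start (verified in development) at ~10× less cost.

Bootstrap p-values use the strict-inequality convention: p = #(statistic_sim
> statistic_obs)/n_boot, so an observed SSD of zero yields p = 1. Replicates
are simulated with the single-population coalescent (size change N₁ → N₀ at
the fitted scaled time, pair rate 1/N, matching sample size and locus
length) under a rate-homogeneous substitution model; the per-locus rate used
to de-scale (θ, τ) into simulator units is arbitrary since the mismatch law
depends only on the scaled parameters.

Dating: t = τ/(2 μ_locus) with μ_locus = μ_site × length / generations-per-
year (7.6e-8 × 565 = 4.294e-5 per year at one generation per year), rounded
to the nearest thousand years by default.

## Scaled-down validation experiments

The full-size inference (24 scenarios × 250,000 simulations on the complete
collection) is not a desk-scale computation, so correctness is demonstrated
on fixed toy conditions (`coalisle.experiments`), chosen once as part of the
validation design:

* **Scenario choice** — four candidate orders that are cyclic shifts of
  (a, b, c, d), so every candidate pair differs in both the earliest and the
  latest colonizer; 8 mtDNA copies per population, a hot mtDNA clock
  (2e-6/site/gen) making the single locus informative, sizes U(15,000,
  25,000), severe founder bottlenecks U(5, 50) × 5 generations (the
  post-founding diversity recovery then adds a colonization-age signal),
  colonization times U(1,000, 250,000), coalescences U(300,000, 1,000,000).
  5,000 simulations per scenario, 1% tolerance, 20 pods from one scenario.
* **Parameter recovery** — same toy, one scenario, 6,000 simulations,
  5% tolerance (≈300 retained rows, comfortably above the 42-statistic
  design dimension), coverage of the central 90% posterior interval for t4
  over 50 pods.
* **MMD calibration** — 200 experiments of n = 25 sequences × 565 sites
  simulated at (θ₀ 0.5, θ₁ 20, τ 5), each fitted and bootstrapped 200
  times; SSD p-values are tested for uniformity (KS). Both the observed
  dataset and its bootstrap replicates are simulated from the same
  fitted-model parameters, making the observed and replicate SSDs
  exchangeable — the property the bootstrap relies on — so the p-values
  are uniform by construction and the experiment verifies the machinery.
  The *production* p-value re-estimates (θ₀, θ₁, τ) from each observed
  dataset before bootstrapping (the standard plug-in procedure); because
  the minimized SSD is not pivotal, that plug-in p-value is only
  approximately calibrated (measured here: mean p ≈ 0.44 rather than 0.5
  under the toy conditions, i.e. slightly anti-conservative) — a known
  property of parametric-bootstrap goodness-of-fit testing, shared by the
  standard implementations of this analysis. τ recovery uses 30 replicates
  at each of τ ∈ {2, 5, 10}.

Some pods are intrinsically ambiguous (colonization times drawn close
together carry little order information), so the scenario-choice success
rate is expected below 100% even for a perfect method.

## Known limitations

* No migration or admixture after colonization, no recombination, no
  sequence indels, and no STR homoplasy beyond the stepwise model.
* The logistic/local-linear post-processing is the classic ABC toolchain;
  random-forest or neural ABC variants are out of scope.
* Whether the 10% "constant sites" setting of the original protocol meant
  an exact fraction or a per-site probability is unknowable from the text;
  an exact fraction is implemented.
* The real collection's statistic subset and size priors (supplementary
  material) are unavailable; defaults here are documented stand-ins, so
  posterior numbers on real data are not expected to reproduce the
  original report exactly.
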