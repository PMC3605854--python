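"""Structured-coalescent simulator with HKY sequence and stepwise STR mutation.

The genealogy process runs backward in time over the scenario's population
tree: within a population of effective size N, each pair of lineages
coalesces at rate 1/(c*N) where the ploidy factor c is 2 for nuclear loci
and, by default, 0.5 for the maternally inherited mtDNA locus (both
configurable; the species is a selfing hermaphrodite so the appropriate
mtDNA scaling is left to the user).  At an island population's colonization
time all of its lineages transfer to the parent lineage; during the window
(t_col - db, t_col) backward from the present the island's size is its
founder-bottleneck size.  At a lineage's coalescence time its lineages
transfer to the unsampled source U, where the remaining ancestry coalesces
at size N_A.

Mutations are overlaid on the genealogy afterwards: the mtDNA locus evolves
under HKY with discrete-Gamma rate heterogeneity (4 categories) and an exact
fraction of invariant sites; each microsatellite locus evolves under a
generalized stepwise model with a per-locus rate drawn once from a Gamma
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .containers import SequenceAlignment, STRDataset, DatasetBundle
from .demography import (
    ISLANDS,
    PAIR_SIZE,
    PAIRING,
    ISLAND_BOTTLENECK,
    LINEAGE_TIME,
    MutationModelMt,
    MutationModelStr,
    ParameterDraw,
    Scenario,
)

__all__ = [
    "GeneGenealogy",
    "PLOIDY_FACTORS",
    "simulate_genealogy",
    "single_population_genealogy",
    "evolve_sequences",
    "evolve_strs",
    "simulate_dataset",
    "SamplingDesign",
]

#: pair-coalescence rate is 1/(c*N); keys are locus kinds
PLOIDY_FACTORS = {"mt": 0.5, "nuclear": 2.0}


class UsageError(ValueError):
    pass


@dataclass
class GeneGenealogy:
    """Binary rooted ultrametric tree in index-array form.

    Nodes 0..n-1 are tips (time 0); internal nodes follow in coalescence
    order.  ``parent[root] == -1``.
    """

    tip_labels: list[tuple[str, int]]  # (population, copy index)
    parent: np.ndarray  # int, len 2n-1
    time: np.ndarray  # float, node ages in generations
    children: np.ndarray  # int, shape (2n-1, 2); -1 for tips

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    def total_branch_length(self) -> float:
        p = self.parent
        return float(np.sum(self.time[p[p >= 0]] - self.time[p >= 0]))

    def preorder(self) -> list[int]:
        """Node ids with every parent before its children."""
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            c0, c1 = self.children[node]
            if c0 >= 0:
                stack.append(int(c0))
                stack.append(int(c1))
        return out

    def newick(self) -> str:
        def rec(node: int) -> str:
            if self.children[node, 0] < 0:
                pop, idx = self.tip_labels[node]
                label = f"{pop}_{idx}"
            else:
                kids = ",".join(rec(int(c)) for c in self.children[node])
                label = f"({kids})"
            bl = self.branch_length(node)
            return f"{label}:{bl:.6f}" if self.parent[node] >= 0 else label

        return rec(self.root) + ";"


def _demographic_script(scenario: Scenario, draw: ParameterDraw):
    """Per-population piecewise sizes and the merge schedule.

    Returns (events, sizes) where events is a time-sorted list of
    ('merge', t, child, parent) and ('resize', t, pop, new_size) records and
    sizes maps population -> present-day (t=0) size.
    """
    t = draw.times
    N = draw.sizes
    col_time = scenario.colonization_times
    sizes: dict[str, float] = {"U": N["N_A"]}
    events: list[tuple] = []
    for ev in scenario.events:
        when = t[ev.time_param]
        if ev.child in ISLANDS:
            isl = ev.child
            present = N[PAIR_SIZE[PAIRING[isl]]]
            bott = N[ISLAND_BOTTLENECK[isl]]
            sizes[isl] = present
            start = max(when - draw.db, 0.0)
            events.append(("resize", start, isl, bott))
            events.append(("merge", when, isl, ev.parent))
        else:
            sizes[ev.child] = N[PAIR_SIZE[ev.child]]
            events.append(("merge", when, ev.child, ev.parent))
    events.sort(key=lambda e: e[1])
    return events, sizes


def simulate_genealogy(
    scenario: Scenario,
    draw: ParameterDraw,
    sampling: Mapping[str, int],
    locus_kind: str = "mt",
    rng: np.random.Generator | int | None = None,
    ploidy_factor: float | None = None,
) -> GeneGenealogy:
    """Simulate one gene genealogy under the structured Kingman coalescent.

    ``sampling`` maps population label -> number of sampled gene copies.
    """
    rng = np.random.default_rng(rng)
    if ploidy_factor is None:
        ploidy_factor = PLOIDY_FACTORS[locus_kind]
    c = float(ploidy_factor)
    pops = scenario.population
    for label, k in sampling.items():
        if label not in pops:
            raise UsageError(f"unknown population {label!r}")
        if k > 0 and pops[label].role == "unsampled_source":
            raise UsageError("cannot sample gene copies from the unsampled source")
    for name, v in draw.sizes.items():
        if v <= 0:
            raise ValueError(f"nonpositive population size {name}={v}")

    events, sizes = _demographic_script(scenario, draw)
    sizes = dict(sizes)

    tip_labels: list[tuple[str, int]] = []
    active: dict[str, list[int]] = {}
    for label in sorted(sampling):
        k = sampling[label]
        if k <= 0:
            continue
        ids = list(range(len(tip_labels), len(tip_labels) + k))
        active[label] = ids
        tip_labels += [(label, i) for i in range(k)]
    n = len(tip_labels)
    if n == 0:
        raise UsageError("empty sampling design")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    time = np.zeros(n_nodes)
    children = np.full((n_nodes, 2), -1, np.int64)
    next_node = n

    T = 0.0
    ev_idx = 0
    n_active = n
    while n_active > 1:
        t_next = events[ev_idx][1] if ev_idx < len(events) else math.inf
        # total coalescence rate under the current (constant) sizes
        rates = []
        for label, lin in active.items():
            k = len(lin)
            if k >= 2:
                rates.append((label, k * (k - 1) / 2.0 / (c * sizes[label])))
        total = sum(r for _, r in rates)
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if T + wait < t_next:
            T += wait
            u = rng.uniform(0, total)
            acc = 0.0
            for label, r in rates:
                acc += r
                if u <= acc:
                    break
            lin = active[label]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            children[node] = (a, b)
            time[node] = T
            lin[:] = [x for x in lin if x not in (a, b)] + [node]
            n_active -= 1
        else:
            if ev_idx >= len(events):
                raise RuntimeError("coalescent failed to complete")  # pragma: no cover
            kind, when, who, what = events[ev_idx]
            ev_idx += 1
            T = when
            if kind == "resize":
                sizes[who] = what
            else:  # merge: move child lineages into parent
                moved = active.pop(who, [])
                if moved:
                    active.setdefault(what, []).extend(moved)
    return GeneGenealogy(tip_labels, parent, time, children)


def single_population_genealogy(
    n: int,
    epochs: Sequence[tuple[float, float]],
    c: float = 1.0,
    rng: np.random.Generator | int | None = None,
    pop_label: str = "pop",
) -> GeneGenealogy:
    """Kingman coalescent for one panmictic population with piecewise-
    constant size.

    ``epochs`` is a list of (start_time, N) pairs, oldest epoch last; the
    first start_time must be 0.  Pair-coalescence rate is 1/(c*N).
    """
    rng = np.random.default_rng(rng)
    if n < 2:
        raise UsageError("need at least 2 gene copies")
    if not epochs or epochs[0][0] != 0:
        raise UsageError("first epoch must start at time 0")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    time = np.zeros(n_nodes)
    children = np.full((n_nodes, 2), -1, np.int64)
    lineages = list(range(n))
    next_node = n
    T = 0.0
    ei = 0
    while len(lineages) > 1:
        N = epochs[ei][1]
        t_next = epochs[ei + 1][0] if ei + 1 < len(epochs) else math.inf
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (c * N)
        wait = rng.exponential(1.0 / rate)
        if T + wait < t_next:
            T += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            children[node] = (a, b)
            time[node] = T
            lineages = [x for x in lineages if x not in (a, b)] + [node]
        else:
            T = t_next
            ei += 1
    tips = [(pop_label, i) for i in range(n)]
    return GeneGenealogy(tips, parent, time, children)


# ---------------------------------------------------------------------------
# HKY sequence evolution
# ---------------------------------------------------------------------------

def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean-1 rates of equal-probability discrete-Gamma categories.

    Each category rate is the mean of its quantile slice of Gamma(shape,
    scale=1/shape) (Yang 1994's mean-of-bin discretization).
    """
    edges = stats.gamma.ppf(np.linspace(0, 1, n_categories + 1), a=shape, scale=1.0 / shape)
    # E[X; X in bin] / P(bin) with P(bin) = 1/K; uses the identity
    # \int x f_a(x) dx = F_{a+1}(x) for the gamma density
    upper = stats.gamma.cdf(edges[1:], a=shape + 1, scale=1.0 / shape)
    lower = stats.gamma.cdf(edges[:-1], a=shape + 1, scale=1.0 / shape)
    rates = n_categories * (upper - lower)
    return rates / rates.mean() * 1.0  # exact mean 1


def hky_rate_matrix(kappa: float, base_freqs: Sequence[float]) -> np.ndarray:
    """HKY instantaneous rate matrix (A,C,G,T order), scaled to one expected
    substitution per unit time at stationarity."""
    pi = np.asarray(base_freqs, float)
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.sum(pi * np.diag(Q))
    return Q / mean_rate


def _hky_spectral(Q: np.ndarray, pi: np.ndarray):
    """Spectral decomposition of the reversible generator.

    Returns (eigenvalues, A, B) with P(t) = A @ diag(exp(lam*t)) @ B exactly.
    Reversibility makes diag(sqrt(pi)) Q diag(1/sqrt(pi)) symmetric, so the
    decomposition is real and stable.
    """
    s = np.sqrt(pi)
    S = (Q * s[None, :]) / s[:, None]
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    A = U / s[:, None]
    B = U.T * s[None, :]
    return lam, A, B


def evolve_sequences(
    genealogy: GeneGenealogy,
    model: MutationModelMt,
    rng: np.random.Generator | int | None = None,
) -> SequenceAlignment:
    """Evolve a sequence alignment along the genealogy under HKY+G+I.

    The root sequence is drawn from the stationary base frequencies; an
    exact fraction ``prop_invariant`` of sites (chosen uniformly once) never
    mutates; the rest carry discrete-Gamma relative rates.  Each site's
    state at a branch's child is sampled from the exact transition matrix
    P(t) = exp(Q * mu * rate * t) obtained from the spectral decomposition
    of the HKY generator, so arbitrarily long branches are handled without
    approximation.
    """
    rng = np.random.default_rng(rng)
    L = model.length
    Q = hky_rate_matrix(model.kappa, model.base_freqs)
    pi = np.asarray(model.base_freqs, float)
    lam, A, B = _hky_spectral(Q, pi)
    # uniformized jump kernel for the short-branch (event-based) path
    lam_max = float((-np.diag(Q)).max())
    jump = Q / lam_max
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(
        np.column_stack([jump, 1.0 - jump.sum(axis=1)]), axis=1
    )

    n_inv = int(round(model.prop_invariant * L))
    perm = rng.permutation(L)
    var_sites = perm[n_inv:]
    cat_rates = discrete_gamma_rates(model.gamma_shape, model.n_categories)
    site_cat = rng.integers(0, model.n_categories, size=var_sites.size)
    site_rates = cat_rates[site_cat]
    rate_total = float(site_rates.sum())
    site_cum = np.cumsum(site_rates) / rate_total if rate_total > 0 else None

    root_seq = rng.choice(4, size=L, p=pi).astype(np.uint8)

    root = genealogy.root
    seqs: dict[int, np.ndarray] = {root: root_seq}
    for node in genealogy.preorder():
        if node == root:
            continue
        par = int(genealogy.parent[node])
        seq = seqs[par]
        bl = genealogy.branch_length(node)
        t_eff = model.mu_site * bl
        if t_eff > 0 and var_sites.size:
            mean_events = lam_max * t_eff * rate_total
            if mean_events < 0.25 * var_sites.size:
                # short branch: simulate the uniformized jump chain directly
                n_events = rng.poisson(mean_events)
                if n_events > 0:
                    seq = seq.copy()
                    hit = np.searchsorted(site_cum, rng.random(n_events))
                    for h in hit:
                        s = var_sites[h]
                        k = int(np.searchsorted(jump_cum[seq[s]], rng.random()))
                        if k < 4:
                            seq[s] = k
            else:
                # long branch: sample each site from the exact P(t) =
                # exp(Q*mu*r*t) via the spectral decomposition
                seq = seq.copy()
                expd = np.exp(lam[None, :] * (cat_rates[:, None] * t_eff))
                P = np.einsum("ij,cj,jk->cik", A, expd, B)
                np.clip(P, 0.0, None, out=P)
                P /= P.sum(axis=2, keepdims=True)
                cum = np.cumsum(P, axis=2)
                cc = cum[site_cat, seq[var_sites]]  # (n_var, 4)
                u = rng.random(var_sites.size)
                child = (u[:, None] > cc).sum(axis=1)
                seq[var_sites] = np.minimum(child, 3).astype(np.uint8)
        seqs[node] = seq
    names = [f"{pop}_{idx:03d}" for pop, idx in genealogy.tip_labels]
    pops = [pop for pop, _ in genealogy.tip_labels]
    mat = np.stack([seqs[i] for i in range(genealogy.n_tips)])
    return SequenceAlignment(names, pops, mat)


# ---------------------------------------------------------------------------
# Generalized stepwise STR evolution
# ---------------------------------------------------------------------------

def evolve_strs(
    genealogies: Sequence[GeneGenealogy],
    model: MutationModelStr,
    rng: np.random.Generator | int | None = None,
) -> STRDataset:
    """Evolve allele sizes for independent microsatellite loci.

    One genealogy per locus; the per-locus mutation rate is drawn once from
    Gamma(shape=locus_rate_shape, mean=mean_rate).  Each mutation moves the
    allele by ±k repeat units with k ~ Geometric(p_geom); allele sizes are
    reflected into a contiguous window of ``range_states`` states centred on
    the ancestral allele (set ``range_states=None`` to disable).
    """
    rng = np.random.default_rng(rng)
    if len(genealogies) != model.n_loci:
        raise UsageError(
            f"need {model.n_loci} genealogies, got {len(genealogies)}"
        )
    anc = model.ancestral_allele
    if model.range_states is not None:
        lo = anc - model.range_states // 2
        hi = lo + model.range_states - 1
    else:
        lo, hi = None, None

    first = genealogies[0]
    names = [f"{pop}_{idx:03d}" for pop, idx in first.tip_labels]
    pops = [pop for pop, _ in first.tip_labels]
    n = first.n_tips
    mat = np.empty((n, model.n_loci), np.int64)

    for locus, g in enumerate(genealogies):
        if g.n_tips != n:
            raise UsageError("all locus genealogies must share the sampling design")
        if model.mean_rate > 0:
            rate = rng.gamma(
                model.locus_rate_shape, model.mean_rate / model.locus_rate_shape
            )
        else:
            rate = 0.0
        alleles: dict[int, int] = {g.root: anc}
        for node in g.preorder():
            if node == g.root:
                continue
            par = int(g.parent[node])
            a = alleles[par]
            bl = g.branch_length(node)
            n_mut = rng.poisson(rate * bl) if rate > 0 else 0
            for _ in range(n_mut):
                step = int(rng.geometric(model.p_geom))
                if rng.random() < 0.5:
                    step = -step
                a = a + step
                if lo is not None:
                    # reflect into the allowed window
                    while a < lo or a > hi:
                        if a < lo:
                            a = 2 * lo - a
                        else:
                            a = 2 * hi - a
            alleles[node] = a
        for tip in range(n):
            mat[tip, locus] = alleles[tip]
    return STRDataset(names, pops, mat)


# ---------------------------------------------------------------------------
# Dataset composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingDesign:
    """Per-population sample sizes for the two marker classes."""

    n_mt: Mapping[str, int]
    n_str: Mapping[str, int]
    duplicate_str_copies: bool = True
    """Emit two identical gene copies per simulated haploid strain lineage
    (near-isogenic selfing strains), matching the observed doubling of STR
    gene-copy counts.  When False, each simulated copy is independent
    (fully-diploid mode)."""

    @classmethod
    def from_scenario(cls, scenario: Scenario, **kw) -> "SamplingDesign":
        return cls(
            n_mt={p.label: p.n_mt for p in scenario.populations if p.n_mt > 0},
            n_str={p.label: p.n_str for p in scenario.populations if p.n_str > 0},
            **kw,
        )


def simulate_dataset(
    scenario: Scenario,
    draw: ParameterDraw,
    design: SamplingDesign,
    rng: np.random.Generator | int | None = None,
) -> DatasetBundle:
    """Simulate one full dataset: mtDNA alignment + STR table + provenance."""
    rng = np.random.default_rng(rng)
    mt_sampling = {k: v for k, v in design.n_mt.items() if v > 0}
    if mt_sampling:
        g_mt = simulate_genealogy(scenario, draw, mt_sampling, "mt", rng)
        mt = evolve_sequences(g_mt, draw.mt_model, rng)
    else:
        mt = SequenceAlignment([], [], np.empty((0, draw.mt_model.length), np.uint8))

    str_sampling = {k: v for k, v in design.n_str.items() if v > 0}
    if str_sampling:
        if design.duplicate_str_copies:
            # simulate one lineage per strain, emit each copy twice
            half = {k: max(v // 2, 1) for k, v in str_sampling.items()}
            gens = [
                simulate_genealogy(scenario, draw, half, "nuclear", rng)
                for _ in range(draw.str_model.n_loci)
            ]
            base = evolve_strs(gens, draw.str_model, rng)
            idx = np.repeat(np.arange(base.n), 2)
            names = [
                f"{base.names[i]}{'ab'[k % 2]}" for k, i in enumerate(idx)
            ]
            strs = STRDataset(
                names, [base.pops[i] for i in idx], base.matrix[idx], base.locus_names
            )
        else:
            gens = [
                simulate_genealogy(scenario, draw, str_sampling, "nuclear", rng)
                for _ in range(draw.str_model.n_loci)
            ]
            strs = evolve_strs(gens, draw.str_model, rng)
    else:
        strs = STRDataset([], [], np.empty((0, draw.str_model.n_loci), np.int64))

    return DatasetBundle(
        mt=mt,
        strs=strs,
        provenance={
            "scenario_id": scenario.scenario_id,
            "colonization_order": "".join(scenario.colonization_order),
            "draw": draw.as_flat_dict(),
        },
    )
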