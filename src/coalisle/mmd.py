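"""Mismatch-distribution analysis of demographic expansion.

The mismatch distribution (MMD) is the histogram of pairwise nucleotide
differences among sampled sequences.  Under a sudden demographic expansion
(scaled pre-/post-expansion sizes θ0 = 2N0μ and θ1 = 2N1μ, scaled time
τ = 2μt, with μ the per-locus mutation rate), the expected class
frequencies follow the Rogers-Harpending closed form

    F_i(τ, θ0, θ1) = F̂_i(θ1)
        + e^{-τ(θ1+1)/θ1} Σ_{j=0}^{i} (τ^j / j!) [F̂_{i-j}(θ0) − F̂_{i-j}(θ1)]

where F̂_i(θ) = θ^i / (1+θ)^{i+1} is the equilibrium (geometric)
distribution.  Parameters are estimated by least squares against the
observed frequencies; goodness of fit is assessed by the sum of squared
deviations (SSD) and Harpending's raggedness index, each with a parametric
bootstrap p-value (coalescent simulation under the fitted expansion).
Fitted τ converts to time since expansion in years as t = τ / (2 μ_locus).

Typical use::

    model = MismatchExpansionModel.from_alignment(aln)
    res = model.fit(n_boot=1000, rng=1)
    res.summary()
    res.expansion_time_years(mu_locus=4.294e-5)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .coalsim import evolve_sequences, single_population_genealogy
from .containers import SequenceAlignment
from .demography import MutationModelMt
from .sumstats import UndefinedStatisticError, _pair_distances

__all__ = [
    "MismatchDistribution",
    "observed_mismatch",
    "equilibrium_mismatch",
    "expansion_mismatch",
    "raggedness",
    "fit_expansion",
    "bootstrap_pvalues",
    "locus_rate",
    "expansion_time",
    "simulate_expansion_alignment",
    "MismatchExpansionModel",
    "MismatchExpansionResults",
]


@dataclass
class MismatchDistribution:
    """Histogram of pairwise difference counts, classes 0..d_max."""

    counts: np.ndarray  # int, length d_max + 1
    n_pairs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.n_pairs:
            raise ValueError("counts must sum to the number of pairs")

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_pairs

    @property
    def mean(self) -> float:
        return float(np.sum(np.arange(len(self.counts)) * self.frequencies))


def observed_mismatch(aln: SequenceAlignment) -> MismatchDistribution:
    """Observed MMD over all unordered sequence pairs (pairwise deletion of
    non-ACGT sites, as in the distance statistics)."""
    if aln.n < 2:
        raise UndefinedStatisticError("mismatch distribution needs >= 2 sequences")
    d = _pair_distances(aln).astype(np.int64)
    counts = np.bincount(d)
    return MismatchDistribution(counts, len(d))


def equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """Equilibrium class frequencies F̂_i(θ) = θ^i/(1+θ)^(i+1), renormalized
    over the truncated support 0..d_max."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    i = np.arange(d_max + 1)
    if theta == 0:
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    # geometric: p * (1-p)^i with p = 1/(1+theta)
    logf = i * math.log(theta / (1.0 + theta)) - math.log(1.0 + theta)
    f = np.exp(logf)
    return f / f.sum()


def _equilibrium_raw(theta: float, d_max: int) -> np.ndarray:
    """F̂_i(θ) without truncation renormalization (used inside the expansion
    series, which is renormalized as a whole)."""
    i = np.arange(d_max + 1)
    if np.isinf(theta):
        return np.zeros(d_max + 1)
    if theta == 0:
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    return np.exp(i * math.log(theta / (1.0 + theta)) - math.log(1.0 + theta))


from scipy.special import gammaln as _gammaln

_GAMMALN_CACHE: dict[int, np.ndarray] = {}


def _poisson_pmf(d_max: int, tau: float) -> np.ndarray:
    lg = _GAMMALN_CACHE.get(d_max)
    if lg is None:
        lg = _gammaln(np.arange(d_max + 2, dtype=float))[1:]
        _GAMMALN_CACHE[d_max] = lg
    j = np.arange(d_max + 1)
    with np.errstate(divide="ignore"):
        return np.exp(-tau + j * np.log(tau) - lg)


def expansion_mismatch(
    theta0: float, theta1: float, tau: float, d_max: int
) -> np.ndarray:
    """Sudden-expansion class frequencies, truncated and renormalized.

    ``theta1 = numpy.inf`` is supported as the infinite-growth limit (with
    θ0 = 0 this reduces to the Poisson(τ) mass function).
    """
    if theta0 < 0 or tau < 0 or (theta1 < 0 and not np.isinf(theta1)):
        raise ValueError("parameters must be non-negative")
    f1 = _equilibrium_raw(theta1, d_max)
    if tau == 0:
        f = _equilibrium_raw(theta0, d_max)
        return f / f.sum()
    if theta1 == 0:
        # post-expansion population of size zero: all coalescence instantaneous
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    f0 = _equilibrium_raw(theta0, d_max)
    # e^{-τ(θ1+1)/θ1} τ^j/j!  =  PoissonPMF(j; τ) · e^{-τ/θ1}   (stable form)
    decay = 1.0 if np.isinf(theta1) else math.exp(-tau / theta1)
    pois = _poisson_pmf(d_max, tau)
    conv = np.convolve(pois, f0 - f1)[: d_max + 1]
    f = f1 + decay * conv
    f = np.clip(f, 0.0, None)
    s = f.sum()
    if s <= 0:
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    return f / s


def raggedness(dist: MismatchDistribution | np.ndarray) -> float:
    """Harpending's raggedness index r = Σ_{i=1}^{d+1} (x_i − x_{i−1})²
    with x_{d+1} := 0."""
    x = dist.frequencies if isinstance(dist, MismatchDistribution) else np.asarray(dist, float)
    ext = np.concatenate([x, [0.0]])
    return float(np.sum(np.diff(ext) ** 2))


# ---------------------------------------------------------------------------
# Least-squares fitting
# ---------------------------------------------------------------------------

THETA_MAX = 100.0
TAU_MAX = 50.0


class FittingError(RuntimeError):
    pass


def _ssd(params: np.ndarray, x: np.ndarray, d_max: int) -> float:
    t0, t1, tau = params
    f = expansion_mismatch(t0, t1, tau, d_max)
    return float(np.sum((x - f) ** 2))


def _grid_best(x: np.ndarray, d_max: int, mean: float) -> tuple[float, float, float]:
    """Best (θ0, θ1, τ) on a coarse grid, evaluated fully vectorized.

    Used to seed the local optimizer; the grid spans the plausible corner
    (θ0 small, θ1 moderate-to-large, τ near the observed mean).
    """
    theta0s = np.array([1e-3, 0.25, 0.75, 1.5, 3.0, 8.0])
    theta1s = np.array([0.5, 2.0, 8.0, 30.0, 100.0])
    taus = np.linspace(1e-3, min(2.0 * mean + 1.0, TAU_MAX), 14)
    d1 = d_max + 1
    f0 = np.stack([_equilibrium_raw(t, d_max) for t in theta0s])  # (n0, d1)
    f1 = np.stack([_equilibrium_raw(t, d_max) for t in theta1s])  # (n1, d1)
    pois = np.stack([_poisson_pmf(d_max, t) for t in taus])  # (nt, d1)
    P = np.zeros((len(taus), d1, d1))
    for i in range(d1):
        P[:, i, : i + 1] = pois[:, i::-1]
    G = f0[:, None, :] - f1[None, :, :]  # (n0, n1, d1)
    C = np.einsum("tij,abj->tabi", P, G)
    decay = np.exp(-taus[:, None] / theta1s[None, :])  # (nt, n1)
    F = f1[None, None, :, :] + decay[:, None, :, None] * C
    np.clip(F, 0.0, None, out=F)
    S = F.sum(axis=-1, keepdims=True)
    S[S <= 0] = 1.0
    F /= S
    ssd = np.sum((F - x) ** 2, axis=-1)
    t_i, a_i, b_i = np.unravel_index(np.argmin(ssd), ssd.shape)
    return float(theta0s[a_i]), float(theta1s[b_i]), float(taus[t_i])


def fit_expansion(
    observed: MismatchDistribution,
    n_starts: int = 20,
    rng: np.random.Generator | int | None = 0,
    xatol: float = 1e-6,
    fatol: float = 1e-12,
    maxiter: int = 2000,
) -> tuple[float, float, float, float]:
    """Least-squares fit of (θ0, θ1, τ) to an observed MMD.

    Multi-start bounded Nelder-Mead over θ0, θ1 ∈ [0, 100], τ ∈ [0, 50];
    the SSD surface is multimodal, so several starts (including a
    moment-based one: τ near the observed mean) are tried and the best SSD
    wins, ties going to the lowest τ.  Returns (theta0, theta1, tau, ssd).
    """
    if len(observed.counts) < 2:
        # degenerate single-class data: all sequences identical
        return 0.0, 0.0, 0.0, 0.0
    rng = np.random.default_rng(rng)
    x = observed.frequencies
    d_max = observed.d_max
    mean = observed.mean

    starts = [
        _grid_best(x, d_max, mean),
        (0.1, 10.0, min(mean, TAU_MAX)),
        (1.0, THETA_MAX / 2, min(mean, TAU_MAX)),
        (0.5, 5.0, min(max(mean / 2, 0.1), TAU_MAX)),
    ]
    while len(starts) < n_starts:
        starts.append(
            (
                float(rng.uniform(0, 5)),
                float(10 ** rng.uniform(-1, 2)),
                float(rng.uniform(0, min(2.5 * mean + 1, TAU_MAX))),
            )
        )
    starts = starts[:n_starts]

    best = None
    n_ok = 0
    for s in starts:
        try:
            res = optimize.minimize(
                _ssd,
                np.asarray(s, float),
                args=(x, d_max),
                method="Nelder-Mead",
                bounds=[(0, THETA_MAX), (0, THETA_MAX), (0, TAU_MAX)],
                options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
            )
        except Exception:
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        cand = (float(res.fun), float(res.x[2]), float(res.x[0]), float(res.x[1]))
        if best is None or cand < best:  # ties broken toward lowest tau
            best = cand
    if best is None or n_ok == 0:
        raise FittingError("expansion fit failed to converge from any start")
    ssd, tau, t0, t1 = best
    return t0, t1, tau, ssd


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

#: per-locus rate used to de-scale (θ, τ) into simulator units; the MMD is a
#: function of the scaled parameters only, so this choice is arbitrary
_BOOT_MU_LOCUS = 1e-3


def simulate_expansion_alignment(
    n: int,
    length: int,
    theta0: float,
    theta1: float,
    tau: float,
    rng: np.random.Generator | int | None = None,
) -> SequenceAlignment:
    """Simulate sequences under the fitted sudden expansion.

    A single population changes size N1 → N0 at scaled time τ backward from
    the present (θ = 2Nμ_locus, τ = 2μ_locus t, pair-coalescence rate 1/N);
    sequences evolve under a rate-homogeneous substitution model over
    ``length`` sites.
    """
    rng = np.random.default_rng(rng)
    mu = _BOOT_MU_LOCUS
    t_change = tau / (2 * mu)
    n0 = max(theta0 / (2 * mu), 1e-6)
    n1 = max(theta1 / (2 * mu), 1e-6)
    g = single_population_genealogy(
        n, [(0.0, n1), (t_change, n0)], c=1.0, rng=rng
    )
    model = MutationModelMt(
        kappa=1.0,
        base_freqs=(0.25, 0.25, 0.25, 0.25),
        gamma_shape=1.0,
        prop_invariant=0.0,
        mu_site=mu / length,
        length=length,
        n_categories=1,
    )
    return evolve_sequences(g, model, rng)


def bootstrap_pvalues(
    aln: SequenceAlignment,
    fit: tuple[float, float, float, float],
    n_boot: int,
    rng: np.random.Generator | int | None = None,
    n_starts: int = 1,
    refit_xatol: float = 1e-4,
    refit_fatol: float = 1e-10,
    refit_maxiter: int = 200,
) -> tuple[float, float]:
    """Parametric-bootstrap p-values for SSD and raggedness.

    ``n_boot`` coalescent replicates are simulated under the fitted
    expansion (matching sample size and locus length) and refitted; the
    p-value is the proportion of replicates whose statistic is strictly
    larger than the observed one (ties count as non-exceedances).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    t0, t1, tau, ssd_obs = fit
    rag_obs = raggedness(observed_mismatch(aln))
    n_exc_ssd = 0
    n_exc_rag = 0
    for _ in range(n_boot):
        sim = simulate_expansion_alignment(aln.n, aln.n_sites, t0, t1, tau, rng)
        dist = observed_mismatch(sim)
        _, _, _, ssd_b = fit_expansion(
            dist, n_starts=n_starts, rng=rng,
            xatol=refit_xatol, fatol=refit_fatol, maxiter=refit_maxiter,
        )
        if ssd_b > ssd_obs:
            n_exc_ssd += 1
        if raggedness(dist) > rag_obs:
            n_exc_rag += 1
    return n_exc_ssd / n_boot, n_exc_rag / n_boot


# ---------------------------------------------------------------------------
# tau -> t dating
# ---------------------------------------------------------------------------

def locus_rate(mu_site: float, length: int, gens_per_year: float = 1.0) -> float:
    """Per-locus per-year mutation rate μ_locus = μ_site × length / (gens/yr)."""
    if mu_site <= 0 or length <= 0 or gens_per_year <= 0:
        raise ValueError("mu_site, length and gens_per_year must be positive")
    return mu_site * length / gens_per_year


def expansion_time(
    tau: float, mu_locus: float, rounding: int | None = 1000
) -> float:
    """Time since expansion t = τ/(2 μ_locus) in years before present,
    rounded to the nearest ``rounding`` years (default 1,000; None = exact)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if mu_locus <= 0:
        raise ValueError("mu_locus must be positive")
    t = tau / (2.0 * mu_locus)
    if rounding:
        t = round(t / rounding) * rounding
    return float(t)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MismatchExpansionModel:
    """Sudden-expansion model for the mismatch distribution of one sample.

    Build from a sequence alignment (``from_alignment``) or directly from a
    ``MismatchDistribution``; ``fit`` returns a
    :class:`MismatchExpansionResults`.
    """

    def __init__(
        self,
        distribution: MismatchDistribution,
        alignment: SequenceAlignment | None = None,
        label: str = "",
    ):
        self.distribution = distribution
        self.alignment = alignment
        self.label = label

    @classmethod
    def from_alignment(cls, aln: SequenceAlignment, label: str = "") -> "MismatchExpansionModel":
        return cls(observed_mismatch(aln), aln, label)

    def fit(
        self,
        n_boot: int = 0,
        n_starts: int = 20,
        rng: np.random.Generator | int | None = 0,
    ) -> "MismatchExpansionResults":
        rng = np.random.default_rng(rng)
        t0, t1, tau, ssd = fit_expansion(self.distribution, n_starts=n_starts, rng=rng)
        rag = raggedness(self.distribution)
        p_ssd = p_rag = float("nan")
        if n_boot > 0:
            if self.alignment is None:
                raise ValueError("bootstrap p-values need the underlying alignment")
            p_ssd, p_rag = bootstrap_pvalues(
                self.alignment, (t0, t1, tau, ssd), n_boot, rng
            )
        return MismatchExpansionResults(
            model=self,
            theta0=t0,
            theta1=t1,
            tau=tau,
            ssd=ssd,
            raggedness=rag,
            p_ssd=p_ssd,
            p_raggedness=p_rag,
            n_boot=n_boot,
        )


@dataclass
class MismatchExpansionResults:
    model: MismatchExpansionModel
    theta0: float
    theta1: float
    tau: float
    ssd: float
    raggedness: float
    p_ssd: float
    p_raggedness: float
    n_boot: int

    @property
    def fitted_frequencies(self) -> np.ndarray:
        return expansion_mismatch(
            self.theta0, self.theta1, self.tau, self.model.distribution.d_max
        )

    def expansion_time_years(
        self, mu_locus: float, rounding: int | None = 1000
    ) -> float:
        """Dating: t = τ/(2 μ_locus) years before present."""
        return expansion_time(self.tau, mu_locus, rounding)

    def summary(self) -> str:
        lab = f" [{self.model.label}]" if self.model.label else ""
        lines = [
            f"Mismatch-distribution sudden-expansion fit{lab}",
            "=" * 48,
            f"pairs: {self.model.distribution.n_pairs}   "
            f"classes: 0..{self.model.distribution.d_max}",
            f"theta0     {self.theta0:10.4f}",
            f"theta1     {self.theta1:10.4f}",
            f"tau        {self.tau:10.4f}",
            f"SSD        {self.ssd:10.6f}" + (
                f"   P(SSD sim > obs) = {self.p_ssd:.4f}" if self.n_boot else ""
            ),
            f"raggedness {self.raggedness:10.6f}" + (
                f"   P(rag sim > obs) = {self.p_raggedness:.4f}" if self.n_boot else ""
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs fitted mismatch distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.model.distribution.d_max + 1)
        ax.bar(x, self.model.distribution.frequencies, alpha=0.5, label="observed")
        ax.plot(x, self.fitted_frequencies, "o-", color="C3", label="fitted expansion")
        ax.set_xlabel("pairwise differences")
        ax.set_ylabel("frequency")
        if self.model.label:
            ax.set_title(self.model.label)
        ax.legend()
        return ax
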