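"""Demographic scenarios for island colonization following lineage diversification.

The model describes nine populations: an unsampled source ``U``, four
"world" genetic lineages ``A``-``D`` that coalesce into ``U`` (backward in
time) at times ``t5``-``t8``, and four island populations ``a``-``d`` founded
from their respective lineages at colonization times ``t1``-``t4``.  Each
island founding is accompanied by a bottleneck of size ``N5``-``N8`` lasting
``db`` generations.  The order of events is constrained:

    t8 > t6, t7 > t6, t6 > t4, t5 > t4, t4 > t3 > t2 > t1

i.e. lineage diversification proceeds ``U > A/D > B/C`` (the mutual order of
t8/t7 and of t6/t5 is free) and colonization is strictly ordered, with ``t4``
assigned to the earliest-colonizing island and ``t1`` to the latest.  The 24
candidate scenarios are the 24 permutations of the colonization order of
(a, b, c, d).

Times are in generations, sizes in (effective) individuals.  All priors are
independent uniforms; order constraints are imposed by rejection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PopulationSpec",
    "BottleneckSpec",
    "SplitEvent",
    "Scenario",
    "PriorSpec",
    "MutationModelMt",
    "MutationModelStr",
    "ParameterDraw",
    "default_template",
    "default_priors",
    "enumerate_colonization_scenarios",
    "draw_parameters",
    "validate_constraints",
    "scenario_to_dict",
    "scenario_from_dict",
    "priors_to_yaml",
    "priors_from_yaml",
    "scenarios_to_yaml",
    "scenarios_from_yaml",
]

ISLANDS = ("a", "b", "c", "d")
LINEAGES = ("A", "B", "C", "D")
#: island -> parent world lineage
PAIRING = {"a": "A", "b": "B", "c": "C", "d": "D"}
#: world lineage -> coalescence-time parameter (D oldest by template label)
LINEAGE_TIME = {"D": "t8", "A": "t7", "C": "t6", "B": "t5"}
#: island -> founder-bottleneck size parameter (fixed mapping)
ISLAND_BOTTLENECK = {"a": "N5", "b": "N6", "c": "N7", "d": "N8"}
#: lineage/island pair -> shared present-day size parameter
PAIR_SIZE = {"A": "N1", "B": "N2", "C": "N3", "D": "N4"}

TIME_PARAMS = ("t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8")
SIZE_PARAMS = ("N_A", "N1", "N2", "N3", "N4", "N5", "N6", "N7", "N8")

#: the fixed order-constraint chain, as (older, younger) pairs
CONSTRAINT_CHAIN = (
    ("t8", "t6"),
    ("t7", "t6"),
    ("t6", "t4"),
    ("t5", "t4"),
    ("t4", "t3"),
    ("t3", "t2"),
    ("t2", "t1"),
)


class StructuralError(ValueError):
    """Raised for malformed scenario templates."""


class ConfigurationError(ValueError):
    """Raised for unsatisfiable or inconsistent prior/constraint settings."""


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    role: str  # 'unsampled_source' | 'world_lineage' | 'island_population'
    n_mt: int = 0
    n_str: int = 0

    def __post_init__(self) -> None:
        if self.n_mt < 0 or self.n_str < 0:
            raise StructuralError(f"negative sample size for population {self.label!r}")
        if self.role == "unsampled_source" and (self.n_mt or self.n_str):
            raise StructuralError("the unsampled source population cannot be sampled")


@dataclass(frozen=True)
class BottleneckSpec:
    size_param: str
    duration_param: str = "db"


@dataclass(frozen=True)
class SplitEvent:
    """One population merger, looking backward in time: ``child`` joins ``parent``."""

    time_param: str
    child: str
    parent: str
    bottleneck: BottleneckSpec | None = None

    def __post_init__(self) -> None:
        if self.child == self.parent:
            raise StructuralError("split child and parent must differ")


@dataclass(frozen=True)
class Scenario:
    scenario_id: int
    populations: tuple[PopulationSpec, ...]
    events: tuple[SplitEvent, ...]  # ordered oldest -> youngest
    colonization_order: tuple[str, ...]  # earliest colonizer first
    constraints: tuple[tuple[str, str], ...] = CONSTRAINT_CHAIN

    def __post_init__(self) -> None:
        labels = {p.label for p in self.populations}
        if "U" not in labels:
            raise StructuralError("a scenario needs the unsampled source population U")
        n_island = sum(p.role == "island_population" for p in self.populations)
        if n_island == 4 and (len(self.populations) != 9 or len(self.events) != 8):
            raise StructuralError(
                "the full four-island scenario has exactly 9 populations and 8 events"
            )
        for ev in self.events:
            if ev.child not in labels or ev.parent not in labels:
                raise StructuralError(f"event references unknown population: {ev}")
        # the event graph must be a tree rooted at U: every non-U population
        # is the child of exactly one event
        children = [ev.child for ev in self.events]
        if sorted(children) != sorted(labels - {"U"}):
            raise StructuralError("event graph is not a tree rooted at U")

    @property
    def population(self) -> Mapping[str, PopulationSpec]:
        return {p.label: p for p in self.populations}

    @property
    def colonization_times(self) -> dict[str, str]:
        """Island label -> its colonization-time parameter under this order."""
        order = self.colonization_order
        # earliest colonizer gets the oldest time (t4 for four islands)
        return {isl: f"t{len(order) - i}" for i, isl in enumerate(order)}

    def sampled_populations(self, locus_kind: str = "mt") -> list[str]:
        attr = "n_mt" if locus_kind == "mt" else "n_str"
        return [p.label for p in self.populations if getattr(p, attr) > 0]


@dataclass(frozen=True)
class MutationModelMt:
    """HKY + discrete-Gamma + invariant-sites model for the mtDNA fragment."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 2.0
    prop_invariant: float = 0.10
    mu_site: float = 7.6e-8  # substitutions / site / generation
    length: int = 565
    n_categories: int = 4

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if not (0.0 <= self.prop_invariant < 1.0):
            raise ValueError("prop_invariant must lie in [0, 1)")
        if self.gamma_shape <= 0 or self.mu_site <= 0:
            raise ValueError("gamma_shape and mu_site must be positive")


@dataclass(frozen=True)
class MutationModelStr:
    """Generalized stepwise mutation model shared by the microsatellite loci.

    Each locus draws its own mean rate from Gamma(shape=locus_rate_shape,
    mean=mean_rate).  A mutation changes the repeat count by ±k, sign
    equiprobable, with k - 1 geometric: ``p_geom = 1`` recovers the strict
    single-step SMM.
    """

    mean_rate: float = 1e-5  # effective per-locus per-generation rate
    locus_rate_shape: float = 2.0
    p_geom: float = 0.22
    n_loci: int = 16
    ancestral_allele: int = 100
    range_states: int | None = 40  # reflecting allele-size window; None = unbounded

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be non-negative")
        if not (0.0 < self.p_geom <= 1.0):
            raise ValueError("p_geom must lie in (0, 1]")


@dataclass(frozen=True)
class ParameterDraw:
    times: dict[str, float]  # t1..t8, generations
    sizes: dict[str, float]  # N_A, N1..N8, individuals
    db: float  # bottleneck duration, generations
    mt_model: MutationModelMt = field(default_factory=MutationModelMt)
    str_model: MutationModelStr = field(default_factory=MutationModelStr)

    def __getitem__(self, name: str) -> float:
        if name in self.times:
            return self.times[name]
        if name in self.sizes:
            return self.sizes[name]
        if name == "db":
            return self.db
        raise KeyError(name)

    def as_flat_dict(self) -> dict[str, float]:
        out = dict(self.times)
        out.update(self.sizes)
        out["db"] = self.db
        return out


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds per parameter plus mutation hyper-settings.

    Defaults follow the study design: lineage-coalescence times t5-t8 ~
    U(10,000, 1,000,000) generations, colonization times t1-t4 ~
    U(1,000, 250,000) generations.  Size priors: present-day and ancestral
    sizes ~ U(100, 100,000); founder-bottleneck sizes ~ U(2, 1,000); the
    bottleneck duration db is fixed at 5 generations by default but may be
    drawn ~ U(1, 100) by setting ``db_fixed=None``.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: _default_bounds())
    db_fixed: float | None = 5.0
    mt_model: MutationModelMt = field(default_factory=MutationModelMt)
    str_model: MutationModelStr = field(default_factory=MutationModelStr)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ConfigurationError(
                    f"prior for {name!r} must satisfy 0 < min < max, got ({lo}, {hi})"
                )


def _default_bounds() -> dict[str, tuple[float, float]]:
    b: dict[str, tuple[float, float]] = {}
    for t in ("t1", "t2", "t3", "t4"):
        b[t] = (1_000.0, 250_000.0)
    for t in ("t5", "t6", "t7", "t8"):
        b[t] = (10_000.0, 1_000_000.0)
    for n in ("N_A", "N1", "N2", "N3", "N4"):
        b[n] = (100.0, 100_000.0)
    for n in ("N5", "N6", "N7", "N8"):
        b[n] = (2.0, 1_000.0)
    b["db"] = (1.0, 100.0)
    return b


def default_priors(**overrides) -> PriorSpec:
    return PriorSpec(**overrides)


def default_template(
    n_mt: Mapping[str, int] | None = None,
    n_str: Mapping[str, int] | None = None,
) -> Scenario:
    """The study-shaped scenario skeleton (order c>a>b>d as a placeholder).

    Default sample sizes follow the study's gene-copy counts: mtDNA copies
    A=58, B=29, C=163, D=33 (world) and a=22, b=29, c=30, d=16 (island);
    microsatellite gene copies are twice the mtDNA counts (two identical
    copies per near-isogenic strain).
    """
    mt = {"A": 58, "B": 29, "C": 163, "D": 33, "a": 22, "b": 29, "c": 30, "d": 16}
    if n_mt is not None:
        mt.update(n_mt)
    strc = {k: 2 * v for k, v in mt.items()}
    if n_str is not None:
        strc.update(n_str)
    pops = [PopulationSpec("U", "unsampled_source")]
    pops += [
        PopulationSpec(L, "world_lineage", mt.get(L, 0), strc.get(L, 0)) for L in LINEAGES
    ]
    pops += [
        PopulationSpec(i, "island_population", mt.get(i, 0), strc.get(i, 0)) for i in ISLANDS
    ]
    return _scenario_for_order(0, tuple(pops), ("c", "a", "b", "d"))


def _scenario_for_order(
    scenario_id: int, populations: tuple[PopulationSpec, ...], order: Sequence[str]
) -> Scenario:
    events = [
        SplitEvent(LINEAGE_TIME[L], child=L, parent="U") for L in ("D", "A", "C", "B")
    ]
    for i, isl in enumerate(order):  # earliest colonizer first -> t4 .. t1
        events.append(
            SplitEvent(
                f"t{4 - i}",
                child=isl,
                parent=PAIRING[isl],
                bottleneck=BottleneckSpec(ISLAND_BOTTLENECK[isl]),
            )
        )
    return Scenario(
        scenario_id=scenario_id,
        populations=populations,
        events=tuple(events),
        colonization_order=tuple(order),
    )


def enumerate_colonization_scenarios(template: Scenario) -> list[Scenario]:
    """All colonization-order scenarios generated from ``template``.

    One scenario per permutation of the template's island populations, with
    the oldest colonization time (t4 for four islands) assigned to the
    earliest colonizer.  Scenario ids follow the lexicographic order of the
    permutations and are therefore stable.
    """
    islands = sorted(
        p.label for p in template.populations if p.role == "island_population"
    )
    if not islands:
        raise StructuralError("template has no island populations")
    for isl in islands:
        if isl not in PAIRING:
            raise StructuralError(f"island {isl!r} has no paired world lineage")
    full = set(ISLANDS)
    out = []
    for sid, perm in enumerate(sorted(itertools.permutations(islands))):
        if set(islands) == full:
            out.append(_scenario_for_order(sid, template.populations, perm))
        else:
            # reduced templates (fewer islands) keep the template's event list
            # for non-island structure; only used in toy settings
            out.append(_reduced_scenario(sid, template, perm))
    return out


def _reduced_scenario(
    scenario_id: int, template: Scenario, order: Sequence[str]
) -> Scenario:
    events = [ev for ev in template.events if ev.child not in ISLANDS]
    for i, isl in enumerate(order):
        events.append(
            SplitEvent(
                f"t{len(order) - i}",
                child=isl,
                parent=PAIRING[isl],
                bottleneck=BottleneckSpec(ISLAND_BOTTLENECK[isl]),
            )
        )
    return replace(
        template,
        scenario_id=scenario_id,
        events=tuple(events),
        colonization_order=tuple(order),
    )


def validate_constraints(draw: ParameterDraw, scenario: Scenario) -> bool:
    """True iff the draw satisfies the scenario's event-order constraints.

    Checks the constraint chain and, additionally, that every colonization
    time is younger than every lineage-coalescence time.
    """
    t = draw.times
    for older, younger in scenario.constraints:
        if older in t and younger in t and not (t[older] > t[younger]):
            return False
    colon = [t[p] for p in ("t1", "t2", "t3", "t4") if p in t]
    coal = [t[p] for p in ("t5", "t6", "t7", "t8") if p in t]
    if colon and coal and max(colon) >= min(coal):
        return False
    return True


REJECTION_CAP = 10_000


def draw_parameters(
    scenario: Scenario,
    priors: PriorSpec,
    rng: np.random.Generator | int | None = None,
) -> ParameterDraw:
    """One prior draw satisfying the scenario's order constraints (rejection).

    Raises ConfigurationError after ``REJECTION_CAP`` rejected attempts —
    this fails fast when prior bounds make the constraint chain unsatisfiable.
    """
    rng = np.random.default_rng(rng)
    needed_times = sorted({ev.time_param for ev in scenario.events})
    for name in needed_times:
        if name not in priors.bounds:
            raise ConfigurationError(f"no prior bound for parameter {name!r}")
    colon = [i for i, n in enumerate(needed_times) if n in ("t1", "t2", "t3", "t4")]
    coal = [i for i, n in enumerate(needed_times) if n in ("t5", "t6", "t7", "t8")]
    chain = [
        (needed_times.index(o), needed_times.index(y))
        for o, y in scenario.constraints
        if o in needed_times and y in needed_times
    ]
    los = np.array([priors.bounds[n][0] for n in needed_times])
    his = np.array([priors.bounds[n][1] for n in needed_times])

    # vectorized rejection in blocks: accept the first candidate satisfying
    # the order constraints (unbiased; identical to one-at-a-time rejection)
    block = 256
    attempts = 0
    times_vec = None
    while attempts < REJECTION_CAP:
        cand = rng.uniform(los, his, size=(block, len(needed_times)))
        ok = np.ones(block, bool)
        for o, y in chain:
            ok &= cand[:, o] > cand[:, y]
        if colon and coal:
            ok &= cand[:, colon].max(axis=1) < cand[:, coal].min(axis=1)
        hit = np.flatnonzero(ok)
        if hit.size:
            times_vec = cand[hit[0]]
            break
        attempts += block
    if times_vec is None:
        raise ConfigurationError(
            f"no constraint-satisfying draw in {REJECTION_CAP} attempts; "
            "check prior bounds against the order constraints"
        )
    times = {n: float(v) for n, v in zip(needed_times, times_vec)}
    sizes = {
        name: float(rng.uniform(*priors.bounds[name]))
        for name in SIZE_PARAMS
        if name in priors.bounds
    }
    db = (
        priors.db_fixed
        if priors.db_fixed is not None
        else rng.uniform(*priors.bounds["db"])
    )
    return ParameterDraw(
        times=times,
        sizes=sizes,
        db=float(db),
        mt_model=priors.mt_model,
        str_model=priors.str_model,
    )


# ---------------------------------------------------------------------------
# YAML serialization (lossless round-trip)
# ---------------------------------------------------------------------------

def scenario_to_dict(s: Scenario) -> dict:
    return {
        "scenario_id": s.scenario_id,
        "colonization_order": list(s.colonization_order),
        "populations": [
            {"label": p.label, "role": p.role, "n_mt": p.n_mt, "n_str": p.n_str}
            for p in s.populations
        ],
        "events": [
            {
                "time_param": ev.time_param,
                "child": ev.child,
                "parent": ev.parent,
                **(
                    {
                        "bottleneck": {
                            "size_param": ev.bottleneck.size_param,
                            "duration_param": ev.bottleneck.duration_param,
                        }
                    }
                    if ev.bottleneck
                    else {}
                ),
            }
            for ev in s.events
        ],
        "constraints": [list(c) for c in s.constraints],
    }


def scenario_from_dict(d: dict) -> Scenario:
    return Scenario(
        scenario_id=int(d["scenario_id"]),
        populations=tuple(
            PopulationSpec(p["label"], p["role"], int(p["n_mt"]), int(p["n_str"]))
            for p in d["populations"]
        ),
        events=tuple(
            SplitEvent(
                ev["time_param"],
                ev["child"],
                ev["parent"],
                BottleneckSpec(**ev["bottleneck"]) if "bottleneck" in ev else None,
            )
            for ev in d["events"]
        ),
        colonization_order=tuple(d["colonization_order"]),
        constraints=tuple(tuple(c) for c in d["constraints"]),
    )


def scenarios_to_yaml(scenarios: Iterable[Scenario]) -> str:
    return yaml.safe_dump(
        {"scenarios": [scenario_to_dict(s) for s in scenarios]}, sort_keys=False
    )


def scenarios_from_yaml(text: str) -> list[Scenario]:
    return [scenario_from_dict(d) for d in yaml.safe_load(text)["scenarios"]]


def priors_to_yaml(p: PriorSpec) -> str:
    d = {
        "bounds": {k: [float(lo), float(hi)] for k, (lo, hi) in p.bounds.items()},
        "db_fixed": p.db_fixed,
        "mt_model": {
            "kappa": p.mt_model.kappa,
            "base_freqs": list(p.mt_model.base_freqs),
            "gamma_shape": p.mt_model.gamma_shape,
            "prop_invariant": p.mt_model.prop_invariant,
            "mu_site": p.mt_model.mu_site,
            "length": p.mt_model.length,
            "n_categories": p.mt_model.n_categories,
        },
        "str_model": {
            "mean_rate": p.str_model.mean_rate,
            "locus_rate_shape": p.str_model.locus_rate_shape,
            "p_geom": p.str_model.p_geom,
            "n_loci": p.str_model.n_loci,
            "ancestral_allele": p.str_model.ancestral_allele,
            "range_states": p.str_model.range_states,
        },
    }
    return yaml.safe_dump(d, sort_keys=False)


def priors_from_yaml(text: str) -> PriorSpec:
    d = yaml.safe_load(text)
    mt = d.get("mt_model", {})
    if "base_freqs" in mt:
        mt["base_freqs"] = tuple(mt["base_freqs"])
    return PriorSpec(
        bounds={k: (float(v[0]), float(v[1])) for k, v in d["bounds"].items()},
        db_fixed=d.get("db_fixed"),
        mt_model=MutationModelMt(**mt),
        str_model=MutationModelStr(**d.get("str_model", {})),
    )
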