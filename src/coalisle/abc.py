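"""Approximate Bayesian computation over colonization scenarios.

The ABC substrate is a reference table of (scenario id, parameter draw,
summary vector) rows simulated from the priors.  Inference follows the
classic rejection + regression recipe:

* rejection keeps the fraction ``tolerance`` of simulations whose summary
  vectors are closest to the observed one in scale-normalized Euclidean
  distance (scales are robust SDs, 1.4826×MAD, over the whole table);
* scenario choice fits a ridge-regularized multinomial logistic regression
  of the scenario label on the summary deviations over the retained set and
  reads the posterior probabilities off at zero deviation;
* parameter estimation applies local-linear regression adjustment
  (Beaumont-style) with Epanechnikov weights, on log scale for times and
  sizes, and reports weighted posterior mean/median/quartiles/90% interval;
* validation: PCA pre-evaluation of prior-scenario combinations, posterior
  predictive model checking, confidence in scenario choice (type I/II error
  on pseudo-observed datasets) and bias/precision of parameter estimates.

The user-facing entry point is :class:`ColonizationABC`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge

from .coalsim import SamplingDesign, simulate_dataset
from .containers import DatasetBundle
from .demography import (
    MutationModelMt,
    MutationModelStr,
    ParameterDraw,
    PriorSpec,
    Scenario,
    draw_parameters,
)
from .sumstats import SummaryConfig, summary_vector

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTable",
    "build_reference_table",
    "normalized_distance",
    "reject",
    "scenario_posterior",
    "estimate_parameters",
    "pca_preevaluation",
    "model_check",
    "confidence_in_choice",
    "bias_precision",
    "ModelChoiceResult",
    "ParameterPosterior",
    "ValidationReport",
    "ColonizationABC",
]


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Rows of (scenario_id, parameter draw, summary vector).

    ``scales`` holds per-statistic robust SDs (1.4826×MAD over all rows;
    SD fallback); statistics with zero spread are dropped with a warning
    and recorded in ``dropped``.
    """

    scenario_ids: np.ndarray  # int, (n_rows,)
    params: pd.DataFrame  # one column per scenario parameter
    stats: pd.DataFrame  # one column per summary statistic
    scales: pd.Series
    dropped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.scenario_ids) == len(self.params) == len(self.stats)):
            raise ValueError("row counts disagree")
        if (self.scales <= 0).any():
            raise ValueError("scale factors must be strictly positive")

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def restrict(self, scenario_id: int) -> "ReferenceTable":
        mask = self.scenario_ids == scenario_id
        return ReferenceTable(
            self.scenario_ids[mask],
            self.params.loc[mask].reset_index(drop=True),
            self.stats.loc[mask].reset_index(drop=True),
            self.scales,
            list(self.dropped),
            dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        """Persist to a columnar TSV with a '#'-prefixed header block."""
        import json

        with open(path, "w") as fh:
            fh.write("# coalisle reference table\n")
            fh.write(f"# provenance: {json.dumps(self.provenance, sort_keys=True)}\n")
            fh.write(f"# dropped: {json.dumps(self.dropped)}\n")
            fh.write(
                "# scales: "
                + json.dumps({k: float(v) for k, v in self.scales.items()})
                + "\n"
            )
            df = pd.concat(
                [pd.Series(self.scenario_ids, name="scenario_id"), self.params, self.stats],
                axis=1,
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        import json

        header: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                pos = fh.tell()
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    header[key.strip()] = val.strip()
            df = pd.read_csv(fh, sep="\t")
        scales = pd.Series(json.loads(header.get("scales", "{}")))
        stat_cols = [c for c in df.columns if c in scales.index]
        param_cols = [c for c in df.columns if c not in stat_cols and c != "scenario_id"]
        return cls(
            df["scenario_id"].to_numpy(),
            df[param_cols],
            df[stat_cols],
            scales,
            json.loads(header.get("dropped", "[]")),
            json.loads(header.get("provenance", "{}")),
        )


def simulate_summary(
    scenario: Scenario,
    draw: ParameterDraw,
    design: SamplingDesign,
    config: SummaryConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    bundle = simulate_dataset(scenario, draw, design, rng)
    return summary_vector(bundle, config=config)


def build_reference_table(
    scenarios: Sequence[Scenario],
    priors: PriorSpec,
    n_per_scenario: int,
    design: SamplingDesign,
    config: SummaryConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` draws per scenario and assemble the table.

    Deterministic for a given seed; scale factors are computed after
    assembly over all rows.
    """
    if n_per_scenario < 1:
        raise UsageError("n_per_scenario must be >= 1")
    rng = np.random.default_rng(rng)
    config = config or SummaryConfig()
    sids, draws_flat, stat_rows = [], [], []
    for scenario in scenarios:
        for _ in range(n_per_scenario):
            draw = draw_parameters(scenario, priors, rng)
            s = simulate_summary(scenario, draw, design, config, rng)
            sids.append(scenario.scenario_id)
            draws_flat.append(draw.as_flat_dict())
            stat_rows.append(s)
    stats = pd.DataFrame(stat_rows).reset_index(drop=True)
    params = pd.DataFrame(draws_flat)
    scales, dropped = _robust_scales(stats)
    if dropped:
        logger.warning("dropping zero-variance statistics: %s", dropped)
        stats = stats.drop(columns=dropped)
    return ReferenceTable(
        np.asarray(sids),
        params,
        stats,
        scales,
        dropped,
        provenance={"n_per_scenario": n_per_scenario, "n_scenarios": len(scenarios)},
    )


def _robust_scales(stats: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    med = stats.median(axis=0)
    mad = (stats - med).abs().median(axis=0)
    scales = 1.4826 * mad
    sd = stats.std(axis=0, ddof=1).fillna(0.0)
    scales = scales.where(scales > 0, sd)
    dropped = list(scales.index[(scales <= 0) | ~np.isfinite(scales)])
    return scales.drop(index=dropped), dropped


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

def normalized_distance(
    sim: pd.Series | np.ndarray, obs: pd.Series | np.ndarray, scales: pd.Series
) -> float:
    """Scale-normalized Euclidean distance between two summary vectors."""
    if isinstance(sim, pd.Series) and isinstance(obs, pd.Series):
        if list(sim.index) != list(obs.index):
            raise UsageError("summary vectors have different statistic configurations")
        sim = sim[scales.index].to_numpy()
        obs = obs[scales.index].to_numpy()
    d = (np.asarray(sim, float) - np.asarray(obs, float)) / scales.to_numpy()
    return float(np.sqrt(np.sum(d**2)))


def _distances(table: ReferenceTable, observed: pd.Series) -> np.ndarray:
    obs = observed[table.stats.columns].to_numpy(float)
    scaled = (table.stats.to_numpy(float) - obs) / table.scales[table.stats.columns].to_numpy()
    return np.sqrt(np.sum(scaled**2, axis=1))


def reject(
    table: ReferenceTable, observed: pd.Series, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the retained ceil(tolerance × n) rows.

    Ties at the cutoff are broken by row index (stable argsort), so the
    result is invariant to row permutation up to that tie-break.
    """
    if table.n_rows == 0:
        raise UsageError("empty reference table")
    if not (0 < tolerance <= 1):
        raise UsageError("tolerance must lie in (0, 1]")
    d = _distances(table, observed)
    n_keep = math.ceil(tolerance * table.n_rows)
    order = np.argsort(d, kind="stable")[:n_keep]
    return order, d[order]


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    posterior: pd.Series  # scenario_id -> probability
    retained_counts: pd.Series
    tolerance: float
    n_retained: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def best_scenario(self) -> int:
        return int(self.posterior.idxmax())

    def summary(self) -> str:
        lines = [
            "ABC scenario choice (logistic regression on retained deviations)",
            "=" * 64,
            f"retained: {self.n_retained} rows at tolerance {self.tolerance}",
            f"{'scenario':>10} {'retained':>10} {'posterior':>12}",
        ]
        for sid, p in self.posterior.sort_values(ascending=False).items():
            lines.append(
                f"{sid:>10} {int(self.retained_counts.get(sid, 0)):>10} {p:>12.4f}"
            )
        return "\n".join(lines)


#: inverse ridge penalty for the multinomial logistic regression; a small
#: fixed amount of regularization keeps perfectly separated retained sets
#: from degenerating
LOGISTIC_C = 10.0


def scenario_posterior(
    table: ReferenceTable, observed: pd.Series, tolerance: float
) -> ModelChoiceResult:
    """Posterior scenario probabilities via multinomial logistic regression.

    The regression of scenario label on scale-normalized summary deviations
    is fitted over the retained rows with Epanechnikov weights (closer
    simulations count more, as in the standard regression-ABC estimator)
    and evaluated at zero deviation.  If only one scenario survives
    rejection it receives probability 1.
    """
    idx, dist = reject(table, observed, tolerance)
    labels = table.scenario_ids[idx]
    all_ids = np.unique(table.scenario_ids)
    counts = pd.Series(
        {int(s): int(np.sum(labels == s)) for s in all_ids}, dtype=int
    )
    present = np.unique(labels)
    if len(present) == 1:
        post = pd.Series(0.0, index=[int(s) for s in all_ids])
        post[int(present[0])] = 1.0
        return ModelChoiceResult(post, counts, tolerance, len(idx),
                                 {"method": "degenerate"})
    obs = observed[table.stats.columns].to_numpy(float)
    X = (table.stats.to_numpy(float)[idx] - obs) / table.scales[
        table.stats.columns
    ].to_numpy()
    w = np.clip(_epanechnikov(dist, float(dist.max())), 1e-6, None)
    clf = LogisticRegression(C=LOGISTIC_C, max_iter=2000)
    clf.fit(X, labels, sample_weight=w)
    probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
    post = pd.Series(0.0, index=[int(s) for s in all_ids])
    for cls_, p in zip(clf.classes_, probs):
        post[int(cls_)] = float(p)
    post /= post.sum()
    return ModelChoiceResult(
        post, counts, tolerance, len(idx), {"method": "multinomial-logistic"}
    )


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParameterPosterior:
    scenario_id: int
    adjusted: pd.DataFrame  # adjusted parameter sample (original scale)
    weights: np.ndarray
    table_stats: pd.DataFrame = field(repr=False, default=None)
    adjustment: str = "local-linear"

    def _wq(self, col: np.ndarray, q: float) -> float:
        order = np.argsort(col)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return float(np.interp(q, cw, col[order]))

    def stats_for(self, name: str) -> dict[str, float]:
        col = self.adjusted[name].to_numpy()
        w = self.weights / self.weights.sum()
        return {
            "mean": float(np.sum(w * col)),
            "median": self._wq(col, 0.5),
            "q25": self._wq(col, 0.25),
            "q75": self._wq(col, 0.75),
            "q05": self._wq(col, 0.05),
            "q95": self._wq(col, 0.95),
        }

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.stats_for(name) for name in self.adjusted.columns}
        ).T[["mean", "median", "q25", "q75", "q05", "q95"]]

    def summary(self) -> str:
        df = self.frame()
        lines = [
            f"ABC parameter posterior (scenario {self.scenario_id}, "
            f"{self.adjustment} adjustment, n={len(self.adjusted)})",
            "=" * 72,
            df.to_string(float_format=lambda v: f"{v:,.1f}"),
        ]
        return "\n".join(lines)


#: per-row ridge penalty for the local-linear adjustment
RIDGE_ALPHA = 0.01


def _epanechnikov(d: np.ndarray, bandwidth: float) -> np.ndarray:
    if bandwidth <= 0:
        return np.ones_like(d)
    u = np.clip(d / bandwidth, 0.0, 1.0)
    w = 1.0 - u**2
    if np.all(w <= 0):  # all points at the bandwidth edge
        w = np.ones_like(d)
    return w


def estimate_parameters(
    table: ReferenceTable,
    observed: pd.Series,
    tolerance: float,
    min_retained: int = 30,
    log_params: bool = True,
) -> ParameterPosterior:
    """Local-linear regression-adjusted posterior for one scenario's
    parameters.

    The table must be restricted to a single scenario.  Each parameter is
    log-transformed (positivity; priors span orders of magnitude), regressed
    on the scale-normalized summary deviations with Epanechnikov weights
    (bandwidth = max retained distance), shifted to zero deviation and
    back-transformed.  Falls back to the unadjusted rejection sample when
    the regression design is singular.
    """
    sids = np.unique(table.scenario_ids)
    if len(sids) != 1:
        raise UsageError("restrict the table to one scenario before estimating")
    idx, d = reject(table, observed, tolerance)
    if len(idx) < min_retained:
        raise UsageError(
            f"only {len(idx)} retained rows; need >= {min_retained}"
        )
    obs = observed[table.stats.columns].to_numpy(float)
    X = (table.stats.to_numpy(float)[idx] - obs) / table.scales[
        table.stats.columns
    ].to_numpy()
    bandwidth = float(d.max())
    w = _epanechnikov(d, bandwidth)
    raw = table.params.iloc[idx].reset_index(drop=True)
    # constant columns (e.g. fixed db) pass through unadjusted
    variable = [c for c in raw.columns if raw[c].nunique() > 1]
    adjusted = raw.copy()
    how = "local-linear"
    if variable and np.ptp(X) > 0:
        Y = raw[variable].to_numpy(float)
        if log_params:
            Y = np.log(Y)
        try:
            # lightly ridge-regularized so a near-square design (retained
            # rows ~ number of statistics) cannot interpolate and collapse
            # the adjusted sample
            reg = Ridge(alpha=RIDGE_ALPHA * len(idx))
            reg.fit(X, Y, sample_weight=w)
            Y_adj = Y - X @ reg.coef_.T
            if log_params:
                Y_adj = np.exp(Y_adj)
            for k, cname in enumerate(variable):
                adjusted[cname] = Y_adj[:, k]
        except np.linalg.LinAlgError:  # pragma: no cover - singular design
            logger.warning("singular regression design; using rejection sample")
            how = "rejection-only"
    else:
        how = "rejection-only"
    return ParameterPosterior(
        scenario_id=int(sids[0]),
        adjusted=adjusted,
        weights=w,
        table_stats=table.stats.iloc[idx].reset_index(drop=True),
        adjustment=how,
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    pca: dict | None = None
    model_check: pd.Series | None = None
    type1: pd.Series | None = None
    type2: pd.Series | None = None
    selection_matrix: pd.DataFrame | None = None
    bias: pd.Series | None = None
    rmse: pd.Series | None = None
    n_pods: int = 0


def pca_preevaluation(
    table: ReferenceTable, observed: pd.Series, n_components: int = 2
) -> dict:
    """Project simulations and the observed vector onto principal components.

    Reports the observed point's coordinates, whether it falls inside the
    convex hull of the simulated cloud in the first two components, and its
    distance to the nearest simulated point.
    """
    if table.n_rows < n_components:
        raise UsageError("need at least n_components rows")
    Xs = table.stats.to_numpy(float) / table.scales[table.stats.columns].to_numpy()
    xo = observed[table.stats.columns].to_numpy(float) / table.scales[
        table.stats.columns
    ].to_numpy()
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(Xs)
    obs_coord = pca.transform(xo.reshape(1, -1))[0]
    inside = _in_hull(coords[:, :2], obs_coord[:2])
    dists = np.sqrt(np.sum((coords - obs_coord) ** 2, axis=1))
    return {
        "sim_coordinates": coords,
        "observed_coordinates": obs_coord,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "observed_inside_cloud": bool(inside),
        "min_distance_to_simulated": float(dists.min()),
        "scenario_ids": table.scenario_ids,
    }


def _in_hull(points2d: np.ndarray, x: np.ndarray, tol: float = 1e-9) -> bool:
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(points2d)
    except QhullError:  # degenerate cloud
        return bool(np.any(np.all(np.abs(points2d - x) < 1e-12, axis=1)))
    eq = hull.equations
    return bool(np.all(eq[:, :2] @ x + eq[:, 2] <= tol))


def model_check(
    scenario: Scenario,
    posterior: ParameterPosterior,
    observed: pd.Series,
    design: SamplingDesign,
    config: SummaryConfig,
    priors: PriorSpec,
    n_pp: int,
    rng: np.random.Generator | int | None = None,
    flag_level: float = 0.025,
) -> pd.Series:
    """Posterior-predictive tail probabilities per summary statistic.

    ``n_pp`` parameter vectors are drawn from the adjusted posterior sample
    (weighted); for each, a dataset is simulated and summarized.  The tail
    probability of a statistic is the fraction of predictive values <= the
    observed value; values within ``flag_level`` of 0 or 1 indicate misfit.
    """
    if n_pp < 1:
        raise UsageError("n_pp must be >= 1")
    rng = np.random.default_rng(rng)
    w = posterior.weights / posterior.weights.sum()
    rows = rng.choice(len(posterior.adjusted), size=n_pp, p=w)
    preds = []
    for r in rows:
        flat = posterior.adjusted.iloc[int(r)].to_dict()
        draw = _draw_from_flat(flat, priors)
        preds.append(simulate_summary(scenario, draw, design, config, rng))
    pred = pd.DataFrame(preds)
    obs = observed[pred.columns]
    tail = (pred.le(obs, axis=1)).mean(axis=0)
    tail.attrs["flagged"] = list(tail.index[(tail < flag_level) | (tail > 1 - flag_level)])
    return tail


def _draw_from_flat(flat: Mapping[str, float], priors: PriorSpec) -> ParameterDraw:
    times = {k: float(v) for k, v in flat.items() if k.startswith("t")}
    sizes = {k: float(v) for k, v in flat.items() if k.startswith("N")}
    return ParameterDraw(
        times=times,
        sizes=sizes,
        db=float(flat.get("db", priors.db_fixed or 5.0)),
        mt_model=priors.mt_model,
        str_model=priors.str_model,
    )


def confidence_in_choice(
    scenarios: Sequence[Scenario],
    priors: PriorSpec,
    n_pods: int,
    table: ReferenceTable,
    tolerance: float,
    design: SamplingDesign,
    config: SummaryConfig,
    rng: np.random.Generator | int | None = None,
) -> ValidationReport:
    """Type I / type II error of scenario choice on pseudo-observed datasets.

    For each scenario, ``n_pods`` pods are simulated from its prior and run
    through model choice against ``table``.  Type I error for scenario S is
    the fraction of S-pods where S is not selected; type II the fraction of
    non-S pods where S is selected.
    """
    if n_pods < 1:
        raise UsageError("n_pods must be >= 1")
    rng = np.random.default_rng(rng)
    ids = [s.scenario_id for s in scenarios]
    sel = pd.DataFrame(0, index=ids, columns=ids)  # true x selected counts
    for s in scenarios:
        for _ in range(n_pods):
            draw = draw_parameters(s, priors, rng)
            pod = simulate_summary(s, draw, design, config, rng)
            res = scenario_posterior(table, pod, tolerance)
            sel.loc[s.scenario_id, res.best_scenario] += 1
    type1 = pd.Series(
        {sid: 1.0 - sel.loc[sid, sid] / n_pods for sid in ids}, name="type1"
    )
    n_other = n_pods * (len(ids) - 1)
    type2 = pd.Series(
        {
            sid: (sel[sid].sum() - sel.loc[sid, sid]) / n_other if n_other else 0.0
            for sid in ids
        },
        name="type2",
    )
    return ValidationReport(
        type1=type1, type2=type2, selection_matrix=sel, n_pods=n_pods
    )


def bias_precision(
    scenario: Scenario,
    priors: PriorSpec,
    n_pods: int,
    table: ReferenceTable,
    tolerance: float,
    design: SamplingDesign,
    config: SummaryConfig,
    rng: np.random.Generator | int | None = None,
    min_retained: int = 30,
) -> ValidationReport:
    """Relative bias and relative RMSE of the posterior-median estimator on
    pods with recorded true parameters."""
    if n_pods < 1:
        raise UsageError("n_pods must be >= 1")
    rng = np.random.default_rng(rng)
    sub = table.restrict(scenario.scenario_id)
    errs: list[pd.Series] = []
    for _ in range(n_pods):
        draw = draw_parameters(scenario, priors, rng)
        pod = simulate_summary(scenario, draw, design, config, rng)
        post = estimate_parameters(sub, pod, tolerance, min_retained=min_retained)
        truth = draw.as_flat_dict()
        est = {name: post.stats_for(name)["median"] for name in post.adjusted.columns}
        errs.append(
            pd.Series(
                {
                    k: (est[k] - truth[k]) / truth[k]
                    for k in est
                    if truth.get(k) not in (None, 0)
                }
            )
        )
    E = pd.DataFrame(errs)
    return ValidationReport(
        bias=E.mean(axis=0), rmse=np.sqrt((E**2).mean(axis=0)), n_pods=n_pods
    )


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class ColonizationABC:
    """ABC analysis of colonization-order scenarios for one observed dataset.

    Parameters
    ----------
    observed : DatasetBundle or pandas.Series
        The observed dataset (its summary vector is computed with
        ``config``) or a precomputed summary vector.
    scenarios : sequence of Scenario
        Candidate colonization scenarios.
    priors : PriorSpec
    design : SamplingDesign
        Per-population sample sizes used for the simulations (normally
        matching the observed data).
    config : SummaryConfig, optional

    ``fit`` builds the reference table (unless one is supplied) and runs
    rejection + scenario choice; parameter estimation and the QC procedures
    are methods on the model that reuse the fitted table.
    """

    def __init__(
        self,
        observed: DatasetBundle | pd.Series,
        scenarios: Sequence[Scenario],
        priors: PriorSpec,
        design: SamplingDesign | None = None,
        config: SummaryConfig | None = None,
    ):
        self.scenarios = list(scenarios)
        self.priors = priors
        self.config = config or SummaryConfig()
        if design is None:
            design = SamplingDesign.from_scenario(self.scenarios[0])
        self.design = design
        if isinstance(observed, DatasetBundle):
            self.observed = summary_vector(observed, config=self.config)
        else:
            self.observed = observed
        self.table: ReferenceTable | None = None

    def scenario_by_id(self, sid: int) -> Scenario:
        for s in self.scenarios:
            if s.scenario_id == sid:
                return s
        raise KeyError(sid)

    def build_reference(
        self, n_per_scenario: int, rng: np.random.Generator | int | None = None
    ) -> ReferenceTable:
        self.table = build_reference_table(
            self.scenarios, self.priors, n_per_scenario, self.design, self.config, rng
        )
        return self.table

    def fit(
        self,
        n_per_scenario: int = 1000,
        tolerance: float = 0.01,
        rng: np.random.Generator | int | None = None,
    ) -> ModelChoiceResult:
        """Build (or reuse) the reference table and run scenario choice."""
        if self.table is None:
            self.build_reference(n_per_scenario, rng)
        return scenario_posterior(self.table, self.observed, tolerance)

    def estimate(
        self, scenario_id: int, tolerance: float = 0.01, **kw
    ) -> ParameterPosterior:
        self._need_table()
        return estimate_parameters(
            self.table.restrict(scenario_id), self.observed, tolerance, **kw
        )

    def pca_check(self, n_components: int = 2) -> dict:
        self._need_table()
        return pca_preevaluation(self.table, self.observed, n_components)

    def model_check(
        self,
        scenario_id: int,
        posterior: ParameterPosterior,
        n_pp: int = 200,
        rng=None,
    ) -> pd.Series:
        return model_check(
            self.scenario_by_id(scenario_id),
            posterior,
            self.observed,
            self.design,
            self.config,
            self.priors,
            n_pp,
            rng,
        )

    def confidence(self, n_pods: int, tolerance: float = 0.01, rng=None) -> ValidationReport:
        self._need_table()
        return confidence_in_choice(
            self.scenarios, self.priors, n_pods, self.table, tolerance,
            self.design, self.config, rng,
        )

    def bias_precision(
        self, scenario_id: int, n_pods: int, tolerance: float = 0.01, rng=None, **kw
    ) -> ValidationReport:
        self._need_table()
        return bias_precision(
            self.scenario_by_id(scenario_id), self.priors, n_pods, self.table,
            tolerance, self.design, self.config, rng, **kw,
        )

    def _need_table(self) -> None:
        if self.table is None:
            raise UsageError("build the reference table first (build_reference/fit)")
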