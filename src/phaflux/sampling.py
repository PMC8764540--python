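"""Uniform sampling of condition-model flux polytopes and flux comparisons.

FBA returns one (typically degenerate) optimum; statements about how flux
is *distributed* across a network therefore go through Monte Carlo
sampling of the whole constraint polytope ``{v : S v = 0, lb ≤ v ≤ ub}``.
The sampler is artificial-centering hit-and-run (ACHR): from a current
point, pick the direction toward a randomly chosen stored point relative
to the running center of all stored points, intersect that chord with the
bounds, and jump to a uniform point on the feasible segment.  Directions
built as differences of feasible points stay inside the null space of S,
so every iterate satisfies the steady-state constraint (a periodic
re-projection absorbs floating-point drift).

The mixing diagnostic is the *mixed fraction*: pair the i-th point of the
first half of the chain with the i-th point of the second half and count
the fraction of pairs lying on opposite sides of that reaction's overall
sample median, averaged over non-constant reactions.  0.5 indicates the
two chain halves are interchangeable (well mixed); strongly autocorrelated
chains give values near 0.

Per-reaction medians of the sample are used as the most probable flux
values, and mutant/wild-type comparisons classify each reaction by the
ratio of medians (increased / reduced / unaffected / undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import null_space
from scipy.optimize import linprog

from .contextualize import ConditionModel
from .model_core import MetabolicModel

#: Feasibility tolerances every emitted sample point must satisfy.
STEADY_STATE_TOL = 1e-6
BOUNDS_TOL = 1e-8

#: Chain defaults: 5,000 stored points, thinning 100, single chain.
DEFAULT_N_SAMPLES = 5000
DEFAULT_THINNING = 100

#: Default ratio thresholds for increased/reduced classification
#: (symmetric on the log scale) and the |median| floor below which a
#: ratio is undefined.
DEFAULT_RATIO_THRESHOLDS = (1.2, 1.0 / 1.2)
DEFAULT_MEDIAN_FLOOR = 1e-6


class DegenerateSampleError(ValueError):
    """The sample set carries no mixing information (all reactions constant)."""


class SamplingError(RuntimeError):
    """The sampler could not make progress (infeasible model, empty chords)."""


def _realize(cm: Union[ConditionModel, MetabolicModel]) -> MetabolicModel:
    return cm.realized() if isinstance(cm, ConditionModel) else cm


@dataclass
class FluxSampleSet:
    """Points from one chain over a flux polytope, plus chain metadata."""

    points: np.ndarray              # (n_samples, n_reactions)
    reaction_ids: Sequence[str]
    seed: int
    n_warmup: int
    thinning: int
    chain_length: int               # total ACHR iterations performed

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != len(self.reaction_ids):
            raise ValueError("points must be (n_samples, n_reactions)")

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    def column(self, rxn_id: str) -> np.ndarray:
        return self.points[:, list(self.reaction_ids).index(rxn_id)]

    def check_feasible(self, model: MetabolicModel) -> None:
        """Assert every point satisfies S·v = 0 and the bounds."""
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds()
        resid = np.abs(S @ self.points.T).max() if self.n_samples else 0.0
        if resid > STEADY_STATE_TOL:
            raise AssertionError(f"steady-state residual {resid:.2e} > tol")
        if (self.points < lb - BOUNDS_TOL).any() or (
            self.points > ub + BOUNDS_TOL
        ).any():
            raise AssertionError("sample point violates flux bounds")

    # -- persistence ------------------------------------------------------
    def to_tsv(self, path: str, sidecar: Optional[str] = None) -> None:
        pd.DataFrame(self.points, columns=list(self.reaction_ids)).to_csv(
            path, sep="\t", index=False
        )
        if sidecar:
            with open(sidecar, "w") as fh:
                yaml.safe_dump(
                    {
                        "seed": int(self.seed),
                        "n_warmup": int(self.n_warmup),
                        "thinning": int(self.thinning),
                        "chain_length": int(self.chain_length),
                        "n_samples": int(self.n_samples),
                    },
                    fh,
                )

    @classmethod
    def from_tsv(cls, path: str, sidecar: str) -> "FluxSampleSet":
        df = pd.read_csv(path, sep="\t")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        return cls(
            points=df.to_numpy(dtype=float),
            reaction_ids=list(df.columns),
            seed=meta["seed"],
            n_warmup=meta["n_warmup"],
            thinning=meta["thinning"],
            chain_length=meta["chain_length"],
        )


# ---------------------------------------------------------------------------
# Warmup and the ACHR chain
# ---------------------------------------------------------------------------

def warmup_points(
    cm: Union[ConditionModel, MetabolicModel],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """``n`` feasible points spread over the polytope boundary.

    Obtained by optimizing randomized objective vectors; for small models
    (2·n_reactions ≤ n) the ±coordinate objectives are all included, which
    hits the per-reaction flux extremes.  Raises :class:`SamplingError`
    before sampling if the model is infeasible.
    """
    model = _realize(cm)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n_rxns = len(model.reactions)
    rng = np.random.default_rng(seed)

    objectives = []
    coord = []
    for i in range(n_rxns):
        e = np.zeros(n_rxns)
        e[i] = 1.0
        coord.extend([e, -e])
    if 2 * n_rxns <= n:
        objectives.extend(coord)
    else:
        idx = rng.choice(len(coord), size=n, replace=False)
        objectives.extend(coord[i] for i in idx)
    while len(objectives) < n:
        objectives.append(rng.normal(size=n_rxns))

    points = []
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    for c in objectives:
        res = linprog(
            -c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs",
            options={"primal_feasibility_tolerance": 1e-9,
                     "dual_feasibility_tolerance": 1e-9},
        )
        if res.status != 0:
            raise SamplingError(
                f"model {model.name!r} infeasible/unbounded during warmup "
                f"(LP status {res.status})"
            )
        points.append(res.x)
    return np.array(points)


def achr_sample(
    cm: Union[ConditionModel, MetabolicModel],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    thinning: int = DEFAULT_THINNING,
    n_warmup: Optional[int] = None,
    max_retries: int = 50,
) -> FluxSampleSet:
    """Artificial-centering hit-and-run over the flux polytope.

    One point is stored every ``thinning`` iterations until ``n_samples``
    points are collected.  Deterministic (bit-reproducible) for a fixed
    seed and chain configuration.  A numerically empty chord triggers
    direction resampling with at most ``max_retries`` attempts.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    model = _realize(cm)
    n_rxns = len(model.reactions)
    if n_warmup is None:
        n_warmup = min(max(2 * n_rxns, 20), 400)
    warmup = warmup_points(cm, n_warmup, seed=seed)
    rng = np.random.default_rng(seed)

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    fixed = ub - lb <= 1e-12
    # null-space basis for periodic drift re-projection
    N = null_space(S)
    if N.size == 0:
        # fully determined: the only feasible point is the warmup point
        points = np.repeat(warmup[:1], n_samples, axis=0)
        return FluxSampleSet(points, model.reaction_ids, seed, n_warmup,
                             thinning, 0)

    # The walk lives in reduced coordinates y with v = x0 + N y, so the
    # steady-state constraint S v = 0 holds by construction and cannot
    # drift.  The bound constraints become a chord computation on the
    # x-space components of the direction; a small slack keeps the chain
    # from deadlocking when the walker sits exactly on several facets of a
    # tight (narrow-banded) polytope.
    # every emitted point is x0 + N y, so x0's own steady-state residual
    # (the warmup LP's feasibility error) would be inherited by the whole
    # chain; remove it by a least-squares projection onto S v = 0
    x0 = warmup[0].copy()
    correction, *_ = np.linalg.lstsq(S, S @ x0, rcond=None)
    x0 = x0 - correction
    to_y = lambda v: N.T @ (v - x0)
    to_x = lambda y: x0 + N @ y

    # direction pool: warmup points plus previously stored samples; the
    # running center averages every iterate visited so far
    pool_y = [to_y(w) for w in warmup]
    center_y = np.mean(pool_y, axis=0)
    n_seen = len(pool_y)
    y = pool_y[rng.integers(len(pool_y))].copy()
    x = to_x(y)

    samples = np.empty((n_samples, n_rxns))
    collected = 0
    iteration = 0
    # constrain every numerically nonzero direction component: skipping
    # "small" ones would let those coordinates creep past their bounds and
    # the repair would push points off the steady-state subspace
    eps = 1e-14
    slack = 1e-9
    while collected < n_samples:
        for attempt in range(max_retries):
            dy = pool_y[rng.integers(len(pool_y))] - center_y
            norm = np.linalg.norm(dy)
            if norm < 1e-10:
                continue
            dy = dy / norm
            direction = N @ dy
            t_min, t_max = -np.inf, np.inf
            pos = direction > eps
            neg = direction < -eps
            if pos.any():
                t_max = min(t_max,
                            np.min((ub[pos] - x[pos] + slack) / direction[pos]))
                t_min = max(t_min,
                            np.max((lb[pos] - x[pos] - slack) / direction[pos]))
            if neg.any():
                t_max = min(t_max,
                            np.min((lb[neg] - x[neg] - slack) / direction[neg]))
                t_min = max(t_min,
                            np.max((ub[neg] - x[neg] + slack) / direction[neg]))
            if not np.isfinite(t_min) or not np.isfinite(t_max):
                continue
            if t_max - t_min < 1e-12:
                continue
            y = y + rng.uniform(t_min, t_max) * dy
            x = to_x(y)
            break
        else:
            raise SamplingError(
                f"no feasible chord after {max_retries} direction resamples "
                f"at iteration {iteration}"
            )
        iteration += 1
        n_seen += 1
        center_y = center_y + (y - center_y) / n_seen
        if iteration % thinning == 0:
            samples[collected] = x
            collected += 1
            pool_y.append(y.copy())

    # points live on the S v = 0 subspace by construction and respect the
    # bounds up to the chord slack, which is below the bounds tolerance;
    # pin the exactly-fixed coordinates to their prescribed value
    samples[:, fixed] = lb[fixed]
    out = FluxSampleSet(
        points=samples,
        reaction_ids=model.reaction_ids,
        seed=seed,
        n_warmup=n_warmup,
        thinning=thinning,
        chain_length=iteration,
    )
    out.check_feasible(model)
    return out


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def mixed_fraction(s: FluxSampleSet) -> float:
    """Chain-mixing diagnostic; 0.5 indicates perfect mixing.

    For each reaction, the i-th first-half point is paired with the i-th
    second-half point and the fraction of pairs lying on strictly opposite
    sides of the reaction's overall sample median is computed; the mean
    over non-constant reactions is returned.  Constant reactions carry no
    mixing information and an all-constant set raises
    :class:`DegenerateSampleError`.
    """
    n = s.n_samples
    if n < 2:
        raise ValueError("mixed fraction needs a chain of length >= 2")
    half = n // 2
    a = s.points[:half]
    b = s.points[half: 2 * half]
    med = np.median(s.points, axis=0)
    nonconstant = np.ptp(s.points, axis=0) > 1e-12
    if not nonconstant.any():
        raise DegenerateSampleError(
            "all reactions constant across the sample; mixed fraction undefined"
        )
    opposite = (a - med) * (b - med) < 0.0
    return float(opposite[:, nonconstant].mean())


def median_fluxes(s: FluxSampleSet) -> Dict[str, float]:
    """Per-reaction sample median — the most probable flux value."""
    med = np.median(s.points, axis=0)
    return dict(zip(s.reaction_ids, (float(v) for v in med)))


@dataclass
class FluxComparison:
    """Per-reaction median-flux comparison between two strains' samples.

    ``table`` columns: reaction, median_a, median_b, ratio, class with
    class ∈ {increased, reduced, unaffected, undefined}; classification is
    a pure function of the ratio and the configured thresholds, and
    undefined iff |median_b| is below the floor.
    """

    table: pd.DataFrame
    thresholds: Tuple[float, float]
    median_floor: float

    def classes(self) -> Dict[str, str]:
        return dict(zip(self.table["reaction"], self.table["class"]))

    def ratio(self, rxn_id: str) -> float:
        row = self.table.loc[self.table["reaction"] == rxn_id]
        if row.empty:
            raise KeyError(rxn_id)
        return float(row["ratio"].iloc[0])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_strains(
    a: FluxSampleSet,
    b: FluxSampleSet,
    thresholds: Tuple[float, float] = DEFAULT_RATIO_THRESHOLDS,
    median_floor: float = DEFAULT_MEDIAN_FLOOR,
) -> FluxComparison:
    """Classify each reaction by the ratio of sample medians a/b.

    ``thresholds = (upper, lower)``: ratio > upper → increased,
    ratio < lower → reduced, otherwise unaffected; |median_b| < floor →
    undefined (no meaningful ratio).  Requires identical reaction lists.
    """
    ids_a, ids_b = list(a.reaction_ids), list(b.reaction_ids)
    if ids_a != ids_b:
        diff = sorted(set(ids_a) ^ set(ids_b))
        raise ValueError(f"reaction lists differ; symmetric difference: {diff}")
    upper, lower = thresholds
    med_a = np.median(a.points, axis=0)
    med_b = np.median(b.points, axis=0)
    rows = []
    for rxn, ma, mb in zip(ids_a, med_a, med_b):
        if abs(mb) < median_floor:
            ratio, cls = math.nan, "undefined"
        else:
            ratio = ma / mb
            cls = ("increased" if ratio > upper
                   else "reduced" if ratio < lower
                   else "unaffected")
        rows.append(
            {"reaction": rxn, "median_a": float(ma), "median_b": float(mb),
             "ratio": ratio, "class": cls}
        )
    return FluxComparison(
        table=pd.DataFrame(rows), thresholds=thresholds,
        median_floor=median_floor,
    )


# -- named energy-metabolism reports ----------------------------------------

def atp_production_summary(
    s: FluxSampleSet,
    model: MetabolicModel,
    atp_id: str = "atp_c",
    exclude: Iterable[str] = ("ATPM",),
) -> float:
    """Total ATP production rate (mmol gCDW^-1 h^-1) implied by the median
    flux distribution: the sum of positive median ATP-producing
    contributions (stoichiometric coefficient × median flux) over all
    reactions, excluding the maintenance drain.

    This is one documented convention among several possible "ATP
    production" summaries; swap ``exclude``/``atp_id`` to change it.
    """
    med = median_fluxes(s)
    excluded = set(exclude)
    total = 0.0
    for rxn in model.reactions:
        if rxn.id in excluded:
            continue
        coef = rxn.stoichiometry.get(atp_id)
        if coef:
            contribution = coef * med.get(rxn.id, 0.0)
            if contribution > 0:
                total += contribution
    return total


def respiration_rate(s: FluxSampleSet, o2_exchange: str = "EX_o2_e") -> float:
    """Respiration = magnitude of the median oxygen-exchange flux."""
    return abs(median_fluxes(s)[o2_exchange])


def co2_production_rate(s: FluxSampleSet, co2_exchange: str = "EX_co2_e") -> float:
    """CO2 production = median CO2-exchange flux (positive = secretion)."""
    return median_fluxes(s)[co2_exchange]
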