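"""Condition-specific model construction and flux balance analysis.

A batch growth curve is split into successive pseudo-steady states
(phases).  For each strain x phase the measured physiology is condensed
into a :class:`PhaseRates` record — growth rate, octanoate uptake, PHA and
(R)-HA production, all in mmol gCDW^-1 h^-1 — and imposed on the base model
as exchange/sink bounds, yielding a :class:`ConditionModel`.  FBA on the
condition model then predicts growth and a flux distribution; the
validation report compares predictions against the measured rates.

The FBA objective is growth maximization in every phase, including the
stationary phase where the growth bound pins the optimum; claims about
flux *distributions* are made through the sampler
(:mod:`phaflux.sampling`), never through a single FBA vector, because
optima are typically degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import (
    FluxSolution,
    MetabolicModel,
    SOLVER_FEASIBILITY_TOL,
)
from .physiology import (
    MonomerMassTable,
    Phase,
    PhysioTimeCourse,
    compute_growth_rate,
    mean_residual_biomass,
    specific_rate,
)

#: Default half-width of the relative band placed around each measured rate.
DEFAULT_CONSTRAINT_TOLERANCE = 0.05

#: Default relative-error threshold for flagging a predicted/observed
#: discrepancy in validation reports.
DEFAULT_VALIDATION_THRESHOLD = 0.10


class InfeasibleConstraintError(RuntimeError):
    """The measured-rate constraint set admits no steady-state flux vector."""


@dataclass
class ReactionMap:
    """Which model reactions carry the measured quantities.

    Defaults name the packaged core network; override for other models
    (e.g. iJN1411 identifiers).
    """

    octanoate_exchange: str = "EX_octa_e"
    pha_sink: str = "PHA_SINK"
    ha_exchange: str = "EX_3ho_e"
    co2_exchange: str = "EX_co2_e"
    o2_exchange: str = "EX_o2_e"
    biomass: Optional[str] = None  # None -> the model's objective reaction


@dataclass
class PhaseRates:
    """Per-phase specific rates used as model constraints.

    All rates are non-negative magnitudes; the uptake sign convention
    (negative exchange flux = uptake) is applied when bounds are built.
    """

    phase: Phase
    growth_rate: float                 # h^-1
    octanoate_uptake: float            # mmol gCDW^-1 h^-1, magnitude
    pha_production: float              # mmol monomer gCDW^-1 h^-1
    ha_secretion: float                # mmol gCDW^-1 h^-1
    initial_residual_biomass: float    # g/L at phase start

    def __post_init__(self) -> None:
        for name in ("growth_rate", "octanoate_uptake", "pha_production",
                     "ha_secretion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative magnitude")


@dataclass
class ConditionModel:
    """A base model plus the bound overrides realizing one strain x phase."""

    base: MetabolicModel
    strain: str
    phase: Phase
    applied_bounds: Dict[str, Tuple[float, float]]
    provenance: Optional[PhaseRates] = None
    reaction_map: ReactionMap = field(default_factory=ReactionMap)

    def realized(self) -> MetabolicModel:
        """Materialize a model copy with the overrides applied."""
        model = self.base.copy()
        for rxn_id, (lb, ub) in self.applied_bounds.items():
            rxn = model.reaction(rxn_id)
            rxn.lb, rxn.ub = lb, ub
        return model

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "phase": {
                "label": self.phase.label,
                "t_start": self.phase.t_start,
                "t_end": self.phase.t_end,
            },
            "base_model": self.base.name,
            "applied_bounds": {
                k: list(v) for k, v in sorted(self.applied_bounds.items())
            },
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_phase_rates(
    tc: PhysioTimeCourse,
    phase: Phase,
    masses: Optional[MonomerMassTable] = None,
    biomass_mean_strategy: str = "endpoint-mean",
) -> PhaseRates:
    """Condense one phase of a time course into model-ready rates.

    Growth rate comes from the log-linear fit over the phase window;
    uptake and production rates from the phase's endpoint deltas
    (interpolated at the boundaries) normalized by interval length and
    mean residual biomass.  Octanoate is measured in mM so 1 mM equals
    1 mmol/L and no molar mass enters its rate.
    """
    masses = masses or MonomerMassTable()
    mu = compute_growth_rate(tc, phase)
    mean_x = mean_residual_biomass(tc, phase, strategy=biomass_mean_strategy)
    dt = phase.duration

    def delta(channel: str) -> float:
        return tc.interp(channel, phase.t_end) - tc.interp(channel, phase.t_start)

    # mM -> mmol/L directly, so pass a unit "molar mass" of 1 g/mmol.
    oct_rate = specific_rate(delta("octanoate"), dt, mean_x, 1.0)
    pha_rate = specific_rate(delta("pha_conc"), dt, mean_x, masses.pha_repeat_unit)
    ha_rate = specific_rate(delta("ha_conc"), dt, mean_x, masses.ha_free_acid)
    return PhaseRates(
        phase=phase,
        growth_rate=max(mu, 0.0),
        octanoate_uptake=max(-oct_rate, 0.0),   # consumption is negative
        pha_production=max(pha_rate, 0.0),
        ha_secretion=max(ha_rate, 0.0),
        initial_residual_biomass=tc.interp("residual_biomass", phase.t_start),
    )


def _banded(rate: float, tolerance: float) -> Tuple[float, float]:
    lo = rate * (1.0 - tolerance)
    hi = rate * (1.0 + tolerance)
    return (min(lo, hi), max(lo, hi))


def apply_phase_constraints(
    model: MetabolicModel,
    rates: PhaseRates,
    tolerance: float = DEFAULT_CONSTRAINT_TOLERANCE,
    reaction_map: Optional[ReactionMap] = None,
    strain: str = "",
    check_feasible: bool = True,
) -> ConditionModel:
    """Clamp the measured rates onto the model as bound overrides.

    * octanoate exchange: [-uptake*(1+tol), -uptake*(1-tol)] (uptake is a
      negative exchange flux),
    * PHA sink and HA exchange: the measured rate +/- tol,
    * biomass: the measured growth rate +/- tol.  Banding growth on both
      sides is what lets FBA "predictions" agree with the observations the
      way a contextualized model should, pins the near-zero stationary
      phase, and leaves the sampler the residual (internal) degrees of
      freedom.

    Bounds are kept inside the base reaction's thermodynamic direction: an
    irreversible reaction never receives a negative lower bound.  With
    ``check_feasible`` the constrained model is immediately solved and an
    :class:`InfeasibleConstraintError` names the applied bounds on failure.
    """
    rmap = reaction_map or ReactionMap()
    biomass_id = rmap.biomass or model.objective_id
    overrides: Dict[str, Tuple[float, float]] = {}

    def clip_to_direction(rxn_id: str, lb: float, ub: float) -> Tuple[float, float]:
        base = model.reaction(rxn_id)
        if base.lb >= 0.0:          # irreversible forward
            lb, ub = max(lb, 0.0), max(ub, 0.0)
        if base.ub <= 0.0:          # irreversible reverse
            lb, ub = min(lb, 0.0), min(ub, 0.0)
        return lb, ub

    lo, hi = _banded(rates.octanoate_uptake, tolerance)
    overrides[rmap.octanoate_exchange] = clip_to_direction(
        rmap.octanoate_exchange, -hi, -lo
    )
    overrides[rmap.pha_sink] = clip_to_direction(
        rmap.pha_sink, *_banded(rates.pha_production, tolerance)
    )
    overrides[rmap.ha_exchange] = clip_to_direction(
        rmap.ha_exchange, *_banded(rates.ha_secretion, tolerance)
    )
    base_biomass = model.reaction(biomass_id)
    bio_lo, bio_hi = _banded(rates.growth_rate, tolerance)
    overrides[biomass_id] = (
        min(max(bio_lo, base_biomass.lb), base_biomass.ub),
        min(max(bio_hi, base_biomass.lb), base_biomass.ub),
    )

    cm = ConditionModel(
        base=model,
        strain=strain,
        phase=rates.phase,
        applied_bounds=overrides,
        provenance=rates,
        reaction_map=rmap,
    )
    if check_feasible:
        sol = fba(cm)
        if sol.status != "optimal":
            lines = [
                f"  {rxn_id}: [{lb:.6g}, {ub:.6g}]"
                for rxn_id, (lb, ub) in sorted(overrides.items())
            ]
            raise InfeasibleConstraintError(
                f"constraint set for strain {strain!r} phase "
                f"{rates.phase.label} is {sol.status}; applied bounds:\n"
                + "\n".join(lines)
            )
    return cm


def fba(cm: Union[ConditionModel, MetabolicModel]) -> FluxSolution:
    """Flux balance analysis: maximize the objective flux subject to
    ``S v = 0`` and the bounds, via HiGHS.

    Deterministic for fixed solver settings.  On infeasible or unbounded
    problems the status is reported and no fluxes are returned.
    """
    model = cm.realized() if isinstance(cm, ConditionModel) else cm
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    c = model.objective_vector()
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
            "dual_feasibility_tolerance": SOLVER_FEASIBILITY_TOL,
        },
    )
    if res.status == 0:
        fluxes = dict(zip(model.reaction_ids, res.x))
        return FluxSolution(
            status="optimal", objective_value=float(-res.fun), fluxes=fluxes
        )
    status = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    return FluxSolution(status=status, objective_value=None, fluxes={})


@dataclass
class ValidationReport:
    """Predicted-versus-observed table for one condition model."""

    strain: str
    phase_label: str
    table: pd.DataFrame         # quantity, observed, predicted, rel_error, flagged
    threshold: float

    @property
    def flagged(self) -> list:
        return self.table.loc[self.table["flagged"], "quantity"].tolist()

    @property
    def ok(self) -> bool:
        return not self.table["flagged"].any()


def validate_phase(
    cm: ConditionModel,
    sol: FluxSolution,
    observed: PhaseRates,
    threshold: float = DEFAULT_VALIDATION_THRESHOLD,
) -> ValidationReport:
    """Tabulate predicted vs observed growth, uptake, PHA and HA rates.

    Relative error is |pred - obs| / max(|obs|, floor) with a small floor so
    an all-zero quantity does not divide by zero; entries beyond
    ``threshold`` are flagged.  Report-only: never raises on discrepancy.
    """
    if sol.status != "optimal":
        raise ValueError("validation requires an optimal FBA solution")
    rmap = cm.reaction_map
    biomass_id = rmap.biomass or cm.base.objective_id
    predicted = {
        "growth_rate": sol.fluxes[biomass_id],
        "octanoate_uptake": -sol.fluxes[rmap.octanoate_exchange],
        "pha_production": sol.fluxes[rmap.pha_sink],
        "ha_secretion": sol.fluxes[rmap.ha_exchange],
    }
    observed_map = {
        "growth_rate": observed.growth_rate,
        "octanoate_uptake": observed.octanoate_uptake,
        "pha_production": observed.pha_production,
        "ha_secretion": observed.ha_secretion,
    }
    floor = 1e-9
    rows = []
    for quantity, obs in observed_map.items():
        pred = predicted[quantity]
        rel = abs(pred - obs) / max(abs(obs), floor)
        if abs(obs) <= floor and abs(pred) <= floor:
            rel = 0.0
        rows.append(
            {
                "quantity": quantity,
                "observed": obs,
                "predicted": pred,
                "rel_error": rel,
                "flagged": bool(rel > threshold),
            }
        )
    return ValidationReport(
        strain=cm.strain,
        phase_label=cm.phase.label,
        table=pd.DataFrame(rows),
        threshold=threshold,
    )
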