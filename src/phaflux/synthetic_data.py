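"""Synthetic strain physiology and packaged metabolic networks.

This module makes the whole pipeline runnable without downloads:

* :func:`builtin_archetypes` — endpoint physiology of the wild type
  (KT2440), the depolymerase knockout (KT40Z), the whole-cluster deletion
  (KT2440 Δpha) and the PhaZ-dose library M1–M4, as measured after 24 h of
  nitrogen-limited growth on 15 mM octanoate.
* :func:`make_strain_timecourse` — a deterministic three-phase trajectory
  model (exponential growth, per-phase polymer/monomer allocation, closed
  carbon bookkeeping) with optional replicate-averaged lognormal noise.
* :func:`make_toy_model` — tiny hand-audited networks whose FBA optima and
  sampling marginals are known exactly; the substrates of the oracle tests.
* :func:`core_pha_model` — a ~57-reaction, fully element-balanced
  octanoate/PHA-cycle core network (β-oxidation, both (R)-HA-CoA routes,
  polymerase/depolymerase/reactivation, TCA + glyoxylate shunt,
  gluconeogenic backbone, lumped oxidative phosphorylation).

The trajectory model: residual biomass follows X(t) = X0·e^{μt} capped at
its final value (nitrogen limitation); PHA, free (R)-HA and CO2 accumulate
toward their 24-h endpoints with fixed per-phase allocation weights; the
octanoate channel is derived from carbon conservation — consumed carbon
equals carbon appearing in residual biomass + PHA + HA + CO2 — and reaches
zero at 24 h.  Noise, when enabled, is multiplicative lognormal per
replicate observation; the emitted series are replicate means, emulating
the mean-of-three-cultures values physiology tables report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .model_core import Metabolite, MetabolicModel, Reaction
from .physiology import CalibrationCurve, PhysioTimeCourse

# ---------------------------------------------------------------------------
# Carbon bookkeeping constants (shared with the dFBA audit)
# ---------------------------------------------------------------------------

#: mmol of carbon drained per gram of residual biomass by the core biomass
#: reaction (5 accoa·2C + 2.5 oaa·4C + 2 akg·5C + 2 g3p·3C + 4/3 pyr·3C).
BIOMASS_CARBON_MMOL_PER_G = 40.0

#: Carbon per gram of PHA, counted as the C8 repeat unit C8H14O2 (142.20 g/mol).
PHA_CARBON_MMOL_PER_G = 8000.0 / 142.20

#: Carbon per gram of free (R)-3-hydroxyoctanoate C8H16O3 (160.21 g/mol).
HA_CARBON_MMOL_PER_G = 8000.0 / 160.21

#: Carbon atoms per mmol of octanoate.
OCTANOATE_CARBON = 8.0

#: Instrument-scale factor mapping a phase-III CO2 evolution rate
#: (mmol CO2 L^-1 h^-1) onto the MicroResp %CO2 reading, chosen so the
#: packaged archetypes produce readings inside the calibrated range of the
#: packaged hyperbola.
CO2_RATE_TO_PCT = 2.6

#: Default sampling grid (h): half-hourly through the exponential phase,
#: hourly to 10 h, then 12 and 24 h.
DEFAULT_TIME_GRID: Tuple[float, ...] = tuple(
    [i * 0.5 for i in range(11)] + [6.0, 7.0, 8.0, 9.0, 10.0, 12.0, 24.0]
)

_PHASE_EDGES = (0.0, 5.0, 10.0, 24.0)


# ---------------------------------------------------------------------------
# Strain archetypes
# ---------------------------------------------------------------------------

@dataclass
class StrainArchetype:
    """Endpoint targets plus per-phase allocation weights for one strain.

    ``pha_weights`` / ``ha_weights`` / ``co2_weights`` give the fraction of
    the respective 24-h total laid down in phases I, II, III; each triple
    sums to 1.
    """

    name: str
    growth_rate: float               # h^-1
    final_total_biomass: float       # g/L at 24 h
    final_pha_pct: float             # % CDW at 24 h
    final_ha: float                  # g/L at 24 h
    final_viable_cells: float        # 10^8 / ml at 24 h
    initial_residual_biomass: float = 0.085   # g/L
    octanoate_initial: float = 15.0           # mM
    noise_cv: float = 0.05
    n_replicates: int = 3
    pha_weights: Tuple[float, float, float] = (0.10, 0.65, 0.25)
    ha_weights: Tuple[float, float, float] = (0.15, 0.35, 0.50)
    co2_weights: Tuple[float, float, float] = (0.35, 0.40, 0.25)

    def __post_init__(self) -> None:
        for name in ("growth_rate", "final_total_biomass", "final_ha",
                     "final_viable_cells", "initial_residual_biomass",
                     "octanoate_initial", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.final_pha_pct <= 100.0:
            raise ValueError("final_pha_pct must be in [0, 100]")
        for wname in ("pha_weights", "ha_weights", "co2_weights"):
            w = getattr(self, wname)
            if len(w) != 3 or any(x < 0 for x in w):
                raise ValueError(f"{wname} must be 3 non-negative weights")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{wname} must sum to 1, got {sum(w)}")
        if self.total_co2_carbon() < 0:
            raise ValueError(
                f"archetype {self.name!r}: product carbon exceeds octanoate "
                "carbon; endpoints are inconsistent"
            )

    # -- derived endpoint quantities -------------------------------------
    @property
    def final_residual_biomass(self) -> float:
        return self.final_total_biomass * (1.0 - self.final_pha_pct / 100.0)

    @property
    def final_pha_conc(self) -> float:
        return self.final_total_biomass * self.final_pha_pct / 100.0

    def total_co2_carbon(self) -> float:
        """mmol C/L respired as CO2 over the whole run (carbon closure)."""
        c_in = self.octanoate_initial * OCTANOATE_CARBON
        c_products = (
            BIOMASS_CARBON_MMOL_PER_G
            * (self.final_residual_biomass - self.initial_residual_biomass)
            + PHA_CARBON_MMOL_PER_G * self.final_pha_conc
            + HA_CARBON_MMOL_PER_G * self.final_ha
        )
        return c_in - c_products


def builtin_archetypes() -> Dict[str, StrainArchetype]:
    """The eight strains of the study, parameterized from their 24-h
    endpoint physiology (growth rate, total biomass, %CDW PHA, free HA,
    viable cells).

    Two behavioural classes: PHA accumulators (KT2440, KT40Z, M1: ~70–72%
    CDW polymer) and hydrolyzers / PHA-negative strains (M2–M4, Δpha: no
    polymer, free-monomer secretion up to 0.6 g/L, CO2-dominated stationary
    metabolism).  Allocation weights encode the three-phase narrative:
    growth in phase I, polymer/monomer production in phase II, and for the
    hydrolyzers a CO2-active stationary phase III.
    """
    accum = dict(
        pha_weights=(0.10, 0.65, 0.25),
        ha_weights=(0.15, 0.35, 0.50),
        co2_weights=(0.35, 0.40, 0.25),
    )
    arch = {
        "KT2440": StrainArchetype(
            "KT2440", 0.31, 1.3, 71.7, 0.2, 1.8, **accum
        ),
        # The depolymerase knockout grows like the wild type but cannot
        # release monomers; its oxidative metabolism is elevated in the
        # early exponential phase (reported as higher phase-I CO2 and
        # respiration), so its CO2 allocation is skewed toward phase I.
        "KT40Z": StrainArchetype(
            "KT40Z", 0.31, 1.4, 72.3, 0.0, 1.2,
            pha_weights=(0.10, 0.65, 0.25),
            ha_weights=(0.15, 0.35, 0.50),
            co2_weights=(0.45, 0.35, 0.20),
        ),
        "KT2440 Δpha": StrainArchetype(
            "KT2440 Δpha", 0.34, 0.6, 0.0, 0.0, 22.3,
            pha_weights=(0.2, 0.4, 0.4),
            ha_weights=(0.2, 0.4, 0.4),
            co2_weights=(0.35, 0.30, 0.35),
        ),
        "M1": StrainArchetype(
            "M1", 0.30, 1.3, 70.2, 0.3, 4.1, **accum
        ),
        "M2": StrainArchetype(
            "M2", 0.29, 0.6, 0.3, 0.5, 16.5,
            pha_weights=(0.2, 0.4, 0.4),
            ha_weights=(0.10, 0.40, 0.50),
            co2_weights=(0.30, 0.25, 0.45),
        ),
        "M3": StrainArchetype(
            "M3", 0.31, 0.7, 0.4, 0.6, 16.8,
            pha_weights=(0.2, 0.4, 0.4),
            ha_weights=(0.10, 0.40, 0.50),
            co2_weights=(0.25, 0.25, 0.50),
        ),
        "M4": StrainArchetype(
            "M4", 0.35, 0.5, 0.7, 0.5, 15.4,
            pha_weights=(0.2, 0.4, 0.4),
            ha_weights=(0.10, 0.40, 0.50),
            co2_weights=(0.12, 0.43, 0.45),
        ),
    }
    arch["KT2440 dpha"] = arch["KT2440 Δpha"]  # ASCII alias
    return arch


def archetypes_to_yaml(archetypes: Dict[str, StrainArchetype], path: str) -> None:
    data = {}
    for key, a in archetypes.items():
        if key != a.name:
            continue  # skip aliases
        data[key] = {
            "growth_rate": a.growth_rate,
            "final_total_biomass": a.final_total_biomass,
            "final_pha_pct": a.final_pha_pct,
            "final_ha": a.final_ha,
            "final_viable_cells": a.final_viable_cells,
            "initial_residual_biomass": a.initial_residual_biomass,
            "octanoate_initial": a.octanoate_initial,
            "noise_cv": a.noise_cv,
            "n_replicates": a.n_replicates,
            "pha_weights": list(a.pha_weights),
            "ha_weights": list(a.ha_weights),
            "co2_weights": list(a.co2_weights),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def archetypes_from_yaml(path: str) -> Dict[str, StrainArchetype]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = {}
    for name, fields_ in data.items():
        for wname in ("pha_weights", "ha_weights", "co2_weights"):
            if wname in fields_:
                fields_[wname] = tuple(fields_[wname])
        out[name] = StrainArchetype(name=name, **fields_)
    return out


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _cumulative_weight(t: float, weights: Sequence[float]) -> float:
    """Piecewise-linear cumulative allocation over phases I/II/III."""
    total = 0.0
    for k in range(3):
        start, end = _PHASE_EDGES[k], _PHASE_EDGES[k + 1]
        if t >= end:
            total += weights[k]
        elif t > start:
            total += weights[k] * (t - start) / (end - start)
    return total


def deterministic_trajectories(
    arch: StrainArchetype, times: Sequence[float]
) -> Dict[str, np.ndarray]:
    """Noise-free channel values at ``times`` (the generative mean curve)."""
    t = np.asarray(times, dtype=float)
    x0, xf = arch.initial_residual_biomass, arch.final_residual_biomass
    residual = np.minimum(x0 * np.exp(arch.growth_rate * t), xf)
    pha = arch.final_pha_conc * np.array(
        [_cumulative_weight(ti, arch.pha_weights) for ti in t]
    )
    ha = arch.final_ha * np.array(
        [_cumulative_weight(ti, arch.ha_weights) for ti in t]
    )
    co2 = arch.total_co2_carbon() * np.array(
        [_cumulative_weight(ti, arch.co2_weights) for ti in t]
    )
    product_carbon = (
        BIOMASS_CARBON_MMOL_PER_G * (residual - x0)
        + PHA_CARBON_MMOL_PER_G * pha
        + HA_CARBON_MMOL_PER_G * ha
    )
    octanoate = np.maximum(
        arch.octanoate_initial - (product_carbon + co2) / OCTANOATE_CARBON, 0.0
    )
    cells = arch.final_viable_cells * residual / xf
    return {
        "residual": residual,
        "pha": pha,
        "ha": ha,
        "co2_mmolC": co2,
        "octanoate": octanoate,
        "cells": cells,
    }


def phase3_co2_rate(arch: StrainArchetype) -> float:
    """Mean CO2 evolution rate over phase III (mmol CO2 L^-1 h^-1)."""
    return arch.total_co2_carbon() * arch.co2_weights[2] / (
        _PHASE_EDGES[3] - _PHASE_EDGES[2]
    )


def _replicate_mean_noise(
    rng: np.random.Generator, n: int, cv: float, n_replicates: int
) -> np.ndarray:
    """Mean of ``n_replicates`` unit-mean lognormal factors per observation."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    draws = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                          size=(n_replicates, n))
    return draws.mean(axis=0)


def make_strain_timecourse(
    arch: StrainArchetype,
    times: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> PhysioTimeCourse:
    """Generate one strain's measured time course.

    ``times`` must lie within [0, 24] and include both endpoints; the
    default grid samples half-hourly through the exponential phase.
    Deterministic for a fixed seed; with ``arch.noise_cv == 0`` the output
    equals the generative mean curve exactly.
    """
    times = list(DEFAULT_TIME_GRID) if times is None else list(times)
    t = np.asarray(times, dtype=float)
    if t[0] != 0.0 or t[-1] != 24.0 or np.any((t < 0) | (t > 24)):
        raise ValueError("times must lie in [0, 24] and include 0 and 24")
    clean = deterministic_trajectories(arch, t)
    rng = np.random.default_rng(seed)
    n = len(t)
    cv, reps = arch.noise_cv, arch.n_replicates

    def noisy(values: np.ndarray) -> np.ndarray:
        if cv == 0.0:
            return values.copy()
        return values * _replicate_mean_noise(rng, n, cv, reps)

    residual = noisy(clean["residual"])
    pha = noisy(clean["pha"])
    ha = noisy(clean["ha"])
    octanoate = np.maximum(noisy(clean["octanoate"]), 0.0)
    cells = noisy(clean["cells"])
    total = residual + pha
    pct = np.where(total > 0, 100.0 * pha / total, 0.0)

    # MicroResp reading: endpoint respirometry after 24 h of growth.  The
    # phase-III CO2 evolution rate is scaled into %CO2, perturbed like any
    # other observation, and inverted through the calibration hyperbola.
    calib = CalibrationCurve()
    pct_co2 = CO2_RATE_TO_PCT * phase3_co2_rate(arch)
    if cv > 0.0:
        pct_co2 *= float(_replicate_mean_noise(rng, 1, cv, reps)[0])
    od570 = np.full(n, np.nan)
    if pct_co2 > calib.A:
        od570[-1] = pct_co2 * calib.B / (calib.A - pct_co2)

    return PhysioTimeCourse(
        strain=arch.name,
        times=t,
        total_biomass=total,
        pha_pct_cdw=pct,
        ha_conc=ha,
        octanoate=octanoate,
        viable_cells=cells,
        od570=od570,
    )


# ---------------------------------------------------------------------------
# Toy networks (oracle substrates)
# ---------------------------------------------------------------------------

def make_toy_model(kind: str) -> MetabolicModel:
    """Hand-audited miniature networks with known optima and marginals.

    * ``interval`` — source/sink pair, polytope = segment v ∈ [0, 10]
      (both coordinates equal; uniform marginal on [0, 10]).
    * ``box`` — two decoupled source/sink pairs; source fluxes uniform on
      [0, 1]^2.
    * ``chain`` — EX_A (uptake ≤ 10) → biomass at yield 0.5; FBA optimum 5.
    * ``branch`` — two routes of different yield, one capacity-limited;
      FBA optimum 4.8 (hand LP: 4·0.6 + 6·0.4).
    * ``pha_mini`` — 10-reaction uptake → monomer-CoA → polymer sink /
      depolymerase → HA-exchange cycle; closing the depolymerase zeroes HA
      secretion.
    """
    M, R = Metabolite, Reaction
    if kind == "interval":
        return MetabolicModel(
            name="interval",
            metabolites=[M("a")],
            reactions=[
                R("SRC", {"a": 1.0}, lb=0.0, ub=10.0),
                R("SNK", {"a": -1.0}, lb=0.0, ub=10.0, is_exchange=True),
            ],
            objective_id="SNK",
        )
    if kind == "box":
        return MetabolicModel(
            name="box",
            metabolites=[M("a"), M("b")],
            reactions=[
                R("SRC_A", {"a": 1.0}, lb=0.0, ub=1.0),
                R("SNK_A", {"a": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
                R("SRC_B", {"b": 1.0}, lb=0.0, ub=1.0),
                R("SNK_B", {"b": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            objective_id="SNK_A",
        )
    if kind == "chain":
        return MetabolicModel(
            name="chain",
            metabolites=[M("a"), M("x")],
            reactions=[
                R("EX_A", {"a": -1.0}, lb=-10.0, ub=0.0, is_exchange=True),
                R("BIOMASS", {"a": -1.0, "x": 0.5}, lb=0.0, ub=1000.0),
                R("DM_X", {"x": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            objective_id="DM_X",
        )
    if kind == "branch":
        return MetabolicModel(
            name="branch",
            metabolites=[M("a"), M("x")],
            reactions=[
                R("EX_A", {"a": -1.0}, lb=-10.0, ub=0.0, is_exchange=True),
                R("P_HIGH", {"a": -1.0, "x": 0.6}, lb=0.0, ub=4.0),
                R("P_LOW", {"a": -1.0, "x": 0.4}, lb=0.0, ub=1000.0),
                R("DM_X", {"x": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            objective_id="DM_X",
        )
    if kind == "pha_mini":
        return MetabolicModel(
            name="pha_mini",
            metabolites=[
                M("oct_e", compartment="e"), M("oct_c"), M("mon_c"),
                M("pha_c"), M("ha_c"), M("ha_e", compartment="e"), M("bio"),
            ],
            reactions=[
                R("EX_oct", {"oct_e": -1.0}, lb=-10.0, ub=0.0, is_exchange=True),
                R("OCTt", {"oct_e": -1.0, "oct_c": 1.0}, lb=0.0, ub=1000.0),
                R("ACT", {"oct_c": -1.0, "mon_c": 1.0}, lb=0.0, ub=1000.0),
                R("POLY", {"mon_c": -1.0, "pha_c": 1.0}, lb=0.0, ub=1000.0),
                R("SINK_PHA", {"pha_c": -1.0}, lb=0.0, ub=1000.0,
                  is_exchange=True),
                R("DEPOLY", {"pha_c": -1.0, "ha_c": 1.0}, lb=0.0, ub=1000.0),
                R("HAt", {"ha_c": -1.0, "ha_e": 1.0}, lb=0.0, ub=1000.0),
                R("EX_ha", {"ha_e": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
                R("GROWTH", {"mon_c": -1.0, "bio": 0.5}, lb=0.0, ub=1000.0),
                R("DM_bio", {"bio": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            objective_id="DM_bio",
        )
    raise ValueError(f"unknown toy model kind {kind!r}")


# ---------------------------------------------------------------------------
# The octanoate/PHA-cycle core network
# ---------------------------------------------------------------------------

_FORMULAS = {
    # small species
    "h": "H", "h2o": "H2O", "o2": "O2", "co2": "CO2", "nh4": "H4N",
    "pi": "HO4P", "ppi": "HO7P2",
    "atp": "C10H12N5O13P3", "adp": "C10H12N5O10P2", "amp": "C10H12N5O7P",
    "nad": "C21H26N7O14P2", "nadh": "C21H27N7O14P2",
    "nadp": "C21H25N7O17P3", "nadph": "C21H26N7O17P3",
    "fad": "C27H31N9O15P2", "fadh2": "C27H33N9O15P2",
    "coa": "C21H32N7O16P3S",
    # fatty-acid / PHA species
    "octa": "C8H15O2",
    "occoa": "C29H46N7O17P3S", "oc2coa": "C29H44N7O17P3S",
    "3hocoa": "C29H46N7O18P3S", "r3hocoa": "C29H46N7O18P3S",
    "3oocoa": "C29H44N7O18P3S",
    "hxcoa": "C27H42N7O17P3S", "hx2coa": "C27H40N7O17P3S",
    "3hhcoa": "C27H42N7O18P3S", "3ohcoa": "C27H40N7O18P3S",
    "btcoa": "C25H38N7O17P3S", "b2coa": "C25H36N7O17P3S",
    "3hbcoa": "C25H38N7O18P3S", "aacoa": "C25H36N7O18P3S",
    "accoa": "C23H34N7O17P3S",
    "phaC8": "C8H14O2", "r3ho": "C8H15O3",
    # central carbon
    "oaa": "C4H2O5", "cit": "C6H5O7", "acon": "C6H3O6", "icit": "C6H5O7",
    "akg": "C5H4O5", "succoa": "C25H35N7O19P3S", "succ": "C4H4O4",
    "fum": "C4H2O4", "mal": "C4H4O5", "glx": "C2HO3",
    "pep": "C3H2O6P", "2pg": "C3H4O7P", "3pg": "C3H4O7P",
    "13dpg": "C3H4O10P2", "g3p": "C3H5O6P", "pyr": "C3H3O3",
}

_EXTRACELLULAR = ("octa_e", "o2_e", "co2_e", "nh4_e", "pi_e", "h2o_e",
                  "h_e", "r3ho_e")

#: Default non-growth-associated ATP maintenance floor
#: (mmol ATP gCDW^-1 h^-1).  Zero by default so a fully clamped (all-zero
#: rate) condition model stays feasible with objective 0; raise the ATPM
#: lower bound on a copy to enforce an NGAM demand.
ATP_MAINTENANCE_LB = 0.0


def core_pha_model() -> MetabolicModel:
    """Build the curated carbon-balanced octanoate/PHA core network.

    Reaction mnemonics follow the field's usage where a named counterpart
    exists (PHAP2C80 polymerase, RHACOAR80 3-oxoacyl reductase FabG,
    RECOAH3 R-specific enoyl-CoA hydratase PhaJ, ECOAH3/HACD3i FadB steps,
    CS/ACONTa/ACONTb/MDH/ICL/MALS/GAPD/PGK/PGM/ENO for central carbon).
    This network is explicitly NOT the genome-scale iJN1411 model; it is a
    desk-scale analogue whose interior reactions all pass the elemental
    balance check.

    The single biomass reaction drains 40 mmol carbon per gCDW and is free
    of any polymer species; PHA accumulation is a separate sink on the
    polymerized repeat unit, so %CDW accumulation is representable at
    steady state.
    """
    mets: List[Metabolite] = []
    for name in _EXTRACELLULAR:
        base = name[:-2]
        mets.append(Metabolite(name, formula=_FORMULAS[base], compartment="e"))
    for base, formula in _FORMULAS.items():
        mets.append(Metabolite(f"{base}_c", formula=formula, compartment="c"))
    mets.append(Metabolite("biomass_c", formula=None, compartment="c",
                           name="lumped residual biomass (pseudo-species)"))

    rxns: List[Reaction] = []

    def add(rid, stoich, lb=0.0, ub=1000.0, subsystem="", exchange=False):
        rxns.append(Reaction(rid, stoich, lb=lb, ub=ub, subsystem=subsystem,
                             is_exchange=exchange))

    # --- exchanges (negative flux = uptake) ------------------------------
    add("EX_octa_e", {"octa_e": -1.0}, lb=-10.0, ub=0.0,
        subsystem="exchange", exchange=True)
    add("EX_o2_e", {"o2_e": -1.0}, lb=-1000.0, ub=0.0,
        subsystem="exchange", exchange=True)
    add("EX_co2_e", {"co2_e": -1.0}, lb=0.0, ub=1000.0,
        subsystem="exchange", exchange=True)
    add("EX_nh4_e", {"nh4_e": -1.0}, lb=-1000.0, ub=0.0,
        subsystem="exchange", exchange=True)
    add("EX_pi_e", {"pi_e": -1.0}, lb=-1000.0, ub=1000.0,
        subsystem="exchange", exchange=True)
    add("EX_h2o_e", {"h2o_e": -1.0}, lb=-1000.0, ub=1000.0,
        subsystem="exchange", exchange=True)
    add("EX_h_e", {"h_e": -1.0}, lb=-1000.0, ub=1000.0,
        subsystem="exchange", exchange=True)
    add("EX_3ho_e", {"r3ho_e": -1.0}, lb=0.0, ub=1000.0,
        subsystem="exchange", exchange=True)

    # --- transport -------------------------------------------------------
    add("OCTAt", {"octa_e": -1.0, "h_e": -1.0, "octa_c": 1.0, "h_c": 1.0},
        subsystem="transport")
    add("O2t", {"o2_e": -1.0, "o2_c": 1.0}, lb=-1000.0, subsystem="transport")
    add("CO2t", {"co2_c": -1.0, "co2_e": 1.0}, lb=-1000.0,
        subsystem="transport")
    add("NH4t", {"nh4_e": -1.0, "nh4_c": 1.0}, subsystem="transport")
    add("PIt", {"pi_e": -1.0, "pi_c": 1.0}, lb=-1000.0, subsystem="transport")
    add("H2Ot", {"h2o_c": -1.0, "h2o_e": 1.0}, lb=-1000.0,
        subsystem="transport")
    add("Ht", {"h_e": -1.0, "h_c": 1.0}, lb=-1000.0, subsystem="transport")
    add("R3HOt", {"r3ho_c": -1.0, "h_c": -1.0, "r3ho_e": 1.0, "h_e": 1.0},
        subsystem="transport")

    # --- octanoate activation and beta-oxidation -------------------------
    bo = "beta-oxidation"
    add("FACOAL80", {"octa_c": -1.0, "atp_c": -1.0, "coa_c": -1.0,
                     "occoa_c": 1.0, "amp_c": 1.0, "ppi_c": 1.0},
        subsystem=bo)
    add("ACOAD80", {"occoa_c": -1.0, "fad_c": -1.0,
                    "oc2coa_c": 1.0, "fadh2_c": 1.0}, subsystem=bo)
    add("ECOAH3", {"oc2coa_c": -1.0, "h2o_c": -1.0, "3hocoa_c": 1.0},
        subsystem=bo)
    add("HACD3i", {"3hocoa_c": -1.0, "nad_c": -1.0,
                   "3oocoa_c": 1.0, "nadh_c": 1.0, "h_c": 1.0}, subsystem=bo)
    add("KAT3", {"3oocoa_c": -1.0, "coa_c": -1.0,
                 "accoa_c": 1.0, "hxcoa_c": 1.0}, subsystem=bo)
    add("ACOAD60", {"hxcoa_c": -1.0, "fad_c": -1.0,
                    "hx2coa_c": 1.0, "fadh2_c": 1.0}, subsystem=bo)
    add("ECOAH60", {"hx2coa_c": -1.0, "h2o_c": -1.0, "3hhcoa_c": 1.0},
        subsystem=bo)
    add("HACD60", {"3hhcoa_c": -1.0, "nad_c": -1.0,
                   "3ohcoa_c": 1.0, "nadh_c": 1.0, "h_c": 1.0}, subsystem=bo)
    add("KAT2", {"3ohcoa_c": -1.0, "coa_c": -1.0,
                 "accoa_c": 1.0, "btcoa_c": 1.0}, subsystem=bo)
    add("ACOAD40", {"btcoa_c": -1.0, "fad_c": -1.0,
                    "b2coa_c": 1.0, "fadh2_c": 1.0}, subsystem=bo)
    add("ECOAH40", {"b2coa_c": -1.0, "h2o_c": -1.0, "3hbcoa_c": 1.0},
        subsystem=bo)
    add("HACD40", {"3hbcoa_c": -1.0, "nad_c": -1.0,
                   "aacoa_c": 1.0, "nadh_c": 1.0, "h_c": 1.0}, subsystem=bo)
    add("KAT1", {"aacoa_c": -1.0, "coa_c": -1.0, "accoa_c": 2.0},
        subsystem=bo)

    # --- (R)-HA-CoA supply and the PHA cycle -----------------------------
    pha = "PHA cycle"
    # R-specific enoyl-CoA hydratase (PhaJ): direct route.
    add("RECOAH3", {"oc2coa_c": -1.0, "h2o_c": -1.0, "r3hocoa_c": 1.0},
        subsystem=pha)
    # 3-oxoacyl reductase (FabG): NADPH-coupled route; reversible, so with
    # ECOAH3 + HACD3i it exchanges one NADH for one NADPH per (R)-HA-CoA.
    add("RHACOAR80", {"3oocoa_c": -1.0, "nadph_c": -1.0, "h_c": -1.0,
                      "r3hocoa_c": 1.0, "nadp_c": 1.0},
        lb=-1000.0, subsystem=pha)
    # PHA polymerase: chain extension releases CoA and one repeat unit.
    add("PHAP2C80", {"r3hocoa_c": -1.0, "phaC8_c": 1.0, "coa_c": 1.0},
        subsystem=pha)
    # Net polymer accumulation leaves the steady-state system here.
    add("PHA_SINK", {"phaC8_c": -1.0}, subsystem=pha, exchange=True)
    # Depolymerase (PhaZ): hydrolyzes one repeat unit to the free acid.
    add("PHAZ", {"phaC8_c": -1.0, "h2o_c": -1.0,
                 "r3ho_c": 1.0, "h_c": 1.0}, subsystem=pha)
    # Acyl-CoA synthetase (FadD): ATP-dependent monomer reactivation.
    add("FADD1", {"r3ho_c": -1.0, "atp_c": -1.0, "coa_c": -1.0,
                  "r3hocoa_c": 1.0, "amp_c": 1.0, "ppi_c": 1.0},
        subsystem=pha)

    # --- TCA cycle and glyoxylate shunt ----------------------------------
    tca = "TCA cycle"
    add("CS", {"accoa_c": -1.0, "oaa_c": -1.0, "h2o_c": -1.0,
               "cit_c": 1.0, "coa_c": 1.0, "h_c": 1.0}, subsystem=tca)
    add("ACONTa", {"cit_c": -1.0, "acon_c": 1.0, "h2o_c": 1.0},
        lb=-1000.0, subsystem=tca)
    add("ACONTb", {"acon_c": -1.0, "h2o_c": -1.0, "icit_c": 1.0},
        lb=-1000.0, subsystem=tca)
    add("ICDHyr", {"icit_c": -1.0, "nadp_c": -1.0,
                   "akg_c": 1.0, "co2_c": 1.0, "nadph_c": 1.0},
        lb=-1000.0, subsystem=tca)
    add("AKGDH", {"akg_c": -1.0, "coa_c": -1.0, "nad_c": -1.0,
                  "succoa_c": 1.0, "co2_c": 1.0, "nadh_c": 1.0},
        subsystem=tca)
    add("SUCOAS", {"succ_c": -1.0, "atp_c": -1.0, "coa_c": -1.0,
                   "succoa_c": 1.0, "adp_c": 1.0, "pi_c": 1.0},
        lb=-1000.0, subsystem=tca)
    add("SUCDi", {"succ_c": -1.0, "fad_c": -1.0,
                  "fum_c": 1.0, "fadh2_c": 1.0}, subsystem=tca)
    add("FUM", {"fum_c": -1.0, "h2o_c": -1.0, "mal_c": 1.0},
        lb=-1000.0, subsystem=tca)
    add("MDH", {"mal_c": -1.0, "nad_c": -1.0,
                "oaa_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
        lb=-1000.0, subsystem=tca)
    glx = "glyoxylate shunt"
    add("ICL", {"icit_c": -1.0, "glx_c": 1.0, "succ_c": 1.0}, subsystem=glx)
    add("MALS", {"accoa_c": -1.0, "glx_c": -1.0, "h2o_c": -1.0,
                 "mal_c": 1.0, "coa_c": 1.0, "h_c": 1.0}, subsystem=glx)

    # --- gluconeogenic backbone and anaplerotic exits --------------------
    gng = "gluconeogenesis"
    add("PPCK", {"oaa_c": -1.0, "atp_c": -1.0,
                 "pep_c": 1.0, "adp_c": 1.0, "co2_c": 1.0}, subsystem=gng)
    add("ENO", {"2pg_c": -1.0, "pep_c": 1.0, "h2o_c": 1.0},
        lb=-1000.0, subsystem=gng)
    add("PGM", {"2pg_c": -1.0, "3pg_c": 1.0}, lb=-1000.0, subsystem=gng)
    add("PGK", {"3pg_c": -1.0, "atp_c": -1.0,
                "13dpg_c": 1.0, "adp_c": 1.0}, lb=-1000.0, subsystem=gng)
    add("GAPD", {"g3p_c": -1.0, "nad_c": -1.0, "pi_c": -1.0,
                 "13dpg_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
        lb=-1000.0, subsystem=gng)
    add("ME1", {"mal_c": -1.0, "nad_c": -1.0,
                "pyr_c": 1.0, "co2_c": 1.0, "nadh_c": 1.0}, subsystem=gng)
    add("PDH", {"pyr_c": -1.0, "coa_c": -1.0, "nad_c": -1.0,
                "accoa_c": 1.0, "co2_c": 1.0, "nadh_c": 1.0}, subsystem=gng)

    # --- energy metabolism (lumped) --------------------------------------
    nrg = "oxidative phosphorylation"
    add("OXPHOS_NADH", {"nadh_c": -1.0, "o2_c": -0.5, "h_c": -3.5,
                        "adp_c": -2.5, "pi_c": -2.5,
                        "nad_c": 1.0, "atp_c": 2.5, "h2o_c": 3.5},
        subsystem=nrg)
    add("OXPHOS_FADH2", {"fadh2_c": -1.0, "o2_c": -0.5, "h_c": -1.5,
                         "adp_c": -1.5, "pi_c": -1.5,
                         "fad_c": 1.0, "atp_c": 1.5, "h2o_c": 2.5},
        subsystem=nrg)
    add("NADTRHD", {"nad_c": -1.0, "nadph_c": -1.0,
                    "nadh_c": 1.0, "nadp_c": 1.0}, lb=-1000.0, subsystem=nrg)
    add("ATPM", {"atp_c": -1.0, "h2o_c": -1.0,
                 "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
        lb=ATP_MAINTENANCE_LB, subsystem="maintenance")
    # Pyrophosphate hydrolysis pulls the two acyl-CoA ligations forward.
    add("PPA", {"ppi_c": -1.0, "h2o_c": -1.0, "pi_c": 2.0, "h_c": 1.0},
        subsystem=nrg)
    # Adenylate kinase regenerates ADP from the AMP left by the ligases.
    add("ADK1", {"amp_c": -1.0, "atp_c": -1.0, "adp_c": 2.0},
        lb=-1000.0, subsystem=nrg)

    # --- biomass ----------------------------------------------------------
    add("BIOMASS_core",
        {"accoa_c": -5.0, "oaa_c": -2.5, "akg_c": -2.0, "g3p_c": -2.0,
         "pyr_c": -4.0 / 3.0, "nh4_c": -10.0, "atp_c": -40.0,
         "nadph_c": -12.0, "h2o_c": -40.0,
         "coa_c": 5.0, "adp_c": 40.0, "pi_c": 42.0, "nadp_c": 12.0,
         "h_c": 40.0, "biomass_c": 1.0},
        subsystem="biomass")
    add("DM_biomass", {"biomass_c": -1.0}, subsystem="biomass", exchange=True)

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS_core",
        name="pha_core",
    )
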