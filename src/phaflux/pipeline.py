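"""End-to-end orchestration: strains × phases → condition models, FBA
validation, flux samples, medians, strain comparisons, dFBA trajectories.

Every run writes a manifest recording the configuration, derived seeds and
diagnostics (including the mixed fraction of each condition model's
chain), which suffices to reproduce every output byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .contextualize import (
    ConditionModel,
    ReactionMap,
    apply_phase_constraints,
    build_phase_rates,
    fba,
    validate_phase,
)
from .dfba import BatchState, endpoint_summary, simulate_batch
from .model_core import MetabolicModel, knockout, load_model
from .physiology import (
    MonomerMassTable,
    PhysioTimeCourse,
    segment_phases,
)
from .sampling import (
    DEFAULT_N_SAMPLES,
    DEFAULT_RATIO_THRESHOLDS,
    DEFAULT_THINNING,
    achr_sample,
    compare_strains,
    median_fluxes,
    mixed_fraction,
)
from .synthetic_data import core_pha_model

log = logging.getLogger("phaflux")

#: Strain-specific reaction knockouts applied to the base model before
#: contextualization: the depolymerase deletion lacks PhaZ; the
#: whole-cluster deletion lacks polymerase, depolymerase and the
#: reactivation ligase.
DEFAULT_STRAIN_KNOCKOUTS: Dict[str, Tuple[str, ...]] = {
    "KT40Z": ("PHAZ",),
    "KT2440 Δpha": ("PHAP2C80", "PHAZ", "FADD1"),
    "KT2440 dpha": ("PHAP2C80", "PHAZ", "FADD1"),
}


@dataclass
class RunConfig:
    """Configuration of one full contextualization run."""

    timecourses: Dict[str, str]                  # strain -> CSV path
    out_dir: str
    model_path: Optional[str] = None             # None -> packaged core model
    reference_strain: str = "KT2440"
    phase_boundaries: Tuple[float, ...] = (5.0, 10.0)
    tolerance: float = 0.05
    n_samples: int = DEFAULT_N_SAMPLES
    thinning: int = DEFAULT_THINNING
    seed: int = 0
    ratio_thresholds: Tuple[float, float] = DEFAULT_RATIO_THRESHOLDS
    dfba_dt: float = 0.01
    strain_knockouts: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STRAIN_KNOCKOUTS)
    )

    def load_base_model(self) -> MetabolicModel:
        if self.model_path is None:
            return core_pha_model()
        return load_model(self.model_path)


def write_flux_tsv(model: MetabolicModel, values: Dict[str, float],
                   path: str) -> None:
    """Flux table in the standard 3-column layout: reaction id, subsystem,
    value."""
    rows = [
        {"reaction": r.id, "subsystem": r.subsystem,
         "value": values.get(r.id, 0.0)}
        for r in model.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain with a FAILED marker."""


def run_contextualization(cfg: RunConfig) -> dict:
    """Run the full pipeline and return the manifest (also written to
    ``manifest.json`` in the output directory).

    For each strain × phase: phase rates, condition model, FBA validation
    report, ACHR flux samples, median-flux table; then per-strain dFBA
    trajectories and per-phase median-flux-ratio comparisons against the
    reference strain.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": "0.1.0",
        "seed": cfg.seed,
        "tolerance": cfg.tolerance,
        "n_samples": cfg.n_samples,
        "thinning": cfg.thinning,
        "phase_boundaries": list(cfg.phase_boundaries),
        "reference_strain": cfg.reference_strain,
        "ratio_thresholds": list(cfg.ratio_thresholds),
        "strains": {},
        "comparisons": [],
        "diagnostics": {},
    }
    stage = "setup"
    try:
        base = cfg.load_base_model()
        masses = MonomerMassTable()
        samples: Dict[Tuple[str, str], object] = {}
        strain_order = sorted(cfg.timecourses)
        for s_idx, strain in enumerate(strain_order):
            stage = f"load[{strain}]"
            t0 = time.perf_counter()
            tc = PhysioTimeCourse.from_csv(cfg.timecourses[strain], strain=strain)
            model = base
            for rxn_id in cfg.strain_knockouts.get(strain, ()):  # strain genotype
                model = knockout(model, rxn_id)
            phases = segment_phases(tc, cfg.phase_boundaries)
            sdir = out / _slug(strain)
            sdir.mkdir(exist_ok=True)
            strain_entry: dict = {"phases": {}, "knockouts": list(
                cfg.strain_knockouts.get(strain, ()))}

            all_rates = []
            for p_idx, phase in enumerate(phases):
                stage = f"contextualize[{strain}:{phase.label}]"
                rates = build_phase_rates(tc, phase, masses)
                all_rates.append(rates)
                cm = apply_phase_constraints(
                    model, rates, tolerance=cfg.tolerance, strain=strain
                )
                with open(sdir / f"condition_{phase.label}.json", "w") as fh:
                    json.dump(cm.to_dict(), fh, indent=1)
                sol = fba(cm)
                report = validate_phase(cm, sol, rates)
                report.table.to_csv(
                    sdir / f"validation_{phase.label}.tsv", sep="\t", index=False
                )
                stage = f"sample[{strain}:{phase.label}]"
                cond_seed = cfg.seed + 97 * s_idx + 13 * p_idx
                sset = achr_sample(
                    cm, n_samples=cfg.n_samples, seed=cond_seed,
                    thinning=cfg.thinning,
                )
                sset.to_tsv(
                    str(sdir / f"samples_{phase.label}.tsv"),
                    sidecar=str(sdir / f"samples_{phase.label}.yaml"),
                )
                med = median_fluxes(sset)
                write_flux_tsv(model, med, str(sdir / f"medians_{phase.label}.tsv"))
                mixed = mixed_fraction(sset)
                samples[(strain, phase.label)] = sset
                manifest["diagnostics"][f"{strain}:{phase.label}"] = {
                    "mixed_fraction": mixed,
                    "seed": cond_seed,
                    "fba_status": sol.status,
                    "fba_objective": sol.objective_value,
                    "validation_ok": bool(report.ok),
                }
                strain_entry["phases"][phase.label] = {
                    "growth_rate": rates.growth_rate,
                    "octanoate_uptake": rates.octanoate_uptake,
                    "pha_production": rates.pha_production,
                    "ha_secretion": rates.ha_secretion,
                }

            stage = f"dfba[{strain}]"
            y0 = BatchState(
                residual_biomass=float(tc.residual_biomass_series[0]),
                pha=float(tc.pha_conc_series[0]),
                ha=float(tc.ha_conc[0]),
                octanoate=float(tc.octanoate[0]),
            )
            traj = simulate_batch(model, all_rates, y0, dt=cfg.dfba_dt)
            traj.to_tsv(str(sdir / "dfba_trajectory.tsv"))
            strain_entry["dfba_endpoint"] = endpoint_summary(traj)
            strain_entry["wall_time_s"] = time.perf_counter() - t0
            manifest["strains"][strain] = strain_entry
            log.info("strain %s done in %.1f s", strain,
                     strain_entry["wall_time_s"])

        stage = "compare"
        ref = cfg.reference_strain
        if ref in strain_order:
            for strain in strain_order:
                if strain == ref:
                    continue
                for phase_label in {k[1] for k in samples if k[0] == strain}:
                    comp = compare_strains(
                        samples[(strain, phase_label)],
                        samples[(ref, phase_label)],
                        thresholds=cfg.ratio_thresholds,
                    )
                    path = out / f"compare_{_slug(strain)}_vs_{_slug(ref)}_{phase_label}.tsv"
                    comp.to_tsv(str(path))
                    manifest["comparisons"].append(str(path.name))

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise StageError(f"pipeline failed at stage {stage}: {err}") from err


def _slug(name: str) -> str:
    return (
        name.replace(" ", "_").replace("Δ", "d").encode("ascii", "ignore")
        .decode("ascii")
    )
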