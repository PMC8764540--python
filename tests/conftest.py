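import dataclasses

import pytest

from phaflux.model_core import knockout
from phaflux.physiology import segment_phases
from phaflux.synthetic_data import (
    builtin_archetypes,
    core_pha_model,
    make_strain_timecourse,
)


@pytest.fixture(scope="session")
def core_model():
    return core_pha_model()


@pytest.fixture(scope="session")
def archetypes():
    return builtin_archetypes()


def noiseless(arch):
    return dataclasses.replace(arch, noise_cv=0.0)


@pytest.fixture(scope="session")
def wt_course(archetypes):
    """Noise-free wild-type time course."""
    return make_strain_timecourse(noiseless(archetypes["KT2440"]), seed=0)


@pytest.fixture(scope="session")
def wt_phases(wt_course):
    return segment_phases(wt_course)


@pytest.fixture(scope="session")
def strain_condition_model(core_model, archetypes):
    """Factory: (strain, phase index) -> feasibility-checked ConditionModel."""
    from phaflux.contextualize import apply_phase_constraints, build_phase_rates
    from phaflux.pipeline import DEFAULT_STRAIN_KNOCKOUTS

    def build(strain, phase_idx, tolerance=0.05, seed=7):
        tc = make_strain_timecourse(noiseless(archetypes[strain]), seed=seed)
        model = core_model
        for rxn_id in DEFAULT_STRAIN_KNOCKOUTS.get(strain, ()):
            model = knockout(model, rxn_id)
        phase = segment_phases(tc)[phase_idx]
        rates = build_phase_rates(tc, phase)
        return apply_phase_constraints(model, rates, tolerance=tolerance,
                                       strain=strain), rates

    return build
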