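import dataclasses

import numpy as np
import pytest

from conftest import noiseless

from phaflux.contextualize import build_phase_rates, fba
from phaflux.model_core import check_mass_balance, knockout
from phaflux.physiology import compute_growth_rate, segment_phases
from phaflux.synthetic_data import (
    BIOMASS_CARBON_MMOL_PER_G,
    HA_CARBON_MMOL_PER_G,
    OCTANOATE_CARBON,
    PHA_CARBON_MMOL_PER_G,
    StrainArchetype,
    archetypes_from_yaml,
    archetypes_to_yaml,
    builtin_archetypes,
    deterministic_trajectories,
    make_strain_timecourse,
    make_toy_model,
)


class TestArchetypes:
    def test_endpoint_table_values(self, archetypes):
        assert archetypes["KT2440"].final_pha_pct == 71.7
        assert archetypes["KT2440"].growth_rate == 0.31
        assert archetypes["KT40Z"].final_ha == 0.0
        assert archetypes["KT2440 Δpha"].final_viable_cells == 22.3
        assert archetypes["M4"].growth_rate == 0.35
        # ascii alias points at the same archetype
        assert archetypes["KT2440 dpha"] is archetypes["KT2440 Δpha"]

    def test_all_strains_start_from_fifteen_millimolar_octanoate(self,
                                                                 archetypes):
        for key, arch in archetypes.items():
            assert arch.octanoate_initial == 15.0

    def test_inconsistent_endpoints_rejected(self):
        # more product carbon than substrate carbon cannot be generated
        with pytest.raises(ValueError, match="carbon"):
            StrainArchetype("impossible", 0.3, 5.0, 50.0, 1.0, 1.0)

    def test_yaml_round_trip(self, archetypes, tmp_path):
        path = tmp_path / "arch.yaml"
        archetypes_to_yaml(archetypes, str(path))
        back = archetypes_from_yaml(str(path))
        assert back["KT2440"] == dataclasses.replace(
            archetypes["KT2440"], name="KT2440"
        )
        assert set(k for k in archetypes if k == archetypes[k].name) == set(back)


class TestTimecourseGenerator:
    def test_initial_residual_biomass_in_reported_range(self, archetypes):
        for key, arch in archetypes.items():
            tc = make_strain_timecourse(noiseless(arch), seed=0)
            assert 0.08 <= tc.residual_biomass_series[0] <= 0.09

    def test_noiseless_wild_type_reproduces_endpoint_row(self, archetypes):
        tc = make_strain_timecourse(noiseless(archetypes["KT2440"]), seed=0)
        assert tc.total_biomass[-1] == pytest.approx(1.3, rel=0.01)
        assert tc.pha_pct_cdw[-1] == pytest.approx(71.7, rel=0.01)
        assert tc.ha_conc[-1] == pytest.approx(0.2, rel=0.01)
        assert tc.octanoate[-1] == pytest.approx(0.0, abs=0.01)

    def test_determinism_contract(self, archetypes):
        a = archetypes["M2"]
        t1 = make_strain_timecourse(a, seed=7)
        t2 = make_strain_timecourse(a, seed=7)
        t3 = make_strain_timecourse(a, seed=8)
        np.testing.assert_array_equal(t1.total_biomass, t2.total_biomass)
        assert not np.array_equal(t1.total_biomass, t3.total_biomass)

    def test_invalid_times_rejected(self, archetypes):
        with pytest.raises(ValueError):
            make_strain_timecourse(archetypes["KT2440"], times=[0, 5, 10])

    @pytest.mark.parametrize("strain", ["KT2440", "KT40Z", "M4", "KT2440 Δpha"])
    def test_growth_rate_recovered_exactly_without_noise(self, archetypes,
                                                         strain):
        arch = noiseless(archetypes[strain])
        tc = make_strain_timecourse(arch, seed=0)
        mu = compute_growth_rate(tc, segment_phases(tc)[0])
        assert mu == pytest.approx(arch.growth_rate, abs=1e-6)

    def test_carbon_bookkeeping_closes_at_every_time(self, archetypes):
        for key, arch in archetypes.items():
            t = np.linspace(0, 24, 97)
            traj = deterministic_trajectories(arch, t)
            consumed = (arch.octanoate_initial - traj["octanoate"]) * OCTANOATE_CARBON
            products = (
                BIOMASS_CARBON_MMOL_PER_G * (traj["residual"] - traj["residual"][0])
                + PHA_CARBON_MMOL_PER_G * traj["pha"]
                + HA_CARBON_MMOL_PER_G * traj["ha"]
            )
            assert (consumed >= products - 1e-9).all()
            assert consumed[-1] == pytest.approx(
                products[-1] + traj["co2_mmolC"][-1], abs=1e-9
            )

    def test_parameter_recovery_through_pipeline(self, archetypes):
        """Archetype -> noisy course -> phase rates must recover the growth
        rate within a noise-scaled tolerance."""
        arch = archetypes["KT2440"]
        hits = 0
        for seed in range(20):
            tc = make_strain_timecourse(arch, seed=seed)
            rates = build_phase_rates(tc, segment_phases(tc)[0])
            if abs(rates.growth_rate - arch.growth_rate) <= 0.02:
                hits += 1
        assert hits >= 18

    def test_microresp_channel_recovers_co2_fold(self, archetypes):
        from phaflux.physiology import CalibrationCurve, microresp_percent_co2

        calib = CalibrationCurve()
        folds = {}
        for strain in ["KT2440", "M2", "M3", "M4"]:
            tc = make_strain_timecourse(noiseless(archetypes[strain]), seed=0)
            od = tc.od570[-1]
            folds[strain] = microresp_percent_co2(od, calib)
        for strain in ["M2", "M3", "M4"]:
            fold = folds[strain] / folds["KT2440"]
            assert 2.5 <= fold <= 3.8  # elevated hydrolyzer respiration


class TestToyModels:
    def test_chain_yield_half(self):
        sol = fba(make_toy_model("chain"))
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_interval_is_one_dimensional(self):
        m = make_toy_model("interval")
        S = m.stoichiometric_matrix()
        assert S.shape[1] - np.linalg.matrix_rank(S) == 1

    def test_pha_mini_depolymerase_gates_ha_secretion(self):
        m = make_toy_model("pha_mini")
        probe = m.copy()
        probe.objective_id = "EX_ha"
        assert fba(probe).objective_value == pytest.approx(10.0, abs=1e-9)
        closed = knockout(probe, "DEPOLY")
        assert fba(closed).objective_value == pytest.approx(0.0, abs=1e-9)
        # growth is unaffected by the knockout (hand LP: 0.5 * uptake)
        assert fba(knockout(m, "DEPOLY")).objective_value == pytest.approx(5.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_toy_model("moebius")


class TestCorePhaModel:
    def test_interior_reactions_elementally_balanced(self, core_model):
        assert check_mass_balance(core_model) == []

    def test_growth_at_reported_uptake(self, core_model):
        m = core_model.copy()
        m.reaction("EX_octa_e").lb = -3.8
        sol = fba(m)
        assert sol.status == "optimal"
        assert sol.objective_value > 0.1

    def test_named_reactions_present(self, core_model):
        for rxn_id in ["PHAP2C80", "RHACOAR80", "RECOAH3", "ECOAH3", "HACD3i",
                       "CS", "ACONTa", "ACONTb", "MDH", "ICL", "MALS",
                       "GAPD", "PGK", "PGM", "ENO", "PHAZ", "FADD1", "ATPM"]:
            assert core_model.reaction(rxn_id) is not None

    def test_depolymerase_knockout_blocks_secretion_in_all_samples(
        self, core_model
    ):
        from phaflux.sampling import achr_sample

        ko = knockout(core_model, "PHAZ")
        ko.reaction("EX_octa_e").lb = -3.8
        s = achr_sample(ko, n_samples=200, seed=3, thinning=5)
        assert np.allclose(s.column("EX_3ho_e"), 0.0, atol=1e-8)

    def test_biomass_drains_forty_millimoles_of_carbon(self, core_model):
        from phaflux.model_core import parse_formula

        bio = core_model.reaction("BIOMASS_core")
        carbon = 0.0
        for met_id, coef in bio.stoichiometry.items():
            formula = core_model.metabolite(met_id).formula
            if formula:
                carbon += coef * parse_formula(formula).get("C", 0)
        assert -carbon == pytest.approx(BIOMASS_CARBON_MMOL_PER_G)
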