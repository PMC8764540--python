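import numpy as np
import pytest

from oracles import rejection_sample_box

from phaflux.sampling import (
    DegenerateSampleError,
    FluxSampleSet,
    achr_sample,
    atp_production_summary,
    compare_strains,
    median_fluxes,
    mixed_fraction,
    warmup_points,
)
from phaflux.synthetic_data import make_toy_model


def sampleset(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"R{i}" for i in range(points.shape[1])]
    return FluxSampleSet(points=points, reaction_ids=ids, seed=0,
                         n_warmup=0, thinning=1, chain_length=len(points))


class TestWarmup:
    def test_interval_warmup_hits_both_endpoints(self):
        interval = make_toy_model("interval")
        w = warmup_points(interval, 8, seed=0)
        assert np.isclose(w[:, 0].min(), 0.0, atol=1e-9)
        assert np.isclose(w[:, 0].max(), 10.0, atol=1e-9)

    def test_box_warmup_reaches_every_coordinate_extreme(self):
        box = make_toy_model("box")
        w = warmup_points(box, 16, seed=0)
        # +/- coordinate objectives pin each source flux at both box edges
        # (vertex enumeration oracle: extremes of the unit square are 0 and 1)
        for j in (0, 2):
            assert np.isclose(w[:, j].min(), 0.0, atol=1e-9)
            assert np.isclose(w[:, j].max(), 1.0, atol=1e-9)

    def test_condition_model_warmup_is_feasible(self, strain_condition_model):
        cm, _ = strain_condition_model("KT2440", 0)
        model = cm.realized()
        w = warmup_points(cm, 40, seed=1)
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds()
        assert np.abs(S @ w.T).max() < 1e-6
        assert (w >= lb - 1e-8).all() and (w <= ub + 1e-8).all()

    def test_infeasible_model_raises_before_sampling(self, core_model):
        from phaflux.sampling import SamplingError

        broken = core_model.copy()
        broken.reaction("BIOMASS_core").lb = 5.0
        broken.reaction("EX_octa_e").lb = -0.1
        with pytest.raises(SamplingError):
            warmup_points(broken, 8, seed=0)


class TestAchr:
    def test_fixed_reaction_is_constant_across_samples(self, core_model):
        m = core_model.copy()
        m.reaction("ATPM").lb = 0.7
        m.reaction("ATPM").ub = 0.7
        m.reaction("EX_octa_e").lb = -4.0
        s = achr_sample(m, n_samples=200, seed=5, thinning=5)
        assert np.allclose(s.column("ATPM"), 0.7, atol=1e-8)

    def test_box_marginals_match_rejection_oracle(self):
        box = make_toy_model("box")
        s = achr_sample(box, n_samples=4000, seed=2, thinning=10)
        oracle = rejection_sample_box(box, 4000, seed=3)
        for j in (0, 2):  # source fluxes, uniform on [0, 1]
            se = oracle[:, j].std() / np.sqrt(len(oracle))
            assert abs(s.points[:, j].mean() - oracle[:, j].mean()) < 3 * se * 2

    def test_chain_coordinates_equal_and_uniform(self):
        interval = make_toy_model("interval")
        s = achr_sample(interval, n_samples=4000, seed=7, thinning=10)
        np.testing.assert_allclose(s.points[:, 0], s.points[:, 1], atol=1e-6)
        from scipy.stats import kstest

        stat = kstest(s.points[:, 0] / 10.0, "uniform").statistic
        # thinned chain retains mild autocorrelation; KS distance stays small
        assert stat < 0.05

    def test_bit_reproducible_for_fixed_seed(self, strain_condition_model):
        cm, _ = strain_condition_model("KT2440", 0)
        s1 = achr_sample(cm, n_samples=50, seed=42, thinning=5)
        s2 = achr_sample(cm, n_samples=50, seed=42, thinning=5)
        assert np.array_equal(s1.points, s2.points)
        s3 = achr_sample(cm, n_samples=50, seed=43, thinning=5)
        assert not np.array_equal(s1.points, s3.points)

    def test_every_point_feasible_on_condition_model(self, strain_condition_model):
        cm, _ = strain_condition_model("KT40Z", 2)
        s = achr_sample(cm, n_samples=300, seed=9, thinning=10)
        s.check_feasible(cm.realized())  # raises on violation

    def test_persistence_round_trip(self, tmp_path):
        s = achr_sample(make_toy_model("box"), n_samples=50, seed=1, thinning=5)
        tsv = tmp_path / "s.tsv"
        yml = tmp_path / "s.yaml"
        s.to_tsv(str(tsv), sidecar=str(yml))
        back = FluxSampleSet.from_tsv(str(tsv), str(yml))
        np.testing.assert_allclose(back.points, s.points)
        assert back.seed == s.seed and back.thinning == s.thinning


class TestMixedFraction:
    def test_iid_samples_mix_perfectly(self):
        rng = np.random.default_rng(0)
        s = sampleset(rng.uniform(size=(10000, 3)))
        assert 0.45 <= mixed_fraction(s) <= 0.55

    def test_identical_points_are_degenerate(self):
        s = sampleset(np.ones((50, 2)))
        with pytest.raises(DegenerateSampleError):
            mixed_fraction(s)

    def test_hand_enumerated_four_point_chain(self):
        # points {1,2,9,10}: median 5.5; pairs (1,9) and (2,10) both cross
        s = sampleset([1.0, 2.0, 9.0, 10.0])
        assert mixed_fraction(s) == 1.0

    def test_sorted_chain_never_crosses(self):
        # a monotone (fully autocorrelated) chain pairs low with high only
        # on opposite sides half the time being sorted -> here all cross
        s = sampleset(np.linspace(0, 1, 100))
        assert mixed_fraction(s) == 1.0

    def test_minimum_chain_length(self):
        with pytest.raises(ValueError):
            mixed_fraction(sampleset([1.0]))


class TestMedians:
    def test_constant_coordinate_returns_its_value(self):
        s = sampleset(np.column_stack([np.full(9, 3.3), np.arange(9.0)]))
        med = median_fluxes(s)
        assert med["R0"] == 3.3

    def test_odd_length_order_statistic(self):
        s = sampleset([1.0, 2.0, 100.0])
        assert median_fluxes(s)["R0"] == 2.0

    def test_box_medians_near_half(self):
        box = make_toy_model("box")
        s = achr_sample(box, n_samples=4000, seed=11, thinning=10)
        med = median_fluxes(s)
        assert med["SRC_A"] == pytest.approx(0.5, abs=0.05)
        assert med["SRC_B"] == pytest.approx(0.5, abs=0.05)


class TestCompareStrains:
    def test_self_comparison_is_all_unaffected(self):
        s = sampleset(np.random.default_rng(1).uniform(1, 2, size=(100, 4)))
        comp = compare_strains(s, s)
        assert (comp.table["ratio"] == 1.0).all()
        assert (comp.table["class"] == "unaffected").all()

    def test_threshold_rule_on_hand_medians(self):
        a = sampleset(np.full((5, 1), 2.0))
        b = sampleset(np.full((5, 1), 1.0))
        comp = compare_strains(a, b, thresholds=(1.2, 0.8))
        assert comp.classes()["R0"] == "increased"
        comp_rev = compare_strains(b, a, thresholds=(1.2, 0.8))
        assert comp_rev.classes()["R0"] == "reduced"

    def test_undefined_below_median_floor(self):
        a = sampleset(np.full((5, 1), 2.0))
        b = sampleset(np.zeros((5, 1)))
        comp = compare_strains(a, b)
        assert comp.classes()["R0"] == "undefined"
        assert np.isnan(comp.ratio("R0"))

    def test_mismatched_reactions_listed(self):
        a = sampleset(np.zeros((5, 1)), ids=["R0"])
        b = sampleset(np.zeros((5, 1)), ids=["R1"])
        with pytest.raises(ValueError, match="R0.*R1|R1.*R0"):
            compare_strains(a, b)


class TestEnergySummaries:
    def test_atp_summary_counts_producers_not_maintenance(self, core_model):
        ids = core_model.reaction_ids
        points = np.zeros((3, len(ids)))
        points[:, ids.index("OXPHOS_NADH")] = 2.0    # +2.5 ATP each
        points[:, ids.index("ATPM")] = 1.0           # excluded drain
        points[:, ids.index("FACOAL80")] = 1.0       # ATP consumer: ignored
        s = FluxSampleSet(points, ids, 0, 0, 1, 3)
        assert atp_production_summary(s, core_model) == pytest.approx(5.0)
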