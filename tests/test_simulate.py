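"""Generator physics: efflux divisor, Crone-Renkin limits, noise, recovery."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import perfusionpk as pk


class TestApparentPS:
    def test_no_transporters_gives_passive_PS(self):
        assert pk.apparent_PS(2.0, {}, "none", {}) == 2.0

    def test_complete_inhibition_restores_passive_PS(self):
        t = {"x": pk.Transporter(activity=3.0)}
        eff = {"inh": {"x": 1.0}}
        assert pk.apparent_PS(2.0, t, "inh", eff) == pytest.approx(2.0, rel=1e-15)

    def test_uninhibited_activity_divides(self):
        t = {"x": pk.Transporter(activity=3.0)}
        assert pk.apparent_PS(2.0, t, "none", {}) == pytest.approx(0.5, rel=1e-15)

    def test_knockout_equivalent_to_full_inhibition_exactly(self):
        t_ko = {"x": pk.Transporter(activity=3.0, genotype_present=False),
                "y": pk.Transporter(activity=1.5)}
        t_wt = {"x": pk.Transporter(activity=3.0),
                "y": pk.Transporter(activity=1.5)}
        eff = {"inh": {"x": 1.0}}
        assert pk.apparent_PS(2.0, t_ko, "none", {}) == pk.apparent_PS(
            2.0, t_wt, "inh", eff
        )

    @given(a=st.floats(min_value=0.01, max_value=50.0))
    @settings(deadline=None)
    def test_inhibition_always_raises_PS(self, a):
        t = {"x": pk.Transporter(activity=a)}
        eff = {"inh": {"x": 1.0}}
        assert pk.apparent_PS(1.0, t, "inh", eff) > pk.apparent_PS(1.0, t, "none", {})


class TestCroneRenkin:
    def test_zero_permeability_zero_uptake(self):
        assert pk.crone_renkin_kin(0.0, 5.0) == 0.0

    def test_flow_limited_plateau(self):
        assert pk.crone_renkin_kin(40.0 * 5.0, 5.0) == pytest.approx(5.0, rel=1e-6)

    def test_closed_form_at_PS_equal_F(self):
        F = 7.3
        assert pk.crone_renkin_kin(F, F) == pytest.approx(F * (1 - math.exp(-1)), rel=1e-12)

    @given(
        ps=st.floats(min_value=1e-3, max_value=100.0),
        dps=st.floats(min_value=1e-3, max_value=10.0),
        F=st.floats(min_value=0.1, max_value=50.0),
    )
    @settings(deadline=None)
    def test_strictly_increasing_in_PS_and_F(self, ps, dps, F):
        # below ~30 F the exponential has not saturated to double precision
        assume((ps + dps) / F < 30.0)
        assert pk.crone_renkin_kin(ps + dps, F) > pk.crone_renkin_kin(ps, F)
        assert pk.crone_renkin_kin(ps, F * 1.5) > pk.crone_renkin_kin(ps, F)

    @given(ratio=st.floats(min_value=1e-4, max_value=0.05))
    @settings(deadline=None)
    def test_low_extraction_linearity_bound(self, ratio):
        """First-order regime: |Kin - PS|/PS <= 2.5% for PS/F <= 0.05."""
        F = 10.0
        ps = ratio * F
        kin = pk.crone_renkin_kin(ps, F)
        assert abs(kin - ps) / ps <= 0.025


class TestGenerateSample:
    def test_same_seed_gives_identical_samples(self, noiseless_rat_scenario):
        scen = replace(noiseless_rat_scenario, biological_cv=0.25)
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        s1 = pk.generate_sample(scen, "cerebrum", "control", "none", "SN38", rng1)
        s2 = pk.generate_sample(scen, "cerebrum", "control", "none", "SN38", rng2)
        assert s1 == s2

    def test_noiseless_sample_inverts_exactly_through_pipeline(
        self, noiseless_rat_scenario
    ):
        scen = noiseless_rat_scenario
        rng = np.random.default_rng(0)
        s = pk.generate_sample(scen, "cerebellum", "control", "none", "SN38", rng)
        (r,) = pk.run_pipeline([s], scen.perfusate)
        phys = scen.regions["cerebellum"]
        ps_app = pk.apparent_PS(
            phys.PS_passive, scen.transporters, "none", scen.inhibitor_effects
        )
        assert r.Vv == pytest.approx(phys.Vv, rel=1e-12)
        assert r.Kin == pytest.approx(pk.crone_renkin_kin(ps_app, phys.F), rel=1e-12)

    def test_unknown_region_rejected(self, noiseless_rat_scenario):
        with pytest.raises(pk.ValidationError):
            pk.generate_sample(
                noiseless_rat_scenario, "other:spinal", "control", "none", "SN38",
                np.random.default_rng(0),
            )

    def test_mean_pipeline_kin_unbiased_over_many_noisy_samples(self):
        scen = replace(pk.default_rat_scenario(seed=11), n_flow=0)
        phys = scen.regions["cerebrum"]
        ps_app = pk.apparent_PS(
            phys.PS_passive, scen.transporters, "none", scen.inhibitor_effects
        )
        kin_true = pk.crone_renkin_kin(ps_app, phys.F)
        n = 10_000
        rng = np.random.default_rng(2024)
        samples = [
            pk.generate_sample(scen, "cerebrum", "control", "none", "SN38", rng,
                               sample_id=f"S{i}")
            for i in range(n)
        ]
        kins = np.array([r.Kin for r in pk.run_pipeline(samples, scen.perfusate)])
        mc_se = kins.std(ddof=1) / math.sqrt(n)
        assert abs(kins.mean() - kin_true) <= 3 * mc_se


class TestGenerateStudy:
    def test_row_count_matches_design(self):
        scen = pk.default_rat_scenario(seed=0, n=5)
        scen = replace(
            scen,
            design=[pk.StudyCell("control", "none", 5),
                    pk.StudyCell("control", "elacridar", 5)],
            n_flow=1,
        )
        samples, truth = pk.generate_study(scen)
        assert len(samples) == 3 * 2 * 5 + 3  # regions x cells x n + flow animals
        assert len(truth) == len(samples)

    def test_regenerating_is_deterministic(self):
        scen = pk.default_mouse_scenario(seed=3)
        s1, t1 = pk.generate_study(scen)
        s2, t2 = pk.generate_study(scen)
        assert s1 == s2
        assert t1.equals(t2)

    def test_flow_animals_use_flow_marker_time_and_sucrose_coperfusion(self):
        samples, _ = pk.generate_study(pk.default_rat_scenario(seed=0))
        flow = [s for s in samples if s.tracer == "diazepam"]
        assert flow and all(s.T == 60.0 for s in flow)
        assert all(s.Xstar > 0 for s in samples)  # vascular marker everywhere

    def test_zero_noise_truth_table_matches_pipeline_output(
        self, noiseless_rat_scenario
    ):
        scen = replace(
            noiseless_rat_scenario,
            design=[pk.StudyCell("control", "none", 1)],
            n_flow=1,
        )
        samples, truth = pk.generate_study(scen)
        results = pk.run_pipeline(samples, scen.perfusate)
        by_id = {r.sample_id: r for r in results}
        for row in truth.itertuples():
            r = by_id[row.sample_id]
            assert r.Kin == pytest.approx(row.Kin_true, rel=1e-12)
            assert r.Vv == pytest.approx(row.Vv_true, rel=1e-12)

    def test_tko_vs_tko_elacridar_ordering_under_third_transporter(self):
        """A TKO still expressing the elacridar-sensitive third transporter
        shows higher Kin when elacridar is added on top of the knockout."""
        scen = pk.default_mouse_scenario(seed=1)
        scen = replace(scen, biological_cv=0.0,
                       counting=replace(scen.counting, counting_noise=False))
        _, truth = pk.generate_study(scen)
        means = truth[truth.tracer == "SN38"].groupby(["group", "treatment"])[
            "Kin_true"
        ].mean()
        assert means[("TKO", "none")] < means[("TKO", "elacridar")]

    def test_diazepam_extraction_is_100_percent_and_low_PS_tracer_in_regime(
        self, noiseless_rat_scenario
    ):
        scen = replace(
            noiseless_rat_scenario,
            design=[pk.StudyCell("control", "none", 1)],
            n_flow=1,
        )
        samples, _ = pk.generate_study(scen)
        flow_estimates = pk.estimate_flow(
            [s for s in samples if s.tracer == "diazepam"], scen.perfusate
        )
        results = pk.run_pipeline(
            [s for s in samples if s.tracer == "SN38"], scen.perfusate, flow_estimates
        )
        for r in results:
            assert 0.5 <= r.E <= 2.0, (r.region, r.E)


class TestScenarioSerialization:
    def test_yaml_dict_round_trip(self):
        scen = pk.default_mouse_scenario(seed=9)
        back = pk.simulate.scenario_from_dict(pk.simulate.scenario_to_dict(scen))
        assert back.species == scen.species
        assert back.regions == scen.regions
        assert back.transporters == scen.transporters
        assert list(back.design) == list(scen.design)
        assert back.seed == scen.seed

    def test_invalid_inhibition_fraction_rejected(self):
        with pytest.raises(pk.ValidationError):
            pk.SimScenario(
                species="rat",
                regions={"cerebrum": pk.RegionPhysiology(F=10, Vv=10, PS_passive=1)},
                inhibitor_effects={"inh": {"x": 1.5}},
            )
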