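import math
from dataclasses import replace

import numpy as np
import pytest

from tgfsmad.errors import DomainError, SimulationError
from tgfsmad.pathway_model import (
    SPECIES,
    DoseSchedule,
    PathwayParams,
    PathwayState,
    default_params,
    dose_convert,
    presimulation_steady_state,
    rhs,
    simulate,
)


class TestParams:
    def test_preset_rates_nonnegative(self, preset):
        for f in ("pR1", "pR2", "kdeg_R1", "kdeg_R2", "ki", "kr", "ka",
                  "k_NFR", "kphos", "kdephos", "kin", "kex", "kin_p"):
            assert getattr(preset, f) >= 0

    def test_unknown_preset(self):
        with pytest.raises(DomainError):
            default_params("hela_like")

    def test_negative_rate_rejected(self, preset):
        with pytest.raises(DomainError):
            replace(preset, ka=-1.0)

    def test_half_life_consistency(self):
        assert PathwayParams.kdeg_from_half_life(60.0) == pytest.approx(
            math.log(2) / 60.0)

    def test_conservation_mode_flag(self, preset):
        assert preset.conservation_mode
        assert not replace(preset, pS2=0.1, kdeg_S2=0.01).conservation_mode


class TestRhs:
    def test_zero_state_zero_production_is_fixed(self, preset):
        p = replace(preset, pR1=0.0, pR2=0.0, pS2=0.0)
        np.testing.assert_array_equal(rhs(0.0, np.zeros(len(SPECIES)), p), 0.0)

    def test_no_ligand_no_complex_fluxes(self, preset):
        y = presimulation_steady_state(preset).to_array()
        dy = rhs(0.0, y, preset)
        i = {s: k for k, s in enumerate(SPECIES)}
        assert dy[i["L"]] == 0.0
        assert dy[i["LRCm"]] == 0.0
        assert dy[i["LRCe"]] == 0.0
        assert dy[i["pS2c"]] == 0.0

    def test_smad_pool_derivatives_sum_to_zero(self, preset):
        # conservation mode: phosphorylation/shuttling/dephosphorylation only
        # move SMAD2 between pools
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.uniform(0.0, 5.0, len(SPECIES))
            dy = rhs(0.0, y, preset)
            i = {s: k for k, s in enumerate(SPECIES)}
            total = dy[i["S2c"]] + dy[i["S2n"]] + dy[i["pS2c"]] + dy[i["pS2n"]]
            assert total == pytest.approx(0.0, abs=1e-12)


class TestSteadyState:
    def test_total_receptor_equals_production_over_degradation(self, preset):
        ss = presimulation_steady_state(preset)
        assert ss.r1_total == pytest.approx(preset.pR1 / preset.kdeg_R1, rel=1e-12)
        assert ss.r2_total == pytest.approx(preset.pR2 / preset.kdeg_R2, rel=1e-12)

    def test_linearity_in_production(self, preset):
        ss1 = presimulation_steady_state(preset)
        ss2 = presimulation_steady_state(replace(preset, pR1=2 * preset.pR1))
        assert ss2.r1_total == pytest.approx(2 * ss1.r1_total, rel=1e-12)
        assert ss2.r2_total == pytest.approx(ss1.r2_total, rel=1e-12)

    def test_no_complex_no_phospho_at_rest(self, preset_ss):
        assert preset_ss.LRCm == 0.0
        assert preset_ss.LRCe == 0.0
        assert preset_ss.pS2c == 0.0
        assert preset_ss.pS2n == 0.0

    def test_is_fixed_point_over_long_horizon(self, preset, preset_ss):
        tc = simulate(preset, 0.0, np.array([0.0, 10000.0]))
        y0, y1 = tc.states[0], tc.states[-1]
        scale = np.maximum(np.abs(y0), 1e-12)
        assert np.max(np.abs(y1 - y0) / scale) < 1e-6

    def test_smad_split_follows_shuttling_ratio(self, preset, preset_ss):
        assert preset_ss.S2n / preset_ss.S2c == pytest.approx(
            preset.kin / preset.kex, rel=1e-12)


class TestSimulate:
    def test_zero_dose_flat(self, preset):
        tc = simulate(preset, 0.0, np.linspace(0, 100, 11))
        for s in SPECIES:
            assert np.allclose(tc[s], tc[s][0], rtol=1e-7, atol=1e-12)

    def test_psmad2_unique_interior_peak(self, preset_tc):
        ps = preset_tc["pS2c"] + preset_tc["pS2n"]
        k = int(np.argmax(ps))
        assert 30 <= preset_tc.t[k] <= 120
        # single interior maximum: rises before, falls after
        assert np.all(np.diff(ps[: k + 1]) > -1e-12)
        assert np.all(np.diff(ps[k + 5 :]) < 1e-12)

    def test_ligand_nonincreasing_with_depletion(self, preset_tc):
        assert np.all(np.diff(preset_tc["L"]) <= 1e-12)

    def test_smad2_conservation_along_trajectory(self, preset, preset_tc):
        total = (preset_tc["S2c"] + preset_tc["S2n"]
                 + preset_tc["pS2c"] + preset_tc["pS2n"])
        assert np.max(np.abs(total - preset.s2_tot)) / preset.s2_tot < 1e-6

    def test_tolerance_refinement(self, preset):
        t = np.array([0.0, 30.0, 60.0, 240.0])
        a = simulate(preset, 0.1, t, rtol=1e-8, atol_scale=1e-10)
        b = simulate(preset, 0.1, t, rtol=1e-11, atol_scale=1e-13)
        ps_a = a["pS2c"] + a["pS2n"]
        ps_b = b["pS2c"] + b["pS2n"]
        assert np.max(np.abs(ps_a - ps_b)[1:] / ps_b[1:]) < 1e-6

    def test_all_pools_nonnegative(self, preset_tc):
        assert np.min(preset_tc.states) >= 0.0

    def test_grid_validation(self, preset):
        with pytest.raises(DomainError):
            simulate(preset, 0.1, np.array([1.0, 2.0]))
        with pytest.raises(DomainError):
            simulate(preset, 0.1, np.array([0.0, 2.0, 2.0]))

    def test_late_dose_event(self, preset):
        sched = DoseSchedule(events=((0.0, 0.0), (60.0, 0.1)))
        tc = simulate(preset, sched, np.arange(0.0, 121.0, 1.0))
        ps = tc["pS2c"] + tc["pS2n"]
        assert np.allclose(ps[:60], 0.0, atol=1e-9)
        assert ps[-1] > 1e-3

    def test_dose_ladder_monotone_without_feedback(self, preset):
        # k_NFR = 0, constant ligand: steady P-SMAD2 nondecreasing in dose
        p = replace(preset, k_NFR=0.0, med_scale=0.0)
        levels = []
        for dose in (0.001, 0.01, 0.1, 1.0):
            tc = simulate(p, dose, np.array([0.0, 5000.0]))
            levels.append(tc["pS2c"][-1] + tc["pS2n"][-1])
        assert all(b >= a - 1e-9 for a, b in zip(levels, levels[1:]))


class TestDoseConvert:
    def test_paper_value_100pM_is_2p5_ng_per_ml(self):
        assert dose_convert(100.0, "pM->ng/mL", mw=25.0) == pytest.approx(2.5)

    def test_zero(self):
        assert dose_convert(0.0, "pM->ng/mL", mw=25.0) == 0.0

    def test_round_trip_identity(self):
        x = 137.5
        y = dose_convert(dose_convert(x, "pM->ng/mL", mw=12.7),
                         "ng/mL->pM", mw=12.7)
        assert y == pytest.approx(x, rel=1e-12)

    def test_bad_mw(self):
        with pytest.raises(DomainError):
            dose_convert(1.0, "pM->ng/mL", mw=0.0)


class TestStateHelpers:
    def test_array_round_trip(self, preset_ss):
        arr = preset_ss.to_array()
        again = PathwayState.from_array(arr)
        assert again == preset_ss

    def test_timecourse_frame(self, preset_tc):
        df = preset_tc.to_frame()
        assert list(df.columns) == ["t_min", *SPECIES]
        assert len(df) == len(preset_tc.t)
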