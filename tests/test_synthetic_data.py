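"""Generator contracts: closed-form values, determinism, physical bounds."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lobsterresp.synthetic_data import (
    ChamberSpec,
    CohortDesign,
    SimulationTruth,
    Trajectory,
    q10_scale,
    simulate_chase_track,
    simulate_cohort,
    simulate_mo2_trajectory,
    substream_seed,
    synthesize_trace,
)


def make_truth(**kw):
    defaults = dict(smr_true=40.0, rmr_true=50.0, mmr_true=110.0, tau_recovery_h=3.0)
    defaults.update(kw)
    return SimulationTruth(**defaults)


class TestSimulationTruth:
    def test_epoc_identity_is_exact(self):
        truth = make_truth()
        assert truth.epoc_true == (110.0 - 50.0) * 3.0 == 180.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(smr_true=60.0),  # smr > rmr
            dict(mmr_true=50.0),  # mmr == rmr
            dict(tau_recovery_h=-1.0),
            dict(q10_smr=0.0),
            dict(background_fraction=-0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            make_truth(**kw)


class TestTrajectory:
    def test_starts_at_mmr_and_decays_to_known_value(self):
        truth = make_truth()
        traj = simulate_mo2_trajectory(truth, 24.0, 0.01, stochastic=False)
        assert traj.mo2[0] == pytest.approx(110.0)
        # at t = tau the excess has decayed by 1/e
        assert traj.mo2_at(3.0) == pytest.approx(50.0 + 60.0 / np.e, rel=1e-9)

    def test_excess_integral_matches_analytic_epoc(self):
        truth = make_truth()
        traj = simulate_mo2_trajectory(truth, 40.0, 0.001, stochastic=False)
        integral = np.trapezoid(traj.mo2 - truth.rmr_true, traj.time_h)
        assert integral == pytest.approx(truth.epoc_true, rel=2e-3)

    def test_non_positive_step_or_tau_rejected(self):
        truth = make_truth()
        with pytest.raises(ValueError, match="step"):
            simulate_mo2_trajectory(truth, 24.0, 0.0)
        with pytest.raises(ValueError, match="duration"):
            simulate_mo2_trajectory(truth, -1.0, 0.1)

    def test_quiescent_dips_reach_smr_but_never_exceed_mmr(self):
        truth = make_truth(seed=7)
        traj = simulate_mo2_trajectory(truth, 48.0, 10.0 / 3600.0)
        late = traj.mo2[traj.time_h > 20.0]
        # floor = SMR plus the (negligible) residual recovery excess
        assert late.min() == pytest.approx(truth.smr_true, abs=1e-3)
        assert np.all(traj.mo2 <= truth.mmr_true + 1e-9)


class TestSynthesizeTrace:
    def test_noise_free_decline_matches_fick_budget(self):
        """Constant MO2=45, 1 kg, V_eff=9 L, 6-min seal -> 0.5 mg/L drop."""
        truth = make_truth(noise_sd=0.0, background_fraction=0.0)
        cham = ChamberSpec(body_mass_kg=1.0, trial_duration_h=1.0)
        t = np.arange(0.0, 1.01, 10.0 / 3600.0)
        traj = Trajectory(time_h=t, mo2=np.full_like(t, 45.0), truth=truth)
        trace = synthesize_trace(traj, cham, truth)
        first_cycle = trace.data[trace.data["cycle_index"] == 0]
        meas = first_cycle[first_cycle["phase"] == "measure"]["o2_mg_l"].to_numpy()
        flush = first_cycle[first_cycle["phase"] == "flush"]["o2_mg_l"].to_numpy()
        assert meas[0] - flush[0] == pytest.approx(0.5, rel=1e-12)

    def test_zero_metabolism_gives_flat_measure_phases(self):
        truth = SimulationTruth(
            smr_true=0.0, rmr_true=0.0, mmr_true=1e-12,
            noise_sd=0.0, background_fraction=0.0,
        )
        cham = ChamberSpec(trial_duration_h=1.0)
        t = np.arange(0.0, 1.01, 10.0 / 3600.0)
        traj = Trajectory(time_h=t, mo2=np.zeros_like(t), truth=truth)
        trace = synthesize_trace(traj, cham, truth)
        meas = trace.data[trace.data["phase"] == "measure"]
        for _, cyc in meas.groupby("cycle_index"):
            assert np.ptp(cyc["o2_mg_l"].to_numpy()) < 1e-12

    def test_same_seed_gives_identical_trace(self, default_truth, default_chamber):
        def build():
            traj = simulate_mo2_trajectory(
                default_truth, default_chamber.trial_duration_h, 10.0 / 3600.0
            )
            return synthesize_trace(traj, default_chamber, default_truth)

        a, b = build(), build()
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_concentration_stays_within_physical_bounds(self, default_truth, default_chamber):
        traj = simulate_mo2_trajectory(
            default_truth, default_chamber.trial_duration_h, 10.0 / 3600.0
        )
        trace = synthesize_trace(traj, default_chamber, default_truth)
        o2 = trace.data["o2_mg_l"].to_numpy()
        sat = default_chamber.saturation_concentration_mg_l
        assert o2.min() > 0.0
        assert o2.max() <= sat + 4 * default_truth.noise_sd

    def test_implausible_depletion_names_offending_cycle(self):
        truth = make_truth(mmr_true=5000.0, rmr_true=4000.0, smr_true=3000.0,
                           noise_sd=0.0)
        cham = ChamberSpec(trial_duration_h=1.0)
        t = np.arange(0.0, 1.01, 10.0 / 3600.0)
        traj = Trajectory(time_h=t, mo2=np.full_like(t, 4000.0), truth=truth)
        with pytest.raises(ValueError, match="cycle 0"):
            synthesize_trace(traj, cham, truth)


class TestChamberSpec:
    def test_body_volume_must_leave_positive_effective_volume(self):
        with pytest.raises(ValueError, match="effective volume"):
            ChamberSpec(chamber_volume_l=1.0, body_volume_l=1.5)

    def test_sample_interval_must_divide_measure_duration(self):
        with pytest.raises(ValueError, match="divide"):
            ChamberSpec(sample_interval_s=7.0)


class TestChaseTrackGenerator:
    def test_unit_calibration_moves_one_px_per_frame(self):
        track = simulate_chase_track(24.0, n_flips=5, fps=24.0, px_per_cm=1.0, seed=1)
        ev = track.events
        d = np.hypot(ev.x_end - ev.x_start, ev.y_end - ev.y_start)
        gaps = ev.frame_end - ev.frame_start
        np.testing.assert_allclose(d / gaps, 1.0, rtol=1e-12)

    def test_empty_track_is_valid(self):
        track = simulate_chase_track(24.0, n_flips=0, seed=1)
        assert track.n_events == 0

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            simulate_chase_track(24.0, 5, fps=0.0)
        with pytest.raises(ValueError):
            simulate_chase_track(24.0, 5, px_per_cm=-1.0)


class TestCohort:
    def test_record_count_matches_factorial_design(self):
        design = CohortDesign(n_per_cell=6)
        assert design.n_records == 2 * 3 * 3 * 6 == 108

    def test_smr_scales_with_q10_across_experimental_temperature(self):
        # closed form: 30 * 3.3**((21.5-14)/10)
        assert q10_scale(30.0, 3.3, 21.5, 14.0) == pytest.approx(
            30.0 * 3.3**0.75, rel=1e-12
        )
        design = CohortDesign(
            species=("J. edwardsii",),
            acclimation_temps_c=(14.0,),
            experimental_temps_c=(14.0, 21.5),
            n_per_cell=2,
            individual_cv=0.0,
        )
        base = make_truth(smr_true=30.0, rmr_true=37.5, mmr_true=110.0)
        cham = ChamberSpec(trial_duration_h=0.5)
        records = simulate_cohort(design, base, cham, seed=3)
        by_temp = {}
        for rec in records:
            by_temp.setdefault(rec.animal.experimental_temp_c, []).append(
                rec.truth.smr_true
            )
        ratio = np.mean(by_temp[21.5]) / np.mean(by_temp[14.0])
        assert ratio == pytest.approx(3.3**0.75, rel=1e-9)

    def test_null_plasticity_when_acclimation_factor_is_one(self):
        design = CohortDesign(
            species=("J. edwardsii",),
            acclimation_temps_c=(14.0, 21.5),
            experimental_temps_c=(14.0,),
            n_per_cell=1,
            acclimation_effect_smr=1.0,
            individual_cv=0.0,
        )
        records = simulate_cohort(
            design, make_truth(), ChamberSpec(trial_duration_h=0.5), seed=5
        )
        smrs = {rec.animal.acclimation_temp_c: rec.truth.smr_true for rec in records}
        assert smrs[14.0] == pytest.approx(smrs[21.5])

    def test_substream_seeds_stable_and_distinct(self):
        assert substream_seed(1, "x") == substream_seed(1, "x")
        assert substream_seed(1, "x") != substream_seed(1, "y")
        assert 0 <= substream_seed(123, "abc") < 2**31
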