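"""Simulation-layer tests: event handling, transit-chain dynamics, peaks."""

import math

import numpy as np
import pytest

import conapkpd as cp

CYTOKINES = ("TNFa", "IFNg", "IL6")


def chain_closed_form(s, n, tau):
    """n-th transit compartment under control: s^n / (n! tau^(n-1)) e^(-s/tau)."""
    return s**n / (math.factorial(n) * tau ** (n - 1)) * np.exp(-s / tau)


class TestTransitChain:
    @pytest.mark.parametrize("state, n", [("T1b", 1), ("T4b", 4), ("T7b", 7), ("T6d", 6)])
    def test_closed_form(self, ref_params, control_traj, state, n):
        s = control_traj.t - ref_params.cona_time
        mask = s >= 0
        expected = chain_closed_form(s[mask], n, ref_params.tau)
        observed = control_traj.state(state)[mask]
        # relative agreement at the peak, absolute in the tails
        peak = expected.max()
        np.testing.assert_allclose(observed, expected, rtol=1e-6, atol=1e-9 * peak)

    def test_t7b_spec_constant(self, ref_params, control_traj):
        """T7b(s) = s^7/(5040 tau^6) e^(-s/tau)."""
        s = 2.0
        i = np.argmin(np.abs(control_traj.t - (ref_params.cona_time + s)))
        s = control_traj.t[i] - ref_params.cona_time
        expected = s**7 / (5040.0 * ref_params.tau**6) * math.exp(-s / ref_params.tau)
        assert control_traj.state("T7b")[i] == pytest.approx(expected, rel=1e-6)


class TestEventHandling:
    def test_precursor_jump_at_challenge(self, ref_params, control_traj):
        i = int(np.flatnonzero(control_traj.t == ref_params.cona_time)[0])
        assert control_traj.state("T1")[i] == 1.0
        assert control_traj.state("T1")[i - 1] == 0.0

    def test_states_continuous_across_event_except_t1(self, ref_params):
        """All states but T1 approach their post-event values continuously."""
        eps = 1e-6
        y = cp.states_at(ref_params, 50.0,
                         [ref_params.cona_time - eps, ref_params.cona_time])
        pre, post = y[:, 0], y[:, 1]
        i_t1 = cp.STATE_INDEX["T1"]
        np.testing.assert_allclose(np.delete(post, i_t1), np.delete(pre, i_t1),
                                   rtol=1e-5, atol=1e-8)
        assert post[i_t1] == 1.0 and pre[i_t1] == 0.0

    def test_t_end_before_challenge_rejected(self, ref_params):
        with pytest.raises(cp.DomainError):
            cp.simulate_group(ref_params, dose=0.0, t_end=0.2)

    def test_no_cona_keeps_biomarkers_at_baseline(self, ref_params):
        """Steady-state conservation: no challenge, long horizon, drug present."""
        traj = cp.simulate_group(ref_params, dose=100.0, t_end=50.0,
                                 grid_step=0.5, cona=False)
        for analyte, r0 in (("TNFa", ref_params.tnf.r0), ("IFNg", ref_params.ifn.r0),
                            ("IL6", ref_params.il6.r0), ("IL10", ref_params.il10.r0),
                            ("ALT", ref_params.disease.r0_alt),
                            ("AST", ref_params.disease.r0_ast)):
            np.testing.assert_allclose(traj.series(analyte), r0, rtol=1e-7)


class TestDynamicsProperties:
    def test_cytokines_never_below_baseline(self, ref_params, control_traj):
        """Stimulation is nonnegative, so TNF-a/IFN-g/IL-6 stay >= R0."""
        tol = 1e-7
        for analyte, r0 in (("TNFa", ref_params.tnf.r0), ("IFNg", ref_params.ifn.r0),
                            ("IL6", ref_params.il6.r0)):
            assert control_traj.series(analyte).min() >= r0 * (1 - tol)

    def test_control_response_scales_linearly_with_baseline(self, ref_params):
        """C_TNFa(t)/R0 is identical for R0 = 1 and R0 = 100 (control group)."""
        series = {}
        for r0 in (1.0, 100.0):
            params = ref_params.with_values({"R0_TNFa": r0})
            traj = cp.simulate_group(params, dose=0.0, t_end=10.0, grid_step=0.05)
            series[r0] = traj.series("TNFa") / r0
        np.testing.assert_allclose(series[1.0], series[100.0], rtol=1e-8)

    def test_peak_times_invariant_to_baseline_rescaling(self, ref_params, control_traj):
        rescaled = ref_params.with_values({
            "R0_TNFa": ref_params.tnf.r0 * 10, "R0_IFNg": ref_params.ifn.r0 * 10,
            "R0_IL6": ref_params.il6.r0 * 10, "R0_IL10": ref_params.il10.r0 * 10,
        })
        traj10 = cp.simulate_group(rescaled, dose=0.0, t_end=30.0, grid_step=0.01)
        for analyte in CYTOKINES:
            t_ref = cp.predicted_tmax(control_traj, analyte).time
            t_10 = cp.predicted_tmax(traj10, analyte).time
            assert t_10 == pytest.approx(t_ref, abs=1e-3)

    def test_higher_dose_never_raises_cytokine_peaks(self, ref_params, control_traj):
        """More drug -> more pathway inhibition -> lower or equal peaks."""
        peaks = {0.0: {a: cp.predicted_tmax(control_traj, a).value for a in CYTOKINES}}
        for dose in (50.0, 100.0):
            traj = cp.simulate_group(ref_params, dose=dose, t_end=30.0, grid_step=0.02)
            peaks[dose] = {a: cp.predicted_tmax(traj, a).value for a in CYTOKINES}
        for analyte in CYTOKINES:
            assert peaks[0.0][analyte] >= peaks[50.0][analyte] >= peaks[100.0][analyte]

    def test_peak_times_stable_under_tighter_tolerances(self, ref_params, control_traj):
        tight = cp.simulate_group(ref_params, dose=0.0, t_end=30.0, grid_step=0.01,
                                  rtol=1e-9, atol=1e-11)
        for analyte in CYTOKINES:
            assert cp.predicted_tmax(tight, analyte).time == pytest.approx(
                cp.predicted_tmax(control_traj, analyte).time, abs=0.01)

    def test_late_time_return_toward_baseline(self, ref_params):
        """Precursors decay, so cytokines relax to R0; IL-10 to its new set point."""
        traj = cp.simulate_group(ref_params, dose=0.0, t_end=200.0, grid_step=0.5)
        assert traj.series("TNFa")[-1] == pytest.approx(ref_params.tnf.r0, rel=0.01)
        assert traj.series("IFNg")[-1] == pytest.approx(ref_params.ifn.r0, rel=0.01)
        assert traj.series("IL6")[-1] == pytest.approx(ref_params.il6.r0, rel=0.01)
        il10 = ref_params.il10
        new_set_point = il10.r0 + il10.kin_dis * (1 - il10.i_ifn * ref_params.ifn.r0) / il10.kout
        assert traj.series("IL10")[-1] == pytest.approx(new_set_point, rel=0.01)


class TestPeakLocation:
    def test_monotone_series_flagged(self, ref_params):
        """A series still rising at t_end has no bracketed interior peak."""
        traj = cp.simulate_group(ref_params, dose=0.0, t_end=2.0, grid_step=0.01)
        peak = cp.predicted_tmax(traj, "ALT")  # ALT peaks near 7 h, far beyond t_end
        assert not peak.interior

    def test_refinement_beats_grid_resolution(self, ref_params):
        coarse = cp.simulate_group(ref_params, dose=0.0, t_end=10.0, grid_step=0.1)
        fine = cp.simulate_group(ref_params, dose=0.0, t_end=10.0, grid_step=0.005)
        t_coarse = cp.predicted_tmax(coarse, "TNFa").time
        t_fine = cp.predicted_tmax(fine, "TNFa").time
        assert t_coarse == pytest.approx(t_fine, abs=0.02)


class TestHalfLife:
    def test_ln2_over_k(self):
        assert cp.half_life_from_rate(math.log(2.0)) == 1.0
        assert cp.half_life_from_rate(0.0997) == pytest.approx(6.95, abs=0.005)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(cp.DomainError):
            cp.half_life_from_rate(0.0)


def test_trajectory_export_shape(control_traj):
    frame = control_traj.to_frame()
    assert list(frame.columns) == ["time_h"] + list(cp.OBSERVABLES)
    assert len(frame) == len(control_traj.t)
    assert (frame["GRMS55"] == 0).all()  # control group carries no drug
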