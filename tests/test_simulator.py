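"""Paced-simulation behavior: protocol handling, determinism, wave shape."""

import numpy as np
import pytest

from atriawave.biomarkers import cat_metrics, extract_biomarkers
from atriawave.dynamics import total_cell_calcium
from atriawave.errors import ParameterError
from atriawave.model import CellState, baseline_parameters, default_state
from atriawave.simulator import (
    PacingProtocol,
    SolverSettings,
    pace_to_steady,
    run_paced,
)

SOLVER = SolverSettings(dt=0.05)


class TestProtocolValidation:
    def test_stimulus_must_fit_cycle(self):
        with pytest.raises(ParameterError):
            PacingProtocol(cycle_length=1.0, stimulus_duration=2.0)

    def test_recorded_beats_bounded(self):
        with pytest.raises(ParameterError):
            PacingProtocol(n_beats=3, record_last_n_beats=5)


class TestRunPaced:
    def test_no_stimulus_stays_quiescent(self):
        prot = PacingProtocol(n_beats=3, record_last_n_beats=3,
                              stimulus_amplitude=0.0)
        res = run_paced(baseline_parameters(), prot, solver=SOLVER)
        assert np.all(np.abs(res.V - res.V[0]) < 2.0)
        bm = extract_biomarkers(res)
        assert max(bm.catm_amplitude) < 0.02  # uM: no transients

    def test_correct_number_of_upstrokes(self, short_result):
        """Five suprathreshold stimuli produce exactly five membrane CaT
        upstrokes."""
        bm = extract_biomarkers(short_result)
        assert len(bm.catm_amplitude) == 5
        assert all(a > 0.05 for a in bm.catm_amplitude)
        # count discrete upstrokes on the membrane trace directly
        tr = short_result.Ca_cyto_matrix[0] * 1e3
        thr = tr.min() + 0.5 * (tr.max() - tr.min())
        crossings = np.sum((tr[:-1] < thr) & (tr[1:] >= thr))
        assert crossings == 5

    def test_record_window_shape(self, short_result):
        prot_cl = short_result.cycle_length
        assert short_result.t[0] == 0.0
        assert short_result.t[-1] < 5 * prot_cl
        assert short_result.Ca_cyto_matrix.shape[0] == 18
        assert short_result.stimulus_times.shape == (5,)

    def test_determinism_bitwise(self):
        prot = PacingProtocol(n_beats=2, record_last_n_beats=2)
        a = run_paced(baseline_parameters(), prot, solver=SOLVER)
        b = run_paced(baseline_parameters(), prot, solver=SOLVER)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.Ca_cyto_matrix, b.Ca_cyto_matrix)

    def test_centripetal_upstroke_ordering(self, control_result):
        """CaT upstroke times increase from each membrane toward the center."""
        res = control_result
        sel = res.t >= res.t[-1] - res.cycle_length + 1
        tt = res.t[sel]
        t50 = []
        for d in range(res.n_domains):
            tr = res.Ca_cyto_matrix[d, sel]
            thr = tr[0] + 0.5 * (tr.max() - tr[0])
            t50.append(tt[np.argmax(tr >= thr)])
        t50 = np.asarray(t50)
        assert np.all(np.diff(t50[:9]) >= 0)
        assert np.all(np.diff(t50[9:]) <= 0)

    def test_no_negative_concentrations(self, control_result):
        assert np.all(control_result.Ca_cyto_matrix >= 0)
        assert np.all(control_result.Ca_SR_mean >= 0)

    def test_refinement_stability(self, control_result):
        """Halving the step changes APD90 by < 1 ms and CaT amplitude < 2%."""
        prot = PacingProtocol(n_beats=40, record_last_n_beats=10)
        fine = run_paced(
            baseline_parameters(), prot, solver=SolverSettings(dt=SOLVER.dt / 2),
        )
        bm0 = extract_biomarkers(control_result)
        bm1 = extract_biomarkers(fine)
        assert abs(bm0.mean_apd90 - bm1.mean_apd90) < 1.0
        a0 = np.mean(bm0.catm_amplitude)
        a1 = np.mean(bm1.catm_amplitude)
        assert abs(a0 - a1) / a1 < 0.02


class TestClosedCellConservation:
    def test_total_calcium_conserved_over_one_second(self):
        """With sarcolemmal calcium fluxes disabled, total cell calcium is
        conserved over 1 s of (unstimulated) integration."""
        import atriawave.dynamics as dyn
        from atriawave.dynamics import pack_params, rhs_kernel, gate_inf_tau

        params = baseline_parameters()
        s = default_state()
        s.Ca_cyto = np.linspace(5e-5, 4e-4, 18)  # non-uniform start
        y = s.to_vector().copy()
        p = pack_params(params, closed_cell=True)
        g = params.geometry.coupling_array()
        before = total_cell_calcium(CellState.from_vector(y), params)
        dt = 0.02
        dy1, dy2, ystar = (np.empty_like(y) for _ in range(3))
        for _ in range(int(1000 / dt)):
            # same operator splitting as the production integrator:
            # Rush-Larsen for the stiff gates, Heun for everything else
            rhs_kernel(y, p, g, 0.0, dy1)
            inf, tau = gate_inf_tau(y[0])
            ystar[:] = y + dt * dy1
            ystar[3:14] = inf + (y[3:14] - inf) * np.exp(-dt / tau)
            rhs_kernel(ystar, p, g, 0.0, dy2)
            gates = ystar[3:14].copy()
            y += 0.5 * dt * (dy1 + dy2)
            y[3:14] = gates
        after = total_cell_calcium(CellState.from_vector(y), params)
        assert after == pytest.approx(before, rel=1e-6)


class TestPaceToSteady:
    def test_infinite_tolerance_returns_after_two_beats(self):
        state, report = pace_to_steady(
            baseline_parameters(), PacingProtocol(n_beats=2, record_last_n_beats=1),
            tolerance=np.inf, beat_cap=10, solver=SOLVER,
        )
        assert report["stopping_rule"] == "converged"
        assert report["beats"] <= 2

    def test_convergence_report(self):
        state, report = pace_to_steady(
            baseline_parameters(), PacingProtocol(n_beats=1, record_last_n_beats=1),
            tolerance=5e-3, beat_cap=60, solver=SOLVER,
        )
        assert report["stopping_rule"] in ("converged", "beat_cap")
        assert isinstance(state, CellState)
        state.validate()

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            pace_to_steady(baseline_parameters(), tolerance=0.0)
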