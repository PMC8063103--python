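"""Paced integration of the cell model and in-silico line-scan recording.

Two integration modes are provided:

* ``fixed`` (default): operator-split fixed-step integration with
  Rush-Larsen exponential updates for the Hodgkin-Huxley gates and forward
  Euler for concentrations and CRU states, compiled with numba.  This is
  the production path for population runs.
* ``adaptive``: scipy's stiff LSODA integrator on the same right-hand
  side, with configurable tolerances; used for refinement checks and
  one-off runs.

Both modes are deterministic: identical parameters, protocol and solver
settings give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .dynamics import gate_inf_tau, pack_params, rhs_kernel
from .errors import ParameterError, SimulationFailedError
from .model import CellParameters, CellState, StateLayout, default_state
from .results import SimulationResult


@dataclass(frozen=True)
class PacingProtocol:
    """Regular field-stimulation protocol.

    ``stimulus_amplitude`` is the depolarizing current in pA/pF applied for
    ``stimulus_duration`` ms at the start of each cycle.  The last
    ``record_last_n_beats`` beats are recorded on a grid of ``output_dt``.
    """

    cycle_length: float = 1000.0
    n_beats: int = 60
    stimulus_amplitude: float = 40.0
    stimulus_duration: float = 2.0
    record_last_n_beats: int = 10
    output_dt: float = 0.5

    def __post_init__(self):
        if not self.cycle_length > self.stimulus_duration > 0:
            raise ParameterError("need cycle_length > stimulus_duration > 0")
        if not self.n_beats >= self.record_last_n_beats >= 1:
            raise ParameterError("need n_beats >= record_last_n_beats >= 1")
        if self.output_dt <= 0:
            raise ParameterError("output_dt must be > 0")


@dataclass(frozen=True)
class SolverSettings:
    mode: str = "fixed"  # "fixed" or "adaptive"
    dt: float = 0.05  # ms, fixed-step size
    rtol: float = 1e-6
    atol: float = 1e-9

    def refined(self) -> "SolverSettings":
        """Settings with halved step / tolerances, for refinement checks."""
        return replace(self, dt=self.dt / 2, rtol=self.rtol / 2, atol=self.atol / 2)


DEFAULT_SOLVER = SolverSettings()


@njit(cache=True)
def _integrate_beats(
    y, p, g_couple, cl, n_beats, amp, dur, dt, out_every,
    rec_from_beat, V_out, Na_out, SR_out, Ca_out, t_out,
):
    """Advance ``n_beats`` cycles in place; record from beat ``rec_from_beat``.

    Returns (status, t_failure): status 0 = ok, 1 = non-finite state.
    Operator split: the 11 Hodgkin-Huxley gates (state indices 3..13) use
    Rush-Larsen exponential updates; all other states take a Heun
    (second-order predictor-corrector) step.
    """
    nper = int(round(cl / dt))
    n = Ca_out.shape[0]
    nstate = y.shape[0]
    dy1 = np.empty_like(y)
    dy2 = np.empty_like(y)
    ystar = np.empty_like(y)
    rec = 0
    for beat in range(n_beats):
        for k in range(nper):
            tb = k * dt
            if beat >= rec_from_beat and k % out_every == 0 and rec < t_out.shape[0]:
                t_out[rec] = (beat - rec_from_beat) * cl + tb
                V_out[rec] = y[0]
                Na_out[rec] = y[1]
                srm = 0.0
                for d in range(n):
                    Ca_out[d, rec] = y[14 + d]
                    srm += y[14 + 2 * n + d]
                SR_out[rec] = srm / n
                rec += 1
            istim = amp if tb < dur else 0.0
            # predictor
            rhs_kernel(y, p, g_couple, istim, dy1)
            inf, tau = gate_inf_tau(y[0])
            for q in range(nstate):
                ystar[q] = y[q] + dt * dy1[q]
            for q in range(11):
                ystar[3 + q] = inf[q] + (y[3 + q] - inf[q]) * np.exp(-dt / tau[q])
            # corrector (stimulus held constant over the step)
            rhs_kernel(ystar, p, g_couple, istim, dy2)
            vmid = 0.5 * (y[0] + ystar[0])
            for q in range(nstate):
                if q < 3 or q >= 14:
                    y[q] = y[q] + 0.5 * dt * (dy1[q] + dy2[q])
            inf, tau = gate_inf_tau(vmid)
            for q in range(11):
                y[3 + q] = inf[q] + (y[3 + q] - inf[q]) * np.exp(-dt / tau[q])
        ok = True
        for q in range(nstate):
            if not np.isfinite(y[q]):
                ok = False
        if not ok:
            return 1, (beat + 1) * cl
    return 0, 0.0


def _empty_result(params, protocol, t_fail, provenance):
    n = params.geometry.n_domains
    t = np.array([0.0])
    return SimulationResult(
        t=t, V=np.array([np.nan]), Ca_cyto_matrix=np.full((n, 1), np.nan),
        Na_i=np.array([np.nan]), Ca_SR_mean=np.array([np.nan]),
        cycle_length=protocol.cycle_length, stimulus_times=np.array([0.0]),
        provenance=provenance or {}, failed=True, failure_time=t_fail,
    )


def run_paced(
    params: CellParameters,
    protocol: PacingProtocol | None = None,
    initial_state: CellState | str = "default",
    solver: SolverSettings = DEFAULT_SOLVER,
    provenance: dict | None = None,
    raise_on_failure: bool = False,
) -> SimulationResult:
    """Pace the cell and record the last ``record_last_n_beats`` beats.

    By default a diverged integration is returned as a result flagged
    ``failed`` (carrying the failure time) so population pipelines can map
    it to the "other" wave category; with ``raise_on_failure`` a
    :class:`SimulationFailedError` is raised instead.
    """
    protocol = protocol or PacingProtocol()
    params.validate()
    state = default_state(params.geometry) if initial_state == "default" else initial_state
    y = state.to_vector().copy()
    p = pack_params(params)
    g = params.geometry.coupling_array()

    n = params.geometry.n_domains
    cl = protocol.cycle_length
    n_rec = protocol.record_last_n_beats
    rec_from = protocol.n_beats - n_rec

    if solver.mode == "fixed":
        out_every = max(1, int(round(protocol.output_dt / solver.dt)))
        nper = int(round(cl / solver.dt))
        nsamp = n_rec * (1 + (nper - 1) // out_every)
        t_out = np.empty(nsamp)
        V_out = np.empty(nsamp)
        Na_out = np.empty(nsamp)
        SR_out = np.empty(nsamp)
        Ca_out = np.empty((n, nsamp))
        status, t_fail = _integrate_beats(
            y, p, g, cl, protocol.n_beats, protocol.stimulus_amplitude,
            protocol.stimulus_duration, solver.dt, out_every, rec_from,
            V_out, Na_out, SR_out, Ca_out, t_out,
        )
        if status != 0:
            if raise_on_failure:
                raise SimulationFailedError("integration diverged", t_fail)
            return _empty_result(params, protocol, t_fail, provenance)
    else:
        t_out, V_out, Na_out, SR_out, Ca_out, failure = _run_adaptive(
            y, p, g, protocol, solver, n
        )
        if failure is not None:
            if raise_on_failure:
                raise SimulationFailedError("adaptive solver failed", failure)
            return _empty_result(params, protocol, failure, provenance)

    stim_times = np.arange(n_rec) * cl
    return SimulationResult(
        t=t_out, V=V_out, Ca_cyto_matrix=Ca_out, Na_i=Na_out,
        Ca_SR_mean=SR_out, cycle_length=cl, stimulus_times=stim_times,
        provenance=provenance or {}, baseline_rmp=state.V,
    )


def _run_adaptive(y, p, g, protocol, solver, n):
    """LSODA integration beat by beat (stimulus-on then stimulus-off spans)."""
    from scipy.integrate import solve_ivp

    cl = protocol.cycle_length
    rec_from = protocol.n_beats - protocol.record_last_n_beats
    dy = np.empty_like(y)

    def make_rhs(istim):
        def f(t, yy):
            return rhs_kernel(yy, p, g, istim, dy).copy()
        return f

    t_chunks, traces = [], []
    for beat in range(protocol.n_beats):
        record = beat >= rec_from
        t_off = protocol.stimulus_duration
        for (t0, t1, istim) in ((0.0, t_off, protocol.stimulus_amplitude),
                                (t_off, cl, 0.0)):
            t_eval = None
            if record:
                t_eval = np.arange(
                    np.ceil(t0 / protocol.output_dt) * protocol.output_dt,
                    t1, protocol.output_dt,
                )
            sol = solve_ivp(
                make_rhs(istim), (t0, t1), y, method="LSODA",
                rtol=solver.rtol, atol=solver.atol, t_eval=t_eval,
                max_step=5.0,
            )
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                return None, None, None, None, None, beat * cl + sol.t[-1]
            y = sol.y[:, -1].copy()
            if record and sol.t.size:
                t_chunks.append((beat - rec_from) * cl + sol.t)
                traces.append(sol.y)
    t_out = np.concatenate(t_chunks)
    Y = np.concatenate(traces, axis=1)
    Ca_out = Y[14:14 + n]
    SR_out = Y[14 + 2 * n:14 + 3 * n].mean(axis=0)
    return t_out, Y[0], Y[1], SR_out, Ca_out, None


def pace_to_steady(
    params: CellParameters,
    protocol: PacingProtocol | None = None,
    tolerance: float = 1e-3,
    beat_cap: int = 200,
    solver: SolverSettings = DEFAULT_SOLVER,
) -> tuple[CellState, dict]:
    """Pace until the beat-to-beat change of the diastolic state converges.

    Convergence: the relative beat-to-beat change of diastolic (end-cycle)
    cytosolic calcium, SR calcium and intracellular sodium all fall below
    ``tolerance``.  Returns the state plus a report stating which stopping
    rule fired ("converged" or "beat_cap") and the beat count.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    protocol = protocol or PacingProtocol()
    params.validate()
    y = default_state(params.geometry).to_vector()
    p = pack_params(params)
    g = params.geometry.coupling_array()
    n = params.geometry.n_domains
    lay = StateLayout(n)
    dt = solver.dt
    dummy = (np.empty(1), np.empty(1), np.empty(1), np.empty((n, 1)), np.empty(1))

    prev = None
    rule, nb = "beat_cap", beat_cap
    for beat in range(beat_cap):
        status, t_fail = _integrate_beats(
            y, p, g, protocol.cycle_length, 1, protocol.stimulus_amplitude,
            protocol.stimulus_duration, dt, 10 ** 9, 10,
            dummy[0], dummy[1], dummy[2], dummy[3], dummy[4],
        )
        if status != 0:
            raise SimulationFailedError(
                "integration diverged during pre-pacing",
                beat * protocol.cycle_length + t_fail,
            )
        cur = np.array([
            float(np.mean(y[lay.Ca_cyto])),
            float(np.mean(y[lay.Ca_SR])),
            float(y[lay.Na_i]),
        ])
        if prev is not None:
            rel = np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-12)
            if np.all(rel < tolerance):
                rule, nb = "converged", beat + 1
                break
        prev = cur
    report = {"stopping_rule": rule, "beats": nb, "tolerance": tolerance}
    return CellState.from_vector(y, n), report
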