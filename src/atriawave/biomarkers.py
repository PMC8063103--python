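"""Per-beat action-potential and calcium-transient biomarkers.

Conventions
-----------
* APD90 runs from the upstroke (maximum dV/dt) to the recovery of 90% of
  the AP amplitude (peak minus diastolic level), with linear interpolation
  between samples.
* RMP is, per beat, the minimum (default) or mean of V over the final
  50 ms before each stimulus, averaged over beats.
* CaT amplitude is peak minus the pre-stimulus diastolic level inside the
  beat window; CD50 is the total time the trace spends above
  diastolic + 50% of amplitude, interpolated at the crossings.
* The membrane transient (CaTm) is the mean of the two membrane domains'
  cytosolic traces; the central transient (CaTc) the mean of the two
  centermost domains.  The CaT ratio is CaTc amplitude / CaTm amplitude.

Voltage in mV, time in ms.  Calcium traces are accepted in mM (the
simulator's internal unit) or uM; amplitudes are *reported* in uM via the
``in_mM`` flag of the extraction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, NoActionPotentialError, ShapeError


def apd(V: np.ndarray, t: np.ndarray, level_pct: float = 90.0) -> float:
    """Action-potential duration of a single-beat voltage trace.

    Duration from the upstroke (sample of maximum dV/dt) to the time V
    first recovers ``level_pct`` percent of the amplitude, linearly
    interpolated.  Raises :class:`NoActionPotentialError` if the trace
    shows no depolarization.
    """
    V = np.asarray(V, float)
    t = np.asarray(t, float)
    if V.ndim != 1 or V.shape != t.shape or V.size < 3:
        raise ShapeError("V and t must be 1-D arrays of equal length >= 3")
    dV = np.diff(V) / np.diff(t)
    iup = int(np.argmax(dV))
    rest = float(np.min(V[: iup + 1])) if iup > 0 else float(V[0])
    peak_idx = iup + int(np.argmax(V[iup:]))
    peak = float(V[peak_idx])
    amp = peak - rest
    if amp < 10.0 or np.max(dV) < 1.0:  # mV, mV/ms: no stimulated beat
        raise NoActionPotentialError("no AP upstroke found in trace")
    # upstroke time: the sample *after* the steepest rise, so a jump that
    # happens between two samples is dated at its completion
    t_up = t[min(iup + 1, V.size - 1)]
    v_level = peak - amp * level_pct / 100.0
    for k in range(peak_idx, V.size - 1):
        if V[k] >= v_level > V[k + 1]:
            frac = (V[k] - v_level) / (V[k] - V[k + 1])
            return t[k] + frac * (t[k + 1] - t[k]) - t_up
    # repolarization did not reach the level inside the trace
    raise NoActionPotentialError(
        f"V never recovered {level_pct}% of the AP amplitude"
    )


def rmp(
    V: np.ndarray,
    t: np.ndarray,
    stimulus_times: np.ndarray,
    window_ms: float = 50.0,
    mode: str = "min",
) -> float:
    """Resting membrane potential from the diastolic intervals of a paced trace.

    For each stimulus time, takes the minimum (or mean, ``mode="mean"``) of
    V over the final ``window_ms`` before the stimulus; returns the average
    over all stimuli preceded by at least one sample.
    """
    V = np.asarray(V, float)
    t = np.asarray(t, float)
    if V.size == 0 or V.shape != t.shape:
        raise ShapeError("empty or mismatched voltage trace")
    vals = []
    for ts in np.atleast_1d(stimulus_times):
        sel = (t >= ts - window_ms) & (t < ts)
        if not np.any(sel):
            continue
        seg = V[sel]
        vals.append(np.min(seg) if mode == "min" else np.mean(seg))
    if not vals:
        # no diastolic window inside the trace; fall back to the global floor
        vals = [np.min(V)]
    return float(np.mean(vals))


@dataclass(frozen=True)
class CaTBeatMetrics:
    amplitude: float
    cd50: float
    diastolic: float


def cat_metrics(
    ca: np.ndarray, t: np.ndarray, beat_windows: list[tuple[float, float]]
) -> list[CaTBeatMetrics]:
    """Amplitude, CD50 and diastolic level of a calcium trace, per beat window.

    The diastolic level is the trace value at the window start (the
    pre-stimulus level); amplitude is the in-window peak above it, floored
    at 0; CD50 is the time spent above diastolic + 50% amplitude.  A flat
    trace yields amplitude 0 and CD50 0, not an error.
    """
    ca = np.asarray(ca, float)
    t = np.asarray(t, float)
    if ca.shape != t.shape or ca.ndim != 1:
        raise ShapeError("ca and t must be 1-D arrays of equal length")
    if not beat_windows:
        raise InsufficientDataError("need at least one beat window")
    out = []
    for t0, t1 in beat_windows:
        sel = (t >= t0) & (t <= t1)
        if np.count_nonzero(sel) < 2:
            raise InsufficientDataError(f"beat window ({t0}, {t1}) has < 2 samples")
        seg, ts = ca[sel], t[sel]
        dia = float(np.interp(t0, t, ca))
        amp = max(float(np.max(seg)) - dia, 0.0)
        if amp == 0.0:
            out.append(CaTBeatMetrics(0.0, 0.0, dia))
            continue
        thr = dia + 0.5 * amp
        above = seg >= thr
        dur = 0.0
        # sum interpolated segments above threshold
        for k in range(seg.size - 1):
            a, b = seg[k], seg[k + 1]
            dt = ts[k + 1] - ts[k]
            if above[k] and above[k + 1]:
                dur += dt
            elif above[k] != above[k + 1] and a != b:
                frac = (thr - a) / (b - a)
                dur += dt * (1.0 - frac) if above[k] else dt * frac
        out.append(CaTBeatMetrics(amp, float(dur), dia))
    return out


def cat_ratio(catc_amp: float, catm_amp: float, return_flag: bool = False):
    """Central-to-membrane CaT amplitude ratio.

    A zero membrane amplitude is degenerate: the ratio is defined as 0 and,
    with ``return_flag=True``, flagged.
    """
    if catc_amp < 0 or catm_amp < 0:
        raise ValueError("CaT amplitudes must be non-negative")
    degenerate = catm_amp == 0
    r = 0.0 if degenerate else catc_amp / catm_amp
    return (r, degenerate) if return_flag else r


@dataclass(frozen=True)
class PopulationComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float


def compare_populations(
    values_a, values_b, alpha: float = 0.05
) -> PopulationComparison:
    """Welch two-sample t-test between two groups of biomarker values."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return PopulationComparison(
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )


# -- extraction from simulation results ------------------------------------


@dataclass
class BeatBiomarkers:
    """Per-beat biomarker table of one simulated (or synthetic) cell."""

    apd90: list[float]
    rmp: float
    catm_amplitude: list[float]  # uM, per beat
    catc_amplitude: list[float]
    cat_ratio: list[float]
    cd50m: list[float]
    cd50c: list[float]
    diastolic_ca_m: list[float]  # uM
    diastolic_na: float  # mM

    @property
    def mean_apd90(self) -> float:
        vals = np.asarray(self.apd90, float)
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if vals.size else float("nan")

    @property
    def mean_cat_ratio(self) -> float:
        return float(np.mean(self.cat_ratio))


def beat_windows_from_stimuli(stim_times, cycle_length: float):
    return [(float(ts), float(ts + cycle_length)) for ts in stim_times]


def extract_biomarkers(result, in_mM: bool = True) -> BeatBiomarkers:
    """Compute the full per-beat biomarker set from a SimulationResult.

    ``result`` needs fields t, V, Ca_cyto_matrix, Na_i, stimulus_times and
    cycle_length (duck-typed; synthetic line scans qualify).  With
    ``in_mM=True`` calcium traces are converted to uM for reporting.
    """
    t = np.asarray(result.t, float)
    V = np.asarray(result.V, float)
    ca = np.asarray(result.Ca_cyto_matrix, float)
    scale = 1e3 if in_mM else 1.0
    n_dom = ca.shape[0]
    mem_lo, mem_hi = 0, n_dom - 1
    c_lo, c_hi = (n_dom - 1) // 2, n_dom // 2
    catm_trace = scale * 0.5 * (ca[mem_lo] + ca[mem_hi])
    catc_trace = scale * 0.5 * (ca[c_lo] + ca[c_hi])

    stim = np.asarray(result.stimulus_times, float)
    cl = float(result.cycle_length)
    windows = beat_windows_from_stimuli(stim, cl)

    m_beats = cat_metrics(catm_trace, t, windows)
    c_beats = cat_metrics(catc_trace, t, windows)

    apd_list = []
    for t0, t1 in windows:
        sel = (t >= t0 - 1.0) & (t <= t1)
        try:
            apd_list.append(apd(V[sel], t[sel]))
        except NoActionPotentialError:
            apd_list.append(float("nan"))

    na = np.asarray(result.Na_i, float)
    dia_sel = np.zeros(t.shape, bool)
    for ts in stim:
        dia_sel |= (t >= ts - 50.0) & (t < ts)
    dia_na = float(np.mean(na[dia_sel])) if np.any(dia_sel) else float(np.mean(na))

    return BeatBiomarkers(
        apd90=apd_list,
        rmp=rmp(V, t, stim),
        catm_amplitude=[b.amplitude for b in m_beats],
        catc_amplitude=[b.amplitude for b in c_beats],
        cat_ratio=[
            cat_ratio(c.amplitude, m.amplitude)
            for c, m in zip(c_beats, m_beats)
        ],
        cd50m=[b.cd50 for b in m_beats],
        cd50c=[b.cd50 for b in c_beats],
        diastolic_ca_m=[b.diastolic for b in m_beats],
        diastolic_na=dia_na,
    )
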