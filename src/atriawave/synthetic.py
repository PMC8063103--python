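"""Synthetic line-scan and action-potential generators.

These produce analytically controlled traces with prescribed phenotype
structure — centripetal delay, center-ward amplitude attenuation,
beat-to-beat alternation, optional repolarization failure — so biomarker
extraction and wave classification can be validated end-to-end without
integrating the ODE model.  The output uses the same
:class:`~atriawave.results.SimulationResult` container (calcium in mM), so
synthetic and simulated data are interchangeable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .results import SimulationResult

#: CaT waveform time constants (ms): difference of exponentials with a fast
#: rise and slower decay, normalized to unit peak.
RISE_TAU = 5.0
DECAY_TAU = 60.0


def _beat_waveform(tau: np.ndarray, rise=RISE_TAU, decay=DECAY_TAU) -> np.ndarray:
    tt = np.maximum(tau, 0.0)  # clamp to avoid exp overflow off-support
    w = np.exp(-tt / decay) - np.exp(-tt / rise)
    t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return w / peak


@dataclass
class TraceSpec:
    """Specification of a synthetic line scan.

    Amplitudes in uM; the generated matrix is stored in mM.  ``attenuation``
    is the per-domain amplitude multiplier (1 at the membrane domains);
    ``centripetal_delay`` the per-domain CaT onset delay in ms;
    ``alternans_ratio`` scales every even-numbered beat (1.0 = no
    alternation).
    """

    n_domains: int = 18
    cycle_length: float = 1000.0
    n_beats: int = 10
    membrane_amplitude: float = 0.33  # uM
    diastolic: float = 0.1  # uM
    centripetal_delay: np.ndarray | None = None  # ms per domain
    attenuation: np.ndarray | None = None  # per-domain in [0, 1]
    alternans_ratio: float = 1.0
    noise_sd: float = 0.0  # uM
    seed: int = 0
    output_dt: float = 1.0  # ms
    # AP options for the accompanying voltage trace
    ap_rest: float = -78.0
    ap_peak: float = 20.0
    ap_apd: float = 96.0
    repolarization_failure: bool = False

    def __post_init__(self):
        if self.n_domains < 3:
            raise ParameterError("n_domains must be >= 3")
        if not (0 < self.alternans_ratio <= 1):
            raise ParameterError("alternans_ratio must be in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.membrane_amplitude <= 0 or self.cycle_length <= 0:
            raise ParameterError("amplitude and cycle length must be positive")
        if self.centripetal_delay is None:
            self.centripetal_delay = default_centripetal_delay(self.n_domains)
        if self.attenuation is None:
            self.attenuation = np.ones(self.n_domains)
        self.centripetal_delay = np.asarray(self.centripetal_delay, float)
        self.attenuation = np.asarray(self.attenuation, float)
        for name in ("centripetal_delay", "attenuation"):
            if getattr(self, name).shape != (self.n_domains,):
                raise ParameterError(f"{name} must have length n_domains")
        mem = (0, self.n_domains - 1)
        if not np.allclose(self.attenuation[list(mem)], 1.0):
            raise ParameterError("attenuation must be 1 at the membrane domains")
        if np.any(self.attenuation < 0) or np.any(self.attenuation > 1):
            raise ParameterError("attenuation must lie in [0, 1]")


def default_centripetal_delay(
    n_domains: int, per_interface_ms: float = 3.0
) -> np.ndarray:
    """Delay growing linearly with distance from the nearest membrane domain."""
    idx = np.arange(n_domains)
    dist = np.minimum(idx, n_domains - 1 - idx)
    return per_interface_ms * dist.astype(float)


def silencing_attenuation(n_domains: int = 18, central: float = 0.05,
                          edge_width: int = 2) -> np.ndarray:
    """Attenuation profile of a silenced cell: release confined to the edges."""
    att = np.full(n_domains, central)
    for k in range(edge_width):
        v = 1.0 - k * (1.0 - central) / edge_width
        att[k] = v
        att[n_domains - 1 - k] = v
    att[0] = att[-1] = 1.0
    return att


def gen_ap_train(
    rest: float,
    peak: float,
    apd: float,
    cycle_length: float,
    n_beats: int,
    shape: str = "triangular",
    output_dt: float = 1.0,
    repolarization_failure: bool = False,
    lead_ms: float = 10.0,
):
    """Analytic AP train with a closed-form APD90.

    Each cycle starts with ``lead_ms`` of diastole, then an instantaneous
    upstroke.  Shapes: ``rectangular`` (V holds at peak for ``apd`` then
    drops; true APD90 = apd) and ``triangular`` (linear repolarization over
    ``apd / 0.9`` ms, so 90% recovery occurs exactly ``apd`` after the
    upstroke).  With ``repolarization_failure`` the trace only ever
    repolarizes to 40% of the amplitude, leaving diastole far above rest.

    Returns ``(t, V, true_apd90)``.
    """
    if peak <= rest:
        raise ParameterError("peak must exceed rest")
    if not 0 < apd < cycle_length - lead_ms:
        raise ParameterError("need 0 < apd < cycle_length - lead_ms")
    t = np.arange(0.0, n_beats * cycle_length, output_dt)
    phase = t % cycle_length - lead_ms
    amp = peak - rest
    if shape == "rectangular":
        V = np.where((phase >= 0) & (phase < apd), peak, rest)
    elif shape == "triangular":
        ramp = apd / 0.9  # full descent duration; 90% recovery at `apd`
        V = np.where(
            (phase >= 0) & (phase < ramp), peak - amp * phase / ramp, rest
        )
    else:
        raise ParameterError(f"unknown AP shape: {shape!r}")
    if repolarization_failure:
        floor = peak - 0.4 * amp
        V = np.maximum(V, floor)
    return t, V, float(apd)


def gen_linescan(spec: TraceSpec) -> SimulationResult:
    """Generate a synthetic line scan (plus AP train) from a TraceSpec.

    Each domain's trace is ``diastolic + amplitude * attenuation[d] *
    waveform(t - beat_start - delay[d])`` with even-numbered beats scaled
    by ``alternans_ratio``, plus seeded Gaussian noise.
    """
    t = np.arange(0.0, spec.n_beats * spec.cycle_length, spec.output_dt)
    mat_uM = np.full((spec.n_domains, t.size), spec.diastolic)
    for beat in range(spec.n_beats):
        t0 = beat * spec.cycle_length
        scale = spec.alternans_ratio if beat % 2 == 0 else 1.0
        for d in range(spec.n_domains):
            tau = t - t0 - spec.centripetal_delay[d]
            mat_uM[d] += (
                spec.membrane_amplitude
                * scale
                * spec.attenuation[d]
                * _beat_waveform(tau)
            )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mat_uM = mat_uM + rng.normal(0.0, spec.noise_sd, mat_uM.shape)
    _, V, _ = gen_ap_train(
        spec.ap_rest, spec.ap_peak, spec.ap_apd, spec.cycle_length,
        spec.n_beats, "triangular", spec.output_dt,
        repolarization_failure=spec.repolarization_failure,
    )
    stim = np.arange(spec.n_beats) * spec.cycle_length
    return SimulationResult(
        t=t,
        V=V,
        Ca_cyto_matrix=mat_uM * 1e-3,  # uM -> mM
        Na_i=np.full(t.size, 9.5),
        Ca_SR_mean=np.full(t.size, 0.5),
        cycle_length=spec.cycle_length,
        stimulus_times=stim,
        provenance={"source": "synthetic", "seed": spec.seed},
        baseline_rmp=spec.ap_rest,
    )
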