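"""Five-category classification of calcium-wave phenotypes.

Each simulated (or externally supplied) cell is assigned exactly one of:

* ``normal`` — full centripetal propagation, stable beat-to-beat amplitude;
* ``alternans`` — beat-to-beat membrane CaT amplitude differences > 5%;
* ``silencing`` — central-to-membrane CaT amplitude ratio <= 0.10 on *all*
  beats (the triggered wave fails to reach the cell centre);
* ``alternans_and_silencing`` — both of the above;
* ``other`` — unphysiological patterns: failed repolarization, irregular
  (neither period-1 nor period-2) amplitude dynamics, or a failed
  simulation.

Validity checks take precedence, so a diverged run is never labelled
silencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .biomarkers import extract_biomarkers, rmp
from .errors import InsufficientDataError


class WaveCategory(str, Enum):
    NORMAL = "normal"
    ALTERNANS = "alternans"
    SILENCING = "silencing"
    ALTERNANS_AND_SILENCING = "alternans_and_silencing"
    OTHER = "other"


CATEGORY_ORDER = (
    WaveCategory.NORMAL,
    WaveCategory.ALTERNANS,
    WaveCategory.SILENCING,
    WaveCategory.ALTERNANS_AND_SILENCING,
    WaveCategory.OTHER,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and conventions of the wave classifier.

    ``alternans_threshold`` is the relative beat-to-beat amplitude
    difference defining alternans; ``normalization`` chooses its
    denominator ("max" of the pair, or "mean").  ``silencing_threshold``
    is the inclusive upper bound on the CaT ratio.  ``amplitude_atol``
    (uM) is an absolute floor below which amplitude fluctuations are
    treated as quiescent rather than irregular.
    """

    alternans_threshold: float = 0.05
    silencing_threshold: float = 0.10
    normalization: str = "max"  # or "mean"
    period_tolerance: float = 0.05
    amplitude_atol: float = 1e-3
    repolarization_margin: float = 15.0  # mV
    n_beats: int = 10


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class ValidityFlags:
    repolarization_failure: bool = False
    irregular_dynamics: bool = False
    simulation_failed: bool = False

    @property
    def any(self) -> bool:
        return (
            self.repolarization_failure
            or self.irregular_dynamics
            or self.simulation_failed
        )


@dataclass
class ClassificationEvidence:
    category: WaveCategory
    beat_amplitudes: list[float] = field(default_factory=list)
    beat_ratios: list[float] = field(default_factory=list)
    alternans: bool = False
    silencing: bool = False
    validity: ValidityFlags = field(default_factory=ValidityFlags)


def _pair_diff(a: float, b: float, normalization: str) -> float:
    denom = max(a, b) if normalization == "max" else 0.5 * (a + b)
    if denom == 0:
        return 0.0
    return abs(b - a) / denom


def detect_alternans(
    beat_amplitudes, config: ClassifierConfig = DEFAULT_CONFIG
) -> bool:
    """True iff any consecutive beat pair differs by more than the threshold.

    The difference is normalized by the larger of the pair (default) or the
    pair mean; pairs in which both amplitudes are zero are excluded.
    """
    amps = [float(a) for a in beat_amplitudes]
    if len(amps) < 2:
        raise InsufficientDataError("alternans detection needs >= 2 beats")
    for a, b in zip(amps, amps[1:]):
        if max(a, b) == 0:
            continue
        # small epsilon keeps the "larger than" boundary strict under
        # floating-point round-off
        if _pair_diff(a, b, config.normalization) > config.alternans_threshold + 1e-12:
            return True
    return False


def detect_silencing(
    beat_ratios, config: ClassifierConfig = DEFAULT_CONFIG
) -> bool:
    """True iff every beat's central-to-membrane ratio is <= the threshold.

    The boundary is inclusive: a ratio exactly at the threshold counts as
    silenced.
    """
    ratios = [float(r) for r in beat_ratios]
    if not ratios:
        raise InsufficientDataError("silencing detection needs >= 1 beat")
    return all(r <= config.silencing_threshold for r in ratios)


def _fits_period(amps: np.ndarray, period: int, config: ClassifierConfig) -> bool:
    """Whether the amplitude sequence is period-``period`` within tolerance.

    Compares *consecutive* beats within each phase, so a slow monotone
    drift (incomplete convergence to the periodic steady state) is not
    mistaken for irregular dynamics.
    """
    for phase in range(period):
        grp = amps[phase::period]
        for a, b in zip(grp, grp[1:]):
            denom = max(a, b)
            if denom <= config.amplitude_atol:
                continue  # quiescent: noise around zero is not irregular
            if abs(a - b) / denom > config.period_tolerance and abs(
                a - b
            ) > config.amplitude_atol:
                return False
    return True


def check_validity(
    result=None,
    *,
    beat_amplitudes=None,
    V=None,
    t=None,
    stimulus_times=None,
    baseline_rmp: float | None = None,
    simulation_failed: bool = False,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ValidityFlags:
    """Screen a run for unphysiological behavior.

    Flags raised: *repolarization failure* (the diastolic V before some
    stimulus never comes back within ``repolarization_margin`` mV of the
    baseline RMP), *irregular dynamics* (the membrane amplitude sequence is
    neither period-1 nor period-2 within tolerance), and *simulation
    failure* (propagated from the integrator).  Any raised flag makes the
    run a candidate for category "other".
    """
    if result is not None:
        if getattr(result, "failed", False):
            return ValidityFlags(simulation_failed=True)
        bm = extract_biomarkers(result)
        beat_amplitudes = bm.catm_amplitude
        V = np.asarray(result.V, float)
        t = np.asarray(result.t, float)
        stimulus_times = np.asarray(result.stimulus_times, float)
        if baseline_rmp is None:
            baseline_rmp = getattr(result, "baseline_rmp", None)
    if simulation_failed:
        return ValidityFlags(simulation_failed=True)

    repol_fail = False
    if V is not None and stimulus_times is not None and len(stimulus_times) > 1:
        V = np.asarray(V, float)
        t = np.asarray(t, float)
        base = (
            baseline_rmp
            if baseline_rmp is not None
            else rmp(V, t, stimulus_times[:1])
        )
        for ts in stimulus_times[1:]:
            sel = (t >= ts - 50.0) & (t < ts)
            if np.any(sel) and np.min(V[sel]) > base + config.repolarization_margin:
                repol_fail = True
                break

    irregular = False
    if beat_amplitudes is not None and len(beat_amplitudes) >= 3:
        amps = np.asarray(beat_amplitudes, float)
        irregular = not (
            _fits_period(amps, 1, config) or _fits_period(amps, 2, config)
        )
    return ValidityFlags(
        repolarization_failure=repol_fail, irregular_dynamics=irregular
    )


def classify_sequences(
    beat_amplitudes,
    beat_ratios,
    validity: ValidityFlags | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassificationEvidence:
    """Core decision rule on per-beat amplitude and ratio sequences."""
    validity = validity or ValidityFlags()
    if validity.any:
        return ClassificationEvidence(
            WaveCategory.OTHER,
            list(beat_amplitudes),
            list(beat_ratios),
            validity=validity,
        )
    alt = detect_alternans(beat_amplitudes, config)
    sil = detect_silencing(beat_ratios, config)
    if sil and alt:
        cat = WaveCategory.ALTERNANS_AND_SILENCING
    elif sil:
        cat = WaveCategory.SILENCING
    elif alt:
        cat = WaveCategory.ALTERNANS
    else:
        cat = WaveCategory.NORMAL
    return ClassificationEvidence(
        cat, list(beat_amplitudes), list(beat_ratios), alt, sil, validity
    )


def classify(result, config: ClassifierConfig = DEFAULT_CONFIG) -> ClassificationEvidence:
    """Classify a SimulationResult (or synthetic line scan) into one category.

    Uses the last ``config.n_beats`` recorded beats.
    """
    if getattr(result, "failed", False):
        return ClassificationEvidence(
            WaveCategory.OTHER, validity=ValidityFlags(simulation_failed=True)
        )
    bm = extract_biomarkers(result)
    amps = bm.catm_amplitude[-config.n_beats:]
    ratios = bm.cat_ratio[-config.n_beats:]
    n_used = len(amps)
    validity = check_validity(
        beat_amplitudes=amps,
        V=result.V,
        t=result.t,
        stimulus_times=np.asarray(result.stimulus_times)[-n_used:],
        baseline_rmp=getattr(result, "baseline_rmp", None),
        config=config,
    )
    return classify_sequences(amps, ratios, validity, config)


def summarize_population(categories) -> dict[str, float]:
    """Percentage of models in each of the five categories (sums to 100)."""
    cats = [WaveCategory(c) for c in categories]
    if not cats:
        raise InsufficientDataError("cannot summarize an empty population")
    n = len(cats)
    return {
        cat.value: 100.0 * sum(c == cat for c in cats) / n
        for cat in CATEGORY_ORDER
    }
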