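"""Wave-phenotype classifier: rule correctness and oracle equivalence."""

import numpy as np
import pytest

from atriawave.classify import (
    CATEGORY_ORDER,
    ClassifierConfig,
    ValidityFlags,
    WaveCategory,
    check_validity,
    classify_sequences,
    detect_alternans,
    detect_silencing,
    summarize_population,
)
from atriawave.errors import InsufficientDataError


# -- straight-line oracle ---------------------------------------------------
# Independent re-statement of the classification rules: alternans iff some
# consecutive amplitude pair differs by >5% of the larger; silencing iff the
# central-to-membrane ratio is <=0.10 on every beat; validity flags win.


def oracle_alternans(amps, thr=0.05):
    flags = []
    for a, b in zip(amps, amps[1:]):
        big = a if a > b else b
        if big == 0:
            continue
        flags.append(abs(a - b) / big > thr)
    return any(flags)


def oracle_silencing(ratios, thr=0.10):
    return all(r <= thr for r in ratios)


def oracle_classify(amps, ratios, invalid=False):
    if invalid:
        return "other"
    alt = oracle_alternans(amps)
    sil = oracle_silencing(ratios)
    if sil and alt:
        return "alternans_and_silencing"
    if sil:
        return "silencing"
    if alt:
        return "alternans"
    return "normal"


class TestDetectAlternans:
    @pytest.mark.parametrize(
        "amps,expected",
        [
            ((0.30, 0.30, 0.30), False),
            ((0.30, 0.40), True),  # 0.10/0.40 = 25%
            ((0.300, 0.312), False),  # 0.012/0.312 ~ 3.8%
            ((0.0, 0.0, 0.3, 0.3), True),  # both-zero pair excluded, 0->0.3 fires
            ((0.3, 0.0, 0.3), True),  # full dropout alternation
        ],
    )
    def test_threshold_cases(self, amps, expected):
        assert detect_alternans(amps) is expected

    def test_requires_two_beats(self):
        with pytest.raises(InsufficientDataError):
            detect_alternans([0.3])

    def test_mean_normalization_option(self):
        cfg = ClassifierConfig(normalization="mean")
        # diff 0.02 over mean 0.31 = 6.5% > 5%, but only 6.25% of the max
        assert detect_alternans([0.30, 0.32], cfg) is True

    def test_boundary_is_strict(self):
        # exactly 5% of the larger value is not alternans ("larger than")
        assert detect_alternans([0.95, 1.0]) is False


class TestDetectSilencing:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ((0.05, 0.08, 0.09), True),
            ((0.10, 0.10), True),  # inclusive boundary
            ((0.05, 0.50), False),
            ((0.100001,), False),
        ],
    )
    def test_threshold_cases(self, ratios, expected):
        assert detect_silencing(ratios) is expected

    def test_requires_one_beat(self):
        with pytest.raises(InsufficientDataError):
            detect_silencing([])


class TestCheckValidity:
    def test_clean_train_has_no_flags(self):
        t = np.arange(0.0, 3000.0)
        V = np.where(t % 1000 < 100, 20.0, -78.0)
        flags = check_validity(
            beat_amplitudes=[0.3, 0.3, 0.3], V=V, t=t,
            stimulus_times=np.array([0.0, 1000.0, 2000.0]),
        )
        assert not flags.any

    def test_repolarization_failure_flag(self):
        t = np.arange(0.0, 3000.0)
        V = np.where(t % 1000 < 100, 20.0, -78.0)
        V[t >= 1000] = np.maximum(V[t >= 1000], -48.0)  # stuck 30 mV high
        flags = check_validity(
            beat_amplitudes=[0.3, 0.3, 0.3], V=V, t=t,
            stimulus_times=np.array([0.0, 1000.0, 2000.0]),
        )
        assert flags.repolarization_failure

    def test_irregular_dynamics_flag(self):
        flags = check_validity(beat_amplitudes=[0.3, 0.1, 0.4, 0.05])
        assert flags.irregular_dynamics

    def test_period_two_is_not_irregular(self):
        flags = check_validity(beat_amplitudes=[0.3, 0.4, 0.3, 0.4, 0.3, 0.4])
        assert not flags.irregular_dynamics

    def test_simulation_failure_propagates(self):
        assert check_validity(simulation_failed=True).simulation_failed


class TestClassify:
    def test_precedence_validity_first(self):
        ev = classify_sequences(
            [0.3, 0.3], [0.05, 0.05], ValidityFlags(repolarization_failure=True)
        )
        assert ev.category is WaveCategory.OTHER

    @pytest.mark.parametrize(
        "amps,ratios,expected",
        [
            ([0.3, 0.3, 0.3], [1.0, 1.0, 1.0], WaveCategory.NORMAL),
            ([0.3, 0.3, 0.3], [0.05, 0.05, 0.05], WaveCategory.SILENCING),
            ([0.3, 0.4, 0.3], [0.05, 0.05, 0.05],
             WaveCategory.ALTERNANS_AND_SILENCING),
            ([0.3, 0.4, 0.3], [1.0, 1.0, 1.0], WaveCategory.ALTERNANS),
        ],
    )
    def test_category_rules(self, amps, ratios, expected):
        assert classify_sequences(amps, ratios).category is expected

    def test_oracle_equivalence_randomized(self):
        """1,000 random amplitude/ratio sequences match the oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 12)
            amps = rng.choice(
                [0.0, 0.01, 0.1, 0.28, 0.3, 0.305, 0.32, 0.4], size=n
            ) + rng.normal(0, 0.002, size=n).clip(-0.005, 0.005)
            amps = np.abs(amps)
            ratios = rng.choice(
                [0.0, 0.05, 0.0999, 0.1, 0.100001, 0.11, 0.5, 1.0], size=n
            )
            invalid = rng.random() < 0.1
            flags = ValidityFlags(simulation_failed=invalid)
            got = classify_sequences(list(amps), list(ratios), flags)
            want = oracle_classify(list(amps), list(ratios), invalid)
            assert got.category.value == want

    def test_threshold_monotonicity(self):
        """Raising the silencing threshold only moves models into silencing."""
        rng = np.random.default_rng(7)
        lo = ClassifierConfig(silencing_threshold=0.10)
        hi = ClassifierConfig(silencing_threshold=0.25)
        for _ in range(200):
            ratios = rng.uniform(0, 0.4, size=6)
            amps = [0.3] * 6
            sil_lo = detect_silencing(ratios, lo)
            sil_hi = detect_silencing(ratios, hi)
            assert not (sil_lo and not sil_hi)


class TestSummarize:
    def test_all_one_category(self):
        pct = summarize_population([WaveCategory.SILENCING] * 16)
        assert pct == {
            "normal": 0.0, "alternans": 0.0, "silencing": 100.0,
            "alternans_and_silencing": 0.0, "other": 0.0,
        }

    def test_mixed_population(self):
        cats = [WaveCategory.NORMAL] * 6 + [WaveCategory.SILENCING] * 10
        pct = summarize_population(cats)
        assert pct["normal"] == 37.5
        assert pct["silencing"] == 62.5

    def test_single_model(self):
        pct = summarize_population([WaveCategory.NORMAL])
        assert pct["normal"] == 100.0

    def test_sums_to_100(self):
        rng = np.random.default_rng(3)
        cats = rng.choice([c.value for c in CATEGORY_ORDER], size=13)
        assert sum(summarize_population(cats).values()) == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_population([])
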