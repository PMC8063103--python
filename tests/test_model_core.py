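"""Ionic current / calcium flux operations and right-hand-side invariants."""

import numpy as np
import pytest

import atriawave.dynamics as dyn
from atriawave.dynamics import (
    buffering_attenuation,
    compute_diffusion,
    compute_membrane_currents,
    compute_ryr_release,
    compute_serca_flux,
    apply_buffering,
    rhs,
    ryr_open_probability_ss,
    total_cell_calcium,
)
from atriawave.errors import InvalidStateError, ParameterError, ShapeError
from atriawave.model import (
    RYR_P_BASELINE,
    CellGeometry,
    CellParameters,
    StateLayout,
    baseline_parameters,
    default_state,
)


@pytest.fixture
def state():
    s = default_state()
    # a mid-AP-ish state with open gates so currents are non-trivial
    s.V = -20.0
    for g in s.gating:
        s.gating[g] = 0.5
    return s


class TestMembraneCurrents:
    def test_returns_all_currents(self, state):
        cur = compute_membrane_currents(state, baseline_parameters())
        assert set(cur) == {
            "ICaL", "ICaT", "INa", "Ito1", "IKr", "IKs", "IK1",
            "ICab", "INab", "IClb", "INCX", "INaK", "ICaP",
        }
        assert all(np.isfinite(v) for v in cur.values())

    def test_sodium_current_zero_at_reversal(self, state):
        p = baseline_parameters()
        state.V = dyn.RTF * np.log(dyn.NA_O / state.Na_i)
        assert compute_membrane_currents(state, p)["INa"] == pytest.approx(0.0, abs=1e-12)

    def test_potassium_currents_zero_at_reversal(self, state):
        p = baseline_parameters()
        state.V = dyn.RTF * np.log(dyn.K_O / state.K_i)
        cur = compute_membrane_currents(state, p)
        for name in ("Ito1", "IKs", "IK1"):
            assert cur[name] == pytest.approx(0.0, abs=1e-12)

    def test_ical_linear_in_gcal(self, state):
        p1 = baseline_parameters()
        p2 = p1.copy()
        p2.GCaL = p1.GCaL / 2
        c1 = compute_membrane_currents(state, p1)["ICaL"]
        c2 = compute_membrane_currents(state, p2)["ICaL"]
        assert c2 == pytest.approx(c1 / 2)

    @pytest.mark.parametrize("field,current", [
        ("ImaxNCX", "INCX"), ("ImaxNaK", "INaK"), ("GNa", "INa"),
    ])
    def test_scaling_linearity(self, state, field, current):
        p1 = baseline_parameters()
        p2 = p1.copy()
        setattr(p2, field, getattr(p1, field) * 2.5)
        c1 = compute_membrane_currents(state, p1)[current]
        c2 = compute_membrane_currents(state, p2)[current]
        assert c2 == pytest.approx(2.5 * c1)

    def test_ncx_runs_in_both_modes(self, state):
        p = baseline_parameters()
        state.V = -80.0
        state.Ca_SL = np.full(2, 5e-4)  # Ca-loaded, hyperpolarized: forward
        fwd = compute_membrane_currents(state, p)["INCX"]
        state.V = 40.0
        state.Ca_SL = np.full(2, 5e-6)  # depolarized, Ca-depleted: reverse
        rev = compute_membrane_currents(state, p)["INCX"]
        assert fwd < 0 < rev

    def test_invalid_state_rejected(self, state):
        state.V = float("nan")
        with pytest.raises(InvalidStateError):
            compute_membrane_currents(state, baseline_parameters())


class TestSerca:
    def test_zero_substrate_no_forward_flux(self):
        assert compute_serca_flux(0.0, 0.6) <= 0.0

    def test_saturation_proportional_to_jmaxup(self):
        sat = compute_serca_flux(100.0, 0.6, Jmaxup=0.0053)
        assert sat == pytest.approx(0.0053, rel=1e-3)
        assert compute_serca_flux(100.0, 0.6, Jmaxup=0.0053 * 0.7) == pytest.approx(
            sat * 0.7, rel=1e-3
        )

    def test_bounded_by_jmaxup(self):
        for ca in np.logspace(-6, 2, 30):
            assert abs(compute_serca_flux(ca, 0.6)) <= 0.0053 + 1e-12

    def test_monotone_in_cytosolic_calcium(self):
        cas = np.logspace(-6, 0, 40)
        fluxes = [compute_serca_flux(c, 0.6) for c in cas]
        assert np.all(np.diff(fluxes) >= -1e-15)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            compute_serca_flux(-1e-4, 0.6)


class TestRyR:
    def test_closed_units_release_nothing(self):
        assert compute_ryr_release(0.0, 1e-4, 0.6, RYR_P_BASELINE, 198000.0) == 0.0

    def test_no_gradient_no_flux(self):
        assert compute_ryr_release(0.7, 0.4, 0.4, RYR_P_BASELINE, 198000.0) == 0.0

    def test_flux_monotone_in_nryrs(self):
        f1 = compute_ryr_release(0.5, 1e-4, 0.6, RYR_P_BASELINE, 99000.0)
        f2 = compute_ryr_release(0.5, 1e-4, 0.6, RYR_P_BASELINE, 198000.0)
        assert 0 < f1 < f2

    def test_open_probability_linear_in_p5(self):
        """Doubling the single-channel open probability doubles the
        steady-state open fraction in the low-calcium linear regime."""
        ryr2 = list(RYR_P_BASELINE)
        ryr2[5] *= 2
        lo_ca = 1e-4  # well below the activation threshold
        p1 = ryr_open_probability_ss(lo_ca, 0.6, RYR_P_BASELINE)
        p2 = ryr_open_probability_ss(lo_ca, 0.6, ryr2)
        assert p2 == pytest.approx(2.0 * p1, rel=1e-3)

    def test_nonpositive_parameters_rejected(self):
        bad = list(RYR_P_BASELINE)
        bad[5] = 0.0
        with pytest.raises(ParameterError):
            compute_ryr_release(0.5, 1e-4, 0.6, bad, 198000.0)


class TestBuffering:
    def test_attenuation_in_unit_interval(self):
        for ca in np.logspace(-6, 0, 20):
            assert 0.0 < buffering_attenuation(ca, 1.0) <= 1.0

    def test_stronger_buffering_below_one(self):
        # Buff_factor scales the buffer Kd: 0.15 binds tighter than 1.0
        ca = 1e-4
        assert buffering_attenuation(ca, 0.15) < buffering_attenuation(ca, 1.0)

    def test_no_buffer_passes_rate_through(self, monkeypatch):
        for key in ("buf_trpn", "buf_cmdn"):
            monkeypatch.setitem(dyn.KINETICS, key, 0.0)
        assert apply_buffering(1.7e-3, 1e-4, 1.0) == pytest.approx(1.7e-3)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ParameterError):
            buffering_attenuation(1e-4, 0.0)


class TestDiffusion:
    def test_uniform_profile_is_stationary(self):
        geo = CellGeometry()
        assert np.allclose(compute_diffusion(np.full(18, 0.3), geo), 0.0)

    def test_two_compartment_linear_law(self):
        geo = CellGeometry(n_domains=3, diffusion_coupling=0.4)
        rates = compute_diffusion(np.array([1.0, 1.0, 0.0]), geo)
        # interface between domains 1 and 2 carries flux g * (0 - 1)
        assert rates[1] == pytest.approx(-0.4)
        assert rates[2] == pytest.approx(0.4)

    def test_matches_dense_operator_oracle(self):
        rng = np.random.default_rng(1)
        geo = CellGeometry()
        g = geo.coupling_array()
        # independently coded dense tridiagonal Laplacian
        L = np.zeros((18, 18))
        for i in range(17):
            L[i, i] -= g[i]
            L[i, i + 1] += g[i]
            L[i + 1, i + 1] -= g[i]
            L[i + 1, i] += g[i]
        for _ in range(25):
            ca = rng.uniform(0, 1e-3, 18)
            assert np.allclose(compute_diffusion(ca, geo), L @ ca, atol=1e-18)

    def test_conserves_volume_weighted_calcium(self):
        rng = np.random.default_rng(2)
        geo = CellGeometry()
        for _ in range(25):
            ca = rng.uniform(0, 1e-3, 18)
            rates = compute_diffusion(ca, geo)
            total = np.sum(rates * geo.v_cyto)
            scale = np.max(np.abs(rates)) * geo.v_cyto
            assert abs(total) <= 1e-12 * max(scale, 1e-30)

    def test_down_gradient_direction(self):
        rng = np.random.default_rng(3)
        geo = CellGeometry(n_domains=5)
        g = geo.coupling_array()
        for _ in range(20):
            ca = rng.uniform(0, 1e-3, 5)
            for i in range(4):
                flux_into_left = g[i] * (ca[i + 1] - ca[i])
                assert np.sign(flux_into_left) == np.sign(ca[i + 1] - ca[i])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            compute_diffusion(np.zeros(7), CellGeometry())


class TestRHS:
    def test_finite_derivative_from_default_state(self):
        dy = rhs(0.0, default_state(), baseline_parameters(), stimulus=40.0)
        assert np.all(np.isfinite(dy))

    def test_nan_state_rejected(self):
        y = default_state().to_vector()
        y[0] = np.nan
        with pytest.raises(InvalidStateError):
            rhs(0.0, y, baseline_parameters())

    def test_closed_cell_calcium_conservation_instantaneous(self):
        """With sarcolemmal Ca fluxes disabled the volume-weighted total
        calcium rate (free + buffered) vanishes."""
        params = baseline_parameters()
        lay = StateLayout(18)
        rng = np.random.default_rng(4)
        s = default_state()
        s.Ca_cyto = rng.uniform(5e-5, 5e-4, 18)
        s.Ca_SRS = rng.uniform(5e-5, 5e-3, 18)
        s.Ca_SR = rng.uniform(0.3, 0.9, 18)
        s.Ca_JSR = rng.uniform(0.2, 0.9, 18)
        s.cru_open = rng.uniform(0, 0.5, 18)
        s.cru_inact = rng.uniform(0, 0.4, 18)
        dy = rhs(0.0, s, params, closed_cell=True)
        geo = params.geometry
        kin = dyn.KINETICS
        vjsr = geo.v_sr * kin["jsr_frac"]
        vnsr = geo.v_sr * (1.0 - kin["jsr_frac"])
        p = dyn.pack_params(params, closed_cell=True)
        total = 0.0
        scale = 0.0
        for d in range(18):
            for sl_, vol, comp in (
                (lay.Ca_cyto, geo.v_cyto, 0), (lay.Ca_SRS, geo.v_srs, 0),
                (lay.Ca_SR, vnsr, 2), (lay.Ca_JSR, vjsr, 2),
            ):
                idx = sl_.start + d
                beta = dyn._buffer_beta(s.to_vector()[idx], p, comp)
                total += vol * dy[idx] / beta
                scale += vol * abs(dy[idx]) / beta
        for k in range(2):
            for sl_, vol in ((lay.Ca_junct, geo.v_junct), (lay.Ca_SL, geo.v_sl)):
                idx = sl_.start + k
                beta = dyn._buffer_beta(s.to_vector()[idx], p, 1)
                total += vol * dy[idx] / beta
                scale += vol * abs(dy[idx]) / beta
        assert abs(total) <= 1e-10 * scale

    def test_total_calcium_helper_positive(self):
        assert total_cell_calcium(default_state(), baseline_parameters()) > 0
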