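"""Ionic currents, calcium fluxes, and the full right-hand side of the cell model.

The electrophysiology follows standard Hodgkin-Huxley formulations for the
fast sodium, transient-outward, delayed-rectifier and inward-rectifier
currents, a calcium-dependent-inactivation L-type calcium current, an
allosteric-saturation Na-Ca exchanger, a Na/K pump with sodium and
potassium half-saturations, a Hill-type SERCA pump with forward and
reverse terms, and a deterministic mean-field three-state
(closed/open/inactivated) ryanodine-receptor scheme per domain.  Calcium
buffering uses the rapid-buffering (instantaneous equilibrium)
approximation; ``Buff_factor`` multiplies the buffer dissociation
constants, so values below 1 mean tighter binding, i.e. *stronger*
buffering.

All formulas live in numba-compiled kernels shared by the object-level
operations below and by the production integrator in
:mod:`atriawave.simulator`.  Fixed kinetic constants (transfer rates, half
saturations, buffer pools) are collected in :data:`KINETICS`; they are part
of the model formulation, not of the remodeling surface, and are passed to
the kernels through the packed parameter vector.

Units: mV, ms, mM, pA/pF.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import InvalidStateError, ParameterError, ShapeError
from .model import CellGeometry, CellParameters, CellState

# -- physical constants -----------------------------------------------------

F = 96.4867  # C/mmol
RTF = 26.712  # RT/F at 310 K, mV
CM = 50.0  # pF, whole-cell capacitance
#: converts (current in pA/pF) x CM to charge rate in C/ms
I_TO_CPMS = CM * 1e-15

NA_O = 140.0  # mM
CA_O = 1.8
K_O = 5.4
CL_O = 132.0
CL_I = 30.0

# NCX (allosteric-saturation formulation)
NCX_GAMMA = 0.35
NCX_KM_NA = 87.5  # mM
NCX_KM_CA = 1.38
NCX_KSAT = 0.1

# NaK pump half-saturations
NAK_KM_NAI = 10.0
NAK_KM_KO = 1.5

# plasmalemmal Ca pump half-saturation
CAP_KM = 0.0005

#: Fixed kinetic constants of the calcium-handling system.  Names:
#: serca_* (Hill pump), ryr_* (CRU gating and release), r_* (inter-
#: compartment transfer rates, 1/ms, defined on the named side), buf_*/kd_*
#: (buffer pools, mM), na_accel (effective acceleration of the sodium
#: balance: the Na pool is given a reduced effective distribution volume so
#: the slow Na/NaK/NCX balance equilibrates within a practical pre-pacing
#: protocol).
KINETICS: dict[str, float] = dict(
    serca_kmf=2.0e-3,  # mM, cytosolic half-activation
    serca_kmr=20.0,  # mM, SR half-saturation of the (weak) reverse term
    serca_h=2.0,
    ryr_ko=4.0,  # 1/ms opening-rate scale
    ryr_kact=0.04,  # mM SRS-Ca half-activation of opening
    ryr_hact=4.0,  # activation Hill coefficient
    ryr_ksr=0.40,  # mM luminal (JSR) half-activation
    ryr_hsr=8.0,
    ryr_kclose=0.45,  # 1/ms
    ryr_kclose_lum=4.0,  # extra closing as the junctional store empties
    ryr_kinact=0.4,  # 1/ms, open -> inactivated
    ryr_kci=0.02,  # 1/ms max closed -> inactivated (Ca-dependent) rate
    ryr_kci_kca=3.2e-4,  # mM SRS-Ca half-activation of closed-state inact.
    ryr_kci_h=6.0,  # Hill coefficient of closed-state inactivation
    ryr_krec=0.0025,  # 1/ms recovery from inactivation
    ryr_krel=10.0,  # 1/ms release scale (JSR side) at full density
    ryr_kleak=4.0e-4,  # 1/ms passive SR leak (network-SR side)
    jsr_frac=0.22,  # fraction of SR volume that is junctional (release) SR
    tau_tr=150.0,  # ms, network-SR -> JSR refill time constant
    g_srs=0.3,  # 1/ms, sub-SR space coupling between adjacent domains
    g_nsr=0.1,  # 1/ms, network-SR (store) coupling between adjacent domains
    r_junct_sl=2.0,
    r_junct_srs=2.0,
    r_sl_cyto=3.0,
    r_srs_cyto=3.0,
    buf_trpn=0.070,
    kd_trpn=5.0e-4,
    buf_cmdn=0.050,
    kd_cmdn=2.38e-3,
    buf_sl=0.40,
    kd_sl=0.013,
    buf_csqn=10.0,
    kd_csqn=0.8,
    na_accel=14.0,
    fca_km=0.025,  # mM, junctional-Ca half-inactivation of the L-type current
)

# baseline normalizations of the remodeling-sensitive RyR properties
_P0_BASE, _P1_BASE, _P5_BASE, _P11_BASE = 0.2, 0.22, 8e-5, 0.007
_NRYRS_BASE = 198000.0

# packed parameter vector layout
_PNAMES = (
    "GCaL", "GCaT", "GNa", "Gto1", "GKr", "GKs", "GK1", "GCab", "GNab",
    "GClb", "ImaxNCX", "ImaxNaK", "ICaP_max", "Jmaxup", "p0n", "p1n",
    "p5n", "dens", "buff", "ndom", "v_cyto", "v_sr", "v_srs", "v_sl",
    "v_junct", "sarco",
) + tuple(KINETICS)
NP_PARAMS = len(_PNAMES)
_IX = {name: i for i, name in enumerate(_PNAMES)}
(
    _GCAL, _GCAT, _GNA, _GTO, _GKR, _GKS, _GK1, _GCAB, _GNAB, _GCLB,
    _INCXMAX, _INAKMAX, _ICAPMAX, _JMAXUP, _P0N, _P1N, _P5N, _DENS,
    _BUFF, _NDOM, _VCYTO, _VSR, _VSRS, _VSL, _VJUNCT, _SARCO,
) = range(26)
(
    _KMF, _KMR, _SERCAH, _KO_RYR, _KACT, _HACT, _KSR, _HSR, _KCLOSE,
    _KCLOSELUM, _KINACT, _KCI, _KCIKCA, _KCIH, _KREC, _KREL, _KLEAK, _JSRFRAC, _TAUTR,
    _GSRS, _GNSR, _RJSL, _RJSRS, _RSLC, _RSRSC, _BTRPN, _KTRPN, _BCMDN, _KCMDN,
    _BSL, _KSL, _BCSQN, _KCSQN, _NAACC, _FCAKM,
) = range(26, NP_PARAMS)


def pack_params(
    params: CellParameters,
    closed_cell: bool = False,
    kinetics: dict | None = None,
) -> np.ndarray:
    """Pack CellParameters + geometry + kinetic constants for the kernels."""
    geo = params.geometry
    kin = dict(KINETICS, **(kinetics or {}))
    p = np.empty(NP_PARAMS)
    p[_GCAL] = params.GCaL
    p[_GCAT] = params.GCaT
    p[_GNA] = params.GNa
    p[_GTO] = params.Gto1
    p[_GKR] = params.GKr
    p[_GKS] = params.GKs
    p[_GK1] = params.GK1
    p[_GCAB] = params.GCab
    p[_GNAB] = params.GNab
    p[_GCLB] = params.GClb
    p[_INCXMAX] = params.ImaxNCX
    p[_INAKMAX] = params.ImaxNaK
    p[_ICAPMAX] = params.ICaP_max
    p[_JMAXUP] = params.Jmaxup
    p[_P0N] = params.RyR_P[0] / _P0_BASE
    p[_P1N] = params.RyR_P[1] / _P1_BASE
    p[_P5N] = params.RyR_P[5] / _P5_BASE
    p[_DENS] = (params.NRyRs / _NRYRS_BASE) * (params.RyR_P[11] / _P11_BASE)
    p[_BUFF] = params.Buff_factor
    p[_NDOM] = geo.n_domains
    p[_VCYTO] = geo.v_cyto
    p[_VSR] = geo.v_sr
    p[_VSRS] = geo.v_srs
    p[_VSL] = geo.v_sl
    p[_VJUNCT] = geo.v_junct
    p[_SARCO] = 0.0 if closed_cell else 1.0
    for name, val in kin.items():
        p[_IX[name]] = val
    return p


# -- gating kinetics --------------------------------------------------------


@njit(cache=True)
def gate_inf_tau(V):
    """Steady states and time constants of the 11 membrane gates.

    Order matches model.GATING_NAMES: m,h,j (INa), d,f (ICaL), b,g (ICaT),
    r,s (Ito1), xr (IKr), xs (IKs).
    """
    inf = np.empty(11)
    tau = np.empty(11)

    # INa m
    if abs(V + 47.13) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    bm = 0.08 * np.exp(-V / 11.0)
    inf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)
    # INa h, j
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = (
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    inf[1] = ah / (ah + bh) if (ah + bh) > 0 else 0.0
    tau[1] = 1.0 / (ah + bh) if (ah + bh) > 0 else 1.0
    inf[2] = aj / (aj + bj) if (aj + bj) > 0 else 0.0
    tau[2] = 1.0 / (aj + bj) if (aj + bj) > 0 else 1.0

    # ICaL d, f
    dv = V + 10.0
    if abs(dv) < 1e-6:
        tau_d = 4.579 / (1.0 + np.exp(-dv / 6.24))
    else:
        tau_d = (1.0 - np.exp(-dv / 6.24)) / (
            0.035 * dv * (1.0 + np.exp(-dv / 6.24))
        )
    inf[3] = 1.0 / (1.0 + np.exp(-dv / 8.0))
    tau[3] = tau_d
    inf[4] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[4] = 15.0 + 120.0 * np.exp(-(((V + 25.0) / 20.0) ** 2))

    # ICaT b, g
    inf[5] = 1.0 / (1.0 + np.exp(-(V + 37.49) / 5.4))
    tau[5] = 0.6 + 5.4 / (1.0 + np.exp(0.03 * (V + 100.0)))
    inf[6] = 1.0 / (1.0 + np.exp((V + 66.0) / 6.0))
    tau[6] = 1.0 + 40.0 / (1.0 + np.exp(0.08 * (V + 65.0)))

    # Ito1 r (activation), s (inactivation)
    ar = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    br = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[7] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau[7] = 1.0 / (3.0 * (ar + br))
    as_ = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    bs = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf[8] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau[8] = 1.0 / (3.0 * (as_ + bs))

    # IKr xr
    if abs(V + 14.1) < 1e-6:
        axr = 0.0015
    else:
        axr = 0.0003 * (V + 14.1) / (1.0 - np.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-6:
        bxr = 3.7836e-4
    else:
        bxr = (
            7.3898e-5 * (V - 3.3328) / (np.exp((V - 3.3328) / 5.1237) - 1.0)
        )
    inf[9] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau[9] = 1.0 / (axr + bxr)

    # IKs xs
    if abs(V - 19.9) < 1e-6:
        axs = 0.00068
        bxs = 0.000315
    else:
        axs = 4e-5 * (V - 19.9) / (1.0 - np.exp(-(V - 19.9) / 17.0))
        bxs = 3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9.0) - 1.0)
    inf[10] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    tau[10] = 0.5 / (axs + bxs)
    return inf, tau


# -- current kernels --------------------------------------------------------


@njit(cache=True)
def _ncx_current(V, Na_i, Ca_sl, imax):
    """Na-Ca exchanger current (pA/pF); negative = forward mode (Ca efflux)."""
    e1 = np.exp(NCX_GAMMA * V / RTF)
    e2 = np.exp((NCX_GAMMA - 1.0) * V / RTF)
    num = imax * (e1 * Na_i ** 3 * CA_O - e2 * NA_O ** 3 * Ca_sl)
    den = (
        (NCX_KM_NA ** 3 + NA_O ** 3)
        * (NCX_KM_CA + CA_O)
        * (1.0 + NCX_KSAT * e2)
    )
    return num / den


@njit(cache=True)
def _nak_current(V, Na_i, imax):
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * V / RTF)
        + 0.0365 * sigma * np.exp(-V / RTF)
    )
    return (
        imax
        * fnak
        / (1.0 + (NAK_KM_NAI / Na_i) ** 1.5)
        * K_O
        / (K_O + NAK_KM_KO)
    )


@njit(cache=True)
def _membrane_currents_kernel(V, Na_i, K_i, gates, ca_j, ca_sl, p):
    """Whole-cell currents (pA/pF) and per-membrane-domain Ca-carrying parts.

    Returns (currents[13], ca_parts[2, 5]) where currents order is
    ICaL, ICaT, INa, Ito1, IKr, IKs, IK1, ICab, INab, IClb, INCX, INaK,
    ICaP and ca_parts[k] holds (ICaL, ICaT, ICab, ICaP, INCX) of membrane
    domain k (each half of the cell total, whole-cell pA/pF units).
    """
    m, h, j, d, f, b, g, r, s, xr, xs = (
        gates[0], gates[1], gates[2], gates[3], gates[4], gates[5],
        gates[6], gates[7], gates[8], gates[9], gates[10],
    )
    ena = RTF * np.log(NA_O / Na_i)
    ek = RTF * np.log(K_O / K_i)
    ecl = -RTF * np.log(CL_O / CL_I)

    ina = p[_GNA] * m ** 3 * h * j * (V - ena)
    ito = p[_GTO] * r * s * (V - ek)
    ikr = p[_GKR] * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4))
    iks = p[_GKS] * xs ** 2 * (V - ek)
    ik1 = p[_GK1] * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0)))
    inab = p[_GNAB] * (V - ena)
    iclb = p[_GCLB] * (V - ecl)
    inak = _nak_current(V, Na_i, p[_INAKMAX])

    ca_parts = np.zeros((2, 5))
    ical = icat = icab = icap = incx = 0.0
    for k in range(2):
        fca = 1.0 / (1.0 + ca_j[k] / p[_FCAKM])
        ical_k = 0.5 * p[_GCAL] * d * f * fca * (V - 65.0)
        icat_k = 0.5 * p[_GCAT] * b * g * (V - 45.0)
        eca = 0.5 * RTF * np.log(CA_O / max(ca_sl[k], 1e-8))
        icab_k = 0.5 * p[_GCAB] * (V - eca)
        icap_k = 0.5 * p[_ICAPMAX] * ca_sl[k] / (CAP_KM + ca_sl[k])
        incx_k = 0.5 * _ncx_current(V, Na_i, ca_sl[k], p[_INCXMAX])
        ca_parts[k, 0] = ical_k
        ca_parts[k, 1] = icat_k
        ca_parts[k, 2] = icab_k
        ca_parts[k, 3] = icap_k
        ca_parts[k, 4] = incx_k
        ical += ical_k
        icat += icat_k
        icab += icab_k
        icap += icap_k
        incx += incx_k

    out = np.empty(13)
    out[0] = ical
    out[1] = icat
    out[2] = ina
    out[3] = ito
    out[4] = ikr
    out[5] = iks
    out[6] = ik1
    out[7] = icab
    out[8] = inab
    out[9] = iclb
    out[10] = incx
    out[11] = inak
    out[12] = icap
    return out, ca_parts


# -- calcium-handling kernels ----------------------------------------------


@njit(cache=True)
def _serca_kernel(ca_c, ca_sr, jmaxup, p):
    fw = (ca_c / p[_KMF]) ** p[_SERCAH]
    rv = (ca_sr / p[_KMR]) ** p[_SERCAH]
    return jmaxup * (fw - rv) / (1.0 + fw + rv)


@njit(cache=True)
def _ryr_rates(ca_srs, ca_jsr, p):
    """(k_open, k_close, k_inact, k_ci, k_rec) of the mean-field CRU scheme.

    Opening is steeply sigmoidal in the local (sub-SR) calcium and gated by
    the junctional-SR load, so release terminates by local store depletion.
    ``k_ci`` is a calcium-dependent closed-to-inactivated rate: sustained
    elevation of diastolic calcium builds standing refractoriness.
    """
    act = ca_srs ** p[_HACT] / (ca_srs ** p[_HACT] + p[_KACT] ** p[_HACT])
    lum = 1.0 / (1.0 + (p[_KSR] / max(ca_jsr, 1e-6)) ** p[_HSR])
    k_open = p[_KO_RYR] * p[_P0N] * p[_P5N] * act * lum
    k_close = p[_KCLOSE] / p[_P1N] * (1.0 + p[_KCLOSELUM] * (1.0 - lum))
    k_ci = p[_KCI] * ca_srs ** p[_KCIH] / (
        ca_srs ** p[_KCIH] + p[_KCIKCA] ** p[_KCIH]
    )
    return k_open, k_close, p[_KINACT], k_ci, p[_KREC]


@njit(cache=True)
def _buffer_beta(ca, p, compartment):
    """Rapid-buffering attenuation factor in (0, 1].

    compartment: 0 = cytosol/SRS (troponin + calmodulin), 1 = SL/junctional
    membrane buffer, 2 = SR (calsequestrin; unaffected by Buff_factor).
    """
    if compartment == 2:
        s = p[_BCSQN] * p[_KCSQN] / (p[_KCSQN] + ca) ** 2
    elif compartment == 1:
        kd = p[_KSL] * p[_BUFF]
        s = p[_BSL] * kd / (kd + ca) ** 2
    else:
        kd1 = p[_KTRPN] * p[_BUFF]
        kd2 = p[_KCMDN] * p[_BUFF]
        s = p[_BTRPN] * kd1 / (kd1 + ca) ** 2 + p[_BCMDN] * kd2 / (kd2 + ca) ** 2
    return 1.0 / (1.0 + s)


@njit(cache=True)
def rhs_kernel(y, p, g_couple, istim, dy):
    """Full state derivative; writes into dy and returns it.

    ``istim`` is the applied stimulus in pA/pF (positive = depolarizing).
    Layout per model.StateLayout.
    """
    n = int(p[_NDOM])
    iV, iNa, iK = 0, 1, 2
    g0 = 3
    o = 3 + 11
    oc, os_, osr = o, o + n, o + 2 * n
    ojr = o + 3 * n
    oo, oi = o + 4 * n, o + 5 * n
    oj, osl = o + 6 * n, o + 6 * n + 2

    V = y[iV]
    Na_i = y[iNa]
    K_i = y[iK]
    gates = y[g0:g0 + 11]
    ca_j = y[oj:oj + 2]
    ca_sl = y[osl:osl + 2]

    sarco = p[_SARCO]

    cur, ca_parts = _membrane_currents_kernel(V, Na_i, K_i, gates, ca_j, ca_sl, p)
    itot = 0.0
    for q in range(13):
        itot += cur[q]
    dy[iV] = -(itot - istim)

    # gating
    inf, tau = gate_inf_tau(V)
    for q in range(11):
        dy[g0 + q] = (inf[q] - gates[q]) / tau[q]

    # sodium (accelerated effective volume); potassium held fixed
    v_cyto_tot = p[_VCYTO] * n
    na_cur = cur[2] + cur[8] + 3.0 * cur[10] + 3.0 * cur[11]
    dy[iNa] = -na_cur * I_TO_CPMS / (F * v_cyto_tot) * p[_NAACC] * sarco
    dy[iK] = 0.0

    vc, vsrs = p[_VCYTO], p[_VSRS]
    vsl, vj = p[_VSL], p[_VJUNCT]
    vjsr = p[_VSR] * p[_JSRFRAC]
    vnsr = p[_VSR] * (1.0 - p[_JSRFRAC])

    for d in range(n):
        ca_c = y[oc + d]
        ca_s = y[os_ + d]
        ca_n = y[osr + d]  # network SR
        ca_jr = y[ojr + d]  # junctional SR
        O = y[oo + d]
        I = y[oi + d]

        k_open, k_close, k_inact, k_ci, k_rec = _ryr_rates(ca_s, ca_jr, p)
        C = 1.0 - O - I
        dy[oo + d] = k_open * C - (k_close + k_inact) * O
        dy[oi + d] = k_inact * O + k_ci * C - k_rec * I

        # release (JSR side), refill (JSR side), leak (network-SR side)
        jrel_jsr = p[_KREL] * p[_DENS] * O * (ca_jr - ca_s)
        jtr_jsr = (ca_n - ca_jr) / p[_TAUTR]
        # diastolic leak scales with the resting open probability (both the
        # opening-rate and single-channel-Po scales) and the RyR density
        jleak_nsr = p[_KLEAK] * p[_P0N] * p[_P5N] * p[_DENS] * (ca_n - ca_c)
        jup = _serca_kernel(ca_c, ca_n, p[_JMAXUP], p)
        jsrs_c = p[_RSRSC] * (ca_s - ca_c)

        dca_c = -jup + jleak_nsr * vnsr / vc + jsrs_c * vsrs / vc
        dca_s = jrel_jsr * vjsr / vsrs - jsrs_c
        dca_n = -jleak_nsr - jtr_jsr * vjsr / vnsr + jup * vc / vnsr
        dca_jr = jtr_jsr - jrel_jsr

        # diffusion between neighbours: bulk cytosol and sub-SR pathway
        if d > 0:
            dca_c += g_couple[d - 1] * (y[oc + d - 1] - ca_c)
            dca_s += p[_GSRS] * (y[os_ + d - 1] - ca_s)
            dca_n += p[_GNSR] * (y[osr + d - 1] - ca_n)
        if d < n - 1:
            dca_c += g_couple[d] * (y[oc + d + 1] - ca_c)
            dca_s += p[_GSRS] * (y[os_ + d + 1] - ca_s)
            dca_n += p[_GNSR] * (y[osr + d + 1] - ca_n)

        # membrane-domain extras
        if d == 0 or d == n - 1:
            k = 0 if d == 0 else 1
            jj_sl = p[_RJSL] * (ca_j[k] - ca_sl[k])
            jj_srs = p[_RJSRS] * (ca_j[k] - ca_s)
            jsl_c = p[_RSLC] * (ca_sl[k] - ca_c)
            # Ca carried by this domain's membrane currents (pA/pF -> mM/ms)
            jca_junct = -ca_parts[k, 0] * I_TO_CPMS / (2.0 * F * vj) * sarco
            jca_sl = (
                (2.0 * ca_parts[k, 4] - ca_parts[k, 3] - ca_parts[k, 2]
                 - ca_parts[k, 1])
                * I_TO_CPMS
                / (2.0 * F * vsl)
                * sarco
            )
            dca_j = jca_junct - jj_sl - jj_srs
            dca_sl_k = jca_sl + jj_sl * vj / vsl - jsl_c
            dca_c += jsl_c * vsl / vc
            dca_s += jj_srs * vj / vsrs
            dy[oj + k] = _buffer_beta(ca_j[k], p, 1) * dca_j
            dy[osl + k] = _buffer_beta(ca_sl[k], p, 1) * dca_sl_k

        dy[oc + d] = _buffer_beta(ca_c, p, 0) * dca_c
        dy[os_ + d] = _buffer_beta(ca_s, p, 0) * dca_s
        dy[osr + d] = _buffer_beta(ca_n, p, 2) * dca_n
        dy[ojr + d] = _buffer_beta(ca_jr, p, 2) * dca_jr

    return dy


# -- object-level operations ------------------------------------------------

_CURRENT_NAMES = (
    "ICaL", "ICaT", "INa", "Ito1", "IKr", "IKs", "IK1",
    "ICab", "INab", "IClb", "INCX", "INaK", "ICaP",
)


def compute_membrane_currents(
    state: CellState, params: CellParameters
) -> dict[str, float]:
    """All sarcolemmal currents (pA/pF, whole-cell) at the given state.

    Currents are evaluated in the two membrane domains only (each carrying
    half the sarcolemma) and summed.
    """
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("state contains non-finite values")
    p = pack_params(params)
    gates = np.array([state.gating[g] for g in
                      ("m", "h", "j", "d", "f", "b", "g", "r", "s", "xr", "xs")])
    cur, _ = _membrane_currents_kernel(
        state.V, state.Na_i, state.K_i, gates,
        np.asarray(state.Ca_junct, float), np.asarray(state.Ca_SL, float), p,
    )
    return dict(zip(_CURRENT_NAMES, cur))


def compute_serca_flux(
    Ca_cyto: float,
    Ca_SR: float,
    Jmaxup: float | None = None,
    params: CellParameters | None = None,
) -> float:
    """SERCA uptake flux (mM/ms in cytosolic units; cytosol -> SR positive)."""
    if Ca_cyto < 0 or Ca_SR < 0:
        raise ValueError("concentrations must be non-negative")
    if Jmaxup is None:
        Jmaxup = params.Jmaxup if params is not None else 0.0053
    p = pack_params(params or CellParameters())
    return float(_serca_kernel(Ca_cyto, Ca_SR, Jmaxup, p))


def ryr_open_probability_ss(Ca_SRS: float, Ca_SR: float, RyR_P) -> float:
    """Closed-form steady-state open fraction of the mean-field CRU scheme."""
    params = CellParameters(RyR_P=tuple(RyR_P))
    p = pack_params(params)
    k_open, k_close, k_inact, k_ci, k_rec = _ryr_rates(Ca_SRS, Ca_SR, p)
    ko = max(k_open, 1e-300)
    # dO=0, dI=0 with C = 1 - O - I
    return 1.0 / (
        (k_close + k_inact) / ko
        + (k_inact + k_ci * (k_close + k_inact) / ko) / k_rec
        + 1.0
    )


def compute_ryr_release(
    cru_open: float, Ca_SRS: float, Ca_SR: float, RyR_P, NRyRs: float
) -> float:
    """RyR release flux (mM/ms in sub-SR-space units; SR -> SRS positive)."""
    for i in (0, 1, 5, 11):
        if RyR_P[i] <= 0:
            raise ParameterError(f"RyR_P[{i}] must be > 0")
    if not 0.0 <= cru_open <= 1.0:
        raise ParameterError("open fraction must be in [0, 1]")
    geo = CellGeometry()
    dens = (NRyRs / _NRYRS_BASE) * (RyR_P[11] / _P11_BASE)
    jrel_jsr = KINETICS["ryr_krel"] * dens * cru_open * (Ca_SR - Ca_SRS)
    v_jsr = geo.v_sr * KINETICS["jsr_frac"]
    return float(jrel_jsr * v_jsr / geo.v_srs)


def buffering_attenuation(
    Ca: float, Buff_factor: float, compartment: str = "cyto"
) -> float:
    """Instantaneous-buffering attenuation factor beta(Ca) in (0, 1]."""
    if Buff_factor <= 0:
        raise ParameterError("Buff_factor must be > 0")
    comp = {"cyto": 0, "srs": 0, "sl": 1, "junct": 1, "sr": 2}[compartment]
    p = pack_params(CellParameters(Buff_factor=Buff_factor))
    return float(_buffer_beta(Ca, p, comp))


def apply_buffering(
    free_Ca_rate: float, Ca: float, Buff_factor: float, compartment: str = "cyto"
) -> float:
    """Attenuate a free-calcium rate by the rapid-buffering factor."""
    return free_Ca_rate * buffering_attenuation(Ca, Buff_factor, compartment)


def compute_diffusion(
    Ca_by_domain: np.ndarray, geometry: CellGeometry
) -> np.ndarray:
    """Net diffusive cytosolic-calcium rate per domain (mM/ms).

    Linear in each interface's concentration difference and directed
    down-gradient; with the (equal) cytosolic domain volumes the
    volume-weighted sum of the returned rates is zero.
    """
    ca = np.asarray(Ca_by_domain, float)
    if ca.shape != (geometry.n_domains,):
        raise ShapeError(
            f"expected {geometry.n_domains} domain concentrations, got {ca.shape}"
        )
    g = geometry.coupling_array()
    out = np.zeros_like(ca)
    diff = g * (ca[1:] - ca[:-1])  # rate into the left domain of each interface
    out[:-1] += diff
    out[1:] -= diff
    return out


def rhs(
    t: float,
    state: CellState | np.ndarray,
    params: CellParameters,
    stimulus: float = 0.0,
    closed_cell: bool = False,
) -> np.ndarray:
    """Full state derivative as a flat vector (layout: model.StateLayout).

    ``stimulus`` is the applied depolarizing current in pA/pF.
    """
    y = state.to_vector() if isinstance(state, CellState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("state contains non-finite values")
    p = pack_params(params, closed_cell=closed_cell)
    g = params.geometry.coupling_array()
    dy = np.empty_like(y)
    return rhs_kernel(y, p, g, float(stimulus), dy)


def total_cell_calcium(state: CellState, params: CellParameters) -> float:
    """Total cell calcium content (free + buffered) in mmol x 1e15.

    Volume-weighted sum over every compartment of every domain; used by the
    closed-cell conservation checks.
    """
    geo = params.geometry
    bf = params.Buff_factor
    kin = KINETICS

    def bound(ca, comp):
        if comp == 2:
            return kin["buf_csqn"] * ca / (kin["kd_csqn"] + ca)
        if comp == 1:
            return kin["buf_sl"] * ca / (kin["kd_sl"] * bf + ca)
        return kin["buf_trpn"] * ca / (kin["kd_trpn"] * bf + ca) + kin[
            "buf_cmdn"
        ] * ca / (kin["kd_cmdn"] * bf + ca)

    v_jsr = geo.v_sr * kin["jsr_frac"]
    v_nsr = geo.v_sr * (1.0 - kin["jsr_frac"])
    tot = 0.0
    for d in range(geo.n_domains):
        tot += geo.v_cyto * (state.Ca_cyto[d] + bound(state.Ca_cyto[d], 0))
        tot += geo.v_srs * (state.Ca_SRS[d] + bound(state.Ca_SRS[d], 0))
        tot += v_nsr * (state.Ca_SR[d] + bound(state.Ca_SR[d], 2))
        tot += v_jsr * (state.Ca_JSR[d] + bound(state.Ca_JSR[d], 2))
    for k in range(2):
        tot += geo.v_junct * (state.Ca_junct[k] + bound(state.Ca_junct[k], 1))
        tot += geo.v_sl * (state.Ca_SL[k] + bound(state.Ca_SL[k], 1))
    return tot * 1e15
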