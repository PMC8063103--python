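"""Cell architecture and parameter containers for the spatial atrial myocyte model.

The cell is represented as a single transverse slice cut into ``n_domains``
serially coupled domains.  Only the first and last domain touch the
sarcolemma and carry membrane currents; calcium entering there triggers
release from the local calcium release units (CRUs) and then spreads toward
the cell centre by diffusion, recruiting interior CRUs in a regenerative
"fire-diffuse-fire" wave.

Every domain holds a cytosolic space, a sarcoplasmic-reticulum (SR) store,
and a small sub-SR space (SRS) where the CRUs sense and deposit calcium.
Membrane domains additionally hold a sub-sarcolemmal (SL) space and a
junctional space where L-type calcium current accumulates before it reaches
the CRUs.

Units: concentrations mM, time ms, voltage mV, membrane currents pA/pF,
volumes litres.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ShapeError

GATING_NAMES = ("m", "h", "j", "d", "f", "b", "g", "r", "s", "xr", "xs")
N_GATES = len(GATING_NAMES)

#: Baseline RyR property vector (Table-style ordering).  Indices used by the
#: model: 0 and 1 scale gating transition rates, 5 is the single-channel
#: open-probability scale, 11 the RyR2 density in the SR fraction.  The
#: remaining slots are reserved and held at 1.0.
RYR_P_BASELINE = (0.2, 0.22, 1.0, 1.0, 1.0, 8e-5, 1.0, 1.0, 1.0, 1.0, 1.0, 0.007)

NRYRS_BASELINE = 198000.0


@dataclass(frozen=True)
class CellGeometry:
    """Spatial discretization of the cell into serially coupled domains.

    Volumes are per-domain; interior domains are identical, membrane domains
    carry the additional sub-sarcolemmal and junctional sub-volumes (2% and
    0.1% of the cytosolic domain volume by default).  ``diffusion_coupling``
    is the per-interface cytosolic calcium transfer rate (1/ms); there are
    ``n_domains - 1`` interfaces and the coupling is symmetric.
    """

    n_domains: int = 18
    v_cyto: float = 6.67e-13
    v_sr: float = 4.0e-14
    v_srs: float = 6.7e-15
    v_sl: float = 1.334e-14
    v_junct: float = 6.67e-16
    diffusion_coupling: float | tuple[float, ...] = 0.85

    def __post_init__(self):
        if self.n_domains < 3:
            raise ParameterError(f"n_domains must be >= 3, got {self.n_domains}")
        for name in ("v_cyto", "v_sr", "v_srs", "v_sl", "v_junct"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        g = self.coupling_array()
        if g.shape != (self.n_domains - 1,):
            raise ShapeError(
                f"diffusion_coupling must be scalar or length {self.n_domains - 1}"
            )
        if np.any(g < 0):
            raise ParameterError("diffusion coupling rates must be >= 0")

    @property
    def membrane_domain_indices(self) -> tuple[int, int]:
        return (0, self.n_domains - 1)

    @property
    def central_domain_indices(self) -> tuple[int, int]:
        """The two centermost domains (one repeated for odd n_domains)."""
        n = self.n_domains
        return ((n - 1) // 2, n // 2)

    def coupling_array(self) -> np.ndarray:
        g = self.diffusion_coupling
        if np.isscalar(g):
            return np.full(self.n_domains - 1, float(g))
        return np.asarray(g, dtype=float)


@dataclass
class CellParameters:
    """Maximum conductances/fluxes and calcium-handling properties of one model.

    Conductance-like entries (``GCaL`` ... ``ICaP_max``) are the quantities
    the population sampler perturbs multiplicatively; the calcium-handling
    block (``Jmaxup``, ``RyR_P``, ``NRyRs``, ``Buff_factor``) is the
    remodeling surface.

    Note the inverse convention on ``Buff_factor``: it multiplies the
    dissociation constant of the cytosolic buffers, so values *below* 1
    mean *stronger* buffering (0.15 is the strongly buffered, remodeled
    setting).
    """

    GCaL: float = 0.2
    GCaT: float = 0.12
    GNa: float = 7.8
    Gto1: float = 0.17
    GKr: float = 0.085
    GKs: float = 0.065
    GK1: float = 0.075
    GCab: float = 0.0012
    GNab: float = 0.0011
    GClb: float = 0.0006
    ImaxNCX: float = 1800.0
    ImaxNaK: float = 1.0
    ICaP_max: float = 0.14
    Jmaxup: float = 0.0053
    RyR_P: tuple[float, ...] = RYR_P_BASELINE
    NRyRs: float = NRYRS_BASELINE
    Buff_factor: float = 1.0
    geometry: CellGeometry = field(default_factory=CellGeometry)

    _SCALE_FIELDS = (
        "GCaL", "GCaT", "GNa", "Gto1", "GKr", "GKs", "GK1", "GCab", "GNab",
        "GClb", "ImaxNCX", "ImaxNaK", "ICaP_max", "Jmaxup", "NRyRs",
        "Buff_factor",
    )

    def __post_init__(self):
        if isinstance(self.RyR_P, list):
            self.RyR_P = tuple(self.RyR_P)
        self.validate()

    def validate(self) -> None:
        for name in self._SCALE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")
        if len(self.RyR_P) < 12:
            raise ParameterError("RyR_P must have at least 12 entries")
        for i, v in enumerate(self.RyR_P):
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"RyR_P[{i}] must be strictly positive, got {v}")

    def copy(self) -> "CellParameters":
        return dataclasses.replace(self, RyR_P=tuple(self.RyR_P))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._SCALE_FIELDS}
        d["RyR_P"] = list(self.RyR_P)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellParameters":
        d = dict(d)
        geo = d.pop("geometry", None)
        if geo is not None:
            if isinstance(geo.get("diffusion_coupling"), list):
                geo["diffusion_coupling"] = tuple(geo["diffusion_coupling"])
            d["geometry"] = CellGeometry(**geo)
        d["RyR_P"] = tuple(d.get("RyR_P", RYR_P_BASELINE))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CellParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def baseline_parameters() -> CellParameters:
    """The baseline (unremodeled) parameter set.

    The calcium-handling block carries the standard unremodeled values
    (Jmaxup 0.0053, RyR_P[0] 0.2, RyR_P[1] 0.22, RyR_P[5] 8e-5,
    RyR_P[11] 0.007, NRyRs 198000, Buff_factor 1.0); the conductances were
    fitted so the baseline cell shows a rabbit-atrial phenotype (APD90 near
    96 ms, RMP near -78 mV, membrane CaT amplitude near 0.33 uM, full
    centripetal propagation) at 1 Hz pacing.
    """
    return CellParameters()


def baseline_parameter_file() -> Path:
    """Path of the versioned baseline parameter JSON shipped with the package."""
    return Path(__file__).parent / "data" / "baseline_parameters.json"


# -- state ------------------------------------------------------------------


class StateLayout:
    """Index layout of the flat state vector for a given geometry.

    Order: V, Na_i, K_i, 11 membrane gates, then per-domain blocks
    Ca_cyto, Ca_SRS, Ca_SR (network SR), Ca_JSR (junctional SR), CRU open
    fraction, CRU inactivated fraction, then the membrane-domain extras
    Ca_junct (first, last) and Ca_SL (first, last).
    """

    def __init__(self, n_domains: int = 18):
        n = n_domains
        self.n_domains = n
        self.V = 0
        self.Na_i = 1
        self.K_i = 2
        self.gates = slice(3, 3 + N_GATES)
        o = 3 + N_GATES
        self.Ca_cyto = slice(o, o + n)
        self.Ca_SRS = slice(o + n, o + 2 * n)
        self.Ca_SR = slice(o + 2 * n, o + 3 * n)
        self.Ca_JSR = slice(o + 3 * n, o + 4 * n)
        self.cru_open = slice(o + 4 * n, o + 5 * n)
        self.cru_inact = slice(o + 5 * n, o + 6 * n)
        self.Ca_junct = slice(o + 6 * n, o + 6 * n + 2)
        self.Ca_SL = slice(o + 6 * n + 2, o + 6 * n + 4)
        self.size = o + 6 * n + 4


@dataclass
class CellState:
    """Full dynamical state of the cell at one instant."""

    V: float
    Na_i: float
    K_i: float
    gating: dict[str, float]
    Ca_cyto: np.ndarray
    Ca_SRS: np.ndarray
    Ca_SR: np.ndarray  # network SR
    Ca_JSR: np.ndarray  # junctional (release-site) SR
    cru_open: np.ndarray
    cru_inact: np.ndarray
    Ca_junct: np.ndarray  # (first, last) membrane domain
    Ca_SL: np.ndarray

    def validate(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            from .errors import InvalidStateError

            raise InvalidStateError("state contains non-finite values")
        for arr_name in ("Ca_cyto", "Ca_SRS", "Ca_SR", "Ca_JSR", "Ca_junct",
                         "Ca_SL"):
            if np.any(getattr(self, arr_name) < 0):
                from .errors import InvalidStateError

                raise InvalidStateError(f"negative concentration in {arr_name}")
        gate_vals = np.array(list(self.gating.values()))
        frac = np.concatenate([gate_vals, self.cru_open, self.cru_inact])
        if np.any(frac < 0) or np.any(frac > 1):
            from .errors import InvalidStateError

            raise InvalidStateError("gating/CRU fractions outside [0, 1]")

    def to_vector(self) -> np.ndarray:
        lay = StateLayout(len(self.Ca_cyto))
        y = np.empty(lay.size)
        y[lay.V] = self.V
        y[lay.Na_i] = self.Na_i
        y[lay.K_i] = self.K_i
        y[lay.gates] = [self.gating[g] for g in GATING_NAMES]
        y[lay.Ca_cyto] = self.Ca_cyto
        y[lay.Ca_SRS] = self.Ca_SRS
        y[lay.Ca_SR] = self.Ca_SR
        y[lay.Ca_JSR] = self.Ca_JSR
        y[lay.cru_open] = self.cru_open
        y[lay.cru_inact] = self.cru_inact
        y[lay.Ca_junct] = self.Ca_junct
        y[lay.Ca_SL] = self.Ca_SL
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray, n_domains: int = 18) -> "CellState":
        lay = StateLayout(n_domains)
        if y.shape != (lay.size,):
            raise ShapeError(f"expected state vector of length {lay.size}")
        gates = dict(zip(GATING_NAMES, y[lay.gates]))
        return cls(
            V=float(y[lay.V]),
            Na_i=float(y[lay.Na_i]),
            K_i=float(y[lay.K_i]),
            gating=gates,
            Ca_cyto=y[lay.Ca_cyto].copy(),
            Ca_SRS=y[lay.Ca_SRS].copy(),
            Ca_SR=y[lay.Ca_SR].copy(),
            Ca_JSR=y[lay.Ca_JSR].copy(),
            cru_open=y[lay.cru_open].copy(),
            cru_inact=y[lay.cru_inact].copy(),
            Ca_junct=y[lay.Ca_junct].copy(),
            Ca_SL=y[lay.Ca_SL].copy(),
        )


def default_state(geometry: CellGeometry | None = None) -> CellState:
    """Packaged initial condition.

    For the default 18-domain geometry this is the end-diastolic state of
    the baseline cell after 150 pre-pacing beats at 1 Hz (shipped as a data
    file); for other geometries a generic quiescent state is used.
    """
    geo = geometry or CellGeometry()
    n = geo.n_domains
    state_file = Path(__file__).parent / "data" / "initial_state.json"
    if n == 18 and state_file.exists():
        d = json.loads(state_file.read_text())
        return CellState(
            V=d["V"], Na_i=d["Na_i"], K_i=d["K_i"], gating=dict(d["gating"]),
            Ca_cyto=np.asarray(d["Ca_cyto"]), Ca_SRS=np.asarray(d["Ca_SRS"]),
            Ca_SR=np.asarray(d["Ca_SR"]), Ca_JSR=np.asarray(d["Ca_JSR"]),
            cru_open=np.asarray(d["cru_open"]),
            cru_inact=np.asarray(d["cru_inact"]),
            Ca_junct=np.asarray(d["Ca_junct"]), Ca_SL=np.asarray(d["Ca_SL"]),
        )
    gates = dict(
        m=0.0029, h=0.97, j=0.98, d=1.4e-4, f=0.98, b=0.0012, g=0.92,
        r=0.0, s=0.96, xr=3e-4, xs=0.019,
    )
    return CellState(
        V=-78.4,
        Na_i=9.5,
        K_i=140.0,
        gating=gates,
        Ca_cyto=np.full(n, 1e-4),
        Ca_SRS=np.full(n, 1e-4),
        Ca_SR=np.full(n, 0.7),
        Ca_JSR=np.full(n, 0.7),
        cru_open=np.zeros(n),
        cru_inact=np.zeros(n),
        Ca_junct=np.full(2, 1e-4),
        Ca_SL=np.full(2, 1e-4),
    )
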