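"""Simulation result container and delimited-text / HDF5 round-trip.

The same container holds ODE-model output and synthetic line scans, so
biomarker extraction and wave classification are agnostic to the source.
Calcium is stored in mM; the line-scan matrix is domains x time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ShapeError


@dataclass
class SimulationResult:
    t: np.ndarray  # ms, strictly increasing
    V: np.ndarray  # mV
    Ca_cyto_matrix: np.ndarray  # n_domains x n_times, mM
    Na_i: np.ndarray  # mM
    Ca_SR_mean: np.ndarray  # mM
    cycle_length: float
    stimulus_times: np.ndarray  # ms, starts of the recorded beats
    provenance: dict = field(default_factory=dict)
    failed: bool = False
    failure_time: float | None = None
    #: resting potential of the unpaced cell (mV), when known; used as the
    #: reference for the repolarization-failure validity check
    baseline_rmp: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.V = np.asarray(self.V, float)
        self.Ca_cyto_matrix = np.atleast_2d(np.asarray(self.Ca_cyto_matrix, float))
        self.Na_i = np.asarray(self.Na_i, float)
        self.Ca_SR_mean = np.asarray(self.Ca_SR_mean, float)
        self.stimulus_times = np.asarray(self.stimulus_times, float)
        nt = self.t.size
        if self.V.size != nt or self.Ca_cyto_matrix.shape[1] != nt:
            raise ShapeError("trace lengths do not match the time grid")
        if self.Na_i.size != nt or self.Ca_SR_mean.size != nt:
            raise ShapeError("trace lengths do not match the time grid")
        if nt > 1 and not np.all(np.diff(self.t) > 0):
            raise ShapeError("time grid must be strictly increasing")

    @property
    def n_domains(self) -> int:
        return self.Ca_cyto_matrix.shape[0]

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path, stem: str = "result") -> None:
        """Write traces as delimited text plus a JSON provenance sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        head = "t_ms\tV_mV\tNa_i_mM\tCa_SR_mean_mM"
        np.savetxt(
            outdir / f"{stem}_traces.tsv",
            np.column_stack([self.t, self.V, self.Na_i, self.Ca_SR_mean]),
            header=head, comments="", delimiter="\t",
        )
        np.savetxt(outdir / f"{stem}_linescan.tsv", self.Ca_cyto_matrix,
                   delimiter="\t")
        meta = {
            "cycle_length": self.cycle_length,
            "stimulus_times": self.stimulus_times.tolist(),
            "provenance": self.provenance,
            "failed": self.failed,
            "failure_time": self.failure_time,
            "baseline_rmp": self.baseline_rmp,
        }
        (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path, stem: str = "result") -> "SimulationResult":
        outdir = Path(outdir)
        traces = np.loadtxt(outdir / f"{stem}_traces.tsv", skiprows=1)
        mat = np.loadtxt(outdir / f"{stem}_linescan.tsv", delimiter="\t")
        meta = json.loads((outdir / f"{stem}_meta.json").read_text())
        return cls(
            t=traces[:, 0], V=traces[:, 1], Na_i=traces[:, 2],
            Ca_SR_mean=traces[:, 3], Ca_cyto_matrix=mat,
            cycle_length=meta["cycle_length"],
            stimulus_times=np.asarray(meta["stimulus_times"]),
            provenance=meta.get("provenance", {}),
            failed=meta.get("failed", False),
            failure_time=meta.get("failure_time"),
            baseline_rmp=meta.get("baseline_rmp"),
        )

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("t", "V", "Ca_cyto_matrix", "Na_i", "Ca_SR_mean",
                         "stimulus_times"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["cycle_length"] = self.cycle_length
            f.attrs["failed"] = self.failed
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                t=f["t"][:], V=f["V"][:], Ca_cyto_matrix=f["Ca_cyto_matrix"][:],
                Na_i=f["Na_i"][:], Ca_SR_mean=f["Ca_SR_mean"][:],
                stimulus_times=f["stimulus_times"][:],
                cycle_length=float(f.attrs["cycle_length"]),
                provenance=json.loads(f.attrs.get("provenance", "{}")),
                failed=bool(f.attrs.get("failed", False)),
            )


def load_external_linescan(
    matrix_file: str | Path,
    cycle_length: float,
    voltage_file: str | Path | None = None,
    dt: float = 1.0,
    delimiter: str | None = None,
) -> SimulationResult:
    """Wrap an externally supplied line-scan matrix for classification.

    ``matrix_file`` holds a domains x time matrix (delimited text) of
    cytosolic calcium in mM, sampled uniformly at ``dt`` ms starting at a
    stimulus.  An optional two-column (t, V) voltage file enables the
    repolarization validity check; without it a flat placeholder voltage
    trace is used (voltage-based checks are then vacuous).
    """
    mat = np.atleast_2d(np.loadtxt(matrix_file, delimiter=delimiter))
    nt = mat.shape[1]
    if voltage_file is not None:
        tv = np.loadtxt(voltage_file, delimiter=delimiter)
        t, V = tv[:, 0], tv[:, 1]
        if t.size != nt:
            raise ShapeError("voltage trace length does not match line scan")
    else:
        t = np.arange(nt) * dt
        V = np.full(nt, -78.0)
    stim = np.arange(0.0, t[-1] - cycle_length * 0.5 + 1e-9, cycle_length)
    if stim.size == 0:
        stim = np.array([0.0])
    return SimulationResult(
        t=t, V=V, Ca_cyto_matrix=mat, Na_i=np.full(t.size, np.nan),
        Ca_SR_mean=np.full(t.size, np.nan), cycle_length=cycle_length,
        stimulus_times=stim, provenance={"source": str(matrix_file)},
    )
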