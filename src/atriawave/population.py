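"""Population-of-models construction and calibration to rabbit-like criteria.

Candidate models share the baseline calcium-handling system and differ only
in maximum conductances/fluxes of the sarcolemmal currents, drawn
log-uniformly (or by Latin hypercube) from multiplicative ranges around the
baseline.  Calibration simulates each candidate under the pacing protocol
and keeps those with (1) fully regenerative centripetal propagation,
(2) no alternans or afterdepolarizations, and (3) AP and CaT biomarkers
inside physiological windows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .biomarkers import extract_biomarkers, rmp as rmp_of
from .classify import DEFAULT_CONFIG, detect_alternans
from .errors import ParameterError
from .model import CellParameters, baseline_parameters
from .simulator import (
    DEFAULT_SOLVER,
    PacingProtocol,
    SolverSettings,
    run_paced,
)

#: Conductances varied across the population; calcium-handling parameters
#: (Jmaxup, RyR_P, NRyRs, Buff_factor) stay at baseline during sampling.
SAMPLED_CONDUCTANCES = (
    "GCaL", "GNa", "Gto1", "GKr", "GKs", "GK1", "ImaxNCX", "ImaxNaK",
)

DEFAULT_RANGES = {name: (0.5, 2.0) for name in SAMPLED_CONDUCTANCES}


@dataclass(frozen=True)
class CalibrationCriteria:
    """Acceptance windows for the control population.

    Windows are the physiological control ranges (mean +/- 2 SD of the
    control phenotype): APD90 in ms, RMP in mV, membrane CaT amplitude in
    uM.  ``min_cat_ratio`` is the full-propagation minimum on the mean
    central-to-membrane amplitude ratio.
    """

    apd90_window: tuple[float, float] = (70.0, 122.0)
    rmp_window: tuple[float, float] = (-82.0, -74.0)
    catm_window: tuple[float, float] = (0.19, 0.47)
    min_cat_ratio: float = 0.5
    forbid_alternans: bool = True
    forbid_afterdepolarizations: bool = True

    def __post_init__(self):
        for w in (self.apd90_window, self.rmp_window, self.catm_window):
            if not w[0] < w[1]:
                raise ParameterError(f"empty calibration window {w}")
        if not 0.0 < self.min_cat_ratio <= 1.0:
            raise ParameterError("min_cat_ratio must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ModelPopulation:
    """A calibrated set of models plus the provenance of its construction."""

    members: list[tuple[str, CellParameters]]
    criteria: CalibrationCriteria
    seed: int | None = None
    ranges: dict = field(default_factory=dict)
    report: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ParameterError("model ids must be unique")

    def __len__(self) -> int:
        return len(self.members)

    def parameters(self) -> list[CellParameters]:
        return [p for _, p in self.members]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "seed": self.seed,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "criteria": self.criteria.to_dict(),
            "members": [
                {"id": mid, "parameters": p.to_dict()} for mid, p in self.members
            ],
        }
        (outdir / "population.json").write_text(json.dumps(payload, indent=1))
        if self.report:
            import pandas as pd

            pd.DataFrame(self.report).to_csv(
                outdir / "calibration_report.csv", index=False
            )

    @classmethod
    def load(cls, outdir: str | Path) -> "ModelPopulation":
        d = json.loads((Path(outdir) / "population.json").read_text())
        return cls(
            members=[
                (m["id"], CellParameters.from_dict(m["parameters"]))
                for m in d["members"]
            ],
            criteria=CalibrationCriteria(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["criteria"].items()}
            ),
            seed=d.get("seed"),
            ranges={k: tuple(v) for k, v in d.get("ranges", {}).items()},
        )


def sample_candidates(
    n: int,
    ranges: dict | None = None,
    seed: int = 0,
    baseline: CellParameters | None = None,
    method: str = "log-uniform",
) -> list[CellParameters]:
    """Draw ``n`` candidate parameter sets by scaling the baseline conductances.

    Multipliers are log-uniform in the given per-conductance interval
    (default [0.5, 2] on all sampled conductances); ``method="lhs"`` uses a
    Latin hypercube in log space instead.  Only maximum conductances/fluxes
    vary; the calcium-handling block stays at baseline.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid range for {name}: ({lo}, {hi})")
        if name not in CellParameters._SCALE_FIELDS:
            raise ParameterError(f"unknown conductance: {name}")
    base = baseline or baseline_parameters()
    names = sorted(ranges)
    rng = np.random.default_rng(seed)
    if method == "lhs":
        from scipy.stats import qmc

        u = qmc.LatinHypercube(d=len(names), seed=rng).random(n) if n else np.empty((0, len(names)))
    elif method == "log-uniform":
        u = rng.random((n, len(names)))
    else:
        raise ParameterError(f"unknown sampling method: {method!r}")
    out = []
    for row in u:
        cand = base.copy()
        for uj, name in zip(row, names):
            lo, hi = ranges[name]
            mult = np.exp(np.log(lo) + uj * (np.log(hi) - np.log(lo)))
            setattr(cand, name, getattr(base, name) * mult)
        cand.validate()
        out.append(cand)
    return out


def detect_afterdepolarization(
    V: np.ndarray,
    t: np.ndarray,
    stimulus_times: np.ndarray,
    cycle_length: float,
    threshold_mV: float = 5.0,
) -> bool:
    """Secondary depolarizations between stimuli.

    After each AP has repolarized to within 20 mV of the trace's diastolic
    floor, any re-rise of V more than ``threshold_mV`` above the running
    repolarization envelope (the minimum V seen so far in that diastole)
    counts as an afterdepolarization.
    """
    V = np.asarray(V, float)
    t = np.asarray(t, float)
    base = rmp_of(V, t, stimulus_times)
    for ts in stimulus_times:
        sel = (t >= ts) & (t < ts + cycle_length)
        seg = V[sel]
        if seg.size < 3:
            continue
        below = np.nonzero(seg < base + 20.0)[0]
        # skip the upstroke: require repolarization after the peak
        ipk = int(np.argmax(seg))
        below = below[below > ipk]
        if below.size == 0:
            continue
        run_min = np.minimum.accumulate(seg[below[0]:])
        if np.any(seg[below[0]:] - run_min > threshold_mV):
            return True
    return False


#: margins of the cheap pre-screening stage: a candidate is rejected
#: without a full-length run only when its short-run biomarkers fall
#: outside the calibration window by more than these slack amounts
SCREEN_APD_SLACK = 12.0  # ms
SCREEN_RMP_SLACK = 1.5  # mV
SCREEN_CATM_FACTOR = 0.35  # relative widening of the amplitude window
SCREEN_RATIO_FLOOR = 0.3  # clear propagation failure
SCREEN_BEATS = 22


def _screen_candidate(
    params: CellParameters,
    protocol: PacingProtocol,
    criteria: CalibrationCriteria,
    solver: SolverSettings,
) -> dict | None:
    """Cheap short-run pre-screen; returns a rejection record or None.

    Only clear-cut failures (outside the calibration windows by a generous
    margin after ~2/3 fewer pre-pacing beats) are rejected here; anything
    marginal proceeds to the full-length evaluation.
    """
    short = PacingProtocol(
        cycle_length=protocol.cycle_length,
        n_beats=SCREEN_BEATS,
        stimulus_amplitude=protocol.stimulus_amplitude,
        stimulus_duration=protocol.stimulus_duration,
        record_last_n_beats=min(protocol.record_last_n_beats, 10),
        output_dt=protocol.output_dt,
    )
    res = run_paced(params, short, solver=solver)
    base: dict = {c: False for c in
                  ("apd90", "rmp", "catm", "propagation", "alternans",
                   "afterdepolarization")}
    if res.failed:
        base.update(accepted=False, reason="simulation_failed", stage="screen")
        return base
    bm = extract_biomarkers(res)
    apd = bm.mean_apd90
    catm = float(np.mean(bm.catm_amplitude))
    ratio = float(np.mean(bm.cat_ratio))
    reason = None
    if ratio < SCREEN_RATIO_FLOOR:  # structural criterion first
        reason = "propagation"
    lo, hi = criteria.apd90_window
    if reason is None and (not np.isfinite(apd) or not (
        lo - SCREEN_APD_SLACK <= apd <= hi + SCREEN_APD_SLACK
    )):
        reason = "apd90"
    lo, hi = criteria.rmp_window
    if reason is None and not (
        lo - SCREEN_RMP_SLACK <= bm.rmp <= hi + SCREEN_RMP_SLACK
    ):
        reason = "rmp"
    lo, hi = criteria.catm_window
    if reason is None and not (
        lo * (1 - SCREEN_CATM_FACTOR) <= catm <= hi * (1 + SCREEN_CATM_FACTOR)
    ):
        reason = "catm"
    if reason is None:
        return None
    base.update(
        accepted=False, reason=reason, stage="screen",
        apd90_ms=apd, rmp_mV=bm.rmp, catm_uM=catm, cat_ratio=ratio,
    )
    return base


def evaluate_candidate(
    params: CellParameters,
    protocol: PacingProtocol,
    criteria: CalibrationCriteria,
    solver: SolverSettings = DEFAULT_SOLVER,
    prescreen: bool = True,
) -> dict:
    """Simulate one candidate and test every calibration criterion.

    Returns a record with per-criterion pass/fail flags, the measured
    biomarkers, and an overall ``accepted`` flag.  Simulation failure is
    recorded as rejection reason "simulation_failed", never raised.  With
    ``prescreen`` (default) a short run rejects clear-cut failures early;
    every accepted model always passes the full-length evaluation.
    """
    if prescreen:
        rec = _screen_candidate(params, protocol, criteria, solver)
        if rec is not None:
            return rec
    rec = {c: False for c in
           ("apd90", "rmp", "catm", "propagation", "alternans",
            "afterdepolarization")}
    res = run_paced(params, protocol, solver=solver)
    if res.failed:
        rec.update(accepted=False, reason="simulation_failed")
        return rec
    bm = extract_biomarkers(res)
    mean_apd = bm.mean_apd90
    mean_catm = float(np.mean(bm.catm_amplitude))
    mean_ratio = float(np.mean(bm.cat_ratio))
    rec.update(
        apd90_ms=mean_apd, rmp_mV=bm.rmp, catm_uM=mean_catm,
        cat_ratio=mean_ratio,
    )
    lo, hi = criteria.apd90_window
    rec["apd90"] = bool(np.isfinite(mean_apd) and lo <= mean_apd <= hi)
    lo, hi = criteria.rmp_window
    rec["rmp"] = bool(lo <= bm.rmp <= hi)
    lo, hi = criteria.catm_window
    rec["catm"] = bool(lo <= mean_catm <= hi)
    rec["propagation"] = bool(mean_ratio >= criteria.min_cat_ratio)
    try:
        alternans = detect_alternans(bm.catm_amplitude, DEFAULT_CONFIG)
    except Exception:
        alternans = True
    rec["alternans"] = (not criteria.forbid_alternans) or not alternans
    adp = detect_afterdepolarization(
        res.V, res.t, res.stimulus_times, res.cycle_length
    )
    rec["afterdepolarization"] = (
        not criteria.forbid_afterdepolarizations
    ) or not adp
    # propagation first: it is the structural criterion, so a candidate
    # failing several checks is reported as a propagation failure
    checks = ("propagation", "apd90", "rmp", "catm", "alternans",
              "afterdepolarization")
    rec["accepted"] = all(rec[c] for c in checks)
    if not rec["accepted"] and "reason" not in rec:
        rec["reason"] = next(c for c in checks if not rec[c])
    return rec


def calibrate(
    candidates: list[CellParameters],
    criteria: CalibrationCriteria | None = None,
    protocol: PacingProtocol | None = None,
    solver: SolverSettings = DEFAULT_SOLVER,
    accept_first: int | None = None,
    seed: int | None = None,
    ranges: dict | None = None,
    progress: bool = False,
) -> ModelPopulation:
    """Filter candidates through the calibration criteria.

    Every candidate is simulated under ``protocol`` and kept iff it passes
    all criteria; per-candidate diagnostics are retained in the report.
    With ``accept_first`` the scan stops once that many models have been
    accepted (candidates beyond that point are recorded as unevaluated).
    """
    criteria = criteria or CalibrationCriteria()
    protocol = protocol or PacingProtocol()
    members: list[tuple[str, CellParameters]] = []
    report = []
    iterator = enumerate(candidates)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="calibrating")
    for i, cand in iterator:
        if accept_first is not None and len(members) >= accept_first:
            break
        rec = evaluate_candidate(cand, protocol, criteria, solver)
        rec["candidate"] = i
        report.append(rec)
        if rec["accepted"]:
            members.append((f"m{i:04d}", cand))
    return ModelPopulation(
        members=members, criteria=criteria, seed=seed,
        ranges=dict(ranges or {}), report=report,
    )


def build_population(
    n_candidates: int = 300,
    seed: int = 0,
    criteria: CalibrationCriteria | None = None,
    protocol: PacingProtocol | None = None,
    solver: SolverSettings = DEFAULT_SOLVER,
    population_size: int = 16,
    ranges: dict | None = None,
    progress: bool = False,
) -> ModelPopulation:
    """Sample candidates and calibrate, accepting the first ``population_size``."""
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    cands = sample_candidates(n_candidates, ranges, seed)
    return calibrate(
        cands, criteria, protocol, solver, accept_first=population_size,
        seed=seed, ranges=ranges, progress=progress,
    )
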