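"""End-to-end study orchestration.

``run_study`` builds (or loads) a calibrated control population, applies
each requested remodeling scenario, simulates every model, extracts
biomarkers, classifies calcium-wave phenotypes, and writes two summary
tables: a biomarker table (mean +/- SD per population) and a category
table (percentage of models per wave category), plus per-model line scans
and JSON provenance.  Reruns with the same config are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import extract_biomarkers
from .classify import CATEGORY_ORDER, ClassifierConfig, classify
from .errors import ConfigurationError
from .model import CellParameters
from .population import (
    CalibrationCriteria,
    ModelPopulation,
    build_population,
)
from .remodeling import get_scenario
from .remodeling import apply_scenario
from .simulator import DEFAULT_SOLVER, PacingProtocol, SolverSettings, run_paced

log = logging.getLogger("atriawave")

TABLE_BIOMARKERS = "table2_summary.csv"
TABLE_CATEGORIES = "table3_categories.csv"


@dataclass
class StudyConfig:
    """Configuration of one full in-silico remodeling study."""

    outdir: str = "study_out"
    seed: int = 0
    n_candidates: int = 300
    population_size: int = 16
    scenarios: list[str] = field(
        default_factory=lambda: ["control", "1", "2", "3", "4", "5", "6", "7", "8"]
    )
    cycle_length: float = 1000.0
    n_beats: int = 60
    record_last_n_beats: int = 10
    stimulus_amplitude: float = 40.0
    stimulus_duration: float = 2.0
    output_dt: float = 0.5
    solver_dt: float = 0.02
    save_linescans: bool = True
    plots: bool = False
    criteria: CalibrationCriteria = field(default_factory=CalibrationCriteria)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    population_dir: str | None = None  # reuse an existing population

    def protocol(self) -> PacingProtocol:
        return PacingProtocol(
            cycle_length=self.cycle_length,
            n_beats=self.n_beats,
            stimulus_amplitude=self.stimulus_amplitude,
            stimulus_duration=self.stimulus_duration,
            record_last_n_beats=self.record_last_n_beats,
            output_dt=self.output_dt,
        )

    def solver(self) -> SolverSettings:
        return SolverSettings(mode="fixed", dt=self.solver_dt)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if isinstance(d.get("criteria"), dict):
            c = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["criteria"].items()
            }
            d["criteria"] = CalibrationCriteria(**c)
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def simulate_scenario_population(
    population: ModelPopulation,
    scenario_id: str,
    protocol: PacingProtocol,
    solver: SolverSettings = DEFAULT_SOLVER,
    classifier: ClassifierConfig | None = None,
):
    """Simulate every model of a population under one scenario.

    Returns a list of records: (model id, SimulationResult, biomarkers or
    None, classification evidence).  A model whose simulation diverges is
    classified "other" and the study continues.
    """
    scenario = get_scenario(scenario_id)
    classifier = classifier or ClassifierConfig()
    out = []
    for mid, params in population.members:
        remodeled = apply_scenario(params, scenario)
        res = run_paced(
            remodeled, protocol, solver=solver,
            provenance={"model_id": mid, "scenario": scenario_id},
        )
        bm = None
        if not res.failed:
            bm = extract_biomarkers(res)
        ev = classify(res, classifier)
        out.append((mid, res, bm, ev))
    return out


def _mean_sd(vals):
    vals = np.asarray([v for v in vals if np.isfinite(v)], float)
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(np.mean(vals)), float(np.std(vals, ddof=1 if vals.size > 1 else 0))


def summarize_biomarkers(records, population_label: str) -> dict:
    """One biomarker-table row (mean +/- SD over models) per population."""
    row = {"population": population_label}
    fields = {
        "APD90_ms": lambda bm: bm.mean_apd90,
        "RMP_mV": lambda bm: bm.rmp,
        "CaTAm_uM": lambda bm: float(np.mean(bm.catm_amplitude)),
        "CaTAc_uM": lambda bm: float(np.mean(bm.catc_amplitude)),
        "CaT_ratio": lambda bm: bm.mean_cat_ratio,
        "CD50m_ms": lambda bm: float(np.mean(bm.cd50m)),
        "CD50c_ms": lambda bm: float(np.mean(bm.cd50c)),
        "dia_Na_mM": lambda bm: bm.diastolic_na,
    }
    for name, getter in fields.items():
        vals = [getter(bm) for _, _, bm, _ in records if bm is not None]
        m, s = _mean_sd(vals)
        row[f"{name}_mean"] = m
        row[f"{name}_sd"] = s
    return row


def summarize_categories(records, population_label: str) -> dict:
    from .classify import summarize_population

    pct = summarize_population([ev.category for _, _, _, ev in records])
    row = {"population": population_label}
    row.update({cat.value: pct[cat.value] for cat in CATEGORY_ORDER})
    return row


def run_study(config: StudyConfig) -> dict:
    """Execute the full study; returns the report as a dict of DataFrames."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("study %s -> %s", chash, outdir)

    protocol = config.protocol()
    solver = config.solver()

    if config.population_dir:
        population = ModelPopulation.load(config.population_dir)
        log.info("loaded population of %d from %s", len(population),
                 config.population_dir)
    else:
        population = build_population(
            n_candidates=config.n_candidates,
            seed=config.seed,
            criteria=config.criteria,
            protocol=protocol,
            solver=solver,
            population_size=config.population_size,
        )
        log.info("calibrated %d models from %d candidates",
                 len(population), len(population.report))
    if len(population) == 0:
        raise ConfigurationError("calibration produced an empty population")
    population.save(outdir / "population")

    bio_rows, cat_rows = [], []
    for sid in config.scenarios:
        log.info("scenario %s", sid)
        records = simulate_scenario_population(
            population, sid, protocol, solver, config.classifier
        )
        label = get_scenario(sid).name if sid != "control" else "Control"
        bio_rows.append(summarize_biomarkers(records, label))
        cat_rows.append(summarize_categories(records, label))
        sdir = outdir / f"scenario_{sid}"
        evidence = {}
        for mid, res, bm, ev in records:
            if config.save_linescans and not res.failed:
                res.save(sdir, stem=mid)
            evidence[mid] = {
                "category": ev.category.value,
                "alternans": ev.alternans,
                "silencing": ev.silencing,
                "beat_amplitudes_uM": [round(a, 5) for a in ev.beat_amplitudes],
                "beat_ratios": [round(r, 5) for r in ev.beat_ratios],
                "validity": dataclasses.asdict(ev.validity),
            }
        sdir.mkdir(parents=True, exist_ok=True)
        (sdir / "classification.json").write_text(json.dumps(evidence, indent=1))
        if config.plots:
            _plot_scenario(records, sdir)

    bio = pd.DataFrame(bio_rows)
    cat = pd.DataFrame(cat_rows)
    bio.to_csv(outdir / TABLE_BIOMARKERS, index=False)
    cat.to_csv(outdir / TABLE_CATEGORIES, index=False)
    (outdir / "provenance.json").write_text(json.dumps({
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "population_size": len(population),
    }, indent=1))
    return {"biomarkers": bio, "categories": cat, "population": population}


def _plot_scenario(records, sdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for mid, res, _, ev in records[:4]:
        if res.failed:
            continue
        fig, ax = plt.subplots(figsize=(7, 3))
        im = ax.imshow(
            res.Ca_cyto_matrix * 1e3, aspect="auto", origin="lower",
            extent=[res.t[0], res.t[-1], 0.5, res.n_domains + 0.5],
            cmap="inferno",
        )
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("domain")
        ax.set_title(f"{mid}: {ev.category.value}")
        fig.colorbar(im, label="[Ca$^{2+}$]$_i$ ($\\mu$M)")
        fig.tight_layout()
        fig.savefig(sdir / f"{mid}_linescan.png", dpi=110)
        plt.close(fig)
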