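"""Tachypacing (RAP) remodeling scenarios as multiplicative parameter scalings.

Eight named scenarios encode the cellular alterations observed in rabbit
atrial myocytes after prolonged rapid pacing: down-regulated L-type calcium
current, up-regulated Na-Ca exchanger, down-regulated Na-K pump, reduced
SERCA density, increased RyR open probability, reduced RyR density,
increased calcium buffering strength, and all seven combined.  Each scenario
is applied to a model's *own* (sampled) parameter values, so the same
remodeling can be imposed on every member of a heterogeneous population.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, ParameterError
from .model import CellParameters

_PATH_RE = re.compile(r"^(?P<name>\w+)(\[(?P<idx>\d+)\])?$")


@dataclass(frozen=True)
class Scenario:
    """A named set of multiplicative parameter scalings.

    ``scalings`` maps a parameter path (e.g. ``"GCaL"`` or ``"RyR_P[5]"``)
    to the multiplier applied to that parameter.
    """

    id: str
    name: str
    scalings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for path, mult in self.scalings.items():
            if not _PATH_RE.match(path):
                raise ConfigurationError(f"malformed parameter path: {path!r}")
            if mult <= 0:
                raise ParameterError(f"multiplier for {path} must be > 0, got {mult}")

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name, "scalings": dict(self.scalings)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(id=str(d["id"]), name=d["name"], scalings=dict(d["scalings"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


CONTROL = Scenario(id="control", name="Control (no remodeling)", scalings={})


def builtin_scenarios() -> list[Scenario]:
    """The eight remodeled-population scenarios.

    Scenario 8 is the union of the scalings of scenarios 1-7 (the scaled
    parameter sets are disjoint, so the union is unambiguous).
    """
    singles = [
        Scenario("1", "Down-regulation of ICaL", {"GCaL": 0.4}),
        Scenario("2", "Up-regulation of INCX", {"ImaxNCX": 2.5}),
        Scenario("3", "Down-regulation of INaK", {"ImaxNaK": 0.5}),
        Scenario("4", "Decreased Serca2a density", {"Jmaxup": 0.7}),
        Scenario(
            "5",
            "Increased RyR open probability",
            {"RyR_P[0]": 2.0, "RyR_P[1]": 2.0, "RyR_P[5]": 2.0},
        ),
        Scenario(
            "6", "Decreased RyR density", {"RyR_P[11]": 0.25, "NRyRs": 0.25}
        ),
        Scenario("7", "Increased calcium buffering strength", {"Buff_factor": 0.15}),
    ]
    merged: dict[str, float] = {}
    for sc in singles:
        overlap = merged.keys() & sc.scalings.keys()
        if overlap:  # defensive: Table-defined scenarios are disjoint
            raise ConfigurationError(f"conflicting scalings for {sorted(overlap)}")
        merged.update(sc.scalings)
    return singles + [Scenario("8", "Full RAP remodeling", merged)]


def get_scenario(scenario_id: str) -> Scenario:
    """Look up a builtin scenario by id ('1'..'8' or 'control')."""
    if str(scenario_id) == "control":
        return CONTROL
    for sc in builtin_scenarios():
        if sc.id == str(scenario_id):
            return sc
    raise ConfigurationError(f"unknown scenario id: {scenario_id!r}")


def apply_scenario(params: CellParameters, scenario: Scenario) -> CellParameters:
    """Return a new parameter set with the scenario's multipliers applied.

    Parameters not named in the scenario are carried over bit-identical;
    the input is not mutated.
    """
    new = params.copy()
    ryr = list(new.RyR_P)
    for path, mult in scenario.scalings.items():
        m = _PATH_RE.match(path)
        name, idx = m.group("name"), m.group("idx")
        if idx is not None:
            if name != "RyR_P" or int(idx) >= len(ryr):
                raise ConfigurationError(f"unknown parameter path: {path!r}")
            ryr[int(idx)] = ryr[int(idx)] * mult
        else:
            if name not in CellParameters._SCALE_FIELDS:
                raise ConfigurationError(f"unknown parameter path: {path!r}")
            setattr(new, name, getattr(new, name) * mult)
    new.RyR_P = tuple(ryr)
    new.validate()
    return new
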