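"""Ready-to-run experiment configurations and the smooth load program.

Two built-in scenarios:

* ``cantilever`` — left short edge clamped, uniform tangential traction on
  the right edge ramped smoothly to tau0 = 1.25e5 N/m over T_s = 60480 s;
* ``three_point`` — half specimen with the symmetry condition u1 = 0 on the
  midline edge, one fixed support pin under the lower face at half the
  137.5 mm span, and a loading pin descending from the top midline by a
  ramped 2 mm.

Configurations are plain nested dictionaries (YAML round-trippable); all
default values reproduce the printed parameter set in
:mod:`osteoadapt.defaults` exactly.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Any

import numpy as np
import yaml

from osteoadapt import defaults
from osteoadapt.constitutive import ModuliSet
from osteoadapt.evolution import CoupledProblem, RemodelingParams
from osteoadapt.fem import BoundarySpec, ContactPin, build_mesh
from osteoadapt.stimulus import StimulusParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoadProgram:
    """Smooth ramp from zero to a held amplitude.

    value(t) = A [t/T_s - sin(2 pi t/T_s)/(2 pi)] for t < T_s, else A.
    C1-smooth at t = T_s; the amplitude is a traction line density [N/m]
    in ``traction`` mode or a pin displacement [m] in ``pin-displacement``
    mode.
    """

    amplitude: float
    T_s: float
    mode: str = "traction"

    def __post_init__(self) -> None:
        if self.T_s <= 0:
            raise ValueError("ramp duration must be positive")
        if self.mode not in ("traction", "pin-displacement"):
            raise ValueError(f"unknown load mode {self.mode!r}")

    def value(self, t):
        return load_ramp(t, self)

    def scale(self, t):
        """Ramp factor in [0, 1] (value / amplitude)."""
        return load_ramp(t, self) / self.amplitude if self.amplitude else 0.0


def load_ramp(t, program: LoadProgram):
    """Evaluate the load program at time(s) t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("load program is defined for t >= 0")
    x = t / program.T_s
    ramp = program.amplitude * (x - np.sin(2.0 * np.pi * x) / (2.0 * np.pi))
    out = np.where(x >= 1.0, program.amplitude, ramp)
    return float(out) if out.ndim == 0 else out


def _base_config() -> dict[str, Any]:
    return {
        "geometry": {**defaults.GEOMETRY_M, "thickness": defaults.SECTION_THICKNESS},
        "mesh": {"nx": 30, "ny": 10, "degree": 2},
        "material": {
            "moduli_gpa": dict(defaults.REFERENCE_MODULI_GPA),
            "second_gradient_n": defaults.SECOND_GRADIENT_STIFFNESS_N,
        },
        "evolution": {
            **dict(defaults.REORIENTATION_PARAMS),
            "chi": 0,
            "floor_frac": 0.01,
            "stiffness": copy.deepcopy(defaults.STIFFNESS_EVOLUTION_PARAMS),
        },
        "stimulus": copy.deepcopy(defaults.STIMULUS_PARAMS),
        "initial_psi": 0.0,
        "schedule": {
            "dt": defaults.RAMP_DURATION / 100.0,
            "dt_max": None,
            "horizon": 2.0 * defaults.RAMP_DURATION,
            "snapshot_every": None,
            "steady_tol": 1e-8,
            "scaled": 1.0,
        },
    }


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


@dataclass
class ScenarioConfig:
    """A fully specified scenario: plain-data dictionary plus builders."""

    name: str
    data: dict[str, Any]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {"name": self.name, **copy.deepcopy(self.data)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = copy.deepcopy(d)
        name = d.pop("name", "custom")
        return cls(name=name, data=d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"malformed scenario file {path!r}")
        return cls.from_dict(d)

    # -- typed accessors ---------------------------------------------------
    def build_moduli(self, validate: bool = True) -> ModuliSet:
        mat = self.data["material"]
        p = ModuliSet.from_gpa(
            mat["moduli_gpa"], mat.get("second_gradient_n", 0.0), validate=validate
        )
        if validate:
            diag = p.diagonal_coefficients() / 1e9
            logger.info(
                "admissibility check passed; quadratic-form diagonal "
                "coefficients: %.4g / %.4g / %.4g GPa",
                *diag,
            )
        return p

    def load_program(self) -> LoadProgram:
        ld = self.data["load"]
        return LoadProgram(
            amplitude=ld["amplitude"], T_s=ld["T_s"], mode=ld["mode"]
        )

    def remodeling_params(self) -> RemodelingParams:
        ev = self.data["evolution"]
        scaled = float(self.data["schedule"].get("scaled", 1.0))
        stiff = ev["stiffness"]
        return RemodelingParams(
            c_gamma=ev["c_gamma"] / scaled,
            tau_gamma=ev["tau_gamma"],
            c_p={k: v["c_p"] / scaled for k, v in stiff.items()},
            tau_p={k: v["tau_p"] for k, v in stiff.items()},
            chi=int(ev.get("chi", 0)),
            floor_frac=float(ev.get("floor_frac", 0.01)),
        )

    def stimulus_params(self) -> dict[str, StimulusParams]:
        stim = self.data["stimulus"]
        stiff = self.data["evolution"]["stiffness"]
        return {
            name: StimulusParams(
                d=pars["d"], kappa=pars["kappa"], R=pars["R"], S0=stiff[name]["S0"]
            )
            for name, pars in stim.items()
        }

    def boundary_spec(self) -> BoundarySpec:
        bc = self.data["bcs"]
        program = self.load_program()
        tractions = []
        if program.mode == "traction":
            ld = self.data["load"]
            direction = np.asarray(ld["direction"], dtype=float)
            thickness = float(self.data["geometry"].get("thickness", 1.0))
            # the printed amplitude is a line density [N/m] on the edge of a
            # slab of the configured through-thickness; the 2D (per unit
            # thickness) traction is amplitude / thickness
            tractions.append(
                (ld["edge"], tuple(program.amplitude / thickness * direction))
            )
        return BoundarySpec(
            fixed=tuple((e, tuple(c)) for e, c in bc.get("fixed", [])),
            tractions=tuple(tractions),
        )

    def build_pins(self) -> list[ContactPin]:
        pins = []
        program = self.load_program()
        for spec in self.data.get("pins", []):
            motion = None
            if spec.get("moving", False):
                if program.mode != "pin-displacement":
                    raise ValueError("moving pin requires a pin-displacement load program")
                motion = lambda t, p=program: np.array([0.0, -p.value(t)])
            pins.append(
                ContactPin(
                    center=np.asarray(spec["center"], dtype=float),
                    radius=float(spec["radius"]),
                    penalty=float(spec["penalty"]),
                    edge=spec["edge"],
                    motion=motion,
                )
            )
        return pins

    def support_span(self) -> float | None:
        """Center-to-center distance of the two support pins of the full
        (mirrored) specimen [m]; None when the scenario has no supports."""
        for spec in self.data.get("pins", []):
            if not spec.get("moving", False):
                return 2.0 * float(spec["center"][0])
        return None

    def build_problem(self) -> CoupledProblem:
        geo = self.data["geometry"]
        mesh_cfg = self.data["mesh"]
        moduli = self.build_moduli()
        has_sg = self.data["material"].get("second_gradient_n", 0.0) > 0
        mesh = build_mesh(
            geo["Lx"],
            geo["Ly"],
            mesh_cfg["nx"],
            mesh_cfg["ny"],
            degree=mesh_cfg.get("degree", 2),
            n_gauss=mesh_cfg.get("n_gauss"),
            second_gradient=has_sg,
        )
        program = self.load_program()
        return CoupledProblem(
            mesh=mesh,
            boundary=self.boundary_spec(),
            pins=self.build_pins(),
            moduli=moduli,
            stimulus_params=self.stimulus_params(),
            remodeling=self.remodeling_params(),
            load_scale=program.scale,
            psi0=float(self.data.get("initial_psi", 0.0)),
        )

    def schedule(self) -> dict[str, Any]:
        return dict(self.data["schedule"])


def cantilever_scenario(overrides: dict[str, Any] | None = None) -> ScenarioConfig:
    """Cantilever bending: clamped left edge, ramped uniform shear traction
    on the right edge, initial material axes parallel to the sides."""
    cfg = _base_config()
    cfg["load"] = {
        "mode": "traction",
        "amplitude": defaults.TRACTION_AMPLITUDE,
        "T_s": defaults.RAMP_DURATION,
        "edge": "right",
        "direction": [0.0, -1.0],
    }
    cfg["bcs"] = {"fixed": [["left", [0, 1]]]}
    cfg["pins"] = []
    if overrides:
        _deep_update(cfg, overrides)
    return ScenarioConfig(name="cantilever", data=cfg)


def three_point_scenario(overrides: dict[str, Any] | None = None) -> ScenarioConfig:
    """Three-point flexure on the half domain.

    The modeled rectangle is the right half of the specimen; the midline
    (left edge) carries the symmetry condition u1 = 0. The support pin sits
    under the lower face at half the configured span from the midline
    (touching at t = 0); the loading pin starts tangent to the top face on
    the midline and descends by the ramped displacement amplitude. Pin radius
    and penalty stiffness are not part of the printed data; the defaults
    below are recorded in the run metadata.
    """
    cfg = _base_config()
    Lx = cfg["geometry"]["Lx"]
    Ly = cfg["geometry"]["Ly"]
    span = defaults.SPAN_RATIO * Lx  # full support span, 0.1375 m
    radius = 0.005
    penalty = 1.0e3 * max(cfg["material"]["moduli_gpa"].values()) * 1e9  # [Pa/m]
    cfg["load"] = {
        "mode": "pin-displacement",
        "amplitude": defaults.PIN_DISPLACEMENT_AMPLITUDE,
        "T_s": defaults.RAMP_DURATION,
    }
    cfg["bcs"] = {"fixed": [["left", [0]]]}
    cfg["pins"] = [
        {
            "center": [span / 2.0, -radius],
            "radius": radius,
            "penalty": penalty,
            "edge": "bottom",
            "moving": False,
        },
        {
            "center": [0.0, Ly + radius],
            "radius": radius,
            "penalty": penalty,
            "edge": "top",
            "moving": True,
        },
    ]
    if overrides:
        _deep_update(cfg, overrides)
    return ScenarioConfig(name="three_point", data=cfg)


SCENARIOS = {
    "cantilever": cantilever_scenario,
    "three_point": three_point_scenario,
}
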