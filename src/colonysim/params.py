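"""Parameter registry, configuration loading and validation.

All quantities are kept in a fixed internal unit system: lengths in
micrometres, time in hours, concentrations in mM (mmol per litre), biomass
in grams dry weight (gdw).  Diffusivities are *entered* in the conventional
um^2/s and converted to um^2/h internally by the solver.  Config files must
use these units; no unit inference is performed.

Each default is tagged with its provenance: ``"measured"`` for values printed
in the primary literature on E. coli colony physiology, ``"literature-default"``
for standard E. coli physiology numbers adopted where no direct measurement
is shipped.  ``load_config`` logs, for every key, whether the value came from
the shipped default or from the user file.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("colonysim")

__all__ = [
    "ParameterSet",
    "Violation",
    "load_config",
    "save_config",
    "validate_params",
    "PARAM_REGISTRY",
]


@dataclass(frozen=True)
class ParamInfo:
    section: str
    unit: str
    source: str  # "measured" | "literature-default" | "numerical"
    doc: str


#: metadata for every ParameterSet field: section, unit, provenance, meaning
PARAM_REGISTRY: dict[str, ParamInfo] = {
    # --- metabolism ------------------------------------------------------
    "lambda_g_aer": ParamInfo("metabolism", "1/h", "literature-default",
                              "maximal aerobic growth rate on glucose"),
    "lambda_g_ana": ParamInfo("metabolism", "1/h", "literature-default",
                              "maximal anaerobic (fermentative) growth rate on glucose"),
    "lambda_a_aer": ParamInfo("metabolism", "1/h", "measured",
                              "maximal aerobic growth rate on acetate"),
    "K_g": ParamInfo("metabolism", "mM", "literature-default",
                     "Monod constant for glucose"),
    "K_o": ParamInfo("metabolism", "mM", "literature-default",
                     "Monod constant for oxygen"),
    "K_a": ParamInfo("metabolism", "mM", "measured",
                     "Monod constant for acetate (batch-culture fit, ~5 mM)"),
    "D_g_agar": ParamInfo("metabolism", "um^2/s", "literature-default",
                          "glucose diffusivity in agar"),
    "D_g_colony": ParamInfo("metabolism", "um^2/s", "literature-default",
                            "effective glucose diffusivity inside the colony"),
    "D_o_agar": ParamInfo("metabolism", "um^2/s", "literature-default",
                          "oxygen diffusivity in agar"),
    "D_o_colony": ParamInfo("metabolism", "um^2/s", "literature-default",
                            "effective oxygen diffusivity inside the colony"),
    "D_a_agar": ParamInfo("metabolism", "um^2/s", "literature-default",
                          "acetate diffusivity in agar"),
    "D_a_colony": ParamInfo("metabolism", "um^2/s", "literature-default",
                            "effective acetate diffusivity inside the colony"),
    "q_g_aer": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                         "glucose uptake per unit aerobic biomass growth (1/yield)"),
    "q_g_ana": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                         "glucose uptake per unit anaerobic biomass growth"),
    "q_o_g": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                       "oxygen uptake per unit aerobic growth on glucose"),
    "q_o_a": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                       "oxygen uptake per unit aerobic growth on acetate"),
    "p_a_aer": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                         "overflow acetate excretion per unit aerobic growth on glucose"),
    "p_a_ana": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                         "fermentative acetate excretion per unit anaerobic growth"),
    "q_a_aer": ParamInfo("metabolism", "mmol/gdw", "literature-default",
                         "acetate uptake per unit aerobic growth on acetate"),
    "m_carbon": ParamInfo("metabolism", "mmol C/gdw/h", "literature-default",
                          "maintenance carbon flux requirement"),
    "acetate_per_glucose_maint": ParamInfo(
        "metabolism", "mol/mol", "measured",
        "acetate excreted per glucose consumed anaerobically for maintenance"),
    "rho_cell": ParamInfo("metabolism", "gdw/L", "literature-default",
                          "biomass density of close-packed colony material"),
    "C_o_ambient": ParamInfo("metabolism", "mM", "literature-default",
                             "Dirichlet oxygen concentration at air-facing surfaces"),
    "C_g_init": ParamInfo("metabolism", "mM", "measured",
                          "initial glucose concentration in agar"),
    "C_a_init": ParamInfo("metabolism", "mM", "measured",
                          "initial acetate concentration in agar"),
    "delta_aer": ParamInfo("metabolism", "1/day", "measured",
                           "death rate under aerobic carbon starvation (~0.2/day)"),
    "delta_ana": ParamInfo("metabolism", "1/day", "measured",
                           "death rate under anaerobic carbon starvation (~2/day)"),
    "growth_threshold": ParamInfo("metabolism", "1/h", "measured",
                                  "growing/non-growing classification rate (0.01/h)"),
    # --- mechanics -------------------------------------------------------
    "r0": ParamInfo("mechanics", "um", "literature-default", "cell radius"),
    "l_div": ParamInfo("mechanics", "um", "literature-default",
                       "cylinder length at which a cell divides"),
    "div_noise": ParamInfo("mechanics", "fraction", "numerical",
                           "uniform noise fraction on the division length"),
    "k_cc": ParamInfo("mechanics", "F/um^2", "numerical",
                      "Hertzian cell-cell contact stiffness"),
    "k_ca": ParamInfo("mechanics", "F/um^2", "numerical",
                      "Hertzian cell-agar contact stiffness"),
    "zeta": ParamInfo("mechanics", "F*h/um^2", "numerical",
                      "viscous drag coefficient per unit cell length"),
    "k_surface": ParamInfo("mechanics", "F/um", "numerical",
                           "surface-tension spring constant on protruding caps"),
    "f_settle": ParamInfo("mechanics", "F/um", "numerical",
                          "settling (gravity-like) force per unit cell length"),
    "angle_kick": ParamInfo("mechanics", "rad", "numerical",
                            "random angle perturbation applied to daughters"),
    # --- numerics --------------------------------------------------------
    "h_grid": ParamInfo("numerics", "um", "numerical", "PDE grid spacing"),
    "dt_macro": ParamInfo("numerics", "min", "numerical",
                          "macro (growth/PDE coupling) time step"),
    "n_mech_sub": ParamInfo("numerics", "count", "numerical",
                            "mechanics substeps per macro step"),
    "pde_tol": ParamInfo("numerics", "relative", "numerical",
                         "early-exit tolerance for the metabolite sub-steps"),
    "pde_max_iter": ParamInfo("numerics", "count", "numerical",
                              "cap on metabolite solver iterations"),
    "domain_width": ParamInfo("numerics", "um", "numerical",
                              "lateral extent of the computational domain"),
    "agar_depth": ParamInfo("numerics", "um", "numerical",
                            "depth of the agar region below z=0"),
    "air_height": ParamInfo("numerics", "um", "numerical",
                            "height of the air gap above z=0"),
    # --- run -------------------------------------------------------------
    "seed": ParamInfo("run", "integer", "numerical",
                      "global RNG seed; every stochastic draw flows from it"),
}


@dataclass
class ParameterSet:
    """All metabolic, mechanical, numerical and death-model constants.

    Growth follows three modes: aerobic growth on glucose, anaerobic
    (fermentative) growth on glucose, and aerobic growth on acetate, each
    with Monod kinetics and a maintenance-shifted threshold.  See
    :mod:`colonysim.metabolism` for how the fields combine.
    """

    # metabolism
    lambda_g_aer: float = 1.0
    lambda_g_ana: float = 0.55
    lambda_a_aer: float = 0.4
    K_g: float = 0.1
    K_o: float = 0.02
    K_a: float = 5.0
    D_g_agar: float = 600.0
    D_g_colony: float = 40.0
    D_o_agar: float = 2000.0
    D_o_colony: float = 300.0
    D_a_agar: float = 900.0
    D_a_colony: float = 100.0
    q_g_aer: float = 11.0
    q_g_ana: float = 37.0
    q_o_g: float = 30.0
    q_o_a: float = 80.0
    p_a_aer: float = 4.0
    p_a_ana: float = 40.0
    q_a_aer: float = 55.0
    m_carbon: float = 1.5
    acetate_per_glucose_maint: float = 2.0
    rho_cell: float = 300.0
    C_o_ambient: float = 0.25
    C_g_init: float = 20.0
    C_a_init: float = 0.0
    delta_aer: float = 0.2
    delta_ana: float = 2.0
    growth_threshold: float = 0.01
    # mechanics
    r0: float = 0.5
    l_div: float = 4.0
    div_noise: float = 0.1
    k_cc: float = 2.0e3
    k_ca: float = 6.0e3
    zeta: float = 0.5
    k_surface: float = 500.0
    f_settle: float = 6.0
    angle_kick: float = 0.01
    # numerics
    h_grid: float = 5.0
    dt_macro: float = 2.0
    n_mech_sub: int = 40
    pde_tol: float = 1.0e-6
    pde_max_iter: int = 100_000
    domain_width: float = 10_000.0
    agar_depth: float = 8_000.0
    air_height: float = 60.0
    # run
    seed: int = 0

    def replace(self, **kwargs: Any) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_sections(self) -> dict[str, dict[str, Any]]:
        """Group the flat fields by config section."""
        out: dict[str, dict[str, Any]] = {}
        for f in fields(self):
            sec = PARAM_REGISTRY[f.name].section
            out.setdefault(sec, {})[f.name] = getattr(self, f.name)
        return out

    def rng(self):
        import numpy as np

        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, its value, the violated bound."""

    field: str
    value: float
    bound: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates {self.bound}"


_NONNEG_OK = {"C_a_init", "seed", "f_settle", "angle_kick", "p_a_aer", "div_noise"}


def validate_params(p: ParameterSet) -> list[Violation]:
    """Check every ParameterSet invariant; empty list means all hold.

    Always returns (never raises); each entry names the failing field, its
    value and the bound it violates.
    """
    v: list[Violation] = []
    for f in fields(p):
        if f.name == "seed":
            continue
        val = getattr(p, f.name)
        if f.name in _NONNEG_OK:
            if val < 0:
                v.append(Violation(f.name, val, ">= 0"))
        elif not (isinstance(val, (int, float)) and val > 0):
            v.append(Violation(f.name, val, "> 0"))
    if p.delta_ana < p.delta_aer:
        v.append(Violation("delta_ana", p.delta_ana,
                           f">= delta_aer ({p.delta_aer}); anaerobic starvation kills faster"))
    lam_min = min(p.lambda_g_aer, p.lambda_g_ana, p.lambda_a_aer)
    if not p.growth_threshold < lam_min:
        v.append(Violation("growth_threshold", p.growth_threshold,
                           f"< min of maximal growth rates ({lam_min})"))
    if not -math.isinf(p.m_carbon):  # keep static analyzers honest about floats
        pass
    return v


class ConfigError(ValueError):
    """Raised for missing files, schema violations and invariant violations."""


_SECTIONS = ("metabolism", "mechanics", "numerics", "run")


def _flatten(doc: dict[str, Any], path: Path) -> dict[str, Any]:
    """Accept either flat keys or keys grouped under the four sections."""
    flat: dict[str, Any] = {}
    for key, val in doc.items():
        if key in _SECTIONS:
            if val is None:
                continue
            if not isinstance(val, dict):
                raise ConfigError(f"{path}: section {key!r} must be a mapping")
            for k2, v2 in val.items():
                flat[k2] = v2
        else:
            flat[key] = val
    return flat


def load_config(path: str | Path) -> ParameterSet:
    """Load a YAML config file into a validated :class:`ParameterSet`.

    Unspecified keys take the shipped defaults.  Every value is logged with
    its source (``default`` vs ``user``).  Raises :class:`ConfigError` on a
    missing file, an unknown key, a non-numeric value, or any invariant
    violation (reported with the failing key and bound).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(doc).__name__}")
    flat = _flatten(doc, path)

    valid = {f.name: f for f in fields(ParameterSet)}
    kwargs: dict[str, Any] = {}
    for key, val in flat.items():
        if key not in valid:
            raise ConfigError(f"{path}: unknown parameter {key!r}")
        if key in ("seed", "n_mech_sub", "pde_max_iter"):
            if not isinstance(val, int):
                raise ConfigError(f"{path}: {key} must be an integer, got {val!r}")
        elif not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ConfigError(f"{path}: {key} must be a number, got {val!r}")
        kwargs[key] = val

    p = ParameterSet(**kwargs)
    for name in valid:
        src = "user" if name in kwargs else "default"
        logger.debug("param %-28s = %-12r [%s, %s]", name, getattr(p, name), src,
                     PARAM_REGISTRY[name].source)
    bad = validate_params(p)
    if bad:
        raise ConfigError("invalid parameters: " + "; ".join(str(b) for b in bad))
    return p


def save_config(p: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet as a sectioned YAML document (round-trip safe)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(p.to_sections(), sort_keys=False))
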