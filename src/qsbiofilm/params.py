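"""Model and numerical parameters.

``ModelParameters`` carries every rate, diffusivity and geometry constant of the
dispersal model; ``NumericalSettings`` carries the discretization knobs. Both are
plain dataclasses; validation is explicit (:func:`validate_parameters`,
:func:`validate_settings`) and is always applied on the config-file path, so that
programmatic construction of deliberately off-manifold parameter sets (e.g. for
numerical benchmarks) remains possible.

Configuration files are YAML with three optional sections::

    model:     {mu: 6.0, tau: 20.0, ...}     # keys = ModelParameters fields
    numerics:  {nx: 128, dt: 1.0e-3, ...}    # keys = NumericalSettings fields
    inoculum:  {n_colonies: 6, density: 0.3, seed: 7, ...}

Unspecified keys take the documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ModelParameters",
    "NumericalSettings",
    "ConfigError",
    "default_parameters",
    "validate_parameters",
    "validate_settings",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised when a configuration file or parameter set is invalid.

    The message always names the offending key.
    """


@dataclass
class ModelParameters:
    """Physical parameters of the dispersal model.

    Rates are per day, concentrations in g/m^3 (nutrient) or nM (autoinducer),
    diffusivities in m^2/d, lengths in m. Sessile biomass M is a volume
    fraction in [0, 1); dispersed biomass N is carried on the same
    volume-fraction scale (density N * M_inf).
    """

    mu: float = 6.0        # maximum specific growth rate, 1/d
    Y: float = 0.63        # yield coefficient, -
    k1: float = 4.0        # half-saturation for growth, g/m^3
    k2: float = 0.05       # 1st threshold in gamma(C), g/m^3 (reserved)
    k3: float = 0.1        # 2nd threshold in gamma(C), g/m^3 (reserved)
    k4: float = 0.4        # lysis rate, 1/d
    k5: float = 0.7        # half-saturation density for re-attachment, g/m^3
    M_inf: float = 1.0e4   # maximum cell density, g/m^3
    eta1: float = 3.6      # maximum dispersal rate, 1/d
    eta2: Optional[float] = None  # maximum re-attachment rate, 1/d; None -> 0.5*eta1
    tau: float = 50.0      # quorum-sensing induction threshold, nM
    alpha: float = 0.5520  # constitutive autoinducer production, nM m^3 / (g d)
    beta: float = 5.5200   # induced autoinducer production, nM m^3 / (g d)
    n: float = 2.5         # Hill exponent (degree of polymerization), -
    dA0: float = 7.8e-5    # autoinducer diffusivity in water, m^2/d
    dA1: float = 3.9e-5    # autoinducer diffusivity in biofilm, m^2/d
    dC0: float = 1.0e-4    # nutrient diffusivity in water, m^2/d
    dC1: float = 8.0e-5    # nutrient diffusivity in biofilm, m^2/d
    dN0: float = 1.0e-4    # dispersed-cell diffusivity in water, m^2/d
    dN1: float = 2.0e-5    # dispersed-cell diffusivity in biofilm, m^2/d
    delta: float = 1.0e-12  # biomass motility coefficient, m^2/d
    a: float = 4.0         # degenerate diffusion exponent, -
    b: float = 4.0         # singular diffusion exponent, -
    L: float = 4.0e-3      # system length, m
    H: float = 1.6e-3      # system height, m
    eps: float = 1.0e-12   # asymptote parameter for gamma_3/gamma_4, - (reserved)
    C_inf: float = 25.0    # bulk nutrient concentration at the top boundary, g/m^3
    gamma_mode: str = "constant_one"  # nutrient modulation of A production
    k5_scale: str = "fraction"  # "fraction": compare M with k5; "density": compare M*M_inf

    def __post_init__(self) -> None:
        if self.eta2 is None:
            self.eta2 = 0.5 * self.eta1


@dataclass
class NumericalSettings:
    """Discretization and run-control settings (artifact plumbing, not physics)."""

    nx: int = 256             # grid cells along x (length L)
    ny: int = 128             # grid cells along y (height H)
    dt: float = 1.0e-3        # fixed time step, d
    t_end: float = 20.0       # maximum simulated time, d
    target_size: float = 1.0  # omega value triggering early termination
    solver_tol: float = 1.0e-10   # relative residual tolerance of the linear solves
    solver_maxit: int = 1000      # iteration cap per linear solve
    omega_threshold: float = 1.0e-3  # M cutoff defining the biofilm region Omega_2
    m_cap: float = 0.99       # cap on M inside D_M to avoid the singularity
    output_every: float = 0.05      # observable sampling interval, d
    seed: int = 42                  # RNG seed (inoculum placement)
    max_halvings: int = 8           # bounded dt-halving retries on solver failure


_POSITIVE_OR_ZERO = (
    "mu", "Y", "k1", "k2", "k3", "k4", "k5", "M_inf", "eta1", "eta2", "tau",
    "alpha", "beta", "n", "dA0", "dA1", "dC0", "dC1", "dN0", "dN1",
    "L", "H", "eps", "C_inf",
)


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Check all model-parameter invariants; raise :class:`ConfigError` naming the key."""
    for key in _POSITIVE_OR_ZERO:
        v = getattr(p, key)
        if not isinstance(v, (int, float)):
            raise ConfigError(f"parameter '{key}' must be numeric, got {v!r}")
        if not (v >= 0):  # also rejects NaN
            raise ConfigError(f"parameter '{key}' must be >= 0, got {v!r}")
    if not p.delta > 0:
        raise ConfigError(f"parameter 'delta' must be > 0, got {p.delta!r}")
    if not p.a > 1:
        raise ConfigError(f"parameter 'a' must be > 1, got {p.a!r}")
    if not p.b > 1:
        raise ConfigError(f"parameter 'b' must be > 1, got {p.b!r}")
    if not (0 < p.Y <= 1):
        raise ConfigError(f"parameter 'Y' must lie in (0, 1], got {p.Y!r}")
    for biofilm, water in (("dA1", "dA0"), ("dC1", "dC0"), ("dN1", "dN0")):
        if getattr(p, biofilm) > getattr(p, water):
            raise ConfigError(
                f"parameter '{biofilm}' must not exceed '{water}' "
                f"(diffusion is reduced in the biofilm)"
            )
    if p.L <= 0 or p.H <= 0:
        key = "L" if p.L <= 0 else "H"
        raise ConfigError(f"parameter '{key}' must be > 0")
    if p.gamma_mode not in ("constant_one", "user_hook"):
        raise ConfigError(f"parameter 'gamma_mode' unknown: {p.gamma_mode!r}")
    if p.k5_scale not in ("density", "fraction"):
        raise ConfigError(f"parameter 'k5_scale' unknown: {p.k5_scale!r}")
    return p


def validate_settings(s: NumericalSettings) -> NumericalSettings:
    """Check numerical-settings invariants; raise :class:`ConfigError` naming the key."""
    if s.nx < 8:
        raise ConfigError(f"setting 'nx' must be >= 8, got {s.nx!r}")
    if s.ny < 8:
        raise ConfigError(f"setting 'ny' must be >= 8, got {s.ny!r}")
    if not s.dt > 0:
        raise ConfigError(f"setting 'dt' must be > 0, got {s.dt!r}")
    if s.t_end < 0:
        raise ConfigError(f"setting 't_end' must be >= 0, got {s.t_end!r}")
    if not (0 < s.omega_threshold < 0.1):
        raise ConfigError(
            f"setting 'omega_threshold' must lie in (0, 0.1), got {s.omega_threshold!r}"
        )
    if not (0 < s.m_cap < 1):
        raise ConfigError(f"setting 'm_cap' must lie in (0, 1), got {s.m_cap!r}")
    if not s.solver_tol > 0:
        raise ConfigError(f"setting 'solver_tol' must be > 0, got {s.solver_tol!r}")
    if s.solver_maxit < 1:
        raise ConfigError(f"setting 'solver_maxit' must be >= 1, got {s.solver_maxit!r}")
    if not s.output_every > 0:
        raise ConfigError(f"setting 'output_every' must be > 0, got {s.output_every!r}")
    return s


def default_parameters(**overrides) -> ModelParameters:
    """Return the default parameter set, optionally overriding individual fields.

    Defaults are the published values for this model family; where a range is
    customary (eta1 in 0.6-4.2/d, tau in 10-70 nM) the default picks the value
    used by the main simulation experiments (eta1=3.6/d, tau=50 nM). eta2
    defaults to 0.5*eta1 whenever not overridden explicitly.
    """
    p = _build(ModelParameters, overrides, what="parameter")
    return validate_parameters(p)


def default_settings(**overrides) -> NumericalSettings:
    s = _build(NumericalSettings, overrides, what="setting")
    return validate_settings(s)


def _build(cls, mapping: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown {what} key(s): {sorted(unknown)}")
    return cls(**mapping)


def load_config(path):
    """Load a YAML scenario configuration.

    Returns ``(ModelParameters, NumericalSettings, InoculumSpec)``. Missing
    sections or keys take defaults; any invariant violation raises
    :class:`ConfigError` naming the offending key.
    """
    from .inoculum import InoculumSpec  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"model", "numerics", "inoculum"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    params = default_parameters(**(raw.get("model") or {}))
    settings = default_settings(**(raw.get("numerics") or {}))
    ino_raw = dict(raw.get("inoculum") or {})
    pockets = ino_raw.pop("pockets", None)
    if pockets is not None:
        ino_raw["pockets"] = [tuple(pk) for pk in pockets]
    if "width_range" in ino_raw:
        ino_raw["width_range"] = tuple(ino_raw["width_range"])
    ino = _build(InoculumSpec, ino_raw, what="inoculum")
    ino.validate(params)
    return params, settings, ino


def save_config(path, params: ModelParameters, settings: NumericalSettings, inoculum=None) -> None:
    """Serialize a full configuration; ``load_config`` round-trips it bit-exactly."""
    doc = {
        "model": dataclasses.asdict(params),
        "numerics": dataclasses.asdict(settings),
    }
    if inoculum is not None:
        d = dataclasses.asdict(inoculum)
        if d.get("pockets") is not None:
            d["pockets"] = [list(pk) for pk in d["pockets"]]
        d["width_range"] = list(d["width_range"])
        doc["inoculum"] = d
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
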