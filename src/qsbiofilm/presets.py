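"""The four canonical simulation experiments as ready-made scenario presets.

Each preset bundles model-parameter overrides, an inoculum specification and
a time horizon:

* ``preset_tau_sweep``            — seven induction thresholds tau = 10..70 nM at
  eta1 = 3.6/d, plus a non-quorum-sensing control (alpha = beta = 0);
* ``preset_constant_dispersal``   — constant dispersal (tau = 0) versus
  quorum-sensing induced dispersal (tau = 50 nM), both at eta1 = 2.4/d;
* ``preset_reattachment_corners`` — the four (tau, eta1) corner scenarios
  tau in {10, 70} nM x eta1 in {0.6, 4.2}/d, for the re-attachment ratio Z;
* ``preset_k5_sweep``             — re-attachment half-saturation k5 = 0.1..0.7 g/m^3
  at tau = 10 nM, eta1 = 3.6/d;
* ``preset_hollowing``            — the discrete-events (tau = 20 nM) and
  continuous-dispersal (tau = 60 nM) runs at eta1 = 3.6/d on a shared inoculum.

All presets share the default six-colony seeded inoculum (density 0.3,
half-discs on the substratum) and gamma(C) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .grid import Grid
from .inoculum import InoculumSpec, generate_inoculum
from .params import (ModelParameters, NumericalSettings, default_parameters,
                     default_settings, validate_parameters)

__all__ = [
    "ScenarioPreset",
    "preset_tau_sweep",
    "preset_constant_dispersal",
    "preset_reattachment_corners",
    "preset_k5_sweep",
    "preset_hollowing",
    "PRESET_GROUPS",
]


@dataclass
class ScenarioPreset:
    """A named, fully specified simulation scenario."""

    name: str
    overrides: dict = field(default_factory=dict)
    inoculum: InoculumSpec = field(default_factory=InoculumSpec)
    t_end: float = 20.0
    target_size: float = 1.0

    def __post_init__(self):
        validate_parameters(self.parameters())

    def parameters(self) -> ModelParameters:
        ov = dict(self.overrides)
        if "eta1" in ov and "eta2" not in ov:
            ov["eta2"] = 0.5 * ov["eta1"]
        p = ModelParameters(**ov)
        return p

    def settings(self, **numeric_overrides) -> NumericalSettings:
        kw = {"t_end": self.t_end, "target_size": self.target_size}
        kw.update(numeric_overrides)
        return default_settings(**kw)

    def materialize(self, seed: Optional[int] = None, **numeric_overrides):
        """Build (params, settings, grid, initial_state) for this preset."""
        params = validate_parameters(self.parameters())
        settings = self.settings(**numeric_overrides)
        if seed is not None:
            settings.seed = seed
        grid = Grid(nx=settings.nx, ny=settings.ny, L=params.L, H=params.H)
        initial = generate_inoculum(self.inoculum, grid, params, seed=settings.seed)
        return params, settings, grid, initial


def _inoculum(seed: Optional[int]) -> InoculumSpec:
    return InoculumSpec(n_colonies=6, density=0.3, seed=seed)


def preset_tau_sweep(seed: Optional[int] = None) -> list[ScenarioPreset]:
    """Seven threshold values plus the non-quorum-sensing control: 8 runs."""
    taus = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
    presets = [
        ScenarioPreset(name=f"tau_sweep/tau{int(tau)}",
                       overrides={"tau": tau, "eta1": 3.6},
                       inoculum=_inoculum(seed))
        for tau in taus
    ]
    presets.append(ScenarioPreset(name="tau_sweep/non_qs",
                                  overrides={"alpha": 0.0, "beta": 0.0, "eta1": 3.6},
                                  inoculum=_inoculum(seed)))
    return presets


def preset_constant_dispersal(seed: Optional[int] = None) -> list[ScenarioPreset]:
    """Constant dispersal (tau = 0) vs QS-induced (tau = 50 nM), eta1 = 2.4/d."""
    return [
        ScenarioPreset(name="constant_dispersal/tau0",
                       overrides={"tau": 0.0, "eta1": 2.4},
                       inoculum=_inoculum(seed)),
        ScenarioPreset(name="constant_dispersal/tau50",
                       overrides={"tau": 50.0, "eta1": 2.4},
                       inoculum=_inoculum(seed)),
    ]


def preset_reattachment_corners(seed: Optional[int] = None) -> list[ScenarioPreset]:
    """The four (tau, eta1) corner scenarios: tau_H eta_H, tau_H eta_L,
    tau_L eta_H, tau_L eta_L."""
    tau_L, tau_H = 10.0, 70.0
    eta_L, eta_H = 0.6, 4.2
    combos = [(tau_H, eta_H, "tauH_etaH"), (tau_H, eta_L, "tauH_etaL"),
              (tau_L, eta_H, "tauL_etaH"), (tau_L, eta_L, "tauL_etaL")]
    return [
        ScenarioPreset(name=f"reattachment/{label}",
                       overrides={"tau": tau, "eta1": eta1},
                       inoculum=_inoculum(seed))
        for tau, eta1, label in combos
    ]


def preset_k5_sweep(seed: Optional[int] = None) -> list[ScenarioPreset]:
    """k5 varied over one order of magnitude at tau = 10 nM, eta1 = 3.6/d."""
    return [
        ScenarioPreset(name=f"k5_sweep/k5_{k5:.1f}",
                       overrides={"k5": k5, "tau": 10.0, "eta1": 3.6},
                       inoculum=_inoculum(seed))
        for k5 in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    ]


def preset_hollowing(seed: Optional[int] = None) -> list[ScenarioPreset]:
    """Discrete-events (tau=20 nM) and continuous (tau=60 nM) runs, shared inoculum."""
    ino = _inoculum(seed)
    return [
        ScenarioPreset(name="hollowing/tau20",
                       overrides={"tau": 20.0, "eta1": 3.6}, inoculum=ino),
        ScenarioPreset(name="hollowing/tau60",
                       overrides={"tau": 60.0, "eta1": 3.6}, inoculum=ino),
    ]


PRESET_GROUPS = {
    "tau_sweep": preset_tau_sweep,
    "constant_dispersal": preset_constant_dispersal,
    "reattachment_corners": preset_reattachment_corners,
    "k5_sweep": preset_k5_sweep,
    "hollowing": preset_hollowing,
}
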