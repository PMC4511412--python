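"""Seeded inoculum generation: biomass pockets on the substratum.

The initial condition places sessile biomass in a few small pockets touching
the bottom boundary (M = density inside, 0 elsewhere), with the nutrient at
bulk level everywhere and no dispersed cells or autoinducer:
C = C_inf, N = A = 0 at t = 0. Pockets are half-discs (semi-ellipses) seated
on the substratum by default; a rectangle shape is retained as an option.
Pocket locations and sizes are either specified explicitly or drawn from a
seeded RNG, making every run bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .grid import Grid, StateFields
from .params import ConfigError, ModelParameters

__all__ = ["InoculumSpec", "generate_inoculum", "resolve_pockets"]

#: a pocket is (center_x [m], width [m], height [m], density [-])
Pocket = Tuple[float, float, float, float]


@dataclass
class InoculumSpec:
    """Description of the initial biomass pockets.

    If ``pockets`` is given it is used verbatim; otherwise ``n_colonies``
    pockets are drawn with the seeded RNG: centers uniform along the
    substratum, widths uniform in ``width_range``, height =
    ``height_to_width * width``, and uniform interior density ``density``.
    """

    n_colonies: int = 6
    density: float = 0.3
    width_range: Tuple[float, float] = (1.0e-4, 2.0e-4)  # m
    height_to_width: float = 0.5      # half-disc: height = radius
    shape: str = "half_disc"          # or "rectangle"
    pockets: Optional[List[Pocket]] = None
    seed: Optional[int] = None        # None -> NumericalSettings.seed

    def validate(self, params: ModelParameters) -> "InoculumSpec":
        if self.pockets is not None:
            for i, (cx, w, h, dens) in enumerate(self.pockets):
                if not (0.0 <= cx - w / 2 and cx + w / 2 <= params.L):
                    raise ConfigError(f"inoculum pocket {i} extends outside [0, L]")
                if not (0 < h <= params.H):
                    raise ConfigError(f"inoculum pocket {i} height outside (0, H]")
                if not (0 < dens < 1):
                    raise ConfigError(f"inoculum pocket {i} density must lie in (0, 1)")
        else:
            if self.n_colonies < 0:
                raise ConfigError("inoculum 'n_colonies' must be >= 0")
            if not (0 < self.density < 1):
                raise ConfigError("inoculum 'density' must lie in (0, 1)")
            lo, hi = self.width_range
            if not (0 < lo <= hi):
                raise ConfigError("inoculum 'width_range' must satisfy 0 < lo <= hi")
            if hi > params.L:
                raise ConfigError("inoculum 'width_range' exceeds the domain length L")
        if self.shape not in ("half_disc", "rectangle"):
            raise ConfigError(f"inoculum 'shape' unknown: {self.shape!r}")
        return self


def resolve_pockets(spec: InoculumSpec, params: ModelParameters,
                    seed: Optional[int] = None) -> List[Pocket]:
    """Concrete pocket list; deterministic given the seed."""
    if spec.pockets is not None:
        return list(spec.pockets)
    rng = np.random.default_rng(spec.seed if spec.seed is not None else seed)
    pockets: List[Pocket] = []
    lo, hi = spec.width_range
    for _ in range(spec.n_colonies):
        w = float(rng.uniform(lo, hi))
        cx = float(rng.uniform(w / 2, params.L - w / 2))
        pockets.append((cx, w, w * spec.height_to_width, spec.density))
    return pockets


def generate_inoculum(spec: InoculumSpec, grid: Grid, params: ModelParameters,
                      seed: Optional[int] = None) -> StateFields:
    """Build the initial state from a pocket specification.

    A cell belongs to a pocket when its center falls inside the pocket's
    half-disc (or rectangle); overlapping pockets take the union (max of
    densities). Every pocket is seated on the substratum (base at y = 0).
    """
    spec.validate(params)
    pockets = resolve_pockets(spec, params, seed=seed)
    X, Y = grid.meshgrid()
    M = np.zeros(grid.shape)
    for cx, w, h, dens in pockets:
        if spec.shape == "half_disc":
            inside = ((X - cx) / (w / 2)) ** 2 + (Y / h) ** 2 <= 1.0
        else:
            inside = (np.abs(X - cx) <= w / 2) & (Y <= h)
        if not inside.any():
            # pocket smaller than a cell: seed the substratum cell under its center
            i = min(int(cx / grid.hx), grid.nx - 1)
            inside[0, i] = True
        M = np.where(inside, np.maximum(M, dens), M)
    return StateFields(
        t=0.0,
        M=M,
        N=np.zeros(grid.shape),
        C=np.full(grid.shape, params.C_inf),
        A=np.zeros(grid.shape),
    )
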