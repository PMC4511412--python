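"""Regular 2D cell-centered grid over [0, L] x [0, H] and the state container.

Cells are indexed (j, i) with i along x (0..nx-1) and j along y (0..ny-1);
j = 0 is the row adjacent to the substratum (bottom boundary), j = ny-1 is
adjacent to the bulk interface (top boundary). Cell centers sit at
((i + 1/2) hx, (j + 1/2) hy). Field arrays have shape (ny, nx); the flat
ordering used by the linear solvers is C-order, k = i + j * nx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "StateFields"]


@dataclass(frozen=True)
class Grid:
    """Cell-centered rectangular grid. Boundaries: bottom = substratum,
    left/right = lateral (symmetry), top = bulk interface."""

    nx: int
    ny: int
    L: float
    H: float

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("Grid: nx and ny must be positive")
        if not (self.L > 0 and self.H > 0):
            raise ValueError("Grid: L and H must be positive")

    @property
    def hx(self) -> float:
        return self.L / self.nx

    @property
    def hy(self) -> float:
        return self.H / self.ny

    @property
    def cell_area(self) -> float:
        return self.hx * self.hy

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def xc(self) -> np.ndarray:
        """Cell-center x coordinates, shape (nx,)."""
        return (np.arange(self.nx) + 0.5) * self.hx

    @property
    def yc(self) -> np.ndarray:
        """Cell-center y coordinates, shape (ny,)."""
        return (np.arange(self.ny) + 0.5) * self.hy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) cell-center coordinate arrays of shape (ny, nx)."""
        return np.meshgrid(self.xc, self.yc)

    def integrate(self, f: np.ndarray) -> float:
        """Midpoint-rule integral of a cell field over the domain."""
        f = np.asarray(f)
        if f.shape != self.shape:
            raise ValueError(f"Grid.integrate: field shape {f.shape} != grid {self.shape}")
        return float(f.sum() * self.cell_area)


@dataclass
class StateFields:
    """The four fields at one time instant, each of shape (ny, nx)."""

    t: float
    M: np.ndarray
    N: np.ndarray
    C: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        shapes = {np.shape(f) for f in (self.M, self.N, self.C, self.A)}
        if len(shapes) != 1:
            raise ValueError(f"StateFields: inconsistent field shapes {shapes}")

    @property
    def shape(self):
        return np.shape(self.M)

    def copy(self) -> "StateFields":
        return StateFields(t=self.t, M=self.M.copy(), N=self.N.copy(),
                           C=self.C.copy(), A=self.A.copy())

    def check_finite(self) -> None:
        for name in ("M", "N", "C", "A"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise FloatingPointError(f"StateFields: non-finite values in {name}")

    @classmethod
    def uniform(cls, grid: Grid, t: float = 0.0, M: float = 0.0, N: float = 0.0,
                C: float = 0.0, A: float = 0.0) -> "StateFields":
        full = lambda v: np.full(grid.shape, float(v))
        return cls(t=t, M=full(M), N=full(N), C=full(C), A=full(A))
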