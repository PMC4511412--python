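"""Diffusivity laws and cell-centered finite-volume diffusion operators.

Biomass motility is degenerate-singular,

    D_M(M) = delta * M^a * (1 - M)^(-b),    a, b > 1, delta > 0,

vanishing at M = 0 (finite interface speed, porous-medium behaviour) and
blowing up as M -> 1 (the density cap). Solute and dispersed-cell
diffusivities interpolate linearly between their water (M=0) and fully
developed biofilm (M=1) values.

:func:`assemble_diffusion` builds, for frozen biomass M, the sparse operator
``Aop`` and affine part ``g`` such that ``Aop @ u - g`` approximates
``-div(d(M) grad u)`` on the flattened grid. Boundary closure follows the
physical setup: homogeneous Neumann on the substratum (bottom) and the
lateral symmetry boundaries for every field; at the top (bulk interface)
Dirichlet C = C_inf, N = A = 0, and a no-flux closure for M (biomass never
reaches the top in a terminated run). Face diffusivities are evaluated at
the arithmetic mean of the two adjacent cell M values, so the degeneracy
enters through D(0) = 0 rather than through the averaging.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import scipy.sparse as sp

from .grid import Grid
from .params import ModelParameters

__all__ = [
    "biomass_diffusivity",
    "solute_diffusivity",
    "assemble_diffusion",
    "boundary_flux_top",
]

ArrayLike = Union[float, np.ndarray]

#: top-boundary closure per field: (kind, value). "dirichlet" value may be a
#: params attribute name resolved at assembly time.
_TOP_BC = {
    "M": ("neumann", 0.0),
    "N": ("dirichlet", 0.0),
    "C": ("dirichlet", "C_inf"),
    "A": ("dirichlet", 0.0),
}

_SOLUTE_D = {"N": ("dN0", "dN1"), "C": ("dC0", "dC1"), "A": ("dA0", "dA1")}


def biomass_diffusivity(M: ArrayLike, delta: float, a: float, b: float,
                        m_cap: float = 0.99) -> ArrayLike:
    """Degenerate-singular biomass diffusivity delta*M^a*(1-M)^(-b), m^2/d.

    M is capped at ``m_cap`` before evaluation to keep the singular factor
    finite under transient overshoot. b = 0 gives the pure porous-medium law
    (used by numerical benchmarks).
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 1):
        raise ValueError("biomass_diffusivity: M must lie in [0, 1]")
    Mc = np.minimum(M, m_cap)
    out = delta * np.power(Mc, a) * np.power(1.0 - Mc, -b)
    return float(out) if out.ndim == 0 else out


def solute_diffusivity(M: ArrayLike, d0: float, d1: float) -> ArrayLike:
    """Linear interpolation d0 + M*(d1 - d0) between water and biofilm values."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 1):
        raise ValueError("solute_diffusivity: M must lie in [0, 1]")
    out = d0 + M * (d1 - d0)
    return float(out) if out.ndim == 0 else out


def _face_diffusivity(field_id: str, M_face: np.ndarray, params: ModelParameters,
                      m_cap: float) -> np.ndarray:
    if field_id == "M":
        return biomass_diffusivity(M_face, params.delta, params.a, params.b, m_cap=m_cap)
    d0_name, d1_name = _SOLUTE_D[field_id]
    return solute_diffusivity(M_face, getattr(params, d0_name), getattr(params, d1_name))


_PHI_CACHE: dict = {}
_PHI_NODES = 4097


def _phi_table(delta: float, a: float, b: float, m_cap: float):
    """Cumulative flux potential Phi(M) = int_0^M D_M(s) ds on a uniform grid
    (trapezoidal; the integrand is capped at m_cap like D_M itself)."""
    key = (delta, a, b, m_cap)
    tab = _PHI_CACHE.get(key)
    if tab is None:
        nodes = np.linspace(0.0, 1.0, _PHI_NODES)
        D = biomass_diffusivity(nodes, delta, a, b, m_cap=m_cap)
        phi = np.concatenate([[0.0], np.cumsum(0.5 * (D[1:] + D[:-1]) * np.diff(nodes))])
        tab = (nodes, phi)
        _PHI_CACHE[key] = tab
    return tab


def _biomass_face_coefficient(ML: np.ndarray, MR: np.ndarray,
                              params: ModelParameters, m_cap: float) -> np.ndarray:
    """Kirchhoff (integral-mean) face diffusivity for the biomass equation:

        d_face = (Phi(MR) - Phi(ML)) / (MR - ML),   Phi' = D_M,

    i.e. the scheme discretizes div grad Phi(M). This reproduces the porous-
    medium front speed; a plain arithmetic mean of D overestimates the flux
    into empty cells by an order of magnitude (spurious creep of the
    interface once growth amplifies the leaked tail), while an arithmetic
    mean of M values freezes both the front and the singular density cap.
    """
    nodes, phi = _phi_table(params.delta, params.a, params.b, m_cap)
    dM = MR - ML
    phiL = np.interp(ML, nodes, phi)
    phiR = np.interp(MR, nodes, phi)
    mid = 0.5 * (ML + MR)
    with np.errstate(divide="ignore", invalid="ignore"):
        secant = (phiR - phiL) / dM
    return np.where(np.abs(dM) > 1e-9,
                    secant,
                    biomass_diffusivity(mid, params.delta, params.a, params.b,
                                        m_cap=m_cap))


def assemble_diffusion(grid: Grid, field_id: str, M_frozen: np.ndarray,
                       params: ModelParameters, m_cap: float = 0.99,
                       all_neumann: bool = False):
    """Assemble the five-point FV diffusion operator for one field.

    Returns ``(Aop, g)`` with ``Aop`` a CSR matrix of shape (n, n) and ``g`` a
    vector such that ``Aop @ u.ravel() - g`` discretizes ``-div(d grad u)``
    including the boundary conditions. ``all_neumann=True`` replaces the top
    closure by homogeneous Neumann (used for conservation checks).
    """
    if field_id not in _TOP_BC:
        raise ValueError(f"assemble_diffusion: unknown field_id {field_id!r}")
    M_frozen = np.asarray(M_frozen, dtype=float)
    if M_frozen.shape != grid.shape:
        raise ValueError(
            f"assemble_diffusion: M_frozen shape {M_frozen.shape} != grid {grid.shape}")
    ny, nx = grid.shape
    n = grid.n_cells
    hx2, hy2 = grid.hx ** 2, grid.hy ** 2

    # interior face couplings. Solutes (laws linear in M): arithmetic mean of
    # the two cell diffusivities, which equals the exact integral mean. The
    # degenerate-singular biomass law uses the Kirchhoff integral-mean
    # coefficient (see _biomass_face_coefficient).
    Mc = np.clip(M_frozen, 0.0, 1.0)
    if field_id == "M":
        cx = _biomass_face_coefficient(Mc[:, :-1], Mc[:, 1:], params, m_cap) / hx2
        cy = _biomass_face_coefficient(Mc[:-1, :], Mc[1:, :], params, m_cap) / hy2
    else:
        Dcell = _face_diffusivity(field_id, Mc, params, m_cap)
        cx = 0.5 * (Dcell[:, :-1] + Dcell[:, 1:]) / hx2
        cy = 0.5 * (Dcell[:-1, :] + Dcell[1:, :]) / hy2

    main = np.zeros((ny, nx))
    main[:, :-1] += cx
    main[:, 1:] += cx
    main[:-1, :] += cy
    main[1:, :] += cy

    g = np.zeros((ny, nx))
    kind, value = _TOP_BC[field_id]
    if kind == "dirichlet" and not all_neumann:
        bc = getattr(params, value) if isinstance(value, str) else float(value)
        # ghost closure: flux through the top face = d_face*(bc - u)/(hy/2);
        # biomass is 0 on the bulk side of the face
        d_bulk = _face_diffusivity(field_id, np.zeros(nx), params, m_cap)
        ct = 2.0 * 0.5 * (Dcell[-1, :] + d_bulk) / hy2
        main[-1, :] += ct
        g[-1, :] = ct * bc

    ex = np.zeros((ny, nx))
    ex[:, :-1] = cx
    ex_flat = ex.ravel()[: n - 1]
    cy_flat = cy.ravel()

    Aop = sp.diags_array(
        [main.ravel(), -ex_flat, -ex_flat, -cy_flat, -cy_flat],
        offsets=[0, 1, -1, nx, -nx],
        shape=(n, n),
        format="csr",
    )
    return Aop, g.ravel()


def boundary_flux_top(field: np.ndarray, M_frozen: np.ndarray, grid: Grid,
                      params: ModelParameters, field_id: str = "N",
                      m_cap: float = 0.99) -> float:
    """Instantaneous diffusive efflux through the top boundary, field-units * m^2/d.

    Uses exactly the operator's face discretization (ghost Dirichlet closure),
    so that accumulated efflux is consistent with the discrete mass balance.
    Positive for outflow.
    """
    kind, value = _TOP_BC[field_id]
    if kind != "dirichlet":
        raise ValueError(f"boundary_flux_top: field {field_id!r} has a no-flux top closure")
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError("boundary_flux_top: field shape does not match grid")
    bc = getattr(params, value) if isinstance(value, str) else float(value)
    M_top = np.clip(np.asarray(M_frozen, dtype=float)[-1, :], 0.0, 1.0)
    d_face = 0.5 * (_face_diffusivity(field_id, M_top, params, m_cap)
                    + _face_diffusivity(field_id, np.zeros_like(M_top), params, m_cap))
    # outward flux density d*(u - bc)/(hy/2) integrated over the top faces
    return float(np.sum(2.0 * d_face * (field[-1, :] - bc) / grid.hy * grid.hx))
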