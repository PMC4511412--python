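"""Pointwise reaction kinetics of the four-field dispersal model.

All functions are pure, vectorized over numpy arrays, and carry no grid
knowledge. The four coupled rates are::

    dM/dt|_react = mu C/(k1+C) M - k4 M - eta1 f(A) M + eta2 g(M) N
    dN/dt|_react = mu C/(k1+C) N - k4 N + eta1 f(A) M - eta2 g(M) N
    dC/dt|_react = -(mu/Y) M_inf C/(k1+C) (M + N)
    dA/dt|_react = gamma(C) [alpha + beta f(A)] M_inf (M + N)

with the Hill switch f(A) = A^n/(tau^n + A^n) and the saturating
re-attachment factor g(M) = Mt/(k5 + Mt), Mt = M on the density scale.
Dispersal and re-attachment only exchange biomass between the sessile (M)
and dispersed (N) pools; their contributions to dM and dN cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .params import ModelParameters

__all__ = [
    "LocalState",
    "ReactionRates",
    "monod",
    "hill",
    "reattachment_factor",
    "gamma_of_C",
    "reaction_rates",
]

ArrayLike = Union[float, np.ndarray]


@dataclass
class LocalState:
    """Field values at one point: M, N (volume fractions), C (g/m^3), A (nM)."""

    M: ArrayLike
    N: ArrayLike
    C: ArrayLike
    A: ArrayLike


@dataclass
class ReactionRates:
    """Reaction parts of the four equations: rM, rN in 1/d; rC in g/(m^3 d); rA in nM/d."""

    rM: ArrayLike
    rN: ArrayLike
    rC: ArrayLike
    rA: ArrayLike


def monod(C: ArrayLike, mu: float, k1: float) -> ArrayLike:
    """Monod growth rate mu*C/(k1+C); in [0, mu) for C >= 0."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("monod: nutrient concentration C must be >= 0")
    if not k1 > 0:
        raise ValueError("monod: half-saturation k1 must be > 0")
    out = mu * C / (k1 + C)
    return float(out) if out.ndim == 0 else out

def hill(A: ArrayLike, tau: float, n: float) -> ArrayLike:
    """Hill switch f(A) = A^n / (tau^n + A^n).

    Strictly increasing in A with f(tau) = 1/2. The limit tau = 0 is the
    constant-dispersal case: the switch is fully open, f identically 1.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("hill: autoinducer concentration A must be >= 0")
    if tau < 0:
        raise ValueError("hill: threshold tau must be >= 0")
    if not n > 0:
        raise ValueError("hill: exponent n must be > 0")
    if tau == 0.0:
        out = np.ones_like(A)
    else:
        # compute on x = A/tau to keep A^n in range for large n
        x = A / tau
        xn = np.power(x, n)
        out = xn / (1.0 + xn)
    return float(out) if out.ndim == 0 else out


def reattachment_factor(M: ArrayLike, k5: float, M_inf: float,
                        scale: str = "fraction") -> ArrayLike:
    """Saturating re-attachment factor Mt/(k5 + Mt).

    Mt is the biofilm density expressed on the same scale as k5: with
    ``scale="fraction"`` (default) k5 is read as a volume fraction and
    Mt = M; with ``scale="density"`` Mt = M*M_inf in g/m^3, which puts the
    half-saturation at M ~ k5/M_inf and makes the factor near-saturated in
    any biofilm.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M >= 1):
        raise ValueError("reattachment_factor: M must lie in [0, 1)")
    if scale == "density":
        Mt = M * M_inf
    elif scale == "fraction":
        Mt = M
    else:
        raise ValueError(f"reattachment_factor: unknown scale {scale!r}")
    out = Mt / (k5 + Mt)
    return float(out) if out.ndim == 0 else out


def gamma_of_C(C: ArrayLike, mode: str = "constant_one",
               hook: Optional[Callable[[ArrayLike], ArrayLike]] = None) -> ArrayLike:
    """Nutrient modulation gamma(C) of autoinducer production.

    ``constant_one`` (the default used throughout the simulation experiments)
    returns 1 for every C. ``user_hook`` delegates to a caller-supplied
    function, whose values must be >= 0.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("gamma_of_C: nutrient concentration C must be >= 0")
    if mode == "constant_one":
        out = np.ones_like(C)
    elif mode == "user_hook":
        if hook is None:
            raise ValueError("gamma_of_C: mode 'user_hook' requires a hook function")
        out = np.asarray(hook(C), dtype=float)
        if np.any(out < 0):
            raise ValueError("gamma_of_C: user hook returned negative values")
    else:
        raise ValueError(f"gamma_of_C: unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def reaction_rates(s: LocalState, p: ModelParameters,
                   gamma_hook: Optional[Callable] = None) -> ReactionRates:
    """Evaluate all four reaction terms at a local state.

    The dispersal term (eta1 f(A) M) and the re-attachment term
    (eta2 g(M) N) appear with opposite signs in rM and rN, so
    rM + rN == (monod - k4) * (M + N) identically.
    """
    mon = monod(s.C, p.mu, p.k1)
    f = hill(s.A, p.tau, p.n)
    g = reattachment_factor(s.M, p.k5, p.M_inf, scale=p.k5_scale)
    gam = gamma_of_C(s.C, mode=p.gamma_mode, hook=gamma_hook)
    dispersal = p.eta1 * f * s.M
    reattach = p.eta2 * g * s.N
    rM = mon * s.M - p.k4 * s.M - dispersal + reattach
    rN = mon * s.N - p.k4 * s.N + dispersal - reattach
    rC = -(p.mu / p.Y) * p.M_inf * (np.asarray(s.C) / (p.k1 + np.asarray(s.C))) * (s.M + s.N)
    rA = gam * (p.alpha + p.beta * f) * p.M_inf * (s.M + s.N)
    return ReactionRates(rM=rM, rN=rN, rC=rC, rA=rA)
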