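"""Semi-implicit time integration of the coupled four-field system.

Each step advances the fields in the order C, A, M, N (nutrient first so that
growth uses the freshest field), solving one sparse linear system per field
with the stabilized biconjugate gradient method. Diffusion is implicit with
diffusivities frozen at the old biomass field; sink terms that are linear in
the solved field (nutrient consumption, lysis, the dispersal sink in M) are
implicit, while cross-field sources (growth, autoinducer production, the
dispersal source into N, the re-attachment exchange) are explicit. This split
needs no nonlinear iteration and preserves the physical bounds
0 <= M < 1, N >= 0, 0 <= C <= C_inf, A >= 0 for any admissible step size.

The re-attachment exchange (eta2 g(M) N) is applied with the old N on both
sides — source into M and sink from N — so that, like the dispersal exchange
(eta1 f(A) M_new on both sides), it cancels identically and the discrete
M+N balance closes to linear-solver tolerance. Explicit treatment of the
re-attachment sink bounds the step size by dt < 1/eta2, which is checked up
front (the default dt = 1e-3 d is three orders of magnitude below the bound).

On solver failure a step is retried with halved dt (two substeps), up to a
bounded recursion depth; the nominal dt is restored afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, bicgstab, splu

from .grid import Grid, StateFields
from .kinetics import gamma_of_C, hill, monod, reattachment_factor
from .observables import TimeSeries, lumped_measures
from .operators import assemble_diffusion, boundary_flux_top
from .params import ModelParameters, NumericalSettings

__all__ = ["SolverFailure", "SolverReport", "StepFluxes", "RunResult", "step", "run"]

logger = logging.getLogger(__name__)


class SolverFailure(RuntimeError):
    """A linear solve failed to converge or produced non-finite values."""


@dataclass
class SolverReport:
    """Per-step diagnostics: iteration counts and final relative residuals per field."""

    dt: float
    iterations: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)

    def max_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)


@dataclass
class StepFluxes:
    """Domain-integrated amounts applied during one step (units fraction*m^2).

    These are the *actually applied* discrete terms, so the balance
    (M_tot + N_tot) increment == growth_MN - lysis_MN - efflux_N
    holds to solver tolerance; the exchange terms cancel by construction.
    ``production_M`` is the sessile-only growth integral entering the
    biomass-loss measure K(T). ``clipped`` is the (signed) mass added by
    projecting solver-noise negatives back to zero — a diagnostic that stays
    many orders below the balance tolerance.
    """

    production_M: float = 0.0
    growth_MN: float = 0.0
    lysis_MN: float = 0.0
    efflux_N: float = 0.0
    clipped: float = 0.0

    def __iadd__(self, other: "StepFluxes") -> "StepFluxes":
        self.production_M += other.production_M
        self.growth_MN += other.growth_MN
        self.lysis_MN += other.lysis_MN
        self.efflux_N += other.efflux_N
        self.clipped += other.clipped
        return self


@dataclass
class RunResult:
    """Outcome of :func:`run`: the observable series, the final state, and any
    states captured at sampling times."""

    timeseries: TimeSeries
    final_state: StateFields
    states: list = field(default_factory=list)
    terminated_by: str = "t_end"


class PreconCache:
    """Per-field frozen-LU preconditioners for the BiCGStab solves.

    The linear operators drift slowly — their dominant 1/dt diagonal is
    constant and the biomass field entering the coefficients changes little
    per step — so a complete LU factorization taken at some recent step stays
    an excellent preconditioner for many subsequent steps (BiCGStab then
    converges in a couple of iterations). Each field's factor is refreshed
    every ``refresh_every`` steps, or immediately when a solve needed more
    than ``stale_iters`` iterations or failed.
    """

    def __init__(self, refresh_every: int = 25, stale_iters: int = 8):
        self.refresh_every = refresh_every
        self.stale_iters = stale_iters
        self._entries: dict = {}  # label -> [lu, age]

    def get(self, label: str, lhs: sp.csr_array, refresh: bool = False):
        entry = self._entries.get(label)
        if refresh or entry is None or entry[1] >= self.refresh_every:
            lu = splu(lhs.tocsc(), permc_spec="MMD_AT_PLUS_A")
            entry = [lu, 0]
            self._entries[label] = entry
        entry[1] += 1
        lu = entry[0]
        return LinearOperator(lhs.shape, lu.solve)


def _solve(lhs: sp.csr_array, rhs: np.ndarray, x0: np.ndarray,
           tol: float, maxit: int, label: str, cache: Optional[PreconCache] = None):
    """ILU-preconditioned BiCGStab solve; returns (x, n_iter, rel_residual)."""
    bnorm = float(np.linalg.norm(rhs))
    if bnorm == 0.0:
        return np.zeros_like(rhs), 0, 0.0
    if cache is None:
        cache = PreconCache(refresh_every=1)
    count = [0]

    def _cb(_xk):
        count[0] += 1

    precon = cache.get(label, lhs)
    x, info = bicgstab(lhs, rhs, x0=x0, rtol=tol, atol=0.0, maxiter=maxit,
                       M=precon, callback=_cb)
    if info != 0 or count[0] > cache.stale_iters:
        # stale preconditioner? refactor once before declaring failure
        precon = cache.get(label, lhs, refresh=True)
        count[0] = 0
        x, info = bicgstab(lhs, rhs, x0=x0, rtol=tol, atol=0.0, maxiter=maxit,
                           M=precon, callback=_cb)
    if info != 0 or not np.all(np.isfinite(x)):
        raise SolverFailure(f"BiCGStab failed for field {label} (info={info})")
    relres = float(np.linalg.norm(rhs - lhs @ x)) / bnorm
    return x, count[0], relres


def _clip_nonneg(u: np.ndarray, scale: float, label: str):
    """Project solver-noise negatives to zero; abort on genuinely negative values."""
    lo = float(u.min())
    if lo >= 0.0:
        return u, 0.0
    if lo < -1.0e-8 * max(scale, 1e-300):
        raise SolverFailure(f"field {label} went negative beyond solver noise ({lo:.3e})")
    clipped = -float(u[u < 0].sum())
    np.clip(u, 0.0, None, out=u)
    return u, clipped


def step(state: StateFields, grid: Grid, params: ModelParameters,
         settings: NumericalSettings, dt: Optional[float] = None,
         gamma_hook: Optional[Callable] = None,
         cache: Optional[PreconCache] = None):
    """Advance the coupled system by one time step.

    Returns ``(new_state, SolverReport, StepFluxes)``. Raises
    :class:`SolverFailure` if any of the four linear solves does not converge
    (the caller may retry with a smaller dt).
    """
    p = params
    s = settings
    if dt is None:
        dt = s.dt
    if dt * p.eta2 >= 1.0:
        raise ValueError("step: dt must be < 1/eta2 for the explicit re-attachment sink")
    M0, N0, C0, A0 = state.M, state.N, state.C, state.A
    n = grid.n_cells
    ca = grid.cell_area
    inv_dt = sp.diags_array(np.full(n, 1.0 / dt))
    report = SolverReport(dt=dt)

    # --- nutrient C: implicit diffusion + linearized implicit consumption sink
    Aop, g = assemble_diffusion(grid, "C", M0, p, m_cap=s.m_cap)
    sink = (p.mu / p.Y) * p.M_inf * (M0 + N0) / (p.k1 + C0)
    lhs = (Aop + inv_dt + sp.diags_array(sink.ravel())).tocsr()
    rhs = C0.ravel() / dt + g
    C1, it, res = _solve(lhs, rhs, C0.ravel(), s.solver_tol, s.solver_maxit, "C", cache)
    report.iterations["C"], report.residuals["C"] = it, res
    C1 = C1.reshape(grid.shape)
    np.clip(C1, 0.0, p.C_inf, out=C1)  # discrete maximum principle, solver noise only

    mon = monod(C1, p.mu, p.k1)
    gam = gamma_of_C(C1, mode=p.gamma_mode, hook=gamma_hook)

    # --- autoinducer A: implicit diffusion + explicit production source
    Aop, g = assemble_diffusion(grid, "A", M0, p, m_cap=s.m_cap)
    f0 = hill(A0, p.tau, p.n)
    srcA = gam * (p.alpha + p.beta * f0) * p.M_inf * (M0 + N0)
    lhs = (Aop + inv_dt).tocsr()
    rhs = A0.ravel() / dt + g + srcA.ravel()
    A1, it, res = _solve(lhs, rhs, A0.ravel(), s.solver_tol, s.solver_maxit, "A", cache)
    report.iterations["A"], report.residuals["A"] = it, res
    A1 = A1.reshape(grid.shape)
    A1, _ = _clip_nonneg(A1, float(A1.max(initial=0.0)), "A")

    f1 = hill(A1, p.tau, p.n)

    # --- sessile biomass M: implicit degenerate diffusion, implicit lysis and
    #     dispersal sinks, explicit growth and re-attachment sources
    Aop, _gM = assemble_diffusion(grid, "M", M0, p, m_cap=s.m_cap)
    g_re = reattachment_factor(M0, p.k5, p.M_inf, scale=p.k5_scale)
    lhs = (Aop + inv_dt + sp.diags_array((p.k4 + p.eta1 * f1).ravel())).tocsr()
    rhs = M0.ravel() / dt + (mon * M0).ravel() + (p.eta2 * g_re * N0).ravel()
    M1, it, res = _solve(lhs, rhs, M0.ravel(), s.solver_tol, s.solver_maxit, "M", cache)
    report.iterations["M"], report.residuals["M"] = it, res
    M1 = M1.reshape(grid.shape)
    M1, clipM = _clip_nonneg(M1, float(M1.max(initial=0.0)), "M")
    # the singular diffusivity (capped at m_cap inside D_M) flattens any density
    # overshoot diffusively, keeping max M at m_cap + O(growth*h^2/D); reaching
    # 1 would mean the step is too large for that mechanism
    if M1.max() >= 1.0:
        raise SolverFailure(f"M reached {M1.max():.6f} >= 1; step too large")

    # --- dispersed cells N: implicit diffusion and lysis, explicit growth,
    #     dispersal source (with the fresh M) and re-attachment sink (old N)
    Aop, g = assemble_diffusion(grid, "N", M0, p, m_cap=s.m_cap)
    lhs = (Aop + inv_dt + sp.diags_array(np.full(n, p.k4))).tocsr()
    rhs = (N0.ravel() / dt + (mon * N0).ravel() + (p.eta1 * f1 * M1).ravel()
           - (p.eta2 * g_re * N0).ravel() + g)
    N1, it, res = _solve(lhs, rhs, N0.ravel(), s.solver_tol, s.solver_maxit, "N", cache)
    report.iterations["N"], report.residuals["N"] = it, res
    N1 = N1.reshape(grid.shape)
    N1, clipN = _clip_nonneg(N1, float(N1.max(initial=0.0)), "N")

    fluxes = StepFluxes(
        production_M=dt * float((mon * M0).sum()) * ca,
        growth_MN=dt * float((mon * (M0 + N0)).sum()) * ca,
        lysis_MN=dt * p.k4 * float((M1 + N1).sum()) * ca,
        efflux_N=dt * boundary_flux_top(N1, M0, grid, p, field_id="N", m_cap=s.m_cap),
        clipped=(clipM + clipN) * ca,
    )
    new_state = StateFields(t=state.t + dt, M=M1, N=N1, C=C1, A=A1)
    new_state.check_finite()
    return new_state, report, fluxes


def _advance(state, grid, params, settings, dt, acc, depth, gamma_hook, cache):
    """One nominal step with bounded dt-halving on solver failure."""
    try:
        new_state, report, fluxes = step(state, grid, params, settings, dt=dt,
                                         gamma_hook=gamma_hook, cache=cache)
    except SolverFailure:
        if depth >= settings.max_halvings:
            raise
        logger.warning("solver failure at t=%.6f, retrying with dt=%g", state.t, dt / 2)
        half = _advance(state, grid, params, settings, dt / 2, acc, depth + 1,
                        gamma_hook, cache)
        return _advance(half[0], grid, params, settings, dt / 2, acc, depth + 1,
                        gamma_hook, cache)
    acc += fluxes
    return new_state, report


def run(initial: StateFields, grid: Grid, params: ModelParameters,
        settings: NumericalSettings, observers: Sequence[Callable] = (),
        capture_states: bool = False, gamma_hook: Optional[Callable] = None) -> RunResult:
    """Integrate from ``initial`` until t_end or until omega >= target_size.

    Observables are sampled every ``settings.output_every`` days (and at t=0
    and the final time); each ``observer(state, record)`` is called at every
    sampling time. ``capture_states=True`` additionally stores a copy of the
    state at each sampling time in ``RunResult.states``.
    """
    state = initial.copy()
    acc = StepFluxes()
    cache = PreconCache()
    M0_tot = grid.integrate(state.M)
    N0_tot = grid.integrate(state.N)
    records: list[dict] = []
    states: list[StateFields] = []

    def _sample():
        rec = lumped_measures(state, grid, params, settings.omega_threshold,
                              accumulators=acc, M0=M0_tot, N0=N0_tot)
        records.append(rec)
        if capture_states:
            states.append(state.copy())
        for obs in observers:
            obs(state, rec)
        return rec

    rec = _sample()
    terminated_by = "t_end"
    next_sample = settings.output_every
    n_steps = 0
    while state.t < settings.t_end - 1e-12:
        dt = min(settings.dt, settings.t_end - state.t)
        state, report = _advance(state, grid, params, settings, dt, acc, 0, gamma_hook, cache)
        n_steps += 1
        sampled = False
        if state.t >= next_sample - 1e-9 or state.t >= settings.t_end - 1e-12:
            rec = _sample()
            sampled = True
            while next_sample <= state.t + 1e-9:
                next_sample += settings.output_every
        if rec["omega"] >= settings.target_size:
            if not sampled:
                rec = _sample()
            terminated_by = "target_size"
            break
        if n_steps % 2000 == 0:
            logger.info("t=%.3f d  M_tot=%.3e  omega=%.3f  max_res=%.2e",
                        state.t, rec["M_tot"], rec["omega"], report.max_residual())

    ts = TimeSeries.from_records(records)
    return RunResult(timeseries=ts, final_state=state, states=states,
                     terminated_by=terminated_by)
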