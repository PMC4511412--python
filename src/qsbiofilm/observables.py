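"""Lumped observables of a simulation run.

All measures are midpoint-rule cell integrals over the domain or over the
biofilm region Omega_2 = {M > omega_threshold}:

* ``omega``   — biofilm size relative to the domain size,
* ``C_avg``   — average nutrient concentration over Omega_2,
* ``M_tot``   — total sessile biomass (fraction * m^2),
* ``N_tot``   — total dispersed biomass,
* ``A_avg``   — average autoinducer concentration over Omega_2, in units of tau,
* ``K``       — biomass loss: the fraction of produced sessile biomass not
  retained, (P_int - (M_tot(T) - M_0)) / P_int with P_int the cumulative
  growth integral of M,
* ``Z``       — ratio of the re-attachment to the detachment flux,
* ``P_cum``   — cumulative diffusive efflux of dispersed cells through the top.

Cumulative integrals (production, efflux, growth, lysis) are accumulated by
the time stepper at every step with the step's dt, not at sampling times, so
the discrete balance identity stays tight. Quantities whose defining ratio is
0/0 (averages over an empty biofilm region, K before any production, Z with
no detachment flux) are reported as NaN markers, serialized as empty CSV
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import Grid, StateFields
from .kinetics import hill, reattachment_factor
from .params import ModelParameters

__all__ = [
    "TimeSeries",
    "EventDetection",
    "lumped_measures",
    "biomass_loss_K",
    "reattachment_ratio_Z",
    "dispersal_event_detector",
    "mass_balance_residual",
]

#: column order of the per-sample records
COLUMNS = [
    "t", "omega", "C_avg", "M_tot", "N_tot", "A_avg",
    "production_cum", "K", "Z", "P_cum", "growth_cum", "lysis_cum",
]


@dataclass
class TimeSeries:
    """Per-sample record of all lumped observables, backed by a DataFrame."""

    data: pd.DataFrame

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "TimeSeries":
        df = pd.DataFrame.from_records(list(records))
        cols = [c for c in COLUMNS if c in df.columns]
        return cls(data=df[cols + [c for c in df.columns if c not in cols]])

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def to_csv(self, path) -> None:
        """One header row of observable symbols; NaN markers become empty cells."""
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TimeSeries":
        return cls(data=pd.read_csv(path))


def lumped_measures(state: StateFields, grid: Grid, params: ModelParameters,
                    omega_threshold: float = 1.0e-3, accumulators=None,
                    M0: Optional[float] = None, N0: Optional[float] = None) -> dict:
    """One observable record for a state (plus run accumulators, if any)."""
    mask = state.M > omega_threshold
    area2 = float(mask.sum()) * grid.cell_area
    domain_area = grid.L * grid.H
    omega = area2 / domain_area
    M_tot = grid.integrate(state.M)
    N_tot = grid.integrate(state.N)
    if area2 > 0:
        C_avg = float(state.C[mask].sum()) * grid.cell_area / area2
        if params.tau > 0:
            A_avg = float(state.A[mask].sum()) * grid.cell_area / (params.tau * area2)
        else:
            A_avg = np.nan  # tau = 0: the Eq-(11)-style normalization is undefined
    else:
        C_avg = np.nan
        A_avg = np.nan
    rec = {
        "t": state.t,
        "omega": omega,
        "C_avg": C_avg,
        "M_tot": M_tot,
        "N_tot": N_tot,
        "A_avg": A_avg,
        "Z": reattachment_ratio_Z(state, grid, params),
    }
    if accumulators is not None:
        rec["production_cum"] = accumulators.production_M
        rec["growth_cum"] = accumulators.growth_MN
        rec["lysis_cum"] = accumulators.lysis_MN
        rec["P_cum"] = accumulators.efflux_N
        if M0 is not None:
            rec["K"] = biomass_loss_K(accumulators.production_M, M_tot, M0)
    return rec


def biomass_loss_K(cumulative_production: float, M_tot_T: float, M0: float) -> float:
    """Biomass loss K(T) = (P - (M_tot(T) - M0)) / P with P the cumulative
    sessile production integral. NaN before any production."""
    if cumulative_production < 0:
        raise ValueError("biomass_loss_K: cumulative production must be >= 0")
    if cumulative_production == 0:
        return float("nan")
    return (cumulative_production - (M_tot_T - M0)) / cumulative_production


def reattachment_ratio_Z(state: StateFields, grid: Grid, params: ModelParameters,
                         hill_denominator: str = "tau") -> float:
    """Ratio of re-attached to detached cells,

        Z = (eta2/eta1) * Int g(M) N dx / Int f(A) M dx.

    The detachment denominator uses the same Hill form as the dynamics,
    f(A) = A^n/(tau^n + A^n); ``hill_denominator="printed"`` selects the
    non-dimensionalized variant A^n/(1 + A^n) instead. NaN when the
    detachment flux vanishes.
    """
    if params.eta1 == 0:
        return float("nan")
    g = reattachment_factor(state.M, params.k5, params.M_inf, scale=params.k5_scale)
    num = grid.integrate(g * state.N)
    if hill_denominator == "tau":
        f = hill(state.A, params.tau, params.n)
    elif hill_denominator == "printed":
        An = np.power(np.asarray(state.A, dtype=float), params.n)
        f = An / (1.0 + An)
    else:
        raise ValueError(f"reattachment_ratio_Z: unknown hill_denominator {hill_denominator!r}")
    den = grid.integrate(f * state.M)
    if den == 0.0:
        return float("nan")
    return (params.eta2 / params.eta1) * num / den


@dataclass
class EventDetection:
    """Result of the dispersal-event detector."""

    n_events: int
    event_times: list
    label: str  # "discrete", "plateau" or "growing"


def dispersal_event_detector(times: np.ndarray, M_tot: np.ndarray,
                             drop_fraction: float = 0.10,
                             plateau_tol: float = 0.05) -> EventDetection:
    """Count discrete dispersal events in a sampled M_tot series.

    An event is a strict local maximum followed (before the next maximum) by a
    relative drop exceeding ``drop_fraction``. With no events the series is
    classified "plateau" when the relative change over its final quarter is
    below ``plateau_tol``, else "growing".
    """
    times = np.asarray(times, dtype=float)
    M_tot = np.asarray(M_tot, dtype=float)
    if len(M_tot) < 3:
        raise ValueError("dispersal_event_detector: need at least 3 samples")
    if times.shape != M_tot.shape:
        raise ValueError("dispersal_event_detector: times and M_tot must match")
    peaks = [i for i in range(1, len(M_tot) - 1)
             if M_tot[i] > M_tot[i - 1] and M_tot[i] > M_tot[i + 1]]
    event_times = []
    for j, i in enumerate(peaks):
        stop = peaks[j + 1] if j + 1 < len(peaks) else len(M_tot)
        trough = float(M_tot[i + 1:stop + 1].min()) if i + 1 <= stop else float(M_tot[-1])
        if M_tot[i] > 0 and (M_tot[i] - trough) / M_tot[i] > drop_fraction:
            event_times.append(float(times[i]))
    if event_times:
        label = "discrete"
    else:
        i0 = (3 * len(M_tot)) // 4
        tail = M_tot[i0:]
        ref = float(np.max(np.abs(M_tot)))
        label = "plateau" if ref > 0 and abs(tail[-1] - tail[0]) / ref < plateau_tol \
            else ("plateau" if ref == 0 else "growing")
    return EventDetection(n_events=len(event_times), event_times=event_times, label=label)


def mass_balance_residual(ts: TimeSeries) -> float:
    """Relative closure error of the discrete M+N balance over a run:

        M_tot(T) + N_tot(T) - (M_0 + N_0) = growth_cum - lysis_cum - P_cum.

    Normalized by the largest of the cumulative terms (or the initial mass
    for a reaction-free run).
    """
    d = ts.data
    lhs = (d["M_tot"].iloc[-1] + d["N_tot"].iloc[-1]
           - d["M_tot"].iloc[0] - d["N_tot"].iloc[0])
    rhs = d["growth_cum"].iloc[-1] - d["lysis_cum"].iloc[-1] - d["P_cum"].iloc[-1]
    scale = max(abs(d["growth_cum"].iloc[-1]), abs(d["lysis_cum"].iloc[-1]),
                abs(d["P_cum"].iloc[-1]), d["M_tot"].iloc[0] + d["N_tot"].iloc[0])
    if scale == 0:
        return 0.0
    return float(abs(lhs - rhs) / scale)
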