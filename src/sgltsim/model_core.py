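"""Nine-sub-segment proximal-tubule model of renal glucose reabsorption.

Filtrate enters the first convoluted sub-segment (PCT1) at the glomerular
filtration rate, flows through PCT1-6 and the straight-tubule sub-segments
PST1-3, and drains into the urinary bladder and then urine.  Water is
reabsorbed at an identical rate in every sub-segment, so the luminal flow
out of sub-segment i is (1 - i * 0.074) * GFR.  Glucose is reabsorbed in
each sub-segment by a Michaelis-Menten process — SGLT2 in the PCT, SGLT1
in the PST, each transporter's whole-kidney capacity split uniformly over
its sub-segments.  An SGLT inhibitor, when present, is freely filtered in
its unbound fraction, travels the lumen without reabsorption, and raises
the apparent Km of the transporter it binds (competitive inhibition).

Two solvers are provided: :func:`simulate` integrates the full ODE system
under arbitrary time-varying forcing, and :func:`steady_state_profile`
solves the clamped (constant-forcing) problem segment by segment as the
positive root of a quadratic — an independent analytic oracle for the ODE
path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import InhibitorParams, PhysiologyParams, TransporterParams

N_SEG = 9
N_PCT = 6
N_PST = 3

# state-vector layout
_GLU = slice(0, 9)          # luminal glucose amounts, mmol
_GLU_UB = 9                 # bladder glucose, mmol
_GLU_URINE = 10             # cumulative urinary glucose, mmol
_SGLT2_CUM = 11             # cumulative glucose reabsorbed in PCT, mmol
_SGLT1_CUM = 12             # cumulative glucose reabsorbed in PST, mmol
_GLU_FILT = 13              # cumulative filtered glucose, mmol
_DRUG = slice(14, 23)       # luminal drug amounts, nmol
_DRUG_UB = 23
_DRUG_URINE = 24
_DRUG_FILT = 25
N_STATE = 26


class SimulationError(RuntimeError):
    """Raised when the integrator fails or produces an invalid trajectory."""


def _as_fn(value: float | Callable[[float], float]) -> Callable[[float], float]:
    if callable(value):
        return value
    const = float(value)
    return lambda t: const


@dataclass(frozen=True)
class Forcing:
    """Time-varying boundary conditions driving the tubule model.

    All members accept either a scalar (held constant) or a callable of
    time in hours.  ``plasma_glucose`` is in mM, ``plasma_drug_total`` in
    nM (total, i.e. bound + unbound), flows in L/h.  ``breakpoints`` lists
    times at which the forcing is discontinuous; the integrator restarts
    there.
    """

    plasma_glucose: Callable[[float], float] | float
    gfr: Callable[[float], float] | float
    urine_outflow: Callable[[float], float] | float
    plasma_drug_total: Callable[[float], float] | float = 0.0
    breakpoints: tuple[float, ...] = ()

    def glucose(self, t: float) -> float:
        return _as_fn(self.plasma_glucose)(t)

    def drug(self, t: float) -> float:
        return _as_fn(self.plasma_drug_total)(t)

    def gfr_at(self, t: float) -> float:
        return _as_fn(self.gfr)(t)

    def kx_at(self, t: float) -> float:
        return _as_fn(self.urine_outflow)(t)

    @classmethod
    def constant(cls, plasma_glucose_mM: float, gfr: float, urine_outflow: float,
                 plasma_drug_nM: float = 0.0) -> "Forcing":
        return cls(plasma_glucose=float(plasma_glucose_mM), gfr=float(gfr),
                   urine_outflow=float(urine_outflow),
                   plasma_drug_total=float(plasma_drug_nM))


@dataclass(frozen=True)
class TubuleGeometry:
    """Static geometry and per-sub-segment kinetic assignments.

    ``flow_fractions[i]`` multiplies the instantaneous GFR to give the
    luminal outflow of sub-segment i.  ``per_segment_ki`` and
    ``free_fraction`` are present only when an inhibitor is attached.
    """

    segment_volumes: np.ndarray
    flow_fractions: np.ndarray
    segment_kind: tuple[str, ...]
    per_segment_vmax: np.ndarray
    per_segment_km: np.ndarray
    bladder_volume: float
    per_segment_ki: np.ndarray | None = None
    free_fraction: float = 0.0
    drug: InhibitorParams | None = None

    @property
    def has_drug(self) -> bool:
        return self.per_segment_ki is not None

    @property
    def pct_mask(self) -> np.ndarray:
        return np.array([k == "PCT" for k in self.segment_kind])

    @property
    def vmax_sglt1(self) -> float:
        return float(self.per_segment_vmax[~self.pct_mask].sum())

    @property
    def vmax_sglt2(self) -> float:
        return float(self.per_segment_vmax[self.pct_mask].sum())

    def outflows(self, gfr: float) -> np.ndarray:
        return self.flow_fractions * gfr


def build_geometry(phys: PhysiologyParams, trans: TransporterParams,
                   drug: InhibitorParams | None = None) -> TubuleGeometry:
    """Assemble the nine-sub-segment geometry from parameter objects.

    Six equal PCT sub-segments carry SGLT2 (vmax2/6, km2 each) and three
    equal PST sub-segments carry SGLT1 (vmax1/3, km1 each).  Outflow of
    sub-segment i is (1 - i * flow_decrement) * GFR.
    """
    pt_volume = phys.renal_cortex_volume * phys.pt_fraction_of_cortex
    pct_volume = pt_volume * phys.pct_fraction_of_pt
    pst_volume = pt_volume * phys.pst_fraction_of_pt
    volumes = np.concatenate([np.full(N_PCT, pct_volume / N_PCT),
                              np.full(N_PST, pst_volume / N_PST)])
    fractions = 1.0 - phys.flow_decrement * np.arange(1, N_SEG + 1)
    kinds = ("PCT",) * N_PCT + ("PST",) * N_PST
    vmax = np.concatenate([np.full(N_PCT, trans.vmax2 / N_PCT),
                           np.full(N_PST, trans.vmax1 / N_PST)])
    km = np.concatenate([np.full(N_PCT, trans.km2), np.full(N_PST, trans.km1)])
    ki = None
    fup = 0.0
    if drug is not None:
        ki = np.concatenate([np.full(N_PCT, drug.ki2), np.full(N_PST, drug.ki1)])
        fup = drug.free_fraction
    return TubuleGeometry(segment_volumes=volumes, flow_fractions=fractions,
                          segment_kind=kinds, per_segment_vmax=vmax,
                          per_segment_km=km, bladder_volume=phys.bladder_volume,
                          per_segment_ki=ki, free_fraction=fup, drug=drug)


def reabsorption_rate(vmax_seg: float, km: float, c_glu) -> float:
    """Michaelis-Menten reabsorption rate (mmol/h) at luminal glucose c_glu (mM)."""
    if vmax_seg < 0 or km <= 0:
        raise ValueError("vmax_seg must be >= 0 and km > 0")
    if np.any(np.asarray(c_glu) < 0):
        raise ValueError("glucose concentration must be non-negative")
    return vmax_seg * c_glu / (km + c_glu)


def inhibited_reabsorption_rate(vmax_seg: float, km: float, c_glu,
                                c_drug, ki: float) -> float:
    """Competitively inhibited Michaelis-Menten rate.

    The inhibitor raises the apparent Km to km * (1 + c_drug/ki); with
    c_drug = 0 this is exactly :func:`reabsorption_rate`.
    """
    if np.any(np.asarray(c_drug) < 0):
        raise ValueError("drug concentration must be non-negative")
    if ki <= 0:
        raise ValueError("ki must be strictly positive")
    if np.all(np.asarray(c_drug) == 0):
        return reabsorption_rate(vmax_seg, km, c_glu)
    if np.any(np.asarray(c_glu) < 0):
        raise ValueError("glucose concentration must be non-negative")
    return vmax_seg * c_glu / (km * (1.0 + c_drug / ki) + c_glu)


def _segment_rates(geom: TubuleGeometry, c_glu: np.ndarray,
                   c_drug: np.ndarray | None) -> np.ndarray:
    """Vectorised per-sub-segment reabsorption rates; accepts raw ODE
    concentrations (may be transiently, negligibly negative)."""
    km_app = geom.per_segment_km.copy()
    if geom.has_drug and c_drug is not None:
        km_app = km_app * (1.0 + np.maximum(c_drug, 0.0) / geom.per_segment_ki)
    return geom.per_segment_vmax * c_glu / (km_app + c_glu)


def ode_rhs(t: float, y: np.ndarray, geom: TubuleGeometry,
            forcing: Forcing) -> np.ndarray:
    """Right-hand side of the full mass-balance ODE system.

    Solute flux between sub-segments is flow times upstream concentration;
    reabsorbed glucose is routed to cumulative accumulator states (PCT ->
    SGLT2, PST -> SGLT1), never back to plasma.  Drug balances are
    identical but with filtration input fup * GFR * C_plasma_drug and no
    reabsorption.
    """
    gfr = forcing.gfr_at(t)
    kx = forcing.kx_at(t)
    Q = geom.outflows(gfr)
    dydt = np.zeros(N_STATE)

    c = y[_GLU] / geom.segment_volumes
    cd = y[_DRUG] / geom.segment_volumes if geom.has_drug else None
    R = _segment_rates(geom, c, cd)
    filt = gfr * forcing.glucose(t)
    inflow = np.empty(N_SEG)
    inflow[0] = filt
    inflow[1:] = Q[:-1] * c[:-1]
    dydt[_GLU] = inflow - Q * c - R
    c_ub = y[_GLU_UB] / geom.bladder_volume
    dydt[_GLU_UB] = Q[-1] * c[-1] - kx * c_ub
    dydt[_GLU_URINE] = kx * c_ub
    pct = geom.pct_mask
    dydt[_SGLT2_CUM] = R[pct].sum()
    dydt[_SGLT1_CUM] = R[~pct].sum()
    dydt[_GLU_FILT] = filt

    if geom.has_drug:
        filt_d = geom.free_fraction * gfr * forcing.drug(t)
        inflow_d = np.empty(N_SEG)
        inflow_d[0] = filt_d
        inflow_d[1:] = Q[:-1] * cd[:-1]
        dydt[_DRUG] = inflow_d - Q * cd
        cd_ub = y[_DRUG_UB] / geom.bladder_volume
        dydt[_DRUG_UB] = Q[-1] * cd[-1] - kx * cd_ub
        dydt[_DRUG_URINE] = kx * cd_ub
        dydt[_DRUG_FILT] = filt_d
    return dydt


@dataclass(frozen=True)
class SteadyStateProfile:
    """Analytic steady state of the tubule under constant forcing."""

    plasma_glucose: float            # mM
    plasma_drug_total: float         # nM
    gfr: float                       # L/h
    glucose_concentrations: np.ndarray   # mM, per sub-segment
    drug_concentrations: np.ndarray      # nM, per sub-segment
    reabsorption_rates: np.ndarray       # mmol/h, per sub-segment
    uge_rate: float                  # mmol/h leaving PST3
    segment_kind: tuple[str, ...]

    @property
    def filtered_rate(self) -> float:
        return self.gfr * self.plasma_glucose

    @property
    def sglt2_rate(self) -> float:
        pct = np.array([k == "PCT" for k in self.segment_kind])
        return float(self.reabsorption_rates[pct].sum())

    @property
    def sglt1_rate(self) -> float:
        pct = np.array([k == "PCT" for k in self.segment_kind])
        return float(self.reabsorption_rates[~pct].sum())

    @property
    def total_reabsorption_rate(self) -> float:
        return float(self.reabsorption_rates.sum())


def steady_state_profile(c_plasma_glu: float, geom: TubuleGeometry, gfr: float,
                         c_plasma_drug: float = 0.0) -> SteadyStateProfile:
    """Solve the clamped steady state sequentially along the tubule.

    In each sub-segment the steady concentration is the positive root of

        Q*C^2 + (Q*K_app + Vmax_seg - L_in)*C - L_in*K_app = 0,

    where L_in is the solute inflow (mmol/h) and K_app the drug-adjusted
    Km.  The drug, not being reabsorbed, is simply concentrated by water
    removal: c_drug_j = fup * GFR * C_plasma_drug / Q_j.
    """
    if c_plasma_glu < 0 or c_plasma_drug < 0:
        raise ValueError("plasma concentrations must be non-negative")
    if gfr <= 0:
        raise ValueError("gfr must be strictly positive")
    Q = geom.outflows(gfr)
    drug_in = geom.free_fraction * gfr * c_plasma_drug if geom.has_drug else 0.0
    c_drug = drug_in / Q if geom.has_drug else np.zeros(N_SEG)
    c = np.zeros(N_SEG)
    R = np.zeros(N_SEG)
    L_in = gfr * c_plasma_glu
    for j in range(N_SEG):
        km_app = geom.per_segment_km[j]
        if geom.has_drug:
            km_app *= 1.0 + c_drug[j] / geom.per_segment_ki[j]
        b = Q[j] * km_app + geom.per_segment_vmax[j] - L_in
        disc = b * b + 4.0 * Q[j] * L_in * km_app
        if disc < 0:
            raise ArithmeticError("no positive steady-state root")  # unreachable for valid input
        if b >= 0:
            # numerically stable form near L_in -> 0
            denom = b + np.sqrt(disc)
            c[j] = 0.0 if denom == 0 else 2.0 * L_in * km_app / denom
        else:
            c[j] = (-b + np.sqrt(disc)) / (2.0 * Q[j])
        R[j] = geom.per_segment_vmax[j] * c[j] / (km_app + c[j]) if c[j] > 0 else 0.0
        L_in = Q[j] * c[j]
    return SteadyStateProfile(plasma_glucose=c_plasma_glu,
                              plasma_drug_total=c_plasma_drug, gfr=gfr,
                              glucose_concentrations=c, drug_concentrations=c_drug,
                              reabsorption_rates=R, uge_rate=float(L_in),
                              segment_kind=geom.segment_kind)


def steady_initial_state(geom: TubuleGeometry, forcing: Forcing,
                         t0: float = 0.0) -> np.ndarray:
    """Full state vector at the analytic steady state of forcing(t0)."""
    gfr = forcing.gfr_at(t0)
    kx = forcing.kx_at(t0)
    prof = steady_state_profile(forcing.glucose(t0), geom, gfr,
                                forcing.drug(t0) if geom.has_drug else 0.0)
    y = np.zeros(N_STATE)
    y[_GLU] = prof.glucose_concentrations * geom.segment_volumes
    Q9 = geom.outflows(gfr)[-1]
    y[_GLU_UB] = prof.uge_rate / kx * geom.bladder_volume
    if geom.has_drug:
        y[_DRUG] = prof.drug_concentrations * geom.segment_volumes
        y[_DRUG_UB] = prof.drug_concentrations[-1] * Q9 / kx * geom.bladder_volume
    return y


@dataclass
class SimulationResult:
    """Trajectory of the tubule system on the requested output grid."""

    t: np.ndarray
    y: np.ndarray                   # (N_STATE, n) raw state trajectory
    geometry: TubuleGeometry
    forcing: Forcing

    @property
    def glucose_amounts(self) -> np.ndarray:
        return self.y[_GLU, :].T

    @property
    def glucose_concentrations(self) -> np.ndarray:
        return self.glucose_amounts / self.geometry.segment_volumes

    @property
    def drug_amounts(self) -> np.ndarray:
        return self.y[_DRUG, :].T

    @property
    def drug_concentrations(self) -> np.ndarray:
        return self.drug_amounts / self.geometry.segment_volumes

    @property
    def bladder_glucose(self) -> np.ndarray:
        return self.y[_GLU_UB, :]

    @property
    def urine_glucose_cum(self) -> np.ndarray:
        return self.y[_GLU_URINE, :]

    @property
    def reabsorbed_by_sglt2_cum(self) -> np.ndarray:
        return self.y[_SGLT2_CUM, :]

    @property
    def reabsorbed_by_sglt1_cum(self) -> np.ndarray:
        return self.y[_SGLT1_CUM, :]

    @property
    def reabsorbed_glucose_cum(self) -> np.ndarray:
        return self.y[_SGLT2_CUM, :] + self.y[_SGLT1_CUM, :]

    @property
    def filtered_glucose_cum(self) -> np.ndarray:
        return self.y[_GLU_FILT, :]

    @property
    def urine_drug_cum(self) -> np.ndarray:
        return self.y[_DRUG_URINE, :]

    def reabsorption_rates(self) -> np.ndarray:
        """Per-sub-segment reabsorption rates (n, 9) recomputed from state."""
        rates = np.empty((len(self.t), N_SEG))
        has_drug = self.geometry.has_drug
        for i in range(len(self.t)):
            c = np.maximum(self.glucose_concentrations[i], 0.0)
            cd = self.drug_concentrations[i] if has_drug else None
            rates[i] = _segment_rates(self.geometry, c, cd)
        return rates

    def mass_balance_error(self) -> float:
        """Max relative glucose mass-balance violation over the trajectory."""
        tubule = self.glucose_amounts.sum(axis=1) + self.bladder_glucose
        gained = self.filtered_glucose_cum - (tubule - tubule[0])
        spent = self.urine_glucose_cum + self.reabsorbed_glucose_cum
        scale = max(self.filtered_glucose_cum[-1], tubule[0], 1e-12)
        return float(np.max(np.abs(gained - spent)) / scale)

    def drug_mass_balance_error(self) -> float:
        if not self.geometry.has_drug:
            return 0.0
        tubule = self.drug_amounts.sum(axis=1) + self.y[_DRUG_UB, :]
        gained = self.y[_DRUG_FILT, :] - (tubule - tubule[0])
        scale = max(self.y[_DRUG_FILT, -1], tubule[0], 1e-12)
        return float(np.max(np.abs(gained - self.urine_drug_cum)) / scale)

    def interp_cum(self, which: str, times) -> np.ndarray:
        """Interpolate a cumulative channel at arbitrary times."""
        series = {"urine_glucose": self.urine_glucose_cum,
                  "sglt1": self.reabsorbed_by_sglt1_cum,
                  "sglt2": self.reabsorbed_by_sglt2_cum,
                  "reabsorbed": self.reabsorbed_glucose_cum,
                  "filtered": self.filtered_glucose_cum}[which]
        return np.interp(np.asarray(times, dtype=float), self.t, series)

    def to_frame(self):
        """Tidy per-time-point table (amounts, concentrations, rates)."""
        import pandas as pd

        rates = self.reabsorption_rates()
        data = {"time_h": self.t}
        for j in range(N_SEG):
            tag = f"{self.geometry.segment_kind[j].lower()}{j + 1 if j < N_PCT else j - N_PCT + 1}"
            data[f"glucose_{tag}_mmol"] = self.glucose_amounts[:, j]
            data[f"conc_{tag}_mM"] = self.glucose_concentrations[:, j]
            data[f"rate_{tag}_mmol_per_h"] = rates[:, j]
        data["bladder_glucose_mmol"] = self.bladder_glucose
        data["urine_glucose_cum_mmol"] = self.urine_glucose_cum
        data["reabsorbed_sglt1_cum_mmol"] = self.reabsorbed_by_sglt1_cum
        data["reabsorbed_sglt2_cum_mmol"] = self.reabsorbed_by_sglt2_cum
        data["filtered_glucose_cum_mmol"] = self.filtered_glucose_cum
        if self.geometry.has_drug:
            for j in range(N_SEG):
                tag = f"{self.geometry.segment_kind[j].lower()}{j + 1 if j < N_PCT else j - N_PCT + 1}"
                data[f"drug_{tag}_nM"] = self.drug_concentrations[:, j]
            data["urine_drug_cum_nmol"] = self.urine_drug_cum
        return pd.DataFrame(data)


def simulate(geom: TubuleGeometry, forcing: Forcing, t_grid: Sequence[float],
             initial: str | np.ndarray = "steady", method: str = "LSODA",
             rtol: float = 1e-8, atol: float = 1e-10,
             mass_balance_tol: float = 1e-6) -> SimulationResult:
    """Integrate the tubule ODE system over ``t_grid``.

    Parameters
    ----------
    initial:
        ``"steady"`` (analytic steady state of the forcing at t_grid[0]),
        ``"zeros"`` (empty tubule), or an explicit state vector.
    mass_balance_tol:
        Maximum tolerated relative glucose mass-balance violation; worse
        trajectories raise :class:`SimulationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if isinstance(initial, str):
        if initial == "steady":
            y0 = steady_initial_state(geom, forcing, t_grid[0])
        elif initial == "zeros":
            y0 = np.zeros(N_STATE)
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    else:
        y0 = np.asarray(initial, dtype=float).copy()
        if y0.shape != (N_STATE,):
            raise ValueError(f"initial state must have shape ({N_STATE},)")

    # restart the integrator at forcing discontinuities
    edges = [t for t in forcing.breakpoints if t_grid[0] < t < t_grid[-1]]
    spans = np.unique(np.concatenate([[t_grid[0], t_grid[-1]], edges]))
    out_t = [t_grid[:1]]
    out_y = [y0[:, None]]
    y = y0
    for a, b in zip(spans[:-1], spans[1:]):
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[mask], [b]]))
        sol = solve_ivp(ode_rhs, (a, b), y, method=method, t_eval=t_eval,
                        args=(geom, forcing), rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"integrator failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_grid[mask])
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep])
    result = SimulationResult(t=np.concatenate(out_t),
                              y=np.concatenate(out_y, axis=1),
                              geometry=geom, forcing=forcing)
    if result.y[:_GLU_URINE + 1, :].min() < -1e3 * atol:
        raise SimulationError("negative state beyond tolerance; tighten rtol/atol")
    err = result.mass_balance_error()
    if err > mass_balance_tol:
        raise SimulationError(f"glucose mass-balance violation {err:.2e} exceeds "
                              f"{mass_balance_tol:.0e}")
    return result
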