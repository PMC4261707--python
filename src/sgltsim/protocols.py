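"""Experimental designs: stepped hyperglycemic clamps and daily profiles.

A protocol packages the time-varying boundary conditions (plasma glucose,
GFR, urine outflow, optional drug) into a
:class:`~sgltsim.model_core.Forcing` plus the accounting windows used to
report per-step urinary glucose excretion (UGE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import Forcing, SimulationResult
from .units import mgdl_to_mM, mmol_to_g

DEFAULT_STEP_DURATION_H = 2.0 / 3.0  # 40-minute clamp steps


def _piecewise_constant(edges: np.ndarray, values: np.ndarray) -> Callable[[float], float]:
    def f(t: float) -> float:
        i = int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(values) - 1))
        return float(values[i])
    return f


@dataclass(frozen=True)
class ClampProtocol:
    """Stepped hyperglycemic clamp: piecewise-constant plasma glucose.

    ``step_targets_mgdl`` are the clamp targets; each step lasts
    ``step_duration_h``.  GFR and urine outflow are per-step constants.
    ``drug`` is an optional plasma drug forcing (nM), scalar or callable.
    """

    step_targets_mgdl: np.ndarray
    step_duration_h: float
    gfr_by_step: np.ndarray
    kx_by_step: np.ndarray
    drug: Callable[[float], float] | float = 0.0

    def __post_init__(self) -> None:
        targets = np.asarray(self.step_targets_mgdl, dtype=float)
        if targets.size < 1 or np.any(targets <= 0):
            raise ValueError("need at least one positive glucose target")
        if self.step_duration_h <= 0:
            raise ValueError("step_duration_h must be positive")
        for name in ("gfr_by_step", "kx_by_step"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != targets.shape:
                raise ValueError(f"{name} must match step_targets_mgdl in length")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "step_targets_mgdl", targets)

    @property
    def n_steps(self) -> int:
        return len(self.step_targets_mgdl)

    @property
    def step_edges(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.step_duration_h

    @property
    def total_duration_h(self) -> float:
        return self.n_steps * self.step_duration_h

    def forcing(self) -> Forcing:
        edges = self.step_edges[:-1]
        return Forcing(
            plasma_glucose=_piecewise_constant(edges, mgdl_to_mM(self.step_targets_mgdl)),
            gfr=_piecewise_constant(edges, self.gfr_by_step),
            urine_outflow=_piecewise_constant(edges, self.kx_by_step),
            plasma_drug_total=self.drug,
            breakpoints=tuple(self.step_edges[1:-1]),
        )


def make_shc_protocol(targets_mgdl: Sequence[float],
                      step_duration_h: float = DEFAULT_STEP_DURATION_H,
                      gfr: float | Sequence[float] = 6.5,
                      kx: float | Sequence[float] = 0.6,
                      drug: Callable[[float], float] | float = 0.0) -> ClampProtocol:
    """Build a stepped hyperglycemic clamp protocol.

    ``gfr``/``kx`` may be scalars (held over all steps) or per-step
    sequences.  The default 40-minute step reproduces the escalation
    100 -> 350 mg/dL in 4 h used by the calibration study design.
    """
    targets = np.asarray(targets_mgdl, dtype=float)
    n = targets.size
    gfr_arr = np.broadcast_to(np.asarray(gfr, dtype=float), (n,)).copy()
    kx_arr = np.broadcast_to(np.asarray(kx, dtype=float), (n,)).copy()
    return ClampProtocol(step_targets_mgdl=targets, step_duration_h=step_duration_h,
                         gfr_by_step=gfr_arr, kx_by_step=kx_arr, drug=drug)


@dataclass(frozen=True)
class DailyProfile:
    """A 24-h plasma glucose profile on a breakpoint grid (mg/dL)."""

    times_h: np.ndarray
    glucose_mgdl: np.ndarray
    declared_mean_mgdl: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        g = np.asarray(self.glucose_mgdl, dtype=float)
        if t.size != g.size or t.size < 2:
            raise ValueError("times and values must have equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "glucose_mgdl", g)
        mean = self.time_weighted_mean_mgdl
        if abs(mean - self.declared_mean_mgdl) > 0.5:
            raise ValueError(f"profile mean {mean:.2f} deviates from declared "
                             f"{self.declared_mean_mgdl:.2f} by > 0.5 mg/dL")

    @property
    def time_weighted_mean_mgdl(self) -> float:
        span = self.times_h[-1] - self.times_h[0]
        return float(np.trapezoid(self.glucose_mgdl, self.times_h) / span)

    def glucose_mM(self, t) -> float:
        """Periodic piecewise-linear interpolation (period 24 h)."""
        period = self.times_h[-1] - self.times_h[0]
        tt = self.times_h[0] + np.mod(np.asarray(t, dtype=float) - self.times_h[0], period)
        return mgdl_to_mM(np.interp(tt, self.times_h, self.glucose_mgdl))

    def forcing(self, gfr: float, kx: float) -> Forcing:
        return Forcing(plasma_glucose=self.glucose_mM, gfr=float(gfr),
                       urine_outflow=float(kx))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h, "glucose_mgdl": self.glucose_mgdl})


def synth_daily_glucose_profile(mean_mgdl: float = 90.0, min_mgdl: float = 80.0,
                                max_mgdl: float = 125.0,
                                meal_times: Sequence[float] = (7.5, 12.5, 18.5),
                                seed: int = 0,
                                resolution_h: float = 1.0 / 60.0) -> DailyProfile:
    """Constrained synthetic normoglycemic daily glucose profile.

    Three post-meal raised-cosine excursions ride on a nocturnal floor;
    seeded jitter perturbs meal timing and relative amplitudes, after
    which the floor and excursion gain are set so that the time-weighted
    mean equals ``mean_mgdl`` exactly (on the breakpoint grid) and the
    range stays inside [min_mgdl, max_mgdl].  Deterministic given seed.
    """
    if not min_mgdl <= mean_mgdl <= max_mgdl:
        raise ValueError("need min_mgdl <= mean_mgdl <= max_mgdl")
    t = np.arange(0.0, 24.0 + resolution_h / 2, resolution_h)
    if max_mgdl == min_mgdl:
        return DailyProfile(times_h=t, glucose_mgdl=np.full_like(t, mean_mgdl),
                            declared_mean_mgdl=mean_mgdl)
    rng = np.random.default_rng(seed)
    width = 4.0
    shape = np.zeros_like(t)
    for m in meal_times:
        mt = m + rng.uniform(-0.5, 0.5)
        amp = rng.uniform(0.85, 1.0)
        x = (t - mt) / width
        mask = np.abs(x) < 0.5
        shape[mask] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * x[mask]))
    peak = shape.max()
    if peak > 0:
        shape /= peak
    mshape = float(np.trapezoid(shape, t) / (t[-1] - t[0]))
    if mshape in (0.0, 1.0):
        gain = 0.0
    else:
        gain = min((mean_mgdl - min_mgdl) / mshape,
                   (max_mgdl - mean_mgdl) / (1.0 - mshape))
    base = mean_mgdl - gain * mshape
    profile = base + gain * shape
    return DailyProfile(times_h=t, glucose_mgdl=profile, declared_mean_mgdl=mean_mgdl)


def stepwise_uge(result: SimulationResult, protocol: ClampProtocol) -> pd.DataFrame:
    """Per-step and cumulative urinary glucose excretion in grams.

    Each step's UGE is the urine-compartment glucose mass accumulated in
    its window; the cumulative column is the running sum and its final
    value equals total simulated UGE.
    """
    edges = protocol.step_edges
    if edges[0] < result.t[0] - 1e-9 or edges[-1] > result.t[-1] + 1e-9:
        raise ValueError("protocol windows extend outside the simulated span")
    cum_mmol = result.interp_cum("urine_glucose", edges)
    per_step = np.diff(cum_mmol)
    return pd.DataFrame({
        "step": np.arange(1, protocol.n_steps + 1),
        "target_mgdl": protocol.step_targets_mgdl,
        "t_start_h": edges[:-1],
        "t_end_h": edges[1:],
        "uge_g": mmol_to_g(per_step),
        "uge_cum_g": mmol_to_g(np.cumsum(per_step)),
    })
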