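"""Derived quantities and simulation experiments.

Implements the reporting layer on top of the tubule simulator: the split
of reabsorption between SGLT1 and SGLT2, each transporter's operation
efficiency (reabsorption rate as a fraction of its capacity),
loss-of-function scans against a daily glucose profile, sensitivity scans
of SGLT1 kinetics under a stepped clamp, and SGLT2 occupancy / residual
activity under inhibition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import Forcing, SimulationResult, build_geometry, simulate
from .params import InhibitorParams, PhysiologyParams, TransporterParams
from .protocols import ClampProtocol, DailyProfile
from .units import mmol_to_g

Windows = Sequence[tuple[float, float]]


def _default_windows(result: SimulationResult) -> list[tuple[float, float]]:
    return [(float(result.t[0]), float(result.t[-1]))]


def _check_windows(result: SimulationResult, windows: Windows) -> None:
    for a, b in windows:
        if b <= a:
            raise ValueError(f"degenerate window ({a}, {b})")
        if a < result.t[0] - 1e-9 or b > result.t[-1] + 1e-9:
            raise ValueError(f"window ({a}, {b}) outside simulated span")


def transporter_contributions(result: SimulationResult,
                              windows: Windows | None = None) -> pd.DataFrame:
    """Per-window reabsorbed mass and fractional share of each transporter.

    Shares are NaN (and flagged ``undefined``) for windows with zero total
    reabsorption.
    """
    windows = list(windows) if windows is not None else _default_windows(result)
    _check_windows(result, windows)
    rows = []
    for a, b in windows:
        s1 = np.diff(result.interp_cum("sglt1", [a, b]))[0]
        s2 = np.diff(result.interp_cum("sglt2", [a, b]))[0]
        total = s1 + s2
        undefined = total <= 0
        rows.append({
            "t_start_h": a, "t_end_h": b,
            "sglt1_mmol": s1, "sglt2_mmol": s2, "total_mmol": total,
            "sglt1_share": np.nan if undefined else s1 / total,
            "sglt2_share": np.nan if undefined else s2 / total,
            "undefined": undefined,
        })
    return pd.DataFrame(rows)


def operation_efficiency(result: SimulationResult,
                         windows: Windows | None = None) -> pd.DataFrame:
    """Window-average reabsorption rate of each transporter as a fraction
    of its whole-kidney capacity (in [0, 1])."""
    windows = list(windows) if windows is not None else _default_windows(result)
    _check_windows(result, windows)
    geom = result.geometry
    rows = []
    for a, b in windows:
        dt = b - a
        r1 = np.diff(result.interp_cum("sglt1", [a, b]))[0] / dt
        r2 = np.diff(result.interp_cum("sglt2", [a, b]))[0] / dt
        rows.append({
            "t_start_h": a, "t_end_h": b,
            "sglt1_rate_mmol_per_h": r1, "sglt2_rate_mmol_per_h": r2,
            "sglt1_efficiency": r1 / geom.vmax_sglt1 if geom.vmax_sglt1 > 0 else np.nan,
            "sglt2_efficiency": r2 / geom.vmax_sglt2 if geom.vmax_sglt2 > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def _run_daily(profile: DailyProfile, phys: PhysiologyParams,
               trans: TransporterParams, drug: InhibitorParams | None,
               drug_forcing, n_out: int = 241) -> SimulationResult:
    geom = build_geometry(phys, trans, drug)
    base = profile.forcing(phys.gfr, phys.urine_outflow)
    forcing = Forcing(plasma_glucose=base.plasma_glucose, gfr=base.gfr,
                      urine_outflow=base.urine_outflow,
                      plasma_drug_total=drug_forcing if drug is not None else 0.0)
    t_grid = np.linspace(0.0, 24.0, n_out)
    return simulate(geom, forcing, t_grid, initial="steady")


def loss_of_function_scan(transporter: str, fractions: Sequence[float],
                          profile: DailyProfile, phys: PhysiologyParams,
                          trans: TransporterParams,
                          drug: InhibitorParams | None = None,
                          drug_forcing=0.0) -> pd.DataFrame:
    """Daily UGE and reabsorption loss vs. fractional loss of one transporter.

    For each fraction f the chosen transporter's capacity is scaled by
    (1 - f) and a 24-h simulation is run under ``profile``; reported are
    daily UGE (g) and the percent reduction in total reabsorbed glucose
    relative to the intact (f = 0) run.
    """
    if transporter not in ("sglt1", "sglt2"):
        raise ValueError("transporter must be 'sglt1' or 'sglt2'")
    fractions = np.asarray(list(fractions), dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    intact = _run_daily(profile, phys, trans, drug, drug_forcing)
    reab_intact = intact.reabsorbed_glucose_cum[-1]
    rows = []
    for f in fractions:
        if f == 0.0:
            res = intact
        else:
            scaled = trans.scale_vmax(**{transporter: 1.0 - f})
            res = _run_daily(profile, phys, scaled, drug, drug_forcing)
        reab = res.reabsorbed_glucose_cum[-1]
        rows.append({
            "fraction_lost": f,
            "uge_g_per_day": mmol_to_g(res.urine_glucose_cum[-1]),
            "reabsorbed_mmol_per_day": reab,
            "reabsorption_reduction_pct":
                100.0 * (1.0 - reab / reab_intact) if reab_intact > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def sensitivity_scan(param: str, values: Sequence[float], protocol: ClampProtocol,
                     phys: PhysiologyParams, trans: TransporterParams,
                     drug: InhibitorParams | None = None) -> pd.DataFrame:
    """UGE under the stepped clamp as one SGLT1 kinetic parameter varies.

    ``param`` is one of ``vmax1``, ``km1``, ``ki1`` (the last requires a
    drug).  The percent change column is relative to the run at the
    nominal (unmodified) parameter value.
    """
    from dataclasses import replace

    if param not in ("vmax1", "km1", "ki1"):
        raise ValueError("param must be one of 'vmax1', 'km1', 'ki1'")
    if param == "ki1" and drug is None:
        raise ValueError("ki1 sensitivity requires a drug")
    values = np.asarray(list(values), dtype=float)
    if np.any(values <= 0):
        raise ValueError("values must be strictly positive")

    def run(tr: TransporterParams, dr: InhibitorParams | None) -> float:
        geom = build_geometry(phys, tr, dr)
        forcing = protocol.forcing()
        t_grid = np.linspace(0.0, protocol.total_duration_h,
                             max(2, protocol.n_steps * 20 + 1))
        res = simulate(geom, forcing, t_grid, initial="steady")
        return mmol_to_g(res.urine_glucose_cum[-1])

    ref_uge = run(trans, drug)
    rows = []
    for v in values:
        if param == "ki1":
            uge = run(trans, replace(drug, ki1=float(v)))
        else:
            uge = run(replace(trans, **{param: float(v)}), drug)
        rows.append({
            "param": param, "value": float(v), "uge_g": uge,
            "pct_change_vs_reference": 100.0 * (uge - ref_uge) / ref_uge
            if ref_uge > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def occupancy_and_residual(result: SimulationResult,
                           windows: Windows | None = None,
                           convention: str = "luminal") -> pd.DataFrame:
    """SGLT2 occupancy by the inhibitor and residual SGLT2 rate per window.

    Occupancy is c/(c + Ki2) with ``c`` the drug concentration averaged
    over the PCT sub-segments — luminal by default (the site of
    competition), or plasma with ``convention="plasma"``.  Residual SGLT2
    activity is the window-average PCT reabsorption rate (mmol/h).
    """
    windows = list(windows) if windows is not None else _default_windows(result)
    _check_windows(result, windows)
    geom = result.geometry
    rows = []
    for a, b in windows:
        dt = b - a
        residual = np.diff(result.interp_cum("sglt2", [a, b]))[0] / dt
        if not geom.has_drug:
            occ = 0.0
        else:
            ki2 = float(geom.per_segment_ki[geom.pct_mask][0])
            mask = (result.t >= a - 1e-12) & (result.t <= b + 1e-12)
            tt = result.t[mask]
            if convention == "luminal":
                cd = result.drug_concentrations[mask][:, geom.pct_mask].mean(axis=1)
            elif convention == "plasma":
                cd = np.array([result.forcing.drug(x) for x in tt])
            else:
                raise ValueError("convention must be 'luminal' or 'plasma'")
            occ_t = cd / (cd + ki2)
            occ = float(np.trapezoid(occ_t, tt) / (tt[-1] - tt[0])) if len(tt) > 1 \
                else float(occ_t.mean())
        rows.append({"t_start_h": a, "t_end_h": b,
                     "sglt2_occupancy": occ,
                     "residual_sglt2_rate_mmol_per_h": residual})
    return pd.DataFrame(rows)
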