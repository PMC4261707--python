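"""Estimation of transporter kinetics from step-wise clamp UGE tables.

The calibration mirrors the strategy used to parameterise the model:
literature values serve as starting points, data points whose actual
plasma glucose deviates 25% or more from the group mean are excluded,
the fit is restricted to the clinically relevant glucose range
(100-400 mg/dL by default), and the healthy SGLT2 capacity is estimated
as a proportion of the diabetic one.  Separating V_max1 from V_max2 (and
identifying Ki2) requires arms both with and without SGLT2 inhibition.

The forward model for a clamp step is quasi-steady: the tubule transit
time (about a minute) is short relative to a 40-minute step, so per-step
UGE is the analytic steady-state excretion rate at the step's actual
glucose times the step duration, accounted at bladder inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import build_geometry, steady_state_profile
from .params import (InhibitorParams, PhysiologyParams, TransporterParams,
                     calibration_starting_points, inhibitor_params,
                     physiology_defaults)
from .units import mgdl_to_mM, mmol_to_g

PARAM_ORDER = ("vmax1", "vmax2_t2dm", "healthy_vmax2_prop", "km1", "km2", "ki2")

REQUIRED_COLUMNS = ("arm", "step", "target_mgdl", "actual_mgdl", "group_mean_mgdl",
                    "uge_g", "gfr_L_per_h", "kx_L_per_h", "drug_nM",
                    "step_duration_h")

DEFAULT_BOUNDS = {
    "vmax1": (1.0, 100.0),
    "vmax2_t2dm": (10.0, 400.0),
    "healthy_vmax2_prop": (0.1, 2.0),
    "km1": (0.05, 20.0),
    "km2": (0.5, 50.0),
    "ki2": (0.01, 100.0),
}


@dataclass(frozen=True)
class UGEDataset:
    """Step-wise clamp UGE observations for one or more arms.

    Arms are labelled ``healthy_baseline``, ``healthy_drug``,
    ``t2dm_baseline``, ``t2dm_drug``; the subject class is the prefix.
    Column schema is :data:`REQUIRED_COLUMNS` (units in the names).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.table["uge_g"] < 0).any():
            raise ValueError("UGE must be non-negative")

    @property
    def arms(self) -> list[str]:
        return sorted(self.table["arm"].unique())

    @property
    def has_drug_arm(self) -> bool:
        return bool((self.table["drug_nM"] > 0).any())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UGEDataset":
        return cls(pd.read_csv(path))


def exclude_deviant_points(dataset: UGEDataset | pd.DataFrame,
                           tolerance: float = 0.25) -> tuple[UGEDataset, dict]:
    """Drop records whose actual glucose deviates >= ``tolerance`` (relative)
    from the group mean; the boundary itself is excluded."""
    df = dataset.table if isinstance(dataset, UGEDataset) else dataset
    if df["group_mean_mgdl"].isna().any():
        raise ValueError("group means are required for the exclusion rule")
    rel_dev = (df["actual_mgdl"] - df["group_mean_mgdl"]).abs() / df["group_mean_mgdl"]
    keep = rel_dev < tolerance
    report = {
        "n_total": int(len(df)),
        "n_excluded": int((~keep).sum()),
        "fraction_excluded": float((~keep).mean()) if len(df) else 0.0,
        "tolerance": tolerance,
    }
    return UGEDataset(df[keep].reset_index(drop=True)), report


@dataclass
class CalibrationSpec:
    """Free parameters with bounds/starting points and fitting options."""

    free: dict[str, tuple[float, float, float]]   # name -> (start, lo, hi)
    fixed: dict[str, float] = field(default_factory=dict)
    phys: PhysiologyParams = field(default_factory=physiology_defaults)
    drug: InhibitorParams | None = None
    glucose_range_mgdl: tuple[float, float] = (100.0, 400.0)
    weighting: str = "relative"        # or "absolute" (unit weights on grams)

    def __post_init__(self) -> None:
        for name, (start, lo, hi) in self.free.items():
            if name not in PARAM_ORDER:
                raise ValueError(f"unknown parameter {name!r}")
            if not lo <= start <= hi:
                raise ValueError(f"starting point for {name} outside its bounds")
        if self.weighting not in ("absolute", "relative"):
            raise ValueError("weighting must be 'absolute' or 'relative'")


def default_calibration_spec(drug_name: str = "dapagliflozin",
                             **overrides) -> CalibrationSpec:
    """Spec with the literature starting points and generous bounds."""
    starts = calibration_starting_points()
    free = {name: (starts[name], *DEFAULT_BOUNDS[name]) for name in PARAM_ORDER}
    return CalibrationSpec(free=free, drug=inhibitor_params(drug_name), **overrides)


def _full_params(free_values: dict[str, float], spec: CalibrationSpec) -> dict[str, float]:
    starts = calibration_starting_points()
    full = {name: spec.fixed.get(name, starts[name]) for name in PARAM_ORDER}
    full.update(free_values)
    return full


def predict_step_uge_g(actual_mgdl: float, gfr: float, duration_h: float,
                       vmax1: float, vmax2: float, km1: float, km2: float,
                       phys: PhysiologyParams,
                       drug: InhibitorParams | None = None,
                       drug_nM: float = 0.0) -> float:
    """Quasi-steady per-step UGE (g): steady excretion rate x duration."""
    trans = TransporterParams(vmax1=vmax1, vmax2=vmax2, km1=km1, km2=km2)
    geom = build_geometry(phys, trans, drug if drug_nM > 0 else None)
    prof = steady_state_profile(mgdl_to_mM(actual_mgdl), geom, gfr,
                                drug_nM if drug_nM > 0 else 0.0)
    return mmol_to_g(prof.uge_rate * duration_h)


def _predict_dataset(df: pd.DataFrame, params: dict[str, float],
                     spec: CalibrationSpec) -> np.ndarray:
    pred = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        healthy = str(row.arm).startswith("healthy")
        vmax2 = params["vmax2_t2dm"] * (params["healthy_vmax2_prop"] if healthy else 1.0)
        drug = None
        if row.drug_nM > 0:
            if spec.drug is None:
                raise ValueError("dataset has drug arms but spec.drug is None")
            drug = replace(spec.drug, ki2=params["ki2"])
        try:
            pred[i] = predict_step_uge_g(row.actual_mgdl, row.gfr_L_per_h,
                                         row.step_duration_h, params["vmax1"],
                                         vmax2, params["km1"], params["km2"],
                                         spec.phys, drug, row.drug_nM)
        except (ValueError, ArithmeticError):
            pred[i] = np.inf     # large finite penalty applied by the caller
    return pred


def _filtered_table(datasets, spec: CalibrationSpec) -> pd.DataFrame:
    if isinstance(datasets, UGEDataset):
        datasets = [datasets]
    df = pd.concat([d.table for d in datasets], ignore_index=True)
    lo, hi = spec.glucose_range_mgdl
    return df[(df["actual_mgdl"] >= lo) & (df["actual_mgdl"] <= hi)].reset_index(drop=True)


def _residuals(df: pd.DataFrame, params: dict[str, float],
               spec: CalibrationSpec) -> np.ndarray:
    pred = _predict_dataset(df, params, spec)
    bad = ~np.isfinite(pred)
    pred[bad] = 1e6
    resid = pred - df["uge_g"].to_numpy()
    if spec.weighting == "relative":
        resid = resid / np.maximum(df["uge_g"].to_numpy(), 0.1)
    return resid


def objective(params_free: dict[str, float], datasets, spec: CalibrationSpec) -> float:
    """Sum of weighted squared per-step UGE residuals inside the glucose
    range filter (steps outside 100-400 mg/dL are not fitted)."""
    df = _filtered_table(datasets, spec)
    if df.empty:
        raise ValueError("no data points inside the glucose-range filter")
    r = _residuals(df, _full_params(params_free, spec), spec)
    return float(np.sum(r * r))


@dataclass
class CalibrationResult:
    estimates: dict[str, float]
    free_names: tuple[str, ...]
    success: bool
    cost: float
    fit_table: pd.DataFrame
    flags: dict[str, str]
    message: str = ""

    def to_json_dict(self) -> dict:
        return {"estimates": self.estimates, "free": list(self.free_names),
                "success": self.success, "cost": self.cost, "flags": self.flags,
                "message": self.message}


def calibrate(datasets, spec: CalibrationSpec | None = None, seed: int = 0,
              n_starts: int = 1) -> CalibrationResult:
    """Bounded least-squares calibration from the literature starting points.

    Structural identifiability is checked up front: without any drug arm
    Ki2 drops out of the model, so it is removed from the free set and
    flagged, and the degraded V_max1/V_max2 separation is flagged too.
    Multi-start (``n_starts`` > 1) perturbs the starting points
    lognormally with the given seed and keeps the best fit.
    """
    if spec is None:
        spec = default_calibration_spec()
    if isinstance(datasets, UGEDataset):
        datasets = [datasets]
    df = _filtered_table(datasets, spec)
    if df.empty:
        raise ValueError("no data points inside the glucose-range filter")

    flags: dict[str, str] = {}
    free = dict(spec.free)
    has_drug = bool((df["drug_nM"] > 0).any())
    if not has_drug:
        if "ki2" in free:
            free.pop("ki2")
            flags["ki2"] = ("non-identifiable: no arm with SGLT2 inhibition; "
                            "held at its starting value")
        flags["vmax_separation"] = ("degraded: separating V_max1 from V_max2 "
                                    "requires arms with and without SGLT2 "
                                    "perturbation")
    names = tuple(n for n in PARAM_ORDER if n in free)
    x0 = np.array([free[n][0] for n in names])
    lo = np.array([free[n][1] for n in names])
    hi = np.array([free[n][2] for n in names])

    def resid_vec(x: np.ndarray) -> np.ndarray:
        return _residuals(df, _full_params(dict(zip(names, x)), spec), spec)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x_start = x0 if start == 0 else np.clip(
            x0 * rng.lognormal(0.0, 0.2, size=x0.size), lo, hi)
        sol = least_squares(resid_vec, x_start, bounds=(lo, hi), method="trf",
                            x_scale=np.maximum(x0, 1e-3), max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
    estimates = _full_params(dict(zip(names, best.x)), spec)
    fit = df.copy()
    fit["uge_pred_g"] = _predict_dataset(df, estimates, spec)
    fit["residual_g"] = fit["uge_pred_g"] - fit["uge_g"]
    return CalibrationResult(estimates=estimates, free_names=names,
                             success=bool(best.success), cost=float(2 * best.cost),
                             fit_table=fit, flags=flags, message=best.message)
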