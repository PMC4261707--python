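"""Synthetic fixture data with the statistical structure calibration assumes.

Clamp UGE tables are generated by running the forward model at known
"truth" parameters and applying multiplicative lognormal noise (UGE and
PK concentrations are positive and right-skewed).  Per-step GFR and
urine outflow are drawn uniformly from the printed per-arm ranges, and
the actual glucose jitters within +/-5% of the clamp target.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import UGEDataset, predict_step_uge_g
from .params import (InhibitorParams, PhysiologyParams, clamp_arm_range,
                     inhibitor_params, physiology_defaults, transporter_params)
from .pk import EmpiricalPKProfile, TwoCompartmentPK
from .protocols import DEFAULT_STEP_DURATION_H

DEFAULT_TARGETS_MGDL = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0,
                        400.0, 450.0, 500.0, 550.0)

ALL_ARMS = ("healthy_baseline", "healthy_drug", "t2dm_baseline", "t2dm_drug")


def default_truth() -> dict[str, float]:
    """Registry parameter values in the calibration parameterization."""
    healthy = transporter_params("healthy")
    t2dm = transporter_params("t2dm")
    drug = inhibitor_params("dapagliflozin")
    return {
        "vmax1": t2dm.vmax1,
        "vmax2_t2dm": t2dm.vmax2,
        "healthy_vmax2_prop": healthy.vmax2 / t2dm.vmax2,
        "km1": t2dm.km1,
        "km2": t2dm.km2,
        "ki2": drug.ki2,
    }


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    # always consume the same number of draws so that noise_cv=0 shares
    # the gfr/glucose realisations of the matching noisy dataset
    z = rng.standard_normal(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * z - sigma * sigma / 2.0)   # unit mean


def synth_shc_uge_dataset(truth: dict[str, float] | None = None,
                          targets_mgdl: Sequence[float] = DEFAULT_TARGETS_MGDL,
                          step_duration_h: float = DEFAULT_STEP_DURATION_H,
                          noise_cv: float = 0.0, seed: int = 0,
                          arms: Sequence[str] = ALL_ARMS,
                          drug: InhibitorParams | None = None,
                          drug_plasma_nM: float = 400.0,
                          phys: PhysiologyParams | None = None) -> UGEDataset:
    """Four-arm stepped-clamp UGE dataset at known truth parameters.

    ``drug_plasma_nM`` is the constant total plasma inhibitor level in the
    drug arms (default a dapagliflozin-like steady exposure).  With
    ``noise_cv = 0`` the UGE column equals the forward model exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    truth = dict(default_truth() if truth is None else truth)
    drug = inhibitor_params("dapagliflozin") if drug is None else drug
    drug = replace(drug, ki2=truth["ki2"])
    phys = physiology_defaults() if phys is None else phys
    rng = np.random.default_rng(seed)
    targets = np.asarray(targets_mgdl, dtype=float)
    rows = []
    for arm in arms:
        rng_range = clamp_arm_range(arm)
        glo, ghi = rng_range["gfr_L_per_h"]
        klo, khi = rng_range["urine_outflow_L_per_h"]
        healthy = arm.startswith("healthy")
        vmax2 = truth["vmax2_t2dm"] * (truth["healthy_vmax2_prop"] if healthy else 1.0)
        drug_nM = drug_plasma_nM if arm.endswith("drug") else 0.0
        gfr_steps = rng.uniform(glo, ghi, size=targets.size)
        kx_steps = rng.uniform(klo, khi, size=targets.size)
        actual = targets * (1.0 + rng.uniform(-0.05, 0.05, size=targets.size))
        noise = _lognormal_factor(rng, noise_cv, targets.size)
        for k, target in enumerate(targets):
            uge = predict_step_uge_g(actual[k], gfr_steps[k], step_duration_h,
                                     truth["vmax1"], vmax2, truth["km1"],
                                     truth["km2"], phys,
                                     drug if drug_nM > 0 else None, drug_nM)
            rows.append({
                "arm": arm, "step": k + 1, "target_mgdl": target,
                "actual_mgdl": actual[k], "group_mean_mgdl": target,
                "uge_g": uge * noise[k], "gfr_L_per_h": gfr_steps[k],
                "kx_L_per_h": kx_steps[k], "drug_nM": drug_nM,
                "step_duration_h": step_duration_h,
            })
    return UGEDataset(pd.DataFrame(rows))


def synth_pk_samples(two_comp_truth: TwoCompartmentPK, times: Sequence[float],
                     noise_cv: float = 0.0, seed: int = 0) -> EmpiricalPKProfile:
    """Sampled plasma concentrations from a known two-compartment model.

    Returns an :class:`EmpiricalPKProfile` in ng/mL with multiplicative
    lognormal noise; ``noise_cv = 0`` reproduces the model exactly.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    nM = np.atleast_1d(two_comp_truth.concentration_nM(times))
    ng_ml = nM * two_comp_truth.molecular_weight / 1000.0
    ng_ml = ng_ml * _lognormal_factor(rng, noise_cv, times.size)
    return EmpiricalPKProfile(sample_times=times, concentrations=ng_ml,
                              molecular_weight=two_comp_truth.molecular_weight)
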