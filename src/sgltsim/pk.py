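"""Plasma drug-concentration forcing for the tubule model.

Two interchangeable sources are provided: a closed-form two-compartment
model with first-order oral absorption and multiple-dose superposition
(canagliflozin-style dosing), and a piecewise-linear empirical profile
(dapagliflozin-style, interpolating observed mean concentrations).  Both
expose total plasma concentration in nM as a callable of time, so either
can serve as the drug channel of a :class:`~sgltsim.model_core.Forcing`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TwoCompartmentPK:
    """Two-compartment disposition with first-order oral absorption.

    Parameters are clearance-style: ``cl`` elimination clearance (L/h),
    ``vc``/``vp`` central/peripheral volumes (L), ``q`` inter-compartment
    clearance (L/h), ``ka`` absorption rate constant (1/h).  ``dose`` is
    the oral dose in mg given every ``interval`` hours for ``n_doses``
    doses starting at t = 0.  Bioavailability is absorbed into vc/cl.
    """

    ka: float
    cl: float
    vc: float
    q: float
    vp: float
    dose: float
    interval: float = 24.0
    n_doses: int = 1
    molecular_weight: float = 454.0

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "vc", "vp", "interval", "molecular_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.q < 0 or self.dose < 0 or self.n_doses < 1:
            raise ValueError("q and dose must be non-negative, n_doses >= 1")

    def _disposition_rates(self) -> tuple[float, float]:
        k10 = self.cl / self.vc
        k12 = self.q / self.vc
        k21 = self.q / self.vp
        s = k10 + k12 + k21
        disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = (s + disc) / 2.0
        beta = (s - disc) / 2.0
        return alpha, beta

    def _single_dose_mg_per_L(self, t: np.ndarray) -> np.ndarray:
        """Central concentration (mg/L) after one dose at t = 0."""
        t = np.asarray(t, dtype=float)
        alpha, beta = self._disposition_rates()
        k21 = self.q / self.vp
        ka = self.ka
        # guard exact pole coincidences by nudging ka
        if np.isclose(ka, alpha) or np.isclose(ka, beta):
            ka *= 1.0 + 1e-9
        coeff = self.dose * ka / self.vc
        A = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
        B = (k21 - beta) / ((ka - beta) * (alpha - beta))
        C = (k21 - ka) / ((alpha - ka) * (beta - ka))
        out = coeff * (A * np.exp(-alpha * t) + B * np.exp(-beta * t)
                       + C * np.exp(-ka * t))
        return np.where(t >= 0, out, 0.0)

    def concentration_nM(self, t) -> np.ndarray:
        """Total plasma concentration (nM) with multiple-dose superposition."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        c = np.zeros_like(t)
        for i in range(self.n_doses):
            c += self._single_dose_mg_per_L(t - i * self.interval)
        # mg/L -> nM: mg/L / (g/mol) = mmol/m^3 = uM; * 1000 = nM
        nM = c / self.molecular_weight * 1.0e6
        return nM if nM.shape != (1,) else float(nM[0])


@dataclass(frozen=True)
class EmpiricalPKProfile:
    """Sampled plasma concentrations with piecewise-linear interpolation.

    ``concentrations`` are in ng/mL; queries return nM via the molecular
    weight.  Outside the sampled span the profile extends flat from the
    edge samples (``extrapolate="flat"``) or raises (``"error"``).
    """

    sample_times: np.ndarray
    concentrations: np.ndarray
    molecular_weight: float
    extrapolate: str = "flat"

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size == 0:
            raise ValueError("profile needs at least one sample")
        if t.size != c.size:
            raise ValueError("sample_times and concentrations differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "concentrations", c)

    def concentration_nM(self, t) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self.extrapolate == "error" and (
                t_arr.min() < self.sample_times[0] or t_arr.max() > self.sample_times[-1]):
            raise ValueError("query time outside sampled span and extrapolation disabled")
        ng_ml = np.interp(t_arr, self.sample_times, self.concentrations)
        nM = ng_ml / self.molecular_weight * 1000.0
        return nM if nM.shape != (1,) else float(nM[0])


def pk_concentration(model: TwoCompartmentPK | EmpiricalPKProfile, t):
    """Total plasma concentration (nM) at time(s) t for either PK source."""
    return model.concentration_nM(t)


def filtered_drug_rate(c_plasma_total: float, fup: float, gfr: float) -> float:
    """Glomerular filtration rate of drug (nmol/h): only the unbound
    fraction of plasma drug is filtered."""
    if c_plasma_total < 0 or fup < 0 or gfr < 0:
        raise ValueError("inputs must be non-negative")
    return fup * gfr * c_plasma_total


@dataclass
class PKFitResult:
    model: TwoCompartmentPK
    success: bool
    cost: float
    residuals: np.ndarray
    message: str = ""


def fit_two_compartment(samples: EmpiricalPKProfile, init: TwoCompartmentPK) -> PKFitResult:
    """Least-squares fit of the two-compartment model to sampled PK.

    Residuals are taken on the log scale (concentrations are positive and
    right-skewed); parameters are optimised in log space, which enforces
    positivity.  Dose, interval and n_doses are held at the ``init``
    values — only ka, cl, vc, q, vp are free.
    """
    if samples.sample_times.size < 5:
        raise ValueError("need at least 5 PK samples to fit five parameters")
    obs_nM = samples.concentrations / samples.molecular_weight * 1000.0
    if np.any(obs_nM <= 0):
        raise ValueError("log-residual fit requires strictly positive concentrations")
    t = samples.sample_times
    names = ("ka", "cl", "vc", "q", "vp")
    x0 = np.log([getattr(init, n) for n in names])

    def unpack(x: np.ndarray) -> TwoCompartmentPK:
        vals = dict(zip(names, np.exp(x)))
        return replace(init, molecular_weight=samples.molecular_weight, **vals)

    def resid(x: np.ndarray) -> np.ndarray:
        pred = np.atleast_1d(unpack(x).concentration_nM(t))
        return np.log(np.maximum(pred, 1e-12)) - np.log(obs_nM)

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    fitted = unpack(sol.x)
    return PKFitResult(model=fitted, success=bool(sol.success), cost=float(sol.cost),
                       residuals=sol.fun, message=sol.message)


def synthetic_dapagliflozin_profile(dose_mg: float = 10.0) -> EmpiricalPKProfile:
    """Synthetic stand-in for a day-7 once-daily dapagliflozin profile.

    This is NOT an observed data set: the study mean profile is not
    publicly tabulated, so drug-arm demonstrations use this plausible
    10 mg steady-state curve (tmax ~1 h, t1/2 ~13 h, Cmax ~140 ng/mL,
    scaled linearly with dose).  Never used for quantitative targets.
    """
    times = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0])
    base = np.array([15.0, 95.0, 140.0, 132.0, 120.0, 98.0, 82.0, 60.0, 45.0,
                     28.0, 20.0, 15.0])
    return EmpiricalPKProfile(sample_times=times,
                              concentrations=base * (dose_mg / 10.0),
                              molecular_weight=409.0)
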