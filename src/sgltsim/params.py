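"""Parameter containers and the shipped parameter registry.

The registry (``data/parameters.json``) holds the default renal physiology
(volumes, flows), transporter kinetics for the ``healthy`` and ``t2dm``
subject classes, inhibitor physicochemistry/affinities for dapagliflozin
and canagliflozin, the per-arm GFR and urine-flow ranges of the stepped
hyperglycemic clamp study used for calibration, and literature starting
points for calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources


@dataclass(frozen=True)
class PhysiologyParams:
    """Renal physiology: compartment volumes and water flows.

    Attributes
    ----------
    renal_cortex_volume:
        Volume of the renal cortex (L).
    pt_fraction_of_cortex:
        Proximal-tubule volume as a fraction of cortex volume.
    pct_fraction_of_pt:
        Convoluted-tubule (PCT) volume as a fraction of proximal-tubule
        volume; the straight tubule (PST) takes the complement.
    bladder_volume:
        Urinary bladder volume (L), treated as fixed and well mixed.
    gfr:
        Glomerular filtration rate (L/h).
    urine_outflow:
        Flow out of the bladder into collected urine (L/h).
    flow_decrement:
        Fractional loss of filtrate flow per sub-segment; outflow of
        sub-segment i is (1 - i * flow_decrement) * GFR, i = 1..9.
    """

    renal_cortex_volume: float = 0.216
    pt_fraction_of_cortex: float = 0.3
    pct_fraction_of_pt: float = 0.7
    bladder_volume: float = 0.2
    gfr: float = 6.5
    urine_outflow: float = 0.6
    flow_decrement: float = 0.074

    def __post_init__(self) -> None:
        for name in ("renal_cortex_volume", "pt_fraction_of_cortex",
                     "bladder_volume", "gfr", "urine_outflow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.pct_fraction_of_pt < 1:
            raise ValueError("pct_fraction_of_pt must lie in (0, 1)")
        if self.flow_decrement <= 0 or self.flow_decrement * 9 >= 1:
            raise ValueError("flow_decrement must satisfy 0 < 9*decrement < 1 "
                             "(last sub-segment outflow stays positive)")

    @property
    def pst_fraction_of_pt(self) -> float:
        return 1.0 - self.pct_fraction_of_pt

    def with_gfr(self, gfr: float) -> "PhysiologyParams":
        return replace(self, gfr=gfr)


@dataclass(frozen=True)
class TransporterParams:
    """SGLT1/SGLT2 kinetics for one subject class.

    ``vmax2``/``km2`` describe SGLT2 (low affinity, high capacity; PCT1-6);
    ``vmax1``/``km1`` describe SGLT1 (high affinity, low capacity; PST1-3).
    Capacities are whole-kidney (mmol/h) and are split uniformly over the
    sub-segments hosting each transporter.
    """

    vmax1: float
    vmax2: float
    km1: float
    km2: float
    subject_class: str = "healthy"

    def __post_init__(self) -> None:
        for name in ("vmax1", "vmax2", "km1", "km2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.km1 <= 0 or self.km2 <= 0:
            raise ValueError("km1 and km2 must be strictly positive")

    def scale_vmax(self, *, sglt1: float = 1.0, sglt2: float = 1.0) -> "TransporterParams":
        """Return a copy with the capacities scaled (loss-of-function proxy)."""
        return replace(self, vmax1=self.vmax1 * sglt1, vmax2=self.vmax2 * sglt2)


@dataclass(frozen=True)
class InhibitorParams:
    """An SGLT inhibitor: physicochemistry and affinity for both transporters."""

    molecular_weight: float
    free_fraction: float
    ki1: float
    ki2: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if not 0 < self.free_fraction <= 1:
            raise ValueError("free_fraction must lie in (0, 1]")
        if self.ki1 <= 0 or self.ki2 <= 0:
            raise ValueError("ki1 and ki2 must be strictly positive")


@lru_cache(maxsize=1)
def load_registry() -> dict:
    """Load the shipped parameter registry as a plain dict."""
    with resources.files("sgltsim.data").joinpath("parameters.json").open() as fh:
        return json.load(fh)


def physiology_defaults(**overrides: float) -> PhysiologyParams:
    p = load_registry()["physiology"]
    kwargs = dict(
        renal_cortex_volume=p["renal_cortex_volume_L"],
        pt_fraction_of_cortex=p["pt_fraction_of_cortex"],
        pct_fraction_of_pt=p["pct_fraction_of_pt"],
        bladder_volume=p["bladder_volume_L"],
        gfr=p["gfr_L_per_h"],
        urine_outflow=p["urine_outflow_L_per_h"],
        flow_decrement=p["flow_decrement"],
    )
    kwargs.update(overrides)
    return PhysiologyParams(**kwargs)


def transporter_params(subject_class: str) -> TransporterParams:
    """Kinetics for a named subject class: ``healthy`` or ``t2dm``."""
    sets = load_registry()["transporters"]
    if subject_class not in sets:
        raise KeyError(f"unknown subject class {subject_class!r}; "
                       f"available: {sorted(sets)}")
    t = sets[subject_class]
    return TransporterParams(vmax1=t["vmax1_mmol_per_h"], vmax2=t["vmax2_mmol_per_h"],
                             km1=t["km1_mM"], km2=t["km2_mM"],
                             subject_class=subject_class)


def inhibitor_params(name: str) -> InhibitorParams:
    """Inhibitor parameters for a named drug (``dapagliflozin``/``canagliflozin``)."""
    drugs = load_registry()["drugs"]
    if name not in drugs:
        raise KeyError(f"unknown drug {name!r}; available: {sorted(drugs)}")
    d = drugs[name]
    return InhibitorParams(molecular_weight=d["molecular_weight"],
                           free_fraction=d["free_fraction"],
                           ki1=d["ki1_nM"], ki2=d["ki2_nM"], name=name)


def clamp_arm_range(arm: str) -> dict:
    """Measured GFR / urine-flow range for a clamp-study arm.

    Arms: ``healthy_baseline``, ``healthy_drug``, ``t2dm_baseline``,
    ``t2dm_drug``.
    """
    ranges = load_registry()["clamp_arm_ranges"]
    if arm not in ranges:
        raise KeyError(f"unknown clamp arm {arm!r}; available: {sorted(ranges)}")
    return ranges[arm]


def clamp_arm_midpoints(arm: str) -> tuple[float, float]:
    """(GFR, urine outflow) midpoints of the printed range for an arm."""
    r = clamp_arm_range(arm)
    lo, hi = r["gfr_L_per_h"]
    klo, khi = r["urine_outflow_L_per_h"]
    return (lo + hi) / 2.0, (klo + khi) / 2.0


def calibration_starting_points() -> dict:
    """Literature starting points for the calibrated kinetic parameters."""
    return dict(load_registry()["calibration_starting_points"])
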