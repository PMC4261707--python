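"""Unit conversions used at the model interface.

Glucose is handled in mg/dL at the user interface and mM internally;
urinary glucose mass in mmol internally and grams in reports.  Drug
concentrations are ng/mL at the interface and nM internally (conversion
requires the compound's molecular weight).
"""

from __future__ import annotations

GLUCOSE_MW = 180.16
"""Molecular weight of D-glucose, g/mol."""


def convert_units(value: float, from_unit: str, to_unit: str, mw: float | None = None) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported pairs (either direction):

    * ``mg/dL`` <-> ``mM`` — plasma glucose (uses ``GLUCOSE_MW`` unless
      ``mw`` is given).
    * ``mmol`` <-> ``g`` — glucose mass (uses ``GLUCOSE_MW`` unless
      ``mw`` is given).
    * ``ng/mL`` <-> ``nM`` — drug concentration; ``mw`` is required.

    Raises ``ValueError`` for an unknown unit pair or a missing molecular
    weight.
    """
    pair = (from_unit, to_unit)
    if pair == (from_unit, from_unit):
        return value
    if pair in {("mg/dL", "mM"), ("mM", "mg/dL")}:
        m = GLUCOSE_MW if mw is None else mw
        # mg/dL * 10 = mg/L; mg/L / MW * 1000 = mM * ... -> mg/dL * 10 / MW = mM
        return value * 10.0 / m if pair == ("mg/dL", "mM") else value * m / 10.0
    if pair in {("mmol", "g"), ("g", "mmol")}:
        m = GLUCOSE_MW if mw is None else mw
        return value * m / 1000.0 if pair == ("mmol", "g") else value * 1000.0 / m
    if pair in {("ng/mL", "nM"), ("nM", "ng/mL")}:
        if mw is None:
            raise ValueError("molecular weight required for ng/mL <-> nM conversion")
        # ng/mL = ug/L; ug/L / (g/mol) = umol/L * 1e-... -> ng/mL / MW * 1000 = nM
        return value / mw * 1000.0 if pair == ("ng/mL", "nM") else value * mw / 1000.0
    raise ValueError(f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}")


def mgdl_to_mM(value: float) -> float:
    """Plasma glucose mg/dL -> mM."""
    return value * 10.0 / GLUCOSE_MW


def mM_to_mgdl(value: float) -> float:
    """Plasma glucose mM -> mg/dL."""
    return value * GLUCOSE_MW / 10.0


def mmol_to_g(value: float) -> float:
    """Glucose mass mmol -> g."""
    return value * GLUCOSE_MW / 1000.0
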