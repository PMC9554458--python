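"""Unit conversion helpers.

All model assembly happens in a single internally consistent unit system:
amounts in mg, volumes in L, times in h, concentrations in mg/L and flows
in L/h.  Physiological inputs are quoted in the units customary for the
neonatal literature (flows in mL/min/kg, volumes in L/kg or mL), so the
converters below are applied exactly once, at parameter assembly.
"""

from __future__ import annotations

#: 1 mL/min expressed in L/h.
ML_PER_MIN_TO_L_PER_H = 60.0 / 1000.0


def ml_per_min_to_l_per_h(flow_ml_min: float) -> float:
    """Convert a flow from mL/min to L/h."""
    return flow_ml_min * ML_PER_MIN_TO_L_PER_H


def l_per_h_to_ml_per_min(flow_l_h: float) -> float:
    """Convert a flow from L/h to mL/min."""
    return flow_l_h / ML_PER_MIN_TO_L_PER_H


def ml_to_l(volume_ml: float) -> float:
    """Convert a volume from mL to L."""
    return volume_ml / 1000.0


def per_kg_to_absolute(value_per_kg: float, tbw_kg: float) -> float:
    """Scale a per-kg quantity to the absolute value for a subject."""
    return value_per_kg * tbw_kg
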