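"""Unit conversions at the configuration boundary.

The solver works in SI internally; clinical units (mmHg, ml, ms, bpm)
are accepted in configs and converted here.
"""

MMHG_TO_PA = 133.322
ML_TO_M3 = 1.0e-6
MS_TO_S = 1.0e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float):
    return p_pa / MMHG_TO_PA


def ml_to_m3(v_ml: float) -> float:
    return v_ml * ML_TO_M3


def m3_to_ml(v_m3: float):
    return v_m3 / ML_TO_M3


def bpm_to_period_s(bpm: float) -> float:
    """Cardiac cycle duration from heart rate (75 bpm -> 0.8 s)."""
    if bpm <= 0:
        raise ValueError("heart rate must be positive")
    return 60.0 / bpm
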