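"""Unit conversion constants.

Pressures are kept in mmHg internally; stresses are reported in kPa at the
API boundary (1 kPa = 7.50062 mmHg). Resistances follow the clinical
convention mmHg·min/L; the beat-level kernel converts to mmHg·s/mL.
"""

MMHG_PER_KPA = 7.50062
KPA_PER_MMHG = 1.0 / MMHG_PER_KPA

#: mmHg·min/L -> mmHg·s/mL
R_CLINICAL_TO_BEAT = 60.0 / 1000.0

#: minutes per year, used by the remodeling rate integration
MIN_PER_YEAR = 365.0 * 24.0 * 60.0
MIN_PER_DAY = 24.0 * 60.0


def kpa_to_mmhg(x: float) -> float:
    return x * MMHG_PER_KPA


def mmhg_to_kpa(x: float) -> float:
    return x * KPA_PER_MMHG
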