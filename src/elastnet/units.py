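"""Unit conversion constants.

The solver integrates in SI (Pa, m3, s); every public interface speaks
clinical units (mmHg, ml, s). Distensibility is quoted in 1e-3/mmHg
throughout the public API, matching the hemodynamics literature.
"""

MMHG_TO_PA = 133.322          # 1 mmHg in Pa
ML_TO_M3 = 1e-6               # 1 ml in m3
CM_TO_M = 1e-2

# resistance: mmHg·s/ml -> Pa·s/m3
R_CLIN_TO_SI = MMHG_TO_PA / ML_TO_M3
# compliance: ml/mmHg -> m3/Pa
C_CLIN_TO_SI = ML_TO_M3 / MMHG_TO_PA


def distensibility_to_si(d_per_mmhg_e3: float) -> float:
    """Convert distensibility from 1e-3/mmHg to 1/Pa."""
    return d_per_mmhg_e3 * 1e-3 / MMHG_TO_PA
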