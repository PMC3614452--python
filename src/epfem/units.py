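"""Unit conventions.

All user-facing field magnitudes are expressed in V/cm (the unit in which
electroporation thresholds are conventionally quoted); mesh coordinates and
assembled quantities are SI (m, V, S/m, A).  The V/cm <-> V/m conversion is
defined here and nowhere else.
"""

#: number of V/m in one V/cm
V_PER_CM = 100.0

#: metres per millimetre (configs specify lengths in mm)
MM = 1e-3


def vm_to_vcm(e_vm):
    """Convert a field magnitude (or array) from V/m to V/cm."""
    return e_vm / V_PER_CM


def vcm_to_vm(e_vcm):
    """Convert a field magnitude (or array) from V/cm to V/m."""
    return e_vcm * V_PER_CM
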