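"""Unit conversions.

All internal computation is in micrometres (µm): positions in µm, areas in
µm², volumes in µm³, lengths in µm, length densities in µm/µm³ = µm⁻².
Millimetre- and metre-scale units appear only at the reporting boundary.
"""

UM3_PER_MM3 = 1e9
UM_PER_M = 1e6
UM2_PER_MM2 = 1e6

#: 1 µm⁻² (µm of length per µm³ of volume) expressed in m/mm³:
#: (1 µm / 1 µm³) = (1e-6 m) / (1e-9 mm³) = 1e3 m/mm³.
M_PER_MM3_PER_UM2 = 1e3


def um3_to_mm3(v_um3: float) -> float:
    return v_um3 / UM3_PER_MM3


def mm3_to_um3(v_mm3: float) -> float:
    return v_mm3 * UM3_PER_MM3


def um_to_m(length_um: float) -> float:
    return length_um / UM_PER_M


def per_um3_to_per_mm3(density_per_um3: float) -> float:
    return density_per_um3 * UM3_PER_MM3


def lv_um2_to_m_per_mm3(lv_per_um2: float) -> float:
    """Convert a length density from µm⁻² to the conventional m/mm³."""
    return lv_per_um2 * M_PER_MM3_PER_UM2


def m_per_mm3_to_lv_um2(lv_m_per_mm3: float) -> float:
    return lv_m_per_mm3 / M_PER_MM3_PER_UM2
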