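"""Published reference values for the bottlenose dolphin auditory nuclei.

These are the printed study quantities the worked examples reproduce:
MRI and Cavalieri volumes per specimen and nucleus, stereological neuron /
glia totals and densities, axonal lengths and length densities, and the
immunoreactivity-compartment percentages per marker and subnucleus
(IC-CN: central nucleus of the inferior colliculus; IC-EC: its external
cortex / tectosomes; VCN: ventral cochlear nucleus).

Note: the study's own VCN total is internally inconsistent between two of
its statements (3.16 million vs 316.38 thousand); 316.38 thousand is the
value consistent with the printed density (2455/mm³ × 129 mm³ ≈ 316.6k)
and is the one recorded here, with the discrepancy noted.
"""

from __future__ import annotations

import pandas as pd

#: MRI (in situ) and Cavalieri (processed) volumes, mm³, per specimen/nucleus.
VOLUMES_MM3 = {
    ("Marine 0142", "LIC"): {"mri": 1775.0, "cavalieri": 1362.0},
    # Cavalieri value covers the intact rostral two-thirds of the nucleus.
    ("Marine 0142", "LVCN"): {"mri": 435.0, "cavalieri": 129.0},
    ("Marine 0116", "LIC"): {"mri": 1345.0, "cavalieri": None},
    ("Marine 0116", "LVCN"): {"mri": 387.0, "cavalieri": None},
    ("Marine 0116", "RIC"): {"mri": 1451.0, "cavalieri": 921.0},
    ("Marine 0116", "RVCN"): {"mri": 378.0, "cavalieri": 285.0},
    ("Dolphin 2", "RIC"): {"mri": None, "cavalieri": 571.0},  # celloidin-embedded
    ("Dolphin 2", "LVCN"): {"mri": None, "cavalieri": 199.0},
}

#: Averaged fractionator neuron totals and densities (Marine 0142).
NEURONS = {
    "IC-CN": {"total": 4.85e6, "density_per_mm3": 3561.0},
    "IC-EC": {"total": 1.28e6, "density_per_mm3": 2621.0},
    "IC": {"total": 6.13e6, "density_per_mm3": 3313.0},
    "VCN": {"total": 316.38e3, "density_per_mm3": 2455.0,
            "note": "printed once as 3.16 million; 316.38k is density-consistent"},
}

#: Spaceballs axonal lengths (m) and length densities (m/mm³).
AXONS = {
    "IC-CN": {"length_m": 2299.47, "length_density_m_per_mm3": 1.69},
    "IC-EC": {"length_m": 1058.09, "length_density_m_per_mm3": 2.17},
    "VCN": {"length_m": 195.31, "length_density_m_per_mm3": 1.52},
}

#: Glial totals and densities per mm³.
GLIA = {
    ("Iba1", "IC-CN"): {"total": 405.63e6, "density_per_mm3": 297.85e3},
    ("Iba1", "IC-EC"): {"total": 316.30e6, "density_per_mm3": 648.62e3},
    ("Iba1", "VCN"): {"total": 39.36e6, "density_per_mm3": 305.44e3},
    ("GFAP", "IC-CN"): {"total": 717.04e6, "density_per_mm3": 526.51e3},
    ("GFAP", "IC-EC"): {"total": 394.37e6, "density_per_mm3": 808.72e3},
    ("GFAP", "VCN"): {"total": 77.23e6, "density_per_mm3": 599.39e3},
}

#: Immunoreactivity-compartment percentages per marker and subnucleus.
IR_PERCENT = {
    ("Abeta", "IC-CN"): {"nuclear": 71.0},
    ("Abeta", "IC-EC"): {"nuclear": 7.0, "both": 48.0},
    ("Abeta", "IC"): {"nuclear": 56.0, "both": 14.0, "cytoplasmic": 0.9},
    ("Abeta", "VCN"): {"nuclear": 18.0, "both": 26.0, "cytoplasmic": 4.0},
    ("FN", "IC-CN"): {"cytoplasmic": 23.0, "both": 14.0},
    ("FN", "IC-EC"): {"cytoplasmic": 17.0, "both": 13.0},
    ("FN", "VCN"): {"cytoplasmic": 18.0, "both": 14.0},
    ("FN", "IC"): {"any": 36.0},
    ("FN", "VCN-any"): {"any": 32.0},
    ("TDP43", "IC-CN"): {"nuclear": 67.0, "both": 17.0, "cytoplasmic": 7.0},
    ("TDP43", "IC-EC"): {"nuclear": 53.0, "both": 26.0, "cytoplasmic": 7.0},
    ("TDP43", "VCN"): {"nuclear": 55.0, "both": 19.0, "cytoplasmic": 8.0},
    ("TDP43", "combined"): {"nuclear": 58.0, "both": 21.0, "cytoplasmic": 7.0},
}

#: Printed processed/in-situ volume ratios (percent).
SHRINKAGE_RATIOS_PERCENT = {
    ("Marine 0142", "LIC"): 77.0,
    ("Marine 0142", "LVCN"): 30.0,
    ("Marine 0116", "RVCN"): 75.0,
}

#: Human ventral cochlear nucleus total for the interspecies comparison.
HUMAN_VCN_NEURONS = 91.47e3

#: Dolphin 2 (celloidin-embedded) totals.
DOLPHIN2_NEURONS = {"IC-CN": 8.30e6, "IC-EC": 1.76e6, "VCN": 2.15e6}


def reference_table() -> pd.DataFrame:
    """The worked-example reference table as one tidy frame."""
    rows = []
    for (spec, nuc), v in VOLUMES_MM3.items():
        rows.append({"name": f"{spec}_{nuc}_mri_mm3", "value": v["mri"]})
        rows.append({"name": f"{spec}_{nuc}_cavalieri_mm3", "value": v["cavalieri"]})
    for nuc, v in NEURONS.items():
        rows.append({"name": f"neurons_{nuc}_total", "value": v["total"]})
        rows.append({"name": f"neurons_{nuc}_per_mm3", "value": v["density_per_mm3"]})
    for nuc, v in AXONS.items():
        rows.append({"name": f"axons_{nuc}_length_m", "value": v["length_m"]})
        rows.append({"name": f"axons_{nuc}_m_per_mm3", "value": v["length_density_m_per_mm3"]})
    for (marker, nuc), d in IR_PERCENT.items():
        for comp, pct in d.items():
            rows.append({"name": f"ir_{marker}_{nuc}_{comp}_pct", "value": pct})
    for (spec, nuc), pct in SHRINKAGE_RATIOS_PERCENT.items():
        rows.append({"name": f"shrinkage_{spec}_{nuc}_pct", "value": pct})
    rows.append({"name": "human_VCN_total", "value": HUMAN_VCN_NEURONS})
    df = pd.DataFrame(rows).dropna(subset=["value"]).reset_index(drop=True)
    return df
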