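"""Frozen physical and spectroscopic constants.

All values are configuration, not hard-coded behaviour: every consumer takes
them as (defaulted) arguments so they can be revised without touching code.
"""

from __future__ import annotations

ETHANOL_MOLAR_MASS_G_PER_MOL: float = 46.068
"""Molar mass of ethanol (C2H5OH), g/mol."""

PROTON_GYROMAGNETIC_MHZ_PER_T: float = 42.577
"""Proton gyromagnetic ratio, MHz/T (for reference only)."""

DEFAULT_FIELD_MHZ: float = 123.25
"""Proton Larmor frequency at 3 T, MHz."""

DEFAULT_TE_MS: float = 74.0
"""Echo time optimized for ethanol detection, ms."""

DEFAULT_LINEWIDTH_HZ: float = 4.0
"""Typical in vivo singlet FWHM at 3 T, Hz."""

WATER_PPM: float = 4.70
"""Chemical shift of tissue water, ppm."""

N_PROTONS_WATER: int = 2

ETHANOL_CH3_PPM: float = 1.18
ETHANOL_CH2_PPM: float = 3.65
ETHANOL_J_HZ: float = 7.1
"""Ethanol CH3 triplet centre, optional CH2 quartet centre, and 3J(H,H)."""

# (center_ppm, n_protons) for the standard singlet metabolites
NAA_PPM: float = 2.01
CR_PPM: float = 3.03
CHO_PPM: float = 3.20

# Compartmental water content: mol/L and volume-% for GM / WM / CSF.
WATER_MOLARITY_GM: float = 42.9
WATER_MOLARITY_WM: float = 35.8
WATER_MOLARITY_CSF: float = 53.4
WATER_PERCENT_GM: float = 78.0
WATER_PERCENT_WM: float = 65.0
WATER_PERCENT_CSF: float = 97.0

SERUM_BLOOD_FACTOR: float = 0.99 / 0.8
"""Serum (g/L) to whole-blood (g/kg) divisor, 1.2375.

Chosen so that a 0.99 g/L serum concentration corresponds exactly to a
0.8 g/kg blood alcohol concentration; the conventional forensic value is
~1.236 and can be passed instead wherever the factor is an argument.
"""

STUDY_REGIONS: tuple[str, ...] = (
    "occipital_cortex",
    "cerebellum",
    "frontal_cortex",
    "putamen",
)
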