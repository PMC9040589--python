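"""Monoisotopic atomic masses and ion-chemistry constants.

Masses are those of the most abundant stable isotope (CODATA/AME2020,
truncated well below the 1e-4 Da round-trip tolerance used elsewhere).
The deprotonated species [M - H]- loses a proton, not a hydrogen atom,
so PROTON_MASS (1.007276 Da) is subtracted; the electron-mass
difference (~0.00055 Da) is far below the annotation tolerances used
here and is not corrected for.
"""

from __future__ import annotations

#: Monoisotopic mass of the lightest (principal) isotope, in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "F": 18.9984031627,
    "Cl": 34.968852682,
    "Br": 78.9183376,
    "I": 126.904473,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Mg": 23.985041697,
    "Ca": 39.962590863,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Mn": 54.9380439,
    "Cu": 62.9295977,
    "Co": 58.9331943,
    "Mo": 97.9054045,
    "Se": 79.9165218,
    "B": 11.0093054,
    "Si": 27.9769265347,
}

#: Mass of a proton in Da (subtracted for [M - H]- ions).
PROTON_MASS = 1.007276

#: Heavy-minus-light monoisotopic mass shift per labeled atom, in Da.
ISOTOPE_SHIFT: dict[str, float] = {
    "C": 1.003355,  # 13C - 12C
    "N": 0.997035,  # 15N - 14N
}
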