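"""Unit conventions: lattice geometry and images in nm, atomic models in A."""

NM_TO_ANGSTROM = 10.0
ANGSTROM_TO_NM = 0.1


def nm_to_angstrom(x: float) -> float:
    return x * NM_TO_ANGSTROM


def angstrom_to_nm(x: float) -> float:
    return x * ANGSTROM_TO_NM
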