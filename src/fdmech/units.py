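"""Unit conventions used throughout the package.

Everything at and below the fitting layer works in a single fixed unit
system chosen so that typical force-spectroscopy magnitudes are O(1..1000):

============  =========  ==================================
quantity      unit       notes
============  =========  ==================================
length        nm         piezo displacement, indentation
force         pN
modulus       kPa        converted to pN/nm^2 internally
spring const  N/m        converted to pN/nm internally
energy        pN*nm      thermal energy k_B*T
============  =========  ==================================

1 kPa = 1e3 N/m^2 = 1e-3 pN/nm^2, and 1 N/m = 1e3 pN/nm.
"""

#: multiply a modulus in kPa by this to get pN/nm^2
KPA_TO_PN_PER_NM2 = 1e-3
#: multiply a spring constant in N/m by this to get pN/nm
N_PER_M_TO_PN_PER_NM = 1e3

#: Boltzmann constant, pN*nm/K
KB_PN_NM_PER_K = 1.380649e-2

#: default experiment temperature (37 C)
DEFAULT_TEMPERATURE_K = 310.0


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_B*T in pN*nm (about 4.28 pN*nm at 310 K)."""
    return KB_PN_NM_PER_K * temperature_k


def modulus_kpa_to_internal(e_kpa: float) -> float:
    return e_kpa * KPA_TO_PN_PER_NM2


def modulus_internal_to_kpa(e_int: float) -> float:
    return e_int / KPA_TO_PN_PER_NM2


def spring_constant_internal(k_n_per_m: float) -> float:
    """Spring constant in pN/nm from N/m."""
    return k_n_per_m * N_PER_M_TO_PN_PER_NM
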