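"""Physical constants and unit conventions.

Internal units are nm and ns throughout the trajectory machinery; permeability
coefficients cross into cm-based units only at the reporting boundary
(cm^3/s for single-channel quantities, cm/s for macroscopic ones).
"""

#: Boltzmann / gas constant in kcal/(mol K)
KB_KCAL_MOL_K = 0.0019872
R_KCAL_MOL_K = KB_KCAL_MOL_K

AVOGADRO = 6.02214076e23

#: molar volume of water, cm^3/mol
WATER_MOLAR_VOLUME_CM3 = 18.0

#: volume of a single water molecule, cm^3 (V_W / N_A)
VW_CM3 = WATER_MOLAR_VOLUME_CM3 / AVOGADRO

#: bulk density of TIP3P water at ambient conditions, molecules/nm^3
#: (0.997 g/cm^3 equivalent)
TIP3P_BULK_DENSITY_NM3 = 33.37

NS_PER_S = 1.0e9

#: stopped-flow working temperature, K (15 degrees C)
DEFAULT_TRACE_TEMPERATURE_K = 288.15
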