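"""Unit conventions and physical constants.

The package works in a single consistent unit system chosen so that the
numbers appearing in cell-adhesion work are O(1)-O(1e5):

==========  =======================  =====================================
quantity    unit                     note
==========  =======================  =====================================
length      micrometre (um)          cell radius ~ 4 um
time        second (s)
force       femtonewton (fN)         single-bond forces ~ 1e2-1e5 fN
energy      fN*um                    1 fN*um = 1e-21 J
viscosity   fN*s/um^2                1 fN*s/um^2 = 1e-3 Pa*s = 1 cP
==========  =======================  =====================================

Plasma viscosity (~1 cP) is therefore simply 1.0 in these units.
"""

#: Boltzmann constant in fN*um per kelvin (1.380649e-23 J/K * 1e21 (fN*um)/J).
BOLTZMANN = 1.380649e-2

#: Default absolute temperature, body temperature (K).
BODY_TEMPERATURE = 310.0


def thermal_energy(temperature: float = BODY_TEMPERATURE) -> float:
    """Thermal energy kB*T in fN*um (~4.28 fN*um at 310 K)."""
    return BOLTZMANN * temperature


#: Dynamic viscosity of 1 centipoise expressed in fN*s/um^2.
CENTIPOISE = 1.0
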