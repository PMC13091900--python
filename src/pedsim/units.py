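"""Unit system and physical constants.

The internal unit system is (mm, g, ms).  In this system the derived
units are the convenient ones for tissue mechanics:

* force:   g·mm/ms² = N
* stress:  N/mm²    = MPa
* density: g/mm³

so all constitutive constants quoted in MPa / g/mm³ can be used as-is,
and ground-reaction forces come out in newtons.  Quantities supplied in
SI (seconds, kilograms, metres) are converted at the I/O boundary.
"""

#: standard gravity, mm/ms^2  (9.81 m/s^2)
GRAVITY = 9.81e-3

#: standard gravity in SI, m/s^2 — used where a formula is stated in SI
GRAVITY_SI = 9.81

#: seconds -> milliseconds
S_TO_MS = 1e3
#: metres -> millimetres
M_TO_MM = 1e3
#: kilograms -> grams
KG_TO_G = 1e3
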