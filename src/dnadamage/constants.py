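"""Physical constants and unit conversions.

Internal units are nanometres for length, degrees for angles and
electron-volts for energy.  Every conversion used anywhere in the package
lives here.
"""

#: Energy of one electron-volt in joules (CODATA exact value).
EV_TO_JOULE = 1.602176634e-19

#: Cubic nanometre in cubic centimetres.
NM3_TO_CM3 = 1e-21

#: Gram in kilograms.
GRAM_TO_KG = 1e-3

#: Linear energy transfer: 1 keV/um equals exactly 1 eV/nm.
KEV_PER_UM_TO_EV_PER_NM = 1.0
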