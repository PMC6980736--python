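"""Internal unit system: micrometre, second, nanonewton.

Derived units:
    stress / pressure   nN/um^2  (= kPa)
    line stiffness      nN/um    (= 1e-3 N/m)
    viscosity (bulk)    nN*s/um^2 (= kPa*s)
    drag (line)         nN*s/um
    bending constant    nN*um

Config files carry SI values with the units of the published parameter
table; the converters below are applied once at load time.  Masses and
densities of matrix particles only ever enter force expressions as
ratios, so the rest density is kept at 1 in model units.
"""

PA = 1e-3          # Pa            -> nN/um^2
PA_S = 1e-3        # Pa*s          -> nN*s/um^2
N_PER_M = 1e3      # N/m           -> nN/um
NS_PER_M = 1e3     # N*s/m         -> nN*s/um
N_M = 1e15         # N*m           -> nN*um
N_PER_M2 = 1e-3    # N/m^2         -> nN/um^3
N_PER_M15 = 1.0    # N/m^1.5       -> nN/um^1.5
NN = 1.0           # nN            -> nN
UM = 1.0           # um            -> um
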