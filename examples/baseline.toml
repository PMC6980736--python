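# Baseline migration scenario at reduced domain size.
# Omitted keys take the published defaults (see protrudesim.config).

[ecm]
radius = 75.0      # um (150.0 reproduces the full-size study domain)
E = 200.0          # Pa
nu = 0.45
mu = 1000.0        # Pa*s

[sim]
duration = 7200.0  # s (21600 = 6 h for the full study)
seed = 1

[protrusion]
r_prot = 6e-5      # 1/s per boundary particle

[adhesion]
zeta_diss = 2e4    # force-dependent disassembly constant
f_rupt = 1e9       # rupture disabled, as in the homogeneous-ECM study
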