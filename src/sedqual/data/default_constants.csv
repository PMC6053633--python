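# Default constants for the classical contamination indices.
# background: average-shale crustal reference concentrations, mg/kg
# (Turekian & Wedepohl 1961).
# tr: Hakanson (1980) toxic-response factors, dimensionless.
# All entries are user-overridable.
metal,background,tr
Cd,0.3,30
Cr,90,2
Cu,45,5
Ni,68,5
Pb,20,5
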