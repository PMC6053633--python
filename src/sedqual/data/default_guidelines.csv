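# Default sediment quality guidelines (mg/kg dry weight).
# TEL/PEL: threshold and probable effect levels from the widely used
# freshwater/coastal sediment-quality-guideline compilations (Smith et al.
# 1996; MacDonald et al. 1996 and subsequent reviews). Cd, Cr, Cu, Ni carry
# the coastal/estuarine TEL-PEL pair; Pb carries the Canadian freshwater
# ISQG/PEL pair (35 / 91.3).
# SEL: severe effect levels from the Ontario provincial sediment quality
# guidelines (Persaud et al. 1993).
# All entries are user-overridable; unknown metals may be appended.
metal,tel,pel,sel
Cd,0.68,4.21,10
Cr,52.3,160.4,110
Cu,18.7,108.2,110
Ni,15.9,42.8,75
Pb,35,91.3,250
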