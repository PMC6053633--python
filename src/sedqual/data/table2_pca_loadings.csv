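# Two-component correlation-PCA summaries (rotated loadings, eigenvalues,
# variability %, cumulative %) of the five-metal monthly concentration data,
# one model per site. PC1 is interpreted as the anthropogenic-contamination
# component; its eigenvalue supplies the ECI weight B_n = 1/eigenvalue.
site,component,eigenvalue,variability_pct,cumulative_pct,load_Cd,load_Cr,load_Cu,load_Ni,load_Pb
DOU,1,1.705,34.108,34.108,0.634,0.160,0.750,0.125,-0.401
DOU,2,1.601,32.022,66.130,0.452,0.345,-0.144,0.558,0.587
OKT,1,2.366,47.314,47.314,0.234,-0.786,0.943,0.368,-0.817
OKT,2,1.214,24.275,71.589,0.936,0.508,-0.002,-0.095,-0.265
STB,1,2.317,46.337,46.337,0.953,0.439,0.907,0.623,-0.060
STB,2,1.605,32.110,78.447,0.114,-0.635,-0.252,0.716,0.783
QUR,1,2.128,42.565,42.565,0.576,-0.682,0.821,0.467,0.662
QUR,2,1.868,37.360,79.925,0.734,0.459,-0.149,0.865,-0.590
QUE,1,2.268,45.365,45.365,0.484,0.485,-0.832,0.522,0.913
QUE,2,1.311,26.226,71.591,-0.758,0.708,-0.068,-0.431,0.210
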