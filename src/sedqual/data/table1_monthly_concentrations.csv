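# Monthly mean concentrations (mg/kg dry weight) +/- s.d. of five trace metals
# in benthic sediments of five coastal aquatic ecosystems of the Equatorial
# Atlantic (Gulf of Guinea, Nigeria): Qua Iboe Estuary (QUE), Douglas Creek
# (DOU), Stubbs Creek (STB), Okorotip Creek (OKT), Qua Iboe River (QUR).
# Totals over the five Tessier fractions (F1+F2+F3+F4+F5).
site,metal,period,c,sd
QUE,Cd,Jun,4.38,1.19
QUE,Cd,Jul,4.96,1.41
QUE,Cd,Aug,4.71,1.27
QUE,Cd,Nov,4.84,1.33
QUE,Cd,Dec,4.71,1.25
QUE,Cd,Jan,4.64,1.26
DOU,Cd,Jun,4.88,1.31
DOU,Cd,Jul,4.63,1.22
DOU,Cd,Aug,4.52,1.25
DOU,Cd,Nov,5.21,1.44
DOU,Cd,Dec,4.80,1.27
DOU,Cd,Jan,4.78,1.23
STB,Cd,Jun,5.02,1.35
STB,Cd,Jul,5.08,1.34
STB,Cd,Aug,4.99,1.36
STB,Cd,Nov,4.47,1.16
STB,Cd,Dec,4.41,1.17
STB,Cd,Jan,4.33,1.12
OKT,Cd,Jun,4.47,1.13
OKT,Cd,Jul,5.67,1.78
OKT,Cd,Aug,4.86,1.27
OKT,Cd,Nov,4.41,1.55
OKT,Cd,Dec,4.71,1.26
OKT,Cd,Jan,4.67,1.26
QUR,Cd,Jun,5.01,1.35
QUR,Cd,Jul,5.63,1.67
QUR,Cd,Aug,4.59,1.23
QUR,Cd,Nov,4.89,1.38
QUR,Cd,Dec,4.69,1.26
QUR,Cd,Jan,4.64,1.24
QUE,Cr,Jun,20.37,4.09
QUE,Cr,Jul,20.08,4.04
QUE,Cr,Aug,18.93,3.69
QUE,Cr,Nov,20.60,4.17
QUE,Cr,Dec,18.61,3.63
QUE,Cr,Jan,20.52,3.99
DOU,Cr,Jun,19.02,3.63
DOU,Cr,Jul,20.63,3.92
DOU,Cr,Aug,17.50,3.22
DOU,Cr,Nov,18.95,3.55
DOU,Cr,Dec,19.90,3.88
DOU,Cr,Jan,20.11,3.88
STB,Cr,Jun,20.34,3.98
STB,Cr,Jul,19.86,3.70
STB,Cr,Aug,20.37,4.02
STB,Cr,Nov,19.05,3.62
STB,Cr,Dec,20.73,4.07
STB,Cr,Jan,18.78,3.58
OKT,Cr,Jun,21.51,4.29
OKT,Cr,Jul,20.84,4.19
OKT,Cr,Aug,20.93,4.21
OKT,Cr,Nov,19.54,3.83
OKT,Cr,Dec,18.44,3.34
OKT,Cr,Jan,20.06,3.73
QUR,Cr,Jun,11.12,1.81
QUR,Cr,Jul,18.11,3.55
QUR,Cr,Aug,15.16,2.59
QUR,Cr,Nov,17.09,3.39
QUR,Cr,Dec,28.52,7.21
QUR,Cr,Jan,18.37,3.46
QUE,Cu,Jun,31.74,4.80
QUE,Cu,Jul,36.43,5.84
QUE,Cu,Aug,38.73,6.69
QUE,Cu,Nov,31.05,4.58
QUE,Cu,Dec,35.75,5.68
QUE,Cu,Jan,38.29,6.25
DOU,Cu,Jun,40.70,7.35
DOU,Cu,Jul,38.61,6.62
DOU,Cu,Aug,36.39,6.16
DOU,Cu,Nov,39.31,6.86
DOU,Cu,Dec,37.25,6.41
DOU,Cu,Jan,36.55,6.09
STB,Cu,Jun,43.01,8.08
STB,Cu,Jul,39.86,6.94
STB,Cu,Aug,43.08,7.93
STB,Cu,Nov,40.54,6.99
STB,Cu,Dec,38.00,6.54
STB,Cu,Jan,37.43,6.31
OKT,Cu,Jun,30.86,4.53
OKT,Cu,Jul,40.69,7.33
OKT,Cu,Aug,30.26,4.97
OKT,Cu,Nov,39.57,7.39
OKT,Cu,Dec,42.02,7.61
OKT,Cu,Jan,41.49,7.48
QUR,Cu,Jun,43.73,8.95
QUR,Cu,Jul,35.07,5.65
QUR,Cu,Aug,38.56,6.67
QUR,Cu,Nov,41.01,7.44
QUR,Cu,Dec,39.87,7.43
QUR,Cu,Jan,39.26,6.68
QUE,Pb,Jun,177.63,4.95
QUE,Pb,Jul,180.03,4.23
QUE,Pb,Aug,231.52,6.82
QUE,Pb,Nov,185.81,8.10
QUE,Pb,Dec,186.48,8.00
QUE,Pb,Jan,185.07,6.59
DOU,Pb,Jun,166.42,9.94
DOU,Pb,Jul,172.50,2.91
DOU,Pb,Aug,177.80,3.59
DOU,Pb,Nov,185.11,6.68
DOU,Pb,Dec,181.59,6.36
DOU,Pb,Jan,186.58,8.71
STB,Pb,Jun,181.48,7.24
STB,Pb,Jul,187.06,8.08
STB,Pb,Aug,175.37,6.90
STB,Pb,Nov,176.86,5.30
STB,Pb,Dec,180.21,7.12
STB,Pb,Jan,183.34,5.51
OKT,Pb,Jun,183.48,8.79
OKT,Pb,Jul,167.61,0.87
OKT,Pb,Aug,190.37,7.83
OKT,Pb,Nov,169.25,3.78
OKT,Pb,Dec,171.71,8.64
OKT,Pb,Jan,185.38,6.06
QUR,Pb,Jun,162.00,8.54
QUR,Pb,Jul,182.37,6.05
QUR,Pb,Aug,173.49,3.95
QUR,Pb,Nov,178.42,4.12
QUR,Pb,Dec,175.72,5.13
QUR,Pb,Jan,183.13,6.51
QUE,Ni,Jun,2.06,0.35
QUE,Ni,Jul,2.60,0.59
QUE,Ni,Aug,2.17,0.38
QUE,Ni,Nov,2.25,0.40
QUE,Ni,Dec,2.27,0.43
QUE,Ni,Jan,2.26,0.41
DOU,Ni,Jun,2.24,0.39
DOU,Ni,Jul,2.12,0.34
DOU,Ni,Aug,2.13,0.34
DOU,Ni,Nov,2.17,0.37
DOU,Ni,Dec,2.25,0.39
DOU,Ni,Jan,2.27,0.40
STB,Ni,Jun,2.23,0.39
STB,Ni,Jul,2.25,0.40
STB,Ni,Aug,2.19,0.36
STB,Ni,Nov,2.23,0.41
STB,Ni,Dec,2.13,0.33
STB,Ni,Jan,2.18,0.36
OKT,Ni,Jun,2.05,0.36
OKT,Ni,Jul,2.17,0.39
OKT,Ni,Aug,2.20,0.39
OKT,Ni,Nov,2.26,0.39
OKT,Ni,Dec,2.09,0.40
OKT,Ni,Jan,2.22,0.38
QUR,Ni,Jun,2.17,0.39
QUR,Ni,Jul,2.23,0.41
QUR,Ni,Aug,2.03,0.41
QUR,Ni,Nov,2.28,0.40
QUR,Ni,Dec,2.16,0.41
QUR,Ni,Jan,2.26,0.40
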