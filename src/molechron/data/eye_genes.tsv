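gene	group	pleiotropic
ARR3	cone_recovery	0
CNGA3	cone_activation	0
CNGB3	cone_activation	0
GNAT2	cone_activation	0
GNB3	cone_activation	1
GNGT2	cone_activation	0
GRK7	cone_recovery	0
OPN1LW	cone_activation	0
OPN1SW	cone_activation	0
PDE6C	cone_activation	0
PDE6H	cone_activation	0
SLC24A2	cone_recovery	1
CNGA1	rod_activation	0
CNGB1	rod_activation	1
GNAT1	rod_activation	0
GNB1	rod_activation	1
GNGT1	rod_activation	0
GRK1	rod_recovery	0
PDE6A	rod_activation	0
PDE6B	rod_activation	0
PDE6G	rod_activation	0
RHO	rod_activation	1
SAG	rod_recovery	0
SLC24A1	rod_recovery	0
CRYAA	lens_cornea	0
CRYAB	lens_cornea	1
CRYBA1	lens_cornea	0
CRYBA4	lens_cornea	0
CRYBB1	lens_cornea	0
CRYBB2	lens_cornea	0
CRYBB3	lens_cornea	0
CRYGS	lens_cornea	0
BFSP1	lens_cornea	0
BFSP2	lens_cornea	0
GJA8	lens_cornea	0
LIM2	lens_cornea	0
MIP	lens_cornea	0
KRT12	lens_cornea	0
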