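# Published 10x10 trait-by-method matrix fixture.
# Measure tags: first letter of crowd + method subscript (1 = photo-grid
# instrument, 2 = ranked-choice instrument), e.g. A1, H2.
# Rows: omega,<tag>,<value>  or  r,<tag_row>,<tag_col>,<value>,<sig marker>
kind,a,b,value,sig
omega,A1,0.78
omega,C1,0.77
omega,H1,0.48
omega,M1,0.44
omega,P1,0.45
omega,A2,0.70
omega,C2,0.77
omega,H2,0.56
omega,M2,0.61
omega,P2,0.59
r,C1,A1,-0.60,***
r,H1,A1,-0.23,***
r,H1,C1,-0.25,***
r,M1,A1,-0.23,***
r,M1,C1,-0.14,***
r,M1,H1,-0.27,***
r,P1,A1,-0.59,***
r,P1,C1,-0.01,
r,P1,H1,0.09,**
r,P1,M1,0.05,
r,A2,A1,0.53,***
r,A2,C1,-0.40,***
r,A2,H1,-0.06,*
r,A2,M1,-0.03,
r,A2,P1,-0.32,***
r,C2,A1,-0.30,***
r,C2,C1,0.55,***
r,C2,H1,-0.12,***
r,C2,M1,-0.14,***
r,C2,P1,-0.03,
r,C2,A2,-0.38,***
r,H2,A1,-0.17,***
r,H2,C1,0.08,**
r,H2,H1,0.17,***
r,H2,M1,-0.08,*
r,H2,P1,0.11,***
r,H2,A2,-0.36,***
r,H2,C2,-0.05,
r,M2,A1,-0.02,
r,M2,C1,-0.07,*
r,M2,H1,-0.13,***
r,M2,M1,0.23,***
r,M2,P1,0.06,*
r,M2,A2,-0.22,***
r,M2,C2,-0.26,***
r,M2,H2,-0.23,***
r,P2,A1,-0.19,***
r,P2,C1,-0.04,
r,P2,H1,0.18,***
r,P2,M1,-0.02,
r,P2,P1,0.26,***
r,P2,A2,-0.28,***
r,P2,C2,-0.19,***
r,P2,H2,-0.17,***
r,P2,M2,-0.28,***
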