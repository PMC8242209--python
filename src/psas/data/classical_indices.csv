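residue,solubility_in_water,side_chain_hydrophobicity,in_out_propensity,hydropathy,alpha_helix,beta_sheet,coil,aromaphilicity
Tyr,0.054,0.96,-0.22,-1.3,0.61,1.29,1.19,0.850
Trp,1.32,2.25,0.45,-0.9,1.14,1.19,0.82,1.000
Phe,2.80,1.79,0.67,2.8,1.12,1.28,0.81,0.575
Arg,19.59,-1.01,-1.34,-4.5,0.79,0.90,1.20,0.750
Lys,24.66,-0.99,-2.00,-3.9,1.07,0.74,1.05,0.100
His,4.36,0.13,0.04,-3.2,1.24,0.71,0.92,0.450
Pro,130.07,0.72,-0.44,-1.6,0.59,0.62,1.45,0.125
Gly,25.23,0.00,0.06,-0.4,0.53,0.81,1.42,0.000
Ala,16.63,0.31,0.20,1.8,1.45,0.97,0.66,0.025
Ser,36.57,-0.04,-0.34,-0.8,0.79,0.72,1.27,0.125
Cys,2.56,1.54,0.67,2.5,0.77,1.30,1.07,0.200
Met,5.59,1.23,0.71,1.9,1.20,1.67,0.61,0.325
Val,5.87,1.22,0.61,4.2,1.14,1.65,0.66,0.150
Leu,2.19,1.70,0.65,3.8,1.34,1.22,0.66,0.125
Ile,3.17,1.80,0.74,4.5,1.00,1.60,0.78,0.200
Thr,9.79,0.26,-0.26,-0.7,0.82,1.20,1.05,0.075
Gln,4.25,-0.22,-0.74,-3.5,1.17,1.23,0.79,0.300
Asn,2.51,-0.60,-0.69,-3.5,0.73,0.65,1.33,0.200
Glu,0.88,-0.64,-1.09,-3.5,1.53,0.26,0.87,0.050
Asp,0.51,-0.77,-0.72,-3.5,0.98,0.80,1.09,-0.025
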