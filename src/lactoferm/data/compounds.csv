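name,c_atoms,h_atoms,o_atoms,molar_mass
lactate,3,6,3,90.08
acetate,2,4,2,60.05
propionate,3,6,2,74.08
butyrate,4,8,2,88.11
valerate,5,10,2,102.13
caproate,6,12,2,116.16
ethanol,2,6,1,46.07
propanol,3,8,1,60.10
butanol,4,10,1,74.12
H2,0,2,0,2.016
CO2,1,0,2,44.01
CH4,1,4,0,16.04
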