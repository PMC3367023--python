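# Synthetic 20-reaction energetics fixture (slope/intercept pairs are
# invented but span the realistic per-electron range for alkaline
# hot-spring chemolithotrophy; they are not measured values).
id,slope,intercept,n_electrons,oxidant,reductant
R01,-1.5,30.0,8,O2,H2S
R02,-1.2,28.0,6,O2,S0
R03,-2.0,35.0,4,O2,H2
R04,-1.0,20.0,8,NO3,H2S
R05,-1.5,25.0,8,NO3,H2
R06,-0.8,15.0,6,NO2,H2S
R07,-0.5,8.0,2,S0,H2
R08,-2.0,15.4,8,SO4,H2
R09,1.5,-11.5,8,SO4,CH4
R10,2.0,-15.2,8,SO4,Fe2
R11,-0.3,1.0,8,CO2,H2
R12,0.4,-6.0,2,hematite,H2S
R13,1.2,5.0,1,O2,Fe2
R14,-1.8,32.0,8,O2,CH4
R15,-1.0,16.0,6,O2,NH4
R16,0.5,-6.0,6,NO2,NH4
R17,-0.6,3.0,2,magnetite,H2
R18,1.0,-4.0,5,NO3,Fe2
R19,0.8,-8.0,8,goethite,CH4
R20,-1.3,24.0,2,O2,CO
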