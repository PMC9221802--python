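variable,table,endpoint,a,b,c,d,printed_p,router_matches
sex_male,1,cr,9,28,5,9,0.490,1
child_pugh_b,1,cr,0,6,14,31,0.170,1
ascites,1,cr,0,8,14,29,0.088,1
varices,1,cr,10,29,4,8,0.715,1
sex_male,1,or,20,17,9,5,0.510,1
child_pugh_b,1,or,3,3,26,19,1.000,1
ascites,1,or,5,3,24,19,1.000,1
varices,1,or,22,17,7,5,0.906,1
nonrim_aphe,2,cr,13,36,1,1,0.478,1
nonperipheral_washout,2,cr,11,32,3,5,0.668,1
enhancing_capsule,2,cr,6,17,8,20,0.843,1
threshold_growth,2,cr,0,4,14,33,0.565,1
us_visibility,2,cr,4,5,10,32,0.236,1
subthreshold_growth,2,cr,5,9,9,28,0.490,1
corona_enhancement,2,cr,1,2,13,35,1.000,1
fat_sparing,2,cr,1,3,13,34,1.000,1
restricted_diffusion,2,cr,9,24,5,13,1.000,1
mild_t2_hyperintensity,2,cr,7,20,7,17,0.796,1
transitional_hypointensity,2,cr,9,33,5,4,0.093,1
hbp_hypointensity,2,cr,12,32,2,5,1.000,1
nonenhancing_capsule,2,cr,0,1,14,36,1.000,1
nodule_in_nodule,2,cr,1,3,13,34,1.000,1
mosaic_architecture,2,cr,1,3,13,34,1.000,1
fat_in_mass,2,cr,2,7,12,30,1.000,1
blood_products,2,cr,1,0,13,37,0.275,1
nonrim_aphe,2,or,27,22,2,0,0.500,1
nonperipheral_washout,2,or,22,21,7,1,0.117,1
enhancing_capsule,2,or,12,11,17,11,0.581,0
threshold_growth,2,or,3,1,26,21,0.624,0
us_visibility,2,or,5,4,24,18,1.000,1
subthreshold_growth,2,or,6,8,23,14,0.214,1
corona_enhancement,2,or,2,1,27,21,1.000,1
fat_sparing,2,or,3,1,26,21,0.625,1
restricted_diffusion,2,or,18,15,11,7,0.651,1
mild_t2_hyperintensity,2,or,13,14,16,8,0.183,1
transitional_hypointensity,2,or,21,21,8,1,0.060,1
hbp_hypointensity,2,or,24,20,5,2,0.684,1
nonenhancing_capsule,2,or,1,0,28,22,1.000,1
nodule_in_nodule,2,or,2,2,27,20,1.000,1
mosaic_architecture,2,or,1,3,28,19,0.303,1
fat_in_mass,2,or,4,5,25,17,0.474,1
blood_products,2,or,1,0,28,22,1.000,1
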