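clade,gamma_lambda_mean,gamma_lambda_lo,gamma_lambda_hi,gamma_mu_mean,gamma_mu_lo,gamma_mu_hi
Athyridida,-0.96,-2.05,-0.08,3.32,2.48,4.24
Auloporida,7.84,2.49,13.90,1.01,-4.98,6.98
Bellerophontidae,-3.15,-4.56,-1.50,-3.54,-5.13,-2.08
Cystiphyllida,-2.35,-5.70,1.32,7.44,4.55,10.14
Cystoporida,-5.79,-8.10,-3.77,1.62,0.12,2.97
Desmoceratidae,-6.15,-10.24,-1.97,2.47,-2.09,6.63
Euomphalidae,-3.64,-6.06,-1.08,-0.05,-2.80,3.07
Favositida,-1.61,-2.39,-0.66,3.75,2.55,4.83
Fenestrida,-3.29,-4.25,-2.15,3.25,2.01,4.35
Lophospiridae,5.06,2.83,7.99,-4.11,-7.46,-0.04
Orthida,-0.61,-0.91,-0.27,1.60,1.23,1.96
Orthotetida,-2.67,-3.85,-1.52,2.74,1.95,3.44
Productida,-0.80,-0.96,-0.65,0.82,0.64,0.99
Proetidae,-29.67,-35.09,-22.79,-14.17,-22.02,-7.70
Pterineidae,-17.30,-38.02,0.95,-16.96,-37.90,3.15
Rhabdomesida,1.54,0.82,2.22,0.40,-0.42,1.07
Spiriferida,-1.59,-2.34,-1.01,3.46,2.51,4.30
Spiriferinida,-0.35,-1.22,0.57,1.96,1.10,2.86
Stauriida,0.64,0.41,0.85,0.68,0.45,0.91
Strophomenida,-0.43,-1.85,0.89,0.88,-0.47,2.18
Trepostomida,-0.89,-1.22,-0.62,1.93,1.47,2.34
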