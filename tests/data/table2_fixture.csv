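major_clade,clade,shift_age_ma,shift_pct,p_dist,p_dist_bold,area_test,net_p,slope,p_slope
Ammonites,Desmoceratidae,101.7,56.8,0.001,1,0.68,0,-10941.1,0.659
Anthozoans,Auloporida,393.9,28.5,0.007,1,136.64,0,-1486.7,0.059
Anthozoans,Auloporida,288.3,85.6,0.024,1,504.43,0,9156.0,0.151
Anthozoans,Cystiphyllida,393.1,84.5,0.184,0,0,0,164389.6,
Anthozoans,Favositida,415.5,17.8,0.003,1,30.98,0,-9464.8,0.000
Anthozoans,Favositida,383.1,34.2,0.002,1,32.11,0,-1562.2,0.012
Anthozoans,Stauriida,358.8,47.7,1.000,0,16.88,0,-2772.6,0.000
Anthozoans,Stauriida,361.2,46.5,0.199,0,18.05,0,-2772.6,0.000
Anthozoans,Stauriida,372.9,40.7,1.000,0,23.38,0,-2810.6,0.000
Bivalves,Pterineidae,400.5,27.2,0.046,1,25.09,0,-4884.8,0.046
Brachiopods,Athyridida,306.4,55.3,0.870,0,13.55,0,-2118.5,0.014
Brachiopods,Athyridida,284.9,63.3,0.298,0,12.78,0,-810.1,0.325
Brachiopods,Orthida,372.8,50.2,0.780,0,53.97,0,-1040.8,0.000
Brachiopods,Orthida,360.2,55.4,0.512,0,49.33,0,-916.3,0.011
Brachiopods,Orthotetida,404.7,24.9,0.003,1,14.79,1,-951.8,0.251
Brachiopods,Orthotetida,347.4,53.2,0.002,1,22.37,0.974,886.4,0.601
Brachiopods,Orthotetida,294.7,79.2,0.000,1,13.73,0,8810.1,0.211
Brachiopods,Productida,276.9,87.1,0.038,1,0.03,0,18956.9,0.144
Brachiopods,Spiriferida,316.9,64.6,1.000,0,45.61,0.014,453.7,0.732
Brachiopods,Spiriferinida,258.3,38.0,0.016,1,0.909,0,219.1,0.335
Brachiopods,Strophomenida,406.7,43.0,0.004,1,61.31,0,-6006.0,0.068
Bryozoans,Cystoporida,276.5,86.5,0.021,1,0.69,0,48723.2,0.093
Bryozoans,Fenestrida,292,78.3,0.000,1,0.08,0,-4184.0,0.612
Bryozoans,Rhabdomesida,294,79.8,0.021,1,1.67,0,-10506.9,0.008
Bryozoans,Trepostomida,399.4,19.9,0.000,1,34.08,0,1655.2,0.003
Bryozoans,Trepostomida,274.2,59.8,0.003,1,44.81,0,2291.5,0.023
Gastropods,Bellerophontidae,324.2,66.0,0.000,1,1.09,0,4228.9,0.046
Gastropods,Euomphalidae,356.7,48.8,0.000,1,74.53,0,-5382.5,0.003
Gastropods,Lophospiridae,294.3,62.4,0.059,1,82.41,0,-4851.4,0.004
Trilobites,Proetidae,375.2,58.0,0.045,1,58.74,0,-22289.3,0.148
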