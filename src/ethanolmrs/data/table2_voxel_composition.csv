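subject,cycle,region,gm_pct,wm_pct,csf_pct,wc_pct
V1,1,occipital_cortex,46,50,4,72.3
V2,1,occipital_cortex,53,42,5,73.5
V3,1,occipital_cortex,40,58,3,71.8
V1,1,cerebellum,80,20,0,75.4
V2,1,cerebellum,86,14,0,76.2
V3,1,cerebellum,78,22,0,75.1
V1,1,frontal_cortex,11,67,22,73.5
V2,1,frontal_cortex,11,67,22,73.5
V3,1,frontal_cortex,11,81,8,69.0
V1,1,putamen,87,13,0,76.3
V2,1,putamen,91,9,0,76.8
V3,1,putamen,83,17,0,75.8
V1,2,occipital_cortex,48,48,4,72.5
V2,2,occipital_cortex,54,42,4,73.3
V3,2,occipital_cortex,41,56,3,71.3
V1,2,cerebellum,83,17,0,75.8
V2,2,cerebellum,89,11,0,76.6
V3,2,cerebellum,77,23,0,75.0
V1,2,frontal_cortex,16,64,20,73.5
V2,2,frontal_cortex,11,66,23,73.8
V3,2,frontal_cortex,12,79,9,69.4
V1,2,putamen,85,15,0,76.1
V2,2,putamen,88,12,0,76.4
V3,2,putamen,77,23,0,75.0
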