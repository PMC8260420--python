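matrix,region,cycle,timepoint,time_min,subject,conc_gL
serum,,,T1,0,V1,0.26
serum,,,T1,0,V2,1.19
serum,,,T1,0,V3,0.54
brain,occipital_cortex,1,,20,V1,0.62
brain,occipital_cortex,1,,20,V2,0.60
brain,occipital_cortex,1,,20,V3,0.56
brain,cerebellum,1,,30,V1,0.62
brain,cerebellum,1,,30,V2,0.58
brain,cerebellum,1,,30,V3,0.50
serum,,,T2,40,V1,1.03
serum,,,T2,40,V2,1.08
serum,,,T2,40,V3,0.80
brain,frontal_cortex,1,,50,V1,0.68
brain,frontal_cortex,1,,50,V2,0.61
brain,frontal_cortex,1,,50,V3,0.62
brain,putamen,1,,60,V1,0.49
brain,putamen,1,,60,V2,0.51
brain,putamen,1,,60,V3,0.43
serum,,,T3,70,V1,1.14
serum,,,T3,70,V2,1.12
serum,,,T3,70,V3,0.87
brain,occipital_cortex,2,,110,V1,0.47
brain,occipital_cortex,2,,110,V2,0.42
brain,occipital_cortex,2,,110,V3,0.59
brain,cerebellum,2,,120,V1,0.39
brain,cerebellum,2,,120,V2,0.38
brain,cerebellum,2,,120,V3,0.42
serum,,,T4,130,V1,0.98
serum,,,T4,130,V2,0.98
serum,,,T4,130,V3,0.87
brain,frontal_cortex,2,,140,V1,0.51
brain,frontal_cortex,2,,140,V2,0.44
brain,frontal_cortex,2,,140,V3,0.67
brain,putamen,2,,150,V1,0.22
brain,putamen,2,,150,V2,0.23
brain,putamen,2,,150,V3,0.47
serum,,,T5,160,V1,0.84
serum,,,T5,160,V2,0.84
serum,,,T5,160,V3,0.85
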