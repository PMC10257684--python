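texture,lambda_c_m,porosity
sand,1.0e-3,0.40
loamy_sand,4.0e-4,0.42
sandy_loam,2.0e-4,0.44
loam,5.0e-5,0.47
silt_loam,3.0e-5,0.48
silt,2.0e-5,0.49
clay_loam,1.0e-5,0.50
clay,2.0e-6,0.52
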