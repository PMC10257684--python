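name,value,units,source
o2_mole_fraction,0.2095,mol mol-1,standard dry-air composition
p0_sea_level,101325.0,Pa,standard atmosphere
henry_o2_cp_ref,1.3e-05,mol m-3 Pa-1,aqueous O2 solubility at 298.15 K
henry_o2_vant_hoff,1700.0,K,van 't Hoff temperature coefficient for O2 solubility
henry_o2_dimless,32.0,1,dimensionless gas/aqueous O2 partition at 298.15 K
henry_co2_dimless,1.2,1,dimensionless gas/aqueous CO2 partition at 298.15 K
d_o2_water_ref,2.1e-09,m2 s-1,O2 aqueous diffusivity at 298.15 K
d_o2_air,1.8e-05,m2 s-1,O2 gas diffusivity
d_doc_water,7e-10,m2 s-1,DOC aqueous diffusivity
d_co2_water,1.9e-09,m2 s-1,CO2 aqueous diffusivity
d_co2_air,1.5e-05,m2 s-1,CO2 gas diffusivity
barometric_scale,0.0341632,K m-1,Mg/R for barometric pressure correction
km_s,0.1,mol m-3,DOC Michaelis constant
km_o2,0.03,mol m-3,O2 Michaelis constant
vm_ref,2.2e-09,mol m-2 s-1,maximum areal respiration rate at 298.15 K (calibrated once: HR(15 degC; saturation 0.5; loam; sea level) = 250 gC m-2 yr-1)
q10,2.0,1,temperature sensitivity of Vm
t_ref,25.0,degC,reference temperature for Vm and Q10
topsoil_depth,0.1,m,topsoil layer thickness (0-10 cm)
rev_length,0.1,m,representative elementary volume lateral scale
gamma,100.0,1,patch-size cutoff coefficient
tau_3d,2.19,1,Fisher exponent for field-scale (d=3) predictions
doc_default,4.0,mol m-3,default dissolved organic carbon concentration
carbon_molar_mass,12.011,g mol-1,molar mass of carbon
seconds_per_year,3.156e7,s yr-1,seconds per year
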