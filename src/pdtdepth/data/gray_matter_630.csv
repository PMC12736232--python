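tissue,thickness_mm,irradiance_mw_cm2
gray,1,6.14
gray,2,3.78
gray,3,2.57
gray,5,1.29
gray,7,0.48
gray,9,0.25
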