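tissue,thickness_mm,irradiance_mw_cm2
white,1,2.85
white,2,1.29
white,3,0.70
white,4,0.38
white,5,0.21
white,6,0.13
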