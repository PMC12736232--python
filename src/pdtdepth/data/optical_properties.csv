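tissue,wavelength_nm,mu_a_mm,mu_s_prime_mm
white,405,0.75,13.30
white,630,0.02,7.82
gray,405,1.21,2.40
gray,630,0.04,1.51
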