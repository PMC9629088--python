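group,r_squared,omega_squared,cohens_f2_reported
combined,0.652,0.645,1.816
personalized,0.768,0.758,3.14
control,-0.267,-0.33,3.09
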