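arm,measure,n,pre_mean,pre_sd,post_mean,post_sd
personalized,pain,14,76.4,6.4,53.2,15.0
personalized,pain_freq,14,62.1,12.0,37.9,18.2
personalized,distension,14,75.4,7.2,42.9,19.9
personalized,dissatisfaction,14,75.0,9.3,53.6,18.3
personalized,qol,14,68.2,10.3,45.0,21.7
personalized,total,14,357.1,18.2,232.5,61.5
personalized,index,14,0.89,0.04,0.62,0.18
control,pain,11,77.3,6.7,72.7,6.2
control,pain_freq,11,66.4,12.3,57.3,17.1
control,distension,11,71.4,9.6,59.1,17.7
control,dissatisfaction,11,74.1,6.0,67.3,18.6
control,qol,11,74.1,7.6,75.5,7.5
control,total,11,363.1,16.7,331.8,42.9
control,index,11,0.87,0.05,0.79,0.11
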