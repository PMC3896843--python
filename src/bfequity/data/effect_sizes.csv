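exposure_category,age_group,outcome,metric,rr_mean,rr_lower,rr_upper
predominant,0_5m,diarrhea,incidence,1.26,0.81,1.95
predominant,0_5m,diarrhea,mortality,2.28,0.85,6.13
predominant,0_5m,pneumonia,incidence,1.79,1.29,2.48
predominant,0_5m,pneumonia,mortality,1.75,0.48,6.43
partial,0_5m,diarrhea,incidence,1.68,1.03,2.76
partial,0_5m,diarrhea,mortality,4.62,1.81,11.76
partial,0_5m,pneumonia,incidence,2.48,0.23,27.15
partial,0_5m,pneumonia,mortality,2.49,1.03,6.04
none,0_5m,diarrhea,incidence,2.65,1.72,4.07
none,0_5m,diarrhea,mortality,10.52,2.79,39.60
none,0_5m,pneumonia,incidence,2.07,0.19,22.64
none,0_5m,pneumonia,mortality,15.13,0.61,373.84
discontinued,6_23m,diarrhea,mortality,2.18,1.14,4.16
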