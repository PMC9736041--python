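# LKB NTCP parameter registry: TD50 in Gy, m dose-response slope, n volume effect
structure,endpoint,td50_gy,m,n
cochlea,tinnitus,46.52,0.35,1
cochlea,hearing_loss,55.57,0.14,1
pituitary,endocrine_dysfunction,60.6,0.08,1
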