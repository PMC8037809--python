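compound_id,logBB,logPS,logPS_Fubrain,Fu,Fb
Arjunic acid,0.14,-3.2,-4.9,0.012,0.02
Akebia saponin D,0.32,-4.4,-5.7,0.12,0.06
Bacoside A,0.03,-3.6,-4.5,0.14,0.13
Platycodin D,<-2,-3.6,-9.0,0.52,0.98
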