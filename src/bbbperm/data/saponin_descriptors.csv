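compound_id,logPow,logPhw,logPcw,MW,TPSA,polarizability
Arjunic acid,5.2,4.179,4.029,488.70,97.99,54.15
Akebia saponin D,0.8,-9.919,-9.932,929.10,294.98,91.23
Bacoside A,2.8,-7.553,-7.110,768.97,215.83,78.66
Platycodin D,-3.7,-24.512,-24.704,1225.32,453.28,114.32
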