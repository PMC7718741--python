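CODONML (in paml version 4.9, March 2015)  seq.phy
Model 0: one-ratio

lnL(ntime:  9  np: 11): -1240.112233      +0.000000

kappa (ts/tv) =  2.05113

omega (dN/dS) =  0.08975
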