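CODONML (in paml version 4.9, March 2015)  seq.phy
Model 2: several dN/dS ratios for branches

lnL(ntime:  9  np: 12): -1234.567890      +0.000000

kappa (ts/tv) =  2.11724

w (dN/dS) for branches:  0.06539 2.27669

dN & dS for each branch
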