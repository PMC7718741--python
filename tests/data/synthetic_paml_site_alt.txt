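CODONML (in paml version 4.9, March 2015)  seq.phy
Model 0: NSsites 2: PositiveSelection

lnL(ntime:  9  np: 14): -3301.776655      +0.000000

dN/dS (w) for site classes (K=3)

p:   0.85591  0.08127  0.06282
w:   0.05496  1.00000  3.25465

Bayes Empirical Bayes (BEB) analysis (Yang, Wong & Nielsen 2005. Mol. Biol. Evol. 22:1107-1118)
Positively selected sites (*: P>95%; **: P>99%)
(amino acids refer to 1st sequence: A)

            Pr(w>1)     post mean +- SE for w

     7 G      0.973*        3.011 +- 0.842
    23 S      0.884         2.410 +- 1.122
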