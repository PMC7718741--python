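CODONML (in paml version 4.9, March 2015)  seq.phy
Model 2: PositiveSelection, with 4 site classes

lnL(ntime: 10  np: 14): -2575.264301      +0.000000

MLEs of dN/dS (w) for site classes (K=4)

site class             0        1       2a       2b
proportion       0.55052  0.25565  0.12863  0.06520
background w     0.09941  1.00000  0.09941  1.00000
foreground w     0.09941  1.00000  4.28790  4.28790

Bayes Empirical Bayes (BEB) analysis (Yang, Wong & Nielsen 2005. Mol. Biol. Evol. 22:1107-1118)
Positively selected sites (*: P>95%; **: P>99%)
(amino acids refer to 1st sequence: A)

            Pr(w>1)     post mean +- SE for w

    12 K      0.952*        3.421 +- 1.234
    17 L      0.900         2.544 +- 1.377
    44 R      0.931         2.876 +- 1.401
    61 T      0.850         2.122 +- 1.455
    99 E      0.991**       4.002 +- 0.914

The grid (opt. 1): discrete
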