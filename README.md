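# omegascan

Genome-wide tests of positive selection in protein-coding genes.

`omegascan` takes a directory of codon-aligned ortholog groups (FASTA,
one file per gene, at most one sequence per taxon), a species topology
(Newick), and a branch-label file assigning taxa to foreground clades,
and tests every gene for positive selection with nested codon models.
It is aimed at comparative genomicists who want a codeml-style
branch/site/branch-site scan that runs over thousands of genes with a
variable number of taxa per gene: the species tree is automatically
pruned to each alignment, low-coverage genes are filtered, work is
parallelized per gene, and results are reduced to a candidate list with
likelihood-ratio statistics and selected codon positions.

A built-in maximum-likelihood engine for Goldman–Yang codon models makes
the whole pipeline self-contained and testable; a codeml interop layer
(control-file generation, PAML marked-tree dialects, main-output
parsing) reproduces the external-program execution mode for users who
want PAML's fits and BEB site probabilities.

## The statistic

For codon *i* → *j* differing at one position, the substitution rate is
`π_j · κ^[transition] · ω^[nonsynonymous]`, where ω = dN/dS.  Three
nested pairs are tested per gene with LRTs (`2Δℓ ~ χ²_df`):

- **branch** — M0 (one ω) vs two-ratios (ω_fg, ω_bg), df=1;
- **site** — M1a (nearly neutral) vs M2a (adds ω2 ≥ 1), df=2;
- **branch-site** — model A null (ω2 = 1) vs model A, df=1.

A gene is a candidate when p < α (optionally Bonferroni-corrected across
tested clades) and, for branch-style tests, ω_fg > 1.  For site and
branch-site models, codon positions with posterior probability > 0.9 of
belonging to a positively selected class are reported when the LRT is
significant.  See `docs/methods.md` for the full model description.

## Worked example

`examples/02_branch_site_scan.py` simulates eight ortholog groups on a
six-taxon tree — two evolving with selected-class ω = 5 on the (A,B)
foreground clade — and runs the branch-site scan:

```
8 genes tested on clade (A,B); 3 candidate(s) at alpha=0.05
  g000_pos: p=3.00e-03 omega_fg=5.05 (true positive); 32 selected codon position(s)
    codon 6: P(positive selection)=0.931
    ...
  g001_pos: p=1.11e-03 omega_fg=5.03 (true positive); 7 selected codon position(s)
    ...
  g006_neu: p=2.75e-02 omega_fg=4.45 (FALSE POSITIVE); 1 selected codon position(s)
```

Both simulated-positive genes are recovered with strongly significant
LRTs and foreground ω near the generating value of 5; the listed codons
are the sites the model places in the selected class with posterior
above 0.9.  One neutral gene slips under α = 0.05 at this small scale —
exactly the type-I behavior the LRT's nominal level implies.

The same scan from the shell:

```bash
omegascan run --cds-dir genes/ --tree species.nwk --branches labels.txt \
    --model branch-site --min-fg 2 --min-bg 2 -p 4 --dnds --out results/
omegascan simulate --tree species.nwk --model MA --foreground A,B \
    --omega2 5 --n-sites 300 --seed 1 --out-prefix sim
```

Outputs are TSVs: `candidates.txt` (candidate genes, then their selected
codon positions), `tests.tsv` (all per-gene statistics), `flags.tsv`
(genes skipped and why), optional `dnds.tsv`, `monophyly.tsv` and
per-gene pruned trees under `trees/`, and a `run.log`.

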