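# Methods

## The problem

Protein-coding genes record the balance between nonsynonymous (amino-acid
changing) and synonymous substitutions.  Under the assumption that
synonymous changes are effectively neutral, the ratio ω = dN/dS measures
selective pressure: ω < 1 purifying selection, ω ≈ 1 neutrality, ω > 1
positive selection.  `omegascan` scans a directory of codon-aligned
ortholog groups on a shared species topology and asks, gene by gene,
whether a designated foreground clade (or a subset of codon sites) shows
evidence of positive selection.

## Substitution model

All models are built on the Goldman–Yang codon process over the 61 sense
codons of the universal genetic code.  For codons *i* ≠ *j*:

    q_ij = 0                     more than one nucleotide difference
    q_ij = π_j                   synonymous transversion
    q_ij = κ π_j                 synonymous transition
    q_ij = ω π_j                 nonsynonymous transversion
    q_ij = ω κ π_j               nonsynonymous transition

κ is the transition/transversion rate ratio and π the codon equilibrium
frequencies, by default F3x4 (position-specific nucleotide frequencies
from the alignment, products renormalized over sense codons, with a 1e-6
pseudo-frequency so unobserved nucleotides cannot zero out a codon);
`uniform` frequencies are available as an option.  The process is
reversible, so transition probabilities P(t) = exp(Qt) are computed by
symmetrizing Q with the π^{1/2} similarity transform and taking a
symmetric eigendecomposition, one decomposition per distinct ω per
likelihood evaluation.

Branch lengths are expected substitutions per codon.  In mixture models
each branch's matrix is rescaled so that the *mixture-averaged*
substitution rate on that branch — using the foreground ω's on marked
branches and background ω's elsewhere — equals one.  This keeps branch
lengths comparable across models and makes the simulator and the
likelihood exactly inverse operations.

## Model configurations and tests

Three nested pairs, each tested with a chi-square LRT on
2(lnL_alt − lnL_null):

| test        | null (constraint)            | alternative            | df |
|-------------|------------------------------|------------------------|----|
| branch      | M0: one ω everywhere         | two-ratios: ω_fg, ω_bg | 1  |
| site        | M1a: (ω0<1, 1)               | M2a: adds ω2 ≥ 1       | 2  |
| branch-site | model A null: ω2 = 1         | model A: ω2 ≥ 1 free   | 1  |

Model A uses four site classes (0, 1, 2a, 2b) with the 2a/2b proportions
tied to p0:p1, as is standard.  Because its null pins ω2 on the boundary,
the formally correct reference is a 50:50 mix of χ²₀ and χ²₁; the plain
χ²₁ used here is conservative (p-values at most a factor ~2 too large),
which we prefer over anti-conservative shortcuts.

A gene is a **candidate** when p < α (default 0.05) and — for branch and
branch-site tests — the foreground ω exceeds 1.  With several foreground
clades the scan runs once per clade; the optional Bonferroni correction
divides α by the number of tested clades (not by the number of genes),
matching the multiple-branch-testing use case.  Positively selected
codon positions are reported only when the LRT is significant, at
posterior probability > 0.9 (strict).

Site posteriors from the internal engine are naive empirical Bayes
(NEB): P(class k | site) ∝ p̂_k L(site | class k) at the MLEs.  Bayes
empirical Bayes, which integrates over parameter uncertainty, is **not**
implemented internally; BEB values are available only through the
external codeml backend and its output parser.  NEB posteriors are known
to be overconfident on small data sets, so internal per-site reports
should be read as rankings more than calibrated probabilities; the
gene-level LRT is unaffected.

## Optimization

Fits maximize the likelihood over branch lengths, κ, and the model's
free ω/proportion parameters with L-BFGS-B on transformed coordinates
(log branch lengths, log κ, log ω, stick-breaking logits for class
proportions).  Bounds: ω0 ∈ [1e-4, 1), ω2 ∈ [1, 999], free ω ∈
[1e-4, 999], κ ∈ [0.01, 100], branch lengths ∈ [1e-6, 50]; lnL tolerance
1e-8.  The default is three seeded starts (one heuristic, the rest
log-normal jitters); the pipeline uses two per fit as its throughput
default, and validation sweeps use one where the surface is unimodal in
practice (M0/two-ratios).  Branch lengths are re-estimated under every
model by default; `fix_branch_lengths` reuses the input tree's lengths,
the common speed-up when an M0 pass has already been run.  Convergence
onto a boundary (ω2 → 1, vanishing selected-class mass) is reported in
the result, not treated as failure.  Site patterns are compressed before
evaluation; partial likelihoods are rescaled per node to avoid
underflow.

Likelihood correctness is pinned by an independent oracle: exhaustive
marginalization over all interior-node state assignments (the full
61^k joint tensor), which agrees with the pruning implementation to
< 1e-8 on random trees, parameters, and mixtures.

## Input conventions and filtering

FASTA record names are resolved to tree taxa by requiring the taxon
label to occur as a substring of the record name, uniquely; exact
equality counts.  This makes resolution deterministic and order
independent, at the price of rejecting taxon sets where one label is a
substring of another (reported as a resolution error).  Codons
containing `-` or `N` are treated as fully missing for that taxon and
site (all-ones partial vector) — the analogue of codeml's cleandata=0 —
preserving site numbering; stop codons are rejected at read time.

Genes are admitted when they contain no duplicated taxon and meet the
minimum foreground/background sequence counts (both default 0).  The
species tree is pruned to each gene's taxa: unsampled leaves removed,
degree-2 nodes suppressed with lengths summed, so surviving leaf-to-leaf
path lengths are exactly preserved.  Foreground marking defaults to the
whole clade (stem + internal + terminal branches); `foreground_scope="stem"`
marks only the stem branch — the two conventions that exist in practice,
since clade-level taxon labels do not determine which branches the test
should treat as foreground.  A foreground that is not monophyletic in the
pruned species tree skips the gene with a flag rather than aborting the
run.  Complete-ortholog selection uses strict taxon-set equality.

Optional gene-tree checking builds a neighbor-joining tree from pairwise
nucleotide p-distances (missing data excluded pairwise; taxa processed
in sorted order for determinism) and flags — informationally, without
skipping — genes whose foreground clade is not a bipartition of the gene
tree.  Bookkeeping therefore satisfies: tested + skip-flagged = number
of input genes, per clade; gene-tree flags are a separate output.

## codeml interop

The external backend writes control files for both hypotheses of each
pair (branch: model 0/2 with NSsites 0; site: NSsites 1/2 with model 0;
branch-site: model 2 NSsites 2, null with fix_omega=1 omega=1), always
seqtype=1, CodonFreq=2, cleandata=0, κ estimated from 2.  Trees are
emitted in PAML's mark dialects: `$k` on the clade MRCA (default) or
`#k` per branch.  The parser targets the PAML 4.9 main output: lnL from
the `lnL(...)` line (the value immediately after the colon; the trailing
`+0.000000` term is ignored), ω from the one-ratio line, the branch-ω
line, the site-class table, or the branch-site class table, and BEB rows
kept strictly above 0.9.  Running codeml itself is optional glue and is
not exercised by the test suite; the control files and parser are tested
against synthetic fixtures written in the PAML 4.9 layout.

## Simulator

The simulator is the generative twin of the likelihood: each site draws
a latent class, the root codon is drawn from π, and every branch samples
the child state from the exact P(t) of that class (foreground ω on
marked branches), with the same mixture-averaged branch scaling.  Only
endpoint states are needed, so no event-level simulation is performed.
Per-site true class labels are returned so tests can score posterior
orderings against truth.  It emulates selection-regime heterogeneity
across sites and branches but not indels, rate variation beyond the ω
classes, non-stationary composition, or alignment error — so passing
benchmarks demonstrate correctness of the inference machinery, not
robustness to real-data misspecification.

## Validation benchmarks and problem sizes

The packaged validation (also re-run by `scripts/acceptance.py`) uses a
six-taxon balanced tree with the (A,B) clade as foreground, the package's
standing desk-scale study system:

- likelihood vs exhaustive enumeration on random 4-taxon trees (≤ 1e-8);
- ω recovery under M0 (ω=0.3, κ=2, 500 codons): median within ±0.05;
- branch-LRT calibration on one-ratio null data (300 codons; 120
  replicates in the test suite) with rejection at α=0.05 expected near
  nominal, and power at foreground ω=5 well above it;
- a 30-gene branch-site benchmark (6 genes with selected-class ω=5 on
  the foreground, 12 purifying one-ratio genes, 12 model-A-null genes,
  250 codons each): the scan is expected to recover most true positives
  with few false positives, and to produce byte-identical result files
  for any worker count (per-gene seeds derive from the global seed and
  gene id; `run.log` carries wall-clock timings and is excluded from
  byte comparisons).

Replicate counts and gene lengths are the package's chosen desk-scale
conditions; they are what the shipped tests and the acceptance script
execute.

## Known limitations

- NEB (not BEB) site posteriors from the internal engine, as above.
- Universal genetic code only; the code table is a single extension point.
- No M3/M7/M8 or clade models C/D; no FDR across genes; no paralogy
  handling, alignment, or gene/species-tree reconciliation.
- χ²₁ (not the boundary mixture) for the branch-site null, conservative.
- NJ gene trees use p-distances; long-branch effects can flag or miss
  monophyly in extreme regimes — the flag is informational only.
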