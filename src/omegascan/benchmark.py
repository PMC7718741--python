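"""Synthetic validation benchmarks for the selection pipeline.

These helpers generate seeded genome-scale fixtures (directories of
simulated ortholog alignments with known selection status) and run the
standard self-checks: parameter recovery under the one-ratio model, the
false-positive calibration of the branch LRT, and candidate recovery of
the branch-site scan on a mixed benchmark.  They are part of the public
surface so users can rerun the package's validation on their own machine.
"""

from __future__ import annotations

import os

import numpy as np

from .engine import OptimizerConfig, fit
from .filtering import mark_foreground
from .io import BranchLabelMap
from .models import SiteClassMix
from .simulate import SimSpec, simulate, write_fasta
from .testing import lrt
from .trees import Phylogeny

#: Six-taxon validation tree; the (A,B) clade is the tested foreground.
BENCHMARK_TREE = (
    "(((A:0.15,B:0.15):0.1,C:0.25):0.1,((D:0.15,E:0.15):0.1,F:0.25):0.1);"
)
FOREGROUND = ("A", "B")


def benchmark_tree() -> Phylogeny:
    return Phylogeny.from_newick(BENCHMARK_TREE)


def marked_benchmark_tree() -> Phylogeny:
    tree = benchmark_tree()
    labels = BranchLabelMap({t: (1 if t in FOREGROUND else 0) for t in tree.taxa})
    marked, mono = mark_foreground(tree, labels, 1)
    assert mono
    return marked


def make_branch_site_benchmark(
    out_dir: str,
    seed: int,
    n_positive: int = 6,
    n_purifying: int = 12,
    n_neutral: int = 12,
    n_sites: int = 250,
    omega_fg: float = 5.0,
) -> dict[str, bool]:
    """Write a benchmark gene directory; returns gene_id -> truly positive.

    Positive genes evolve under model A with the selected-class foreground
    omega set to ``omega_fg``; negatives are either purifying one-ratio
    genes or model-A-null genes (selected class neutral).
    """
    os.makedirs(out_dir, exist_ok=True)
    marked = marked_benchmark_tree()
    truth: dict[str, bool] = {}
    specs = (
        [("pos", SiteClassMix.model_a(0.5, 0.2, 0.1, omega_fg), True)] * n_positive
        + [("pur", SiteClassMix.m0(0.2), False)] * n_purifying
        + [("neu", SiteClassMix.model_a(0.5, 0.2, 0.1, 1.0, null=True), False)]
        * n_neutral
    )
    for i, (tag, mix, positive) in enumerate(specs):
        gene_id = f"g{i:03d}_{tag}"
        aln, _ = simulate(
            SimSpec(tree=marked, mix=mix, kappa=2.0, n_sites=n_sites, seed=seed + i),
            gene_id=gene_id,
        )
        write_fasta(aln, os.path.join(out_dir, f"{gene_id}.fa"))
        truth[gene_id] = positive
    benchmark_tree().write(os.path.join(out_dir, "tree.nwk"))
    with open(os.path.join(out_dir, "labels.txt"), "w", newline="\n") as fh:
        fh.write("".join(f"{t} 1\n" for t in FOREGROUND))
    return truth


def m0_omega_recovery(
    n_reps: int = 10,
    seed: int = 0,
    omega: float = 0.3,
    kappa: float = 2.0,
    n_sites: int = 500,
) -> list[float]:
    """Refit omega on data simulated under the one-ratio model."""
    tree = benchmark_tree()
    estimates = []
    for rep in range(n_reps):
        aln, _ = simulate(
            SimSpec(
                tree=tree,
                mix=SiteClassMix.m0(omega),
                kappa=kappa,
                n_sites=n_sites,
                seed=(seed * 1000 + rep) % 2**31,
            )
        )
        res = fit(aln, tree, "M0", OptimizerConfig(n_starts=1, seed=rep))
        estimates.append(float(res.omega_foreground))
    return estimates


def branch_test_rejection_rate(
    n_reps: int,
    seed: int,
    omega_fg: float | None = None,
    n_sites: int = 300,
    alpha: float = 0.05,
) -> float:
    """Fraction of branch LRTs rejecting at ``alpha``.

    ``omega_fg=None`` simulates under the null (one-ratio, omega=0.3) to
    measure the type-I error; a value simulates under the two-ratio
    alternative to measure power.
    """
    marked = marked_benchmark_tree()
    mix = (
        SiteClassMix.m0(0.3)
        if omega_fg is None
        else SiteClassMix.two_ratios(0.3, omega_fg)
    )
    rejections = 0
    for rep in range(n_reps):
        aln, _ = simulate(
            SimSpec(
                tree=marked, mix=mix, kappa=2.0, n_sites=n_sites,
                seed=(seed * 100_000 + rep) % 2**31,
            )
        )
        opt = OptimizerConfig(n_starts=1, seed=rep)
        null = fit(aln, marked, "M0", opt)
        alt = fit(aln, marked, "two_ratios", opt)
        _, p = lrt(null.lnL, alt.lnL, 1)
        if p < alpha:
            rejections += 1
    return rejections / n_reps
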