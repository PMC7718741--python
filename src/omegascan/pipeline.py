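"""End-to-end genome-wide selection scan.

For every ortholog alignment in a directory the pipeline applies the
admission filters, prunes the species tree to the taxa present, marks the
tested foreground clade, fits the null and alternative models (internal
engine by default, codeml optionally), performs the LRT, applies the
candidate rules, and writes TSV outputs.  With several foreground clades
the whole workflow runs once per clade, with an optional Bonferroni
correction of the significance level by the number of tested clades.

Per-gene work is independent and distributed over worker processes; each
gene derives its own RNG seed from the global seed and the gene id, so
results are identical for any thread count.
"""

from __future__ import annotations

import glob
import logging
import os
import shutil
import subprocess
import time
import zlib
from dataclasses import dataclass, field

from joblib import Parallel, delayed

from . import interop
from .engine import EngineError, OptimizerConfig, fit, positive_site_probabilities, site_posteriors
from .filtering import (
    FilterPolicy,
    GeneFlag,
    admit,
    build_gene_tree,
    check_monophyly,
    mark_foreground,
    prune_to_alignment,
)
from .io import (
    AlignmentError,
    BranchLabelMap,
    DuplicateTaxonError,
    read_branch_labels,
    read_codon_fasta,
    read_newick,
)
from .models import TEST_PAIRS
from .testing import TestOutcome, bonferroni_alpha, classify
from .trees import Phylogeny, TreeError

log = logging.getLogger(__name__)

_FASTA_PATTERNS = ("*.fa", "*.fasta", "*.fna")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    alignment_dir: str
    tree_path: str
    branch_label_path: str | None = None
    model: str = "branch-site"  # branch | site | branch-site | custom
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    alpha: float = 0.05
    site_threshold: float = 0.9
    bonferroni: bool = False
    gene_trees: bool = False
    dnds_out: bool = False
    threads: int = 1
    backend: str = "internal"  # internal | codeml
    seed: int = 1
    foreground_scope: str = "clade"  # clade | stem
    frequency_source: str = "F3x4"  # F3x4 | uniform
    n_starts: int = 2  # optimizer restarts per fit (pipeline throughput default)
    fix_branch_lengths: bool = False
    write_trees: bool = False  # emit each gene's pruned (marked) tree
    out_dir: str | None = None
    codeml_binary: str = "codeml"
    custom_null_ctl: str | None = None
    custom_alt_ctl: str | None = None
    custom_df: int | None = None

    def __post_init__(self):
        if self.model not in ("branch", "site", "branch-site", "custom"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.backend not in ("internal", "codeml"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.model == "custom" and (
            self.backend != "codeml"
            or not (self.custom_null_ctl and self.custom_alt_ctl and self.custom_df)
        ):
            raise ValueError(
                "custom model requires backend='codeml' plus null/alt control "
                "templates and df"
            )
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class ResultsBundle:
    """Aggregated results of one run."""

    model: str
    outcomes: list[TestOutcome]
    flags: list[GeneFlag]  # genes excluded from testing, one reason each
    monophyly_flags: list[GeneFlag]  # informational gene-tree disagreements
    n_input: int
    clades: list[int | None]
    alpha_used: float
    timings: dict[tuple[str, int | None], float] = field(default_factory=dict)
    pruned_trees: dict[tuple[str, int | None], str] = field(default_factory=dict)

    def candidates(self) -> list[TestOutcome]:
        return [o for o in self.outcomes if o.candidate]


def gene_seed(global_seed: int, gene_id: str, clade_id) -> int:
    """Deterministic per-gene RNG seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{clade_id}:{gene_id}".encode()) & 0x7FFFFFFF


def list_alignment_files(alignment_dir: str) -> list[str]:
    files: list[str] = []
    for pat in _FASTA_PATTERNS:
        files.extend(glob.glob(os.path.join(alignment_dir, pat)))
    return sorted(files)


def _analyze_gene(
    path: str,
    tree_newick: str,
    labels_dict: dict[str, int],
    clade_id: int | None,
    config: RunConfig,
    alpha_used: float,
) -> dict:
    """Worker: one gene x one tested clade.  Never raises."""
    gene_id = os.path.splitext(os.path.basename(path))[0]
    tree = Phylogeny.from_newick(tree_newick)
    labels = BranchLabelMap(labels_dict)
    started = time.perf_counter()
    out: dict = {"gene_id": gene_id, "clade_id": clade_id}
    try:
        alignment = read_codon_fasta(path, tree.taxa, gene_id=gene_id)
    except DuplicateTaxonError as exc:
        out["flag"] = GeneFlag(gene_id, "duplicate_taxon", str(exc))
        return out
    except (AlignmentError, ValueError) as exc:
        out["flag"] = GeneFlag(gene_id, "read_error", str(exc))
        return out

    flag = admit(alignment, labels, clade_id, config.policy)
    if flag is not None:
        out["flag"] = flag
        return out
    if alignment.n_taxa < 2:
        out["flag"] = GeneFlag(gene_id, "read_error", "fewer than 2 taxa")
        return out

    pruned = prune_to_alignment(tree, alignment.taxa)

    test = config.model
    fg_taxa: set[str] = set()
    if clade_id is not None:
        fg_taxa = labels.taxa_in_clade(clade_id) & pruned.taxa
        if not fg_taxa:
            out["flag"] = GeneFlag(gene_id, "no_foreground_taxon", f"clade {clade_id}")
            return out
        marked, mono = mark_foreground(
            pruned, labels, clade_id, scope=config.foreground_scope
        )
        if not mono:
            out["flag"] = GeneFlag(
                gene_id, "foreground_not_monophyletic_species_tree", f"clade {clade_id}"
            )
            return out
        work_tree = marked
    else:
        work_tree = pruned

    if config.gene_trees and fg_taxa and alignment.n_taxa >= 3 and len(fg_taxa) >= 1:
        gtree = build_gene_tree(alignment)
        if not check_monophyly(gtree, fg_taxa):
            out["monophyly_flag"] = GeneFlag(
                gene_id, "foreground_not_monophyletic_gene_tree", f"clade {clade_id}"
            )

    if config.write_trees:
        out["tree_newick"] = work_tree.to_newick(lengths=True)

    null_id, alt_id, df = TEST_PAIRS[test]
    seed = gene_seed(config.seed, gene_id, clade_id)
    try:
        if config.backend == "internal":
            opt = OptimizerConfig(
                n_starts=config.n_starts,
                seed=seed,
                fix_branch_lengths=config.fix_branch_lengths,
            )
            fit_null = fit(alignment, work_tree, null_id, opt)
            fit_alt = fit(alignment, work_tree, alt_id, opt)
            probs = None
            if alt_id in ("M2a", "MA"):
                post = site_posteriors(fit_alt, alignment, work_tree)
                probs = positive_site_probabilities(fit_alt, post)
            outcome = classify(
                gene_id,
                clade_id,
                test,
                fit_null,
                fit_alt,
                df,
                alpha_used=alpha_used,
                site_threshold=config.site_threshold,
                positive_site_probs=probs,
            )
        else:
            outcome = _run_codeml_gene(
                gene_id, clade_id, alignment, work_tree, test, df, alpha_used, config
            )
    except (EngineError, TreeError, ValueError, FloatingPointError) as exc:
        out["flag"] = GeneFlag(gene_id, "fit_error", str(exc))
        return out
    out["outcome"] = outcome
    out["elapsed"] = time.perf_counter() - started
    return out


def _run_codeml_gene(
    gene_id, clade_id, alignment, work_tree, test, df, alpha_used, config
) -> TestOutcome:
    """External backend: write inputs, invoke codeml twice, parse outputs.

    Requires the codeml binary on PATH (or `config.codeml_binary`); the
    internal engine is the tested default.
    """
    if shutil.which(config.codeml_binary) is None:
        raise EngineError(f"codeml binary {config.codeml_binary!r} not found")
    base = os.path.join(config.out_dir or ".", "codeml", f"{gene_id}_c{clade_id}")
    os.makedirs(base, exist_ok=True)
    seqfile = os.path.join(base, "seq.phy")
    treefile = os.path.join(base, "tree.nwk")
    interop.write_paml_sequences(alignment, seqfile)
    if clade_id is not None:
        style = "$" if config.foreground_scope == "clade" else "#"
        interop.write_marked_newick(work_tree, treefile, mark_style=style)
    else:
        work_tree.write(treefile, lengths=False)
    results = {}
    for hyp in ("null", "alt"):
        outfile = os.path.join(base, f"{hyp}.mlc")
        ctl = os.path.join(base, f"{hyp}.ctl")
        if test == "custom":
            template = (
                config.custom_null_ctl if hyp == "null" else config.custom_alt_ctl
            )
            with open(template) as fh:
                text = fh.read()
            text = (
                text.replace("{seqfile}", seqfile)
                .replace("{treefile}", treefile)
                .replace("{outfile}", outfile)
            )
            with open(ctl, "w", newline="\n") as fh:
                fh.write(text)
        else:
            interop.write_control_file(test, hyp, seqfile, treefile, outfile, ctl)
        subprocess.run(
            [config.codeml_binary, os.path.basename(ctl)],
            cwd=base,
            check=True,
            capture_output=True,
        )
        with open(outfile) as fh:
            results[hyp] = interop.parse_codeml_output(
                fh.read(), beb_threshold=config.site_threshold
            )
    from .testing import lrt

    statistic, p_value = lrt(results["null"].lnL, results["alt"].lnL, df)
    alt = results["alt"]
    candidate = p_value < alpha_used
    if test in ("branch", "branch-site", "custom"):
        candidate = candidate and (alt.omega_foreground or 0.0) > 1.0
    sites = (
        [(pos, prob) for pos, _aa, prob in alt.beb_sites]
        if (p_value < alpha_used and test in ("site", "branch-site"))
        else []
    )
    return TestOutcome(
        gene_id=gene_id,
        clade_id=clade_id,
        test=test,
        lnL_null=results["null"].lnL,
        lnL_alt=alt.lnL,
        statistic=statistic,
        df=df,
        p_value=p_value,
        alpha_used=alpha_used,
        candidate=candidate,
        omega_foreground=alt.omega_foreground,
        omega_background=alt.omega_background,
        positive_sites=sites,
    )


def run(config: RunConfig) -> ResultsBundle:
    """Execute the full scan; per-gene failures are flagged, never fatal."""
    files = list_alignment_files(config.alignment_dir)
    if not files:
        raise FileNotFoundError(f"no FASTA files in {config.alignment_dir}")
    tree = read_newick(config.tree_path)
    if config.branch_label_path:
        labels = read_branch_labels(config.branch_label_path, tree)
    else:
        labels = BranchLabelMap({t: 0 for t in tree.taxa})

    if config.model == "site":
        clades: list[int | None] = [None]
    else:
        clades = list(labels.foreground_clades())
        if not clades:
            raise ValueError(
                f"{config.model} model requires at least one foreground clade "
                "(label >= 1) in the branch-label file"
            )

    alpha_used = config.alpha
    if config.bonferroni and len(clades) > 1:
        alpha_used = bonferroni_alpha(config.alpha, len(clades))

    tree_newick = tree.to_newick(lengths=True)
    tasks = [
        (path, clade_id) for clade_id in clades for path in files
    ]
    log.info(
        "running %s model on %d genes x %d clade(s), alpha=%g, backend=%s",
        config.model, len(files), len(clades), alpha_used, config.backend,
    )
    results = Parallel(n_jobs=config.threads, prefer="processes")(
        delayed(_analyze_gene)(
            path, tree_newick, dict(labels.labels), clade_id, config, alpha_used
        )
        for path, clade_id in tasks
    )

    outcomes, flags, mono_flags = [], [], []
    timings: dict[tuple[str, int | None], float] = {}
    pruned_trees: dict[tuple[str, int | None], str] = {}
    for res in results:
        if "elapsed" in res:
            timings[(res["gene_id"], res["clade_id"])] = res["elapsed"]
        if "tree_newick" in res:
            pruned_trees[(res["gene_id"], res["clade_id"])] = res["tree_newick"]
        if "outcome" in res:
            outcomes.append(res["outcome"])
        if "flag" in res:
            flags.append(res["flag"])
            log.info("flagged %s (clade %s): %s", res["gene_id"], res["clade_id"],
                     res["flag"].reason)
        if "monophyly_flag" in res:
            mono_flags.append(res["monophyly_flag"])
    outcomes.sort(key=lambda o: (str(o.clade_id), o.gene_id))
    flags.sort(key=lambda f: f.gene_id)
    mono_flags.sort(key=lambda f: f.gene_id)
    if not outcomes:
        log.warning("no gene was admitted for testing")
    return ResultsBundle(
        model=config.model,
        outcomes=outcomes,
        flags=flags,
        monophyly_flags=mono_flags,
        n_input=len(files),
        clades=clades,
        alpha_used=alpha_used,
        timings=timings,
        pruned_trees=pruned_trees,
    )


# ----------------------------------------------------------------------
# output files
# ----------------------------------------------------------------------
def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_results(bundle: ResultsBundle, config: RunConfig, out_dir: str) -> list[str]:
    """Write the TSV outputs; returns the list of files written."""
    os.makedirs(out_dir, exist_ok=True)
    written = []

    path = os.path.join(out_dir, "candidates.txt")
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# candidate genes under positive selection\t"
            f"model={bundle.model}\talpha_used={_fmt(bundle.alpha_used)}\n"
        )
        for o in bundle.candidates():
            clade = "-" if o.clade_id is None else str(o.clade_id)
            fh.write(
                f"{o.gene_id}\t{clade}\tp={_fmt(o.p_value)}"
                + (
                    f"\twfg={_fmt(o.omega_foreground)}"
                    if o.omega_foreground is not None
                    else ""
                )
                + "\n"
            )
            for pos, prob in o.positive_sites:
                fh.write(f"{o.gene_id}\tsite\t{pos}\t{_fmt(prob)}\n")
    written.append(path)

    path = os.path.join(out_dir, "tests.tsv")
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "gene_id\tclade_id\ttest\tlnL_null\tlnL_alt\tstatistic\tdf\t"
            "p_value\talpha_used\tcandidate\tomega_fg\tomega_bg\n"
        )
        for o in bundle.outcomes:
            clade = "-" if o.clade_id is None else str(o.clade_id)
            wfg = "-" if o.omega_foreground is None else _fmt(o.omega_foreground)
            wbg = "-" if o.omega_background is None else _fmt(o.omega_background)
            fh.write(
                f"{o.gene_id}\t{clade}\t{o.test}\t{_fmt(o.lnL_null)}\t"
                f"{_fmt(o.lnL_alt)}\t{_fmt(o.statistic)}\t{o.df}\t"
                f"{_fmt(o.p_value)}\t{_fmt(o.alpha_used)}\t{int(o.candidate)}\t"
                f"{wfg}\t{wbg}\n"
            )
    written.append(path)

    path = os.path.join(out_dir, "flags.tsv")
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\treason\tdetail\n")
        for f in bundle.flags:
            fh.write(f"{f.gene_id}\t{f.reason}\t{f.detail}\n")
    written.append(path)

    if config.dnds_out:
        if bundle.model in ("branch", "branch-site", "custom"):
            path = os.path.join(out_dir, "dnds.tsv")
            with open(path, "w", newline="\n") as fh:
                fh.write("gene_id\tclade_id\tomega_fg\tomega_bg\n")
                for o in bundle.outcomes:
                    if o.omega_foreground is None:
                        continue
                    clade = "-" if o.clade_id is None else str(o.clade_id)
                    fh.write(
                        f"{o.gene_id}\t{clade}\t{_fmt(o.omega_foreground)}\t"
                        f"{_fmt(o.omega_background)}\n"
                    )
            written.append(path)
        else:
            log.info("dnds output skipped: no branch omegas under the site model")

    if config.write_trees and bundle.pruned_trees:
        tree_dir = os.path.join(out_dir, "trees")
        os.makedirs(tree_dir, exist_ok=True)
        for (gene, clade), newick in sorted(bundle.pruned_trees.items()):
            suffix = "" if clade is None else f"_c{clade}"
            path = os.path.join(tree_dir, f"{gene}{suffix}.nwk")
            with open(path, "w", newline="\n") as fh:
                fh.write(newick + "\n")
            written.append(path)

    path = os.path.join(out_dir, "run.log")
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# model={bundle.model} alpha_used={_fmt(bundle.alpha_used)} "
            f"genes={bundle.n_input} tested={len(bundle.outcomes)} "
            f"flagged={len(bundle.flags)}\n"
        )
        for (gene, clade), elapsed in sorted(bundle.timings.items()):
            fh.write(f"{gene}\tclade={clade}\t{elapsed:.2f}s\n")
        for f in bundle.flags:
            fh.write(f"{f.gene_id}\tflag={f.reason}\t{f.detail}\n")
    written.append(path)

    if config.gene_trees:
        path = os.path.join(out_dir, "monophyly.tsv")
        with open(path, "w", newline="\n") as fh:
            fh.write("gene_id\treason\tdetail\n")
            for f in bundle.monophyly_flags:
                fh.write(f"{f.gene_id}\t{f.reason}\t{f.detail}\n")
        written.append(path)

    return written
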