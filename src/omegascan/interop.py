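"""codeml (PAML 4.9) interoperability: control files, marked trees, parsing.

The pipeline can delegate model fitting to the external ``codeml``
program.  This module generates the control files for both hypotheses of
each nested pair, writes trees in PAML's branch-mark dialects (``#k`` for
individual branches, ``$k`` for whole clades), and parses the quantities
the pipeline needs from codeml's main output file: the maximized
log-likelihood, the foreground/background dN/dS estimates, and the Bayes
empirical Bayes (BEB) positively selected sites above the 0.9 posterior
threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .trees import Phylogeny


class ParseError(ValueError):
    """Required field missing from a codeml output file."""


#: codeml keys shared by every generated control file.
_COMMON_SETTINGS = (
    ("noisy", "0"),
    ("verbose", "0"),
    ("runmode", "0"),
    ("seqtype", "1"),
    ("CodonFreq", "2"),
    ("clock", "0"),
    ("model", None),
    ("NSsites", None),
    ("icode", "0"),
    ("fix_kappa", "0"),
    ("kappa", "2"),
    ("fix_omega", None),
    ("omega", None),
    ("cleandata", "0"),
)

#: (model, NSsites, fix_omega, omega) per test and hypothesis.
_HYPOTHESIS_SETTINGS = {
    ("branch", "null"): ("0", "0", "0", "0.4"),
    ("branch", "alt"): ("2", "0", "0", "0.4"),
    ("site", "null"): ("0", "1", "0", "0.4"),
    ("site", "alt"): ("0", "2", "0", "0.4"),
    ("branch-site", "null"): ("2", "2", "1", "1"),
    ("branch-site", "alt"): ("2", "2", "0", "1.5"),
}


def control_file_text(
    model_id: str, hypothesis: str, seqfile: str, treefile: str, outfile: str
) -> str:
    """Deterministic codeml control-file text for one hypothesis.

    ``model_id`` is ``branch``, ``site`` or ``branch-site``; ``hypothesis``
    is ``null`` or ``alt``.  Null and alternative files of a pair differ
    only in the model/NSsites/fix_omega/omega keys.
    """
    key = (model_id, hypothesis)
    if key not in _HYPOTHESIS_SETTINGS:
        raise ValueError(f"unknown model/hypothesis {key!r}")
    model, nssites, fix_omega, omega = _HYPOTHESIS_SETTINGS[key]
    overrides = {
        "model": model,
        "NSsites": nssites,
        "fix_omega": fix_omega,
        "omega": omega,
    }
    lines = [
        f"seqfile = {seqfile}",
        f"treefile = {treefile}",
        f"outfile = {outfile}",
    ]
    for k, default in _COMMON_SETTINGS:
        lines.append(f"{k} = {overrides.get(k, default)}")
    return "\n".join(lines) + "\n"


def write_control_file(
    model_id: str, hypothesis: str, seqfile, treefile, outfile, path
) -> None:
    text = control_file_text(model_id, hypothesis, str(seqfile), str(treefile), str(outfile))
    with open(path, "w", newline="\n") as fh:
        fh.write(text)


def write_marked_newick(tree: Phylogeny, path=None, mark_style: str = "$") -> str:
    """Tree in PAML's marked-Newick dialect.

    ``mark_style="$"`` annotates only the rootmost marked node (PAML clade
    mark, covering the whole subtree); ``"#"`` annotates every marked
    branch individually.  Branch lengths are omitted (codeml re-estimates
    them).  Raises if the tree carries no mark.
    """
    if mark_style not in ("#", "$"):
        raise ValueError("mark_style must be '#' or '$'")
    if all(n.mark == 0 for n in tree.postorder()):
        raise ValueError("tree has no marked branch")
    text = tree.to_newick(lengths=False, mark_style=mark_style)
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text + "\n")
    return text


def write_paml_sequences(alignment, path) -> None:
    """Alignment in PAML's sequential phylip-like format."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f" {alignment.n_taxa} {alignment.n_sites * 3}\n")
        for taxon, row in zip(alignment.taxa, alignment.codons):
            fh.write(f"{taxon}\n{''.join(row)}\n")


@dataclass
class CodemlOutput:
    """Quantities parsed from a codeml main result file."""

    lnL: float
    omega_foreground: float | None = None
    omega_background: float | None = None
    beb_sites: list[tuple[int, str, float]] = field(default_factory=list)


_LNL_RE = re.compile(r"lnL\([^)]*\)\s*:\s*(-?\d+(?:\.\d+)?)")
_FLOAT_RE = re.compile(r"-?\d+\.?\d*")


def parse_codeml_output(text: str, beb_threshold: float = 0.9) -> CodemlOutput:
    """Parse lnL, omega estimates and BEB sites from codeml main output.

    BEB rows are kept only when the posterior probability is strictly
    greater than ``beb_threshold``; an absent BEB block (null fits, branch
    models) yields an empty site list.  A missing lnL line is an error.
    """
    lines = text.splitlines()
    m = _LNL_RE.search(text)
    if not m:
        raise ParseError("no lnL line found")
    lnL = float(m.group(1))

    omega_fg = omega_bg = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("w (dN/dS) for branches:"):
            vals = [float(v) for v in _FLOAT_RE.findall(s.split(":", 1)[1])]
            if vals:
                omega_bg = vals[0]
                omega_fg = vals[-1]
        elif s.startswith("omega (dN/dS)"):
            vals = _FLOAT_RE.findall(s.split("=", 1)[1])
            if vals:
                omega_fg = omega_bg = float(vals[0])
        elif s.startswith("background w"):
            vals = [float(v) for v in _FLOAT_RE.findall(s.split("w", 1)[1])]
            if vals:
                omega_bg = vals[0]
        elif s.startswith("foreground w"):
            vals = [float(v) for v in _FLOAT_RE.findall(s.split("w", 1)[1])]
            if vals:
                omega_fg = vals[-1]
        elif s.startswith("p:") and i + 1 < len(lines):
            nxt = lines[i + 1].strip()
            if nxt.startswith("w:"):
                vals = [float(v) for v in _FLOAT_RE.findall(nxt[2:])]
                if vals:
                    omega_bg = vals[0]
                    omega_fg = vals[-1]

    beb_sites = _parse_beb_block(lines, beb_threshold)
    return CodemlOutput(
        lnL=lnL,
        omega_foreground=omega_fg,
        omega_background=omega_bg,
        beb_sites=beb_sites,
    )


_BEB_ROW_RE = re.compile(
    r"^\s*(\d+)\s+([A-Z*\-])\s+(\d?\.\d+)\s*(\*{0,2})"
)


def _parse_beb_block(lines: list[str], threshold: float) -> list[tuple[int, str, float]]:
    sites: list[tuple[int, str, float]] = []
    in_beb = False
    in_rows = False
    for line in lines:
        if "Bayes Empirical Bayes" in line:
            in_beb = True
            in_rows = False
            continue
        if in_beb and "Positively selected sites" in line:
            in_rows = True
            continue
        if in_rows:
            s = line.rstrip()
            if not s.strip():
                if sites:
                    break
                continue
            if s.lstrip().startswith(("Pr(", "(amino acids", "lnL", "The grid")):
                continue
            m = _BEB_ROW_RE.match(s)
            if m is None:
                break
            pos, aa, prob = int(m.group(1)), m.group(2), float(m.group(3))
            if prob > threshold:
                sites.append((pos, aa, prob))
    return sites
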