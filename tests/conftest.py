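"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from omegascan.codons import N_CODONS
from omegascan.engine import TreeIndex, _Propagator
from omegascan.io import CodonAlignment
from omegascan.models import SiteClassMix
from omegascan.trees import Phylogeny


@pytest.fixture
def tree4() -> Phylogeny:
    return Phylogeny.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.2);")


@pytest.fixture
def tree6() -> Phylogeny:
    return Phylogeny.from_newick(
        "(((A:0.15,B:0.15):0.1,C:0.25):0.1,((D:0.15,E:0.15):0.1,F:0.25):0.1);"
    )


@pytest.fixture
def marked_tree6(tree6) -> Phylogeny:
    """tree6 with the (A,B) clade marked as foreground 1."""
    from omegascan.filtering import mark_foreground
    from omegascan.io import BranchLabelMap

    labels = BranchLabelMap({t: (1 if t in ("A", "B") else 0) for t in tree6.taxa})
    marked, mono = mark_foreground(tree6, labels, 1)
    assert mono
    return marked


# ----------------------------------------------------------------------
# independent likelihood oracle: exhaustive marginalization
# ----------------------------------------------------------------------
def brute_force_loglik(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mix: SiteClassMix,
    kappa: float,
    pi: np.ndarray,
) -> float:
    """Site log-likelihood by full enumeration of interior-node states.

    The joint probability tensor over every interior node's 61 states is
    materialized and summed — no pruning recursion — so it is an
    independent check of the engine's Felsenstein implementation.
    Practical for trees with at most ~3 interior nodes.
    """
    index = TreeIndex.from_phylogeny(tree)
    internal = [
        i for i in range(index.n_nodes) if (index.parent == i).any()
    ]
    axes = {node: ax for ax, node in enumerate(internal)}
    n_int = len(internal)
    assert n_int <= 3, "oracle limited to small trees"
    root = int(index.postorder[-1])
    states = alignment.states()
    order = [lab for lab, _ in sorted(index.leaf_ids.items(), key=lambda kv: kv[1])]
    rows = {lab: alignment.taxa.index(lab) for lab in order}

    props = mix.proportions
    omegas = sorted(
        {c.omega_background for c in mix.classes}
        | {c.omega_foreground for c in mix.classes}
    )
    propagators = {w: _Propagator(kappa, w, pi) for w in omegas}
    trans: dict[tuple[int, int], np.ndarray] = {}
    for node in range(index.n_nodes):
        if index.parent[node] == -1:
            continue
        fg = index.marks[node] > 0
        ws = [(c.omega_foreground if fg else c.omega_background) for c in mix.classes]
        scale = sum(p * propagators[w].rate for p, w in zip(props, ws))
        for k, w in enumerate(ws):
            trans[(node, k)] = propagators[w].expm(index.lengths[node] / scale)

    def shape_for(node_ax):
        shp = [1] * n_int
        shp[node_ax] = N_CODONS
        return shp

    total = 0.0
    for s in range(alignment.n_sites):
        site_lik = 0.0
        for k in range(len(mix.classes)):
            tensor = np.ones([N_CODONS] * n_int)
            tensor = tensor * pi.reshape(shape_for(axes[root]))
            for node in range(index.n_nodes):
                par = index.parent[node]
                if par == -1:
                    continue
                P = trans[(node, k)]
                if node in axes:  # internal child: factor over (parent, child) axes
                    ap, ac = axes[int(par)], axes[node]
                    shp = [1] * n_int
                    shp[ap] = N_CODONS
                    shp[ac] = N_CODONS
                    # reshape consumes dimensions in axis order: transpose so
                    # the earlier tensor axis comes first in memory
                    mat = P if ap < ac else P.T
                    tensor = tensor * mat.reshape(shp)
                else:  # leaf child
                    leaf_label = [
                        lab for lab, nid in index.leaf_ids.items() if nid == node
                    ][0]
                    st = states[rows[leaf_label], s]
                    vec = P[:, st] if st >= 0 else P.sum(axis=1)
                    tensor = tensor * vec.reshape(shape_for(axes[int(par)]))
            site_lik += props[k] * tensor.sum()
        total += np.log(site_lik)
    return float(total)


def random_tree(rng: np.random.Generator, labels: list[str]) -> Phylogeny:
    """Random binary rooted topology with U(0.02, 0.8) branch lengths."""
    from omegascan.trees import Node

    nodes = [Node(lab, float(rng.uniform(0.02, 0.8))) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(rng.uniform(0.02, 0.8)))
        parent.children = [nodes[i], nodes[j]]
        rest = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes = rest + [parent]
    root = Node(None, None)
    root.children = nodes
    return Phylogeny(root)
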