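"""Maximum-likelihood codon-model engine.

Implements the Goldman–Yang codon substitution process and fits the six
nested model configurations by maximizing the phylogenetic likelihood
(Felsenstein pruning over a site-class mixture) with a bounded
quasi-Newton optimizer on log/logit-transformed parameters.

Rate matrix
-----------
For sense codons *i* ≠ *j*::

    q_ij = 0                      if i and j differ at more than one position
    q_ij = pi_j                   synonymous transversion
    q_ij = kappa * pi_j           synonymous transition
    q_ij = omega * pi_j           nonsynonymous transversion
    q_ij = omega * kappa * pi_j   nonsynonymous transition

with the diagonal set so rows sum to zero.  Branch lengths are expected
substitutions per codon: on every branch the matrix is rescaled so the
mixture-averaged substitution rate (over the site classes active on that
branch, foreground or background) equals one.

Transition probabilities use the reversible similarity transform
``S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` followed by a symmetric
eigendecomposition, so ``P(t)`` costs one scaled matrix product per branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .codons import (
    IS_NONSYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_STEP,
    f3x4_frequencies,
    uniform_frequencies,
)
from .io import CodonAlignment
from .models import (
    BRANCH_MODELS,
    CodonModelParams,
    FitResult,
    SITE_CLASS_MODELS,
    SiteClassMix,
)
from .trees import Node, Phylogeny


class EngineError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# rate matrix
# ----------------------------------------------------------------------
def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 instantaneous rate matrix over the 61 sense codons.

    With ``scale=True`` the matrix is normalized to one expected
    substitution per codon per unit time at equilibrium.
    """
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi is not normalized")
    Q = np.where(SINGLE_STEP, pi[None, :], 0.0)
    Q = Q * np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_NONSYNONYMOUS, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = mean_rate_unscaled(kappa, omega, pi)
        if rate > 0:
            Q = Q / rate
    return Q


def mean_rate_unscaled(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Equilibrium substitution rate of the unscaled GY94 matrix."""
    R = np.where(SINGLE_STEP, pi[None, :], 0.0)
    R = R * np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_NONSYNONYMOUS, omega, 1.0)
    return float(pi @ R.sum(axis=1))


class _Propagator:
    """Eigendecomposition of an unscaled reversible Q, reused across branches."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        Q = build_rate_matrix(kappa, omega, pi, scale=False)
        self.rate = mean_rate_unscaled(kappa, omega, pi)
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]  # diag(pi^-1/2) @ U
        self.right = (U * sqrt_pi[:, None]).T  # U.T @ diag(pi^1/2)

    def expm(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1, entries clipped at 0."""
        P = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(P, 0.0, None)


def transition_matrix(
    kappa: float, omega: float, pi: np.ndarray, t: float
) -> np.ndarray:
    """P(t) for a single scaled GY94 matrix (convenience wrapper)."""
    prop = _Propagator(kappa, omega, pi)
    return prop.expm(t / prop.rate if prop.rate > 0 else t)


# ----------------------------------------------------------------------
# tree indexing
# ----------------------------------------------------------------------
@dataclass
class TreeIndex:
    """Flattened postorder view of a phylogeny for likelihood computation.

    ``edges[i]`` is the node id whose branch (to its parent) is the i-th
    optimizable branch; the root carries no branch.
    """

    n_nodes: int
    postorder: np.ndarray  # node ids, root last
    parent: np.ndarray  # parent id per node (-1 for root)
    lengths: np.ndarray  # input branch length per node (0 where unknown)
    marks: np.ndarray  # integer mark per node's branch
    leaf_ids: dict[str, int]
    edges: np.ndarray  # node ids owning a branch, postorder

    @classmethod
    def from_phylogeny(cls, tree: Phylogeny) -> "TreeIndex":
        nodes: list[Node] = tree.postorder()
        ids = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        for n in nodes:
            for c in n.children:
                parent[ids[id(c)]] = ids[id(n)]
        lengths = np.array([n.length if n.length is not None else 0.0 for n in nodes])
        marks = np.array([n.mark for n in nodes], dtype=np.int64)
        leaf_ids = {n.label: ids[id(n)] for n in nodes if n.is_leaf}
        root = ids[id(tree.root)]
        edges = np.array([i for i in range(len(nodes)) if i != root], dtype=np.int64)
        return cls(
            n_nodes=len(nodes),
            postorder=np.arange(len(nodes), dtype=np.int64),
            parent=parent,
            lengths=lengths,
            marks=marks,
            leaf_ids=leaf_ids,
            edges=edges,
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def taxa(self) -> set[str]:
        return set(self.leaf_ids)


def _pattern_compress(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    patterns, inverse, counts = np.unique(
        states, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), counts.astype(float)


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------
def _per_class_site_logliks(
    patterns: np.ndarray,
    index: TreeIndex,
    mix: SiteClassMix,
    kappa: float,
    pi: np.ndarray,
    branch_lengths: np.ndarray,
) -> np.ndarray:
    """(n_classes, n_patterns) log-likelihoods conditional on each class."""
    n_classes = len(mix.classes)
    n_pat = patterns.shape[1]
    props = mix.proportions

    omegas = sorted(
        {c.omega_background for c in mix.classes}
        | {c.omega_foreground for c in mix.classes}
    )
    propagators = {w: _Propagator(kappa, w, pi) for w in omegas}

    # per-branch class omegas and mixture-average rate scaling
    bl = np.zeros(index.n_nodes)
    bl[index.edges] = branch_lengths
    trans: dict[tuple[int, int], np.ndarray] = {}  # (node, class) -> P
    for node in index.edges:
        fg = index.marks[node] > 0
        ws = [
            (c.omega_foreground if fg else c.omega_background) for c in mix.classes
        ]
        scale = float(sum(p * propagators[w].rate for p, w in zip(props, ws)))
        t = bl[node] / scale if scale > 0 else bl[node]
        cache: dict[float, np.ndarray] = {}
        for k, w in enumerate(ws):
            if w not in cache:
                cache[w] = propagators[w].expm(t)
            trans[(node, k)] = cache[w]

    leaf_row = {node: r for r, node in enumerate(sorted(index.leaf_ids.values()))}
    # map taxon order of patterns: caller passes rows ordered by leaf label sort
    out = np.empty((n_classes, n_pat))
    eye = np.eye(N_CODONS)
    for k in range(n_classes):
        partial = {}
        logscale = np.zeros(n_pat)
        for node in index.postorder:
            pid = int(node)
            if index.parent[pid] == -1 and not _has_children(index, pid):
                raise EngineError("degenerate single-node tree")
            children = np.flatnonzero(index.parent == pid)
            if len(children) == 0:
                row = leaf_row[pid]
                st = patterns[row]
                L = np.ones((N_CODONS, n_pat))
                obs = st >= 0
                L[:, obs] = eye[:, st[obs]]
                partial[pid] = L
            else:
                L = np.ones((N_CODONS, n_pat))
                for cid in children:
                    L = L * (trans[(int(cid), k)] @ partial[int(cid)])
                    del partial[int(cid)]
                m = L.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                L = L / m
                logscale = logscale + np.log(m)
                partial[pid] = L
        root = int(index.postorder[-1])
        site_lik = pi @ partial[root]
        with np.errstate(divide="ignore"):
            out[k] = np.log(site_lik) + logscale
    return out


def _has_children(index: TreeIndex, pid: int) -> bool:
    return bool((index.parent == pid).any())


def _states_for_tree(alignment: CodonAlignment, index: TreeIndex) -> np.ndarray:
    """Alignment rows reordered to match the engine's leaf ordering."""
    taxa = index.taxa
    missing = taxa - set(alignment.taxa)
    if missing:
        raise EngineError(f"tree taxa absent from alignment: {sorted(missing)}")
    order = [lab for lab, _ in sorted(index.leaf_ids.items(), key=lambda kv: kv[1])]
    states = alignment.states()
    rows = [alignment.taxa.index(lab) for lab in order]
    return states[rows]


def log_likelihood(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mix: SiteClassMix,
    kappa: float,
    pi: np.ndarray,
    branch_lengths: np.ndarray | None = None,
) -> float:
    """Mixture log-likelihood of the alignment on the (marked) tree.

    Foreground omegas apply on branches with a positive mark; missing
    codons contribute all-ones partial vectors; the root is weighted by pi.
    """
    index = TreeIndex.from_phylogeny(tree)
    if branch_lengths is None:
        branch_lengths = index.lengths[index.edges]
    states = _states_for_tree(alignment, index)
    if states.shape[1] == 0:
        raise EngineError("zero-length alignment")
    patterns, _, counts = _pattern_compress(states)
    per_class = _per_class_site_logliks(patterns, index, mix, kappa, pi, branch_lengths)
    log_props = np.log(np.clip(mix.proportions, 1e-300, None))
    site_ll = logsumexp(per_class + log_props[:, None], axis=0)
    lnL = float(site_ll @ counts)
    if not np.isfinite(lnL):
        raise EngineError("non-finite log-likelihood")
    return lnL


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class OptimizerConfig:
    """Controls for the bounded quasi-Newton fit."""

    n_starts: int = 3
    seed: int = 0
    ftol: float = 1e-8
    maxiter: int = 400
    fix_branch_lengths: bool = False  # reuse input tree lengths instead of refitting
    init_branch_length: float = 0.1
    jitter: float = 0.5  # lognormal sd applied to restart initial points


_LOG_W_LO, _LOG_W_HI = np.log(1e-4), np.log(999.0)
_LOG_W0_HI = np.log(0.9999)  # purifying class stays below 1
_LOG_W2_LO, _LOG_W2_HI = 0.0, np.log(999.0)  # selected class at or above 1
_LOG_K_LO, _LOG_K_HI = np.log(1e-2), np.log(100.0)
_LOG_T_LO, _LOG_T_HI = np.log(1e-6), np.log(50.0)
_LOGIT_LO, _LOGIT_HI = -12.0, 12.0

_MODEL_FREE = {
    "M0": [("logw", _LOG_W_LO, _LOG_W_HI)],
    "two_ratios": [
        ("logw_bg", _LOG_W_LO, _LOG_W_HI),
        ("logw_fg", _LOG_W_LO, _LOG_W_HI),
    ],
    "M1a": [("q0", _LOGIT_LO, _LOGIT_HI), ("logw0", _LOG_W_LO, _LOG_W0_HI)],
    "M2a": [
        ("q0", _LOGIT_LO, _LOGIT_HI),
        ("q1", _LOGIT_LO, _LOGIT_HI),
        ("logw0", _LOG_W_LO, _LOG_W0_HI),
        ("logw2", _LOG_W2_LO, _LOG_W2_HI),
    ],
    "MA_null": [
        ("q0", _LOGIT_LO, _LOGIT_HI),
        ("q1", _LOGIT_LO, _LOGIT_HI),
        ("logw0", _LOG_W_LO, _LOG_W0_HI),
    ],
    "MA": [
        ("q0", _LOGIT_LO, _LOGIT_HI),
        ("q1", _LOGIT_LO, _LOGIT_HI),
        ("logw0", _LOG_W_LO, _LOG_W0_HI),
        ("logw2", _LOG_W2_LO, _LOG_W2_HI),
    ],
}


def _mix_from_free(model_id: str, values: dict[str, float]) -> SiteClassMix:
    if model_id == "M0":
        return SiteClassMix.m0(np.exp(values["logw"]))
    if model_id == "two_ratios":
        return SiteClassMix.two_ratios(
            np.exp(values["logw_bg"]), np.exp(values["logw_fg"])
        )
    if model_id == "M1a":
        return SiteClassMix.m1a(expit(values["q0"]), np.exp(values["logw0"]))
    if model_id == "M2a":
        q0, q1 = expit(values["q0"]), expit(values["q1"])
        p0 = q0
        p1 = (1.0 - q0) * q1
        return SiteClassMix.m2a(p0, p1, np.exp(values["logw0"]), np.exp(values["logw2"]))
    if model_id in ("MA", "MA_null"):
        q0, q1 = expit(values["q0"]), expit(values["q1"])
        p0 = np.clip(q0, 1e-9, 1 - 1e-9)
        p1 = np.clip((1.0 - q0) * q1, 1e-9, 1 - 1e-9)
        w2 = np.exp(values["logw2"]) if model_id == "MA" else 1.0
        return SiteClassMix.model_a(
            p0, p1, np.exp(values["logw0"]), w2, null=(model_id == "MA_null")
        )
    raise ValueError(f"unknown model {model_id!r}")


def _default_free_start(model_id: str) -> dict[str, float]:
    w_start = np.log(0.4)
    starts = {
        "logw": w_start,
        "logw_bg": w_start,
        "logw_fg": np.log(0.8),
        "logw0": np.log(0.2),
        "logw2": np.log(2.5),
        "q0": 1.0,  # p0 ~ 0.73
        "q1": 1.0,
    }
    return {name: starts[name] for name, _, _ in _MODEL_FREE[model_id]}


def fit(
    alignment: CodonAlignment,
    tree: Phylogeny,
    model_id: str,
    config: OptimizerConfig | None = None,
    pi: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model.

    Branch lengths (unless fixed by config), kappa, and the model's free
    omega/proportion parameters are jointly optimized with L-BFGS-B on
    transformed coordinates, from ``config.n_starts`` seeded starting
    points.  Boundary convergence (omega2 at 1, vanishing selected-class
    mass) is flagged in the result rather than treated as an error.
    """
    if model_id not in _MODEL_FREE:
        raise ValueError(f"unknown model {model_id!r}")
    config = config or OptimizerConfig()
    if pi is None:
        pi = f3x4_frequencies(alignment.codons)

    index = TreeIndex.from_phylogeny(tree)
    if model_id in BRANCH_MODELS and not (index.marks > 0).any():
        raise EngineError(f"{model_id} requires a marked foreground branch")
    states = _states_for_tree(alignment, index)
    patterns, _, counts = _pattern_compress(states)

    free_spec = _MODEL_FREE[model_id]
    n_free = len(free_spec)
    fit_bl = not config.fix_branch_lengths
    n_bl = index.n_edges if fit_bl else 0
    input_bl = np.clip(index.lengths[index.edges], 1e-6, 50.0)
    if not (index.lengths[index.edges] > 0).any():
        input_bl = np.full(index.n_edges, config.init_branch_length)

    log_props_guard = 1e-300

    def unpack(x: np.ndarray):
        values = {name: x[i] for i, (name, _, _) in enumerate(free_spec)}
        kappa = float(np.exp(x[n_free]))
        bl = np.exp(x[n_free + 1 :]) if fit_bl else input_bl
        return _mix_from_free(model_id, values), kappa, bl

    def negloglik(x: np.ndarray) -> float:
        try:
            mix, kappa, bl = unpack(x)
            per_class = _per_class_site_logliks(
                patterns, index, mix, kappa, pi, bl
            )
            lp = np.log(np.clip(mix.proportions, log_props_guard, None))
            lnL = float(logsumexp(per_class + lp[:, None], axis=0) @ counts)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e12
        return -lnL if np.isfinite(lnL) else 1e12

    bounds = [(lo, hi) for _, lo, hi in free_spec]
    bounds.append((_LOG_K_LO, _LOG_K_HI))
    if fit_bl:
        bounds.extend([(_LOG_T_LO, _LOG_T_HI)] * n_bl)

    start_free = _default_free_start(model_id)
    x0 = np.array(
        [start_free[name] for name, _, _ in free_spec]
        + [np.log(2.0)]
        + (list(np.log(input_bl)) if fit_bl else [])
    )

    rng = np.random.default_rng(config.seed)
    best = None
    for s in range(max(1, config.n_starts)):
        xs = x0.copy()
        if s > 0:
            xs = xs + rng.normal(0.0, config.jitter, size=xs.shape)
            xs = np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(xs, bounds)])
        res = minimize(
            negloglik,
            xs,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res

    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise EngineError(f"optimizer failed for {model_id} on {alignment.gene_id}")

    mix, kappa, bl = unpack(best.x)
    params = CodonModelParams(
        model_id=model_id,
        kappa=kappa,
        pi=pi,
        mix=mix,
        branch_lengths=np.asarray(bl, dtype=float),
    )
    omega_fg = omega_bg = None
    if model_id == "M0":
        omega_fg = omega_bg = mix.classes[0].omega_background
    elif model_id == "two_ratios":
        omega_bg = mix.classes[0].omega_background
        omega_fg = mix.classes[0].omega_foreground
    elif model_id in ("MA", "MA_null"):
        omega_bg = mix.classes[0].omega_background
        omega_fg = mix.classes[2].omega_foreground  # selected-class omega2
    elif model_id == "M2a":
        omega_fg = omega_bg = mix.classes[2].omega_foreground

    boundary = {}
    if model_id in ("MA", "M2a"):
        w2 = (
            mix.classes[2].omega_foreground
            if model_id == "MA"
            else mix.classes[2].omega_background
        )
        p_sel = sum(mix.classes[k].proportion for k in range(2, len(mix.classes)))
        if w2 <= 1.0 + 1e-3:
            boundary["omega2_at_one"] = True
        if p_sel <= 1e-4:
            boundary["selected_mass_zero"] = True

    result = FitResult(
        model_id=model_id,
        lnL=float(-best.fun),
        params=params,
        omega_foreground=omega_fg,
        omega_background=omega_bg,
        converged=bool(best.success or best.status == 1),
        at_boundary=boundary,
        n_starts=max(1, config.n_starts),
    )
    return result


def site_posteriors(
    fit_result: FitResult, alignment: CodonAlignment, tree: Phylogeny
) -> np.ndarray:
    """Naive empirical Bayes class posteriors, (n_sites, n_classes).

    P(class k | site) is proportional to the fitted class weight times the
    conditional site likelihood at the MLEs.  Only defined for models with
    more than one site class.
    """
    if fit_result.model_id not in SITE_CLASS_MODELS:
        raise EngineError(
            f"site posteriors undefined for model {fit_result.model_id}"
        )
    index = TreeIndex.from_phylogeny(tree)
    states = _states_for_tree(alignment, index)
    patterns, inverse, _ = _pattern_compress(states)
    params = fit_result.params
    per_class = _per_class_site_logliks(
        patterns, index, params.mix, params.kappa, params.pi, params.branch_lengths
    )
    log_joint = per_class + np.log(np.clip(params.mix.proportions, 1e-300, None))[:, None]
    post = np.exp(log_joint - logsumexp(log_joint, axis=0, keepdims=True))
    return post[:, inverse].T


def positive_site_probabilities(
    fit_result: FitResult, posteriors: np.ndarray
) -> np.ndarray:
    """Per-site posterior mass on classes under positive selection."""
    sel = fit_result.mix.positive_classes
    if not sel:
        return np.zeros(posteriors.shape[0])
    return posteriors[:, sel].sum(axis=1)


def default_pi(alignment: CodonAlignment, source: str = "F3x4") -> np.ndarray:
    if source == "F3x4":
        return f3x4_frequencies(alignment.codons)
    if source == "uniform":
        return uniform_frequencies()
    raise ValueError(f"unknown frequency source {source!r}")
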