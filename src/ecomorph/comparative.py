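"""Phylogenetic comparative analyses.

* PCA of the standardized character table with broken-stick axis retention.
* Phylomorphospace: ancestral node scores under Brownian motion (BM),
  equivalent to branch-length-weighted squared-change parsimony.
* Phylogenetic MANOVA: the observed Wilks lambda is referred to a null
  distribution built by simulating multivariate BM on the phylogeny with the
  rate matrix estimated from the data via independent contrasts, holding
  group labels fixed.
* Mk ancestral state reconstruction: single-rate symmetric Markov model
  ("Mk1"), rate fitted by maximum likelihood with the pruning algorithm,
  marginal reconstructions at every node, uniform root prior.
* Linear discriminant re-classification of diet category from morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import pic_rate_matrix, vcv_matrix

__all__ = [
    "ComparativeError",
    "PCAResult",
    "PhyloManovaResult",
    "ASRResult",
    "DFAResult",
    "pca",
    "broken_stick_retention",
    "bm_ancestral_states",
    "phylomorphospace",
    "wilks_lambda",
    "phylo_manova",
    "mk1_asr",
    "asr_transition_summary",
    "lda_classify",
]


class ComparativeError(ValueError):
    """Raised for singular, degenerate, or mislabelled inputs."""


# --------------------------------------------------------------------------
# PCA and broken stick
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: pd.DataFrame      # characters x axes, orthonormal columns
    scores: pd.DataFrame        # species x axes, zero column means
    variance_fraction: np.ndarray
    retained: list[int]         # 0-based indices of retained axes


def pca(z_table: pd.DataFrame) -> PCAResult:
    """Eigen-decomposition of the sample covariance of the standardized table.

    Axes are ordered by decreasing variance.  The sign of each axis is fixed
    so that its largest-magnitude loading is positive, which makes outputs
    byte-stable across BLAS implementations.
    """
    x = z_table.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ComparativeError("PCA needs at least 2 species and 2 characters")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ComparativeError("rank-0 input: all rows identical")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention
    for j in range(vt.shape[0]):
        i = int(np.abs(vt[j]).argmax())
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2 / (n - 1)
    frac = var / var.sum()
    axes = [f"PC{j + 1}" for j in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=z_table.columns, columns=axes)
    scores = pd.DataFrame(xc @ vt.T, index=z_table.index, columns=axes)
    retained = broken_stick_retention(frac)
    return PCAResult(loadings=loadings, scores=scores,
                     variance_fraction=frac, retained=retained)


def broken_stick_retention(variance_fractions: np.ndarray) -> list[int]:
    """Axes whose variance fraction exceeds the broken-stick expectation.

    For p axes, the expected fraction of axis j (1-based) is
    b_j = (1/p) * sum_{i=j}^{p} 1/i.  Axes are retained in order while the
    observed fraction exceeds b_j, stopping at the first failure.
    """
    f = np.asarray(variance_fractions, dtype=float)
    p = len(f)
    b = np.array([sum(1.0 / i for i in range(j, p + 1)) / p
                  for j in range(1, p + 1)])
    retained: list[int] = []
    for j in range(p):
        if f[j] > b[j]:
            retained.append(j)
        else:
            break
    return retained


# --------------------------------------------------------------------------
# BM ancestral states / phylomorphospace
# --------------------------------------------------------------------------

def bm_ancestral_states(
    tree: dendropy.Tree, tip_values: dict[str, float]
) -> dict[dendropy.Node, float]:
    """Maximum-likelihood ancestral values under Brownian motion.

    Solves the weighted squared-change parsimony problem: internal values
    minimize sum over edges of (delta x)^2 / branch length, with tips fixed.
    For a Gaussian model the joint optimum equals the marginal means, so
    these are the node placements used in a phylomorphospace.
    """
    tips = [l for l in tree.leaf_node_iter()]
    missing = [l.taxon.label for l in tips if l.taxon.label not in tip_values]
    if missing:
        raise ComparativeError(f"missing tip values for {missing}")
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {n: i for i, n in enumerate(internals)}
    m = len(internals)
    a = np.zeros((m, m))
    rhs = np.zeros(m)
    for node in internals:
        i = index[node]
        neighbors = list(node.child_nodes())
        lengths = [c.edge.length for c in neighbors]
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
            lengths.append(node.edge.length)
        for nb, t in zip(neighbors, lengths):
            w = 1.0 / t
            a[i, i] += w
            if nb.is_leaf():
                rhs[i] += w * tip_values[nb.taxon.label]
            else:
                a[i, index[nb]] -= w
    sol = np.linalg.solve(a, rhs)
    out: dict[dendropy.Node, float] = {n: float(sol[index[n]]) for n in internals}
    for l in tips:
        out[l] = float(tip_values[l.taxon.label])
    return out


def phylomorphospace(
    tree: dendropy.Tree, scores: pd.DataFrame, axes: list[str] | None = None
) -> dict:
    """Tip and ancestral-node scores plus the parent/child edge list.

    Node scores are BM ancestral estimates computed independently per axis.
    """
    axes = list(axes or scores.columns)
    node_ids = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        node_ids[node] = (node.taxon.label if node.is_leaf() else f"node_{i}")
    coords: dict[str, dict[str, float]] = {nid: {} for nid in node_ids.values()}
    for ax in axes:
        vals = bm_ancestral_states(tree, scores[ax].to_dict())
        for node, v in vals.items():
            coords[node_ids[node]][ax] = v
    edges = [
        (node_ids[n.parent_node], node_ids[n])
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    return {"nodes": coords, "edges": edges, "axes": axes}


# --------------------------------------------------------------------------
# Phylogenetic MANOVA
# --------------------------------------------------------------------------

@dataclass
class PhyloManovaResult:
    wilks_observed: float
    wilks_simulated: np.ndarray
    p_value: float
    nsim: int
    seed: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def wilks_lambda(x: np.ndarray, groups: np.ndarray) -> float:
    """Wilks lambda = det(W) / det(W + B) from the standard MANOVA scatter
    decomposition; small values indicate strong group separation."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ComparativeError("need at least 2 groups")
    if n - len(levels) < p:
        raise ComparativeError(
            f"singular within-group scatter: {p} characters but only "
            f"{n - len(levels)} residual degrees of freedom"
        )
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for g in levels:
        sub = x[groups == g]
        mu = sub.mean(axis=0)
        d = sub - mu
        w += d.T @ d
        b += len(sub) * np.outer(mu - grand, mu - grand)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise ComparativeError("singular scatter matrix in Wilks lambda")
    return float(np.exp(logdet_w - logdet_t))


def phylo_manova(
    tree: dendropy.Tree,
    z_table: pd.DataFrame,
    groups: pd.Series,
    nsim: int = 1000,
    seed: int = 0,
    rate_matrix: str = "pic",
) -> PhyloManovaResult:
    """MANOVA with a Brownian-motion simulated Wilks null.

    The evolutionary rate matrix is estimated from the data (by default via
    phylogenetically independent contrasts, ``rate_matrix="raw"`` for the
    ordinary covariance); ``nsim`` multivariate BM datasets are simulated on
    the tree, group labels held fixed, and

        p = (1 + #{lambda_sim <= lambda_obs}) / (nsim + 1).
    """
    if nsim < 99:
        raise ComparativeError("nsim must be at least 99")
    order = list(z_table.index)
    gr = np.asarray(groups.loc[order])
    x = z_table.to_numpy(dtype=float)
    lam_obs = wilks_lambda(x, gr)

    if rate_matrix == "pic":
        values = {sp: x[i] for i, sp in enumerate(order)}
        r = pic_rate_matrix(tree, values)
    elif rate_matrix == "raw":
        r = np.cov(x, rowvar=False)
    else:
        raise ComparativeError(f"unknown rate_matrix {rate_matrix!r}")

    c, _ = vcv_matrix(tree, order=order)
    lc = np.linalg.cholesky(c + 1e-12 * np.eye(len(order)))
    lr = np.linalg.cholesky(r + 1e-12 * np.trace(r) / r.shape[0] * np.eye(r.shape[0]))

    rng = np.random.default_rng(seed)
    n, p = x.shape
    sims = np.empty(nsim)
    for i in range(nsim):
        zmat = rng.standard_normal((n, p))
        y = lc @ zmat @ lr.T
        sims[i] = wilks_lambda(y, gr)
    pval = (1 + int((sims <= lam_obs).sum())) / (nsim + 1)
    sizes = {str(g): int((gr == g).sum()) for g in np.unique(gr)}
    return PhyloManovaResult(
        wilks_observed=lam_obs, wilks_simulated=sims, p_value=pval,
        nsim=nsim, seed=seed, group_sizes=sizes,
    )


# --------------------------------------------------------------------------
# Mk1 ancestral state reconstruction
# --------------------------------------------------------------------------

@dataclass
class ASRResult:
    states: tuple[str, ...]
    node_marginals: dict          # node id -> probability vector (np.ndarray)
    node_labels: dict             # node id -> tip label or internal name
    log_likelihood: float
    rate: float
    tree: dendropy.Tree


def _mk_transition(k: int, q: float, t: float) -> np.ndarray:
    """Transition matrix of the k-state symmetric Mk model with all
    off-diagonal rates q: P_same = 1/k + (1-1/k) exp(-k q t)."""
    e = np.exp(-k * q * t)
    same = 1.0 / k + (1.0 - 1.0 / k) * e
    diff = 1.0 / k - e / k
    p = np.full((k, k), diff)
    np.fill_diagonal(p, same)
    return p


def _mk_loglik(tree: dendropy.Tree, tip_states: dict[str, str],
               states: tuple[str, ...], q: float) -> tuple[float, dict]:
    """Pruning-algorithm log-likelihood; also returns the per-node downward
    partial likelihoods (conditional on the subtree below each node)."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    partial: dict = {}
    scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(k)
            v[sidx[tip_states[node.taxon.label]]] = 1.0
            partial[node] = v
            continue
        v = np.ones(k)
        for c in node.child_nodes():
            pmat = _mk_transition(k, q, c.edge.length)
            v = v * (pmat @ partial[c])
        m = v.max()
        if m <= 0:
            return -np.inf, partial
        partial[node] = v / m
        scale += np.log(m)
    root = tree.seed_node
    lik = float(partial[root] @ np.full(k, 1.0 / k))
    return np.log(lik) + scale, partial


def mk1_asr(
    tree: dendropy.Tree,
    tip_states: dict[str, str],
    states: tuple[str, ...] | None = None,
    rate: float | None = None,
) -> ASRResult:
    """Mk1 (equal-rates) ancestral state reconstruction.

    The single symmetric rate q (all off-diagonal rates equal) is estimated
    by maximizing the pruning likelihood unless ``rate`` is supplied.
    Marginal reconstructions use the standard up-down algorithm, which for
    this reversible model equals re-rooting at every node; the root prior is
    uniform.
    """
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = sorted(labels - set(tip_states))
    if missing:
        raise ComparativeError(f"tips without states: {missing}")
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    unknown = sorted(set(tip_states.values()) - set(states))
    if unknown:
        raise ComparativeError(f"unknown state labels: {unknown}")
    if len(states) < 2:
        raise ComparativeError("need at least 2 states")
    k = len(states)

    if rate is None:
        # bracket on log10 q around 1 / total tree length
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        lo, hi = np.log10(1e-4 / total), np.log10(1e4 / total)
        res = minimize_scalar(
            lambda lq: -_mk_loglik(tree, tip_states, states, 10.0**lq)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        q = float(10.0 ** res.x)
    else:
        if rate <= 0:
            raise ComparativeError("rate must be positive")
        q = float(rate)

    loglik, down = _mk_loglik(tree, tip_states, states, q)

    # upward pass: up[node] = likelihood of everything outside node's subtree,
    # as seen from the top of node's edge
    up: dict = {tree.seed_node: np.full(k, 1.0 / k)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for c in node.child_nodes():
            sib = np.ones(k)
            for s in node.child_nodes():
                if s is c:
                    continue
                pmat = _mk_transition(k, q, s.edge.length)
                sib = sib * (pmat @ down[s])
            msg = up[node] * sib
            pmat = _mk_transition(k, q, c.edge.length)
            v = pmat.T @ msg
            m = v.max()
            up[c] = v / m if m > 0 else v

    marginals: dict = {}
    node_labels: dict = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        nid = f"node_{i}"
        node_labels[nid] = (node.taxon.label if node.is_leaf() else nid)
        post = up[node] * down[node]
        marginals[nid] = post / post.sum()
    return ASRResult(states=states, node_marginals=marginals,
                     node_labels=node_labels, log_likelihood=loglik,
                     rate=q, tree=tree)


def asr_transition_summary(asr: ASRResult) -> list[dict]:
    """Edges where the most-probable state differs between parent and child."""
    ids = {node: f"node_{i}"
           for i, node in enumerate(asr.tree.preorder_node_iter())}
    out = []
    for node in asr.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pm = asr.node_marginals[ids[node.parent_node]]
        cm = asr.node_marginals[ids[node]]
        ps, cs = asr.states[int(pm.argmax())], asr.states[int(cm.argmax())]
        if ps != cs:
            out.append({
                "parent": asr.node_labels[ids[node.parent_node]],
                "child": asr.node_labels[ids[node]],
                "from_state": ps,
                "to_state": cs,
                "parent_marginals": pm.tolist(),
                "child_marginals": cm.tolist(),
            })
    return out


# --------------------------------------------------------------------------
# Linear discriminant re-classification
# --------------------------------------------------------------------------

@dataclass
class DFAResult:
    classes: tuple[str, ...]
    posterior: pd.DataFrame       # species x classes, rows sum to 1
    predicted: pd.Series
    confusion: pd.DataFrame       # given class (rows) x predicted (columns)
    mismatches: list[str]
    accuracy: float


def lda_classify(
    z_table: pd.DataFrame,
    labels: pd.Series,
    priors: str | dict[str, float] = "proportional",
    cov_divisor: str = "n-g",
) -> DFAResult:
    """Linear discriminant analysis with a shared within-class covariance.

    Posterior class probabilities follow the Gaussian discriminant rule with
    the configured priors ("proportional" to class sizes, "uniform", or an
    explicit mapping).  ``cov_divisor`` selects the pooled-covariance
    denominator: the classic unbiased ``"n-g"`` or ``"n"`` (the convention of
    some library implementations).  A small ridge is added only if the pooled
    covariance is numerically singular.  Reports the resubstitution confusion
    matrix and the species whose predicted class differs from the given one.
    """
    x = z_table.to_numpy(dtype=float)
    y = np.asarray(labels.loc[z_table.index])
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ComparativeError("need at least 2 classes")
    n, p = x.shape
    g = len(classes)

    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = x[y == c] - means[i]
        pooled += d.T @ d
    pooled /= (n - g) if cov_divisor == "n-g" else n

    if priors == "proportional":
        pi = np.array([(y == c).mean() for c in classes])
    elif priors == "uniform":
        pi = np.full(g, 1.0 / g)
    else:
        pi = np.array([priors[c] for c in classes])
        pi = pi / pi.sum()

    try:
        chol = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(pooled) / p
        chol = np.linalg.cholesky(pooled + ridge * np.eye(p))
    # log discriminant: x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k
    minv_mu = np.linalg.solve(chol.T, np.linalg.solve(chol, means.T))  # p x g
    disc = x @ minv_mu - 0.5 * np.einsum("pk,pk->k", means.T, minv_mu) + np.log(pi)
    disc -= disc.max(axis=1, keepdims=True)
    post = np.exp(disc)
    post /= post.sum(axis=1, keepdims=True)

    pred = np.array([classes[i] for i in post.argmax(axis=1)])
    posterior = pd.DataFrame(post, index=z_table.index, columns=classes)
    predicted = pd.Series(pred, index=z_table.index, name="predicted")
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for yi, pi_ in zip(y, pred):
        confusion.loc[yi, pi_] += 1
    mism = sorted(z_table.index[pred != y])
    return DFAResult(
        classes=classes, posterior=posterior, predicted=predicted,
        confusion=confusion, mismatches=list(mism),
        accuracy=float((pred == y).mean()),
    )
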