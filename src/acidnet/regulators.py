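"""Module-network regulator detection.

A simplified module-network scheme in the spirit of two-way Bayesian
clustering tools: gene clusters are sampled by a collapsed Gibbs sampler
over a finite Bayesian mixture of Gaussians (conjugate normal-gamma priors
per cluster and sample), several independent runs are condensed into
*tight clusters* (connected components of the pair co-clustering graph),
each tight cluster's mean profile is recursively split into a binary
*sample tree*, and candidate regulators are scored by how well their own
expression separates the sample sets at each tree node (summed
``-log10 p`` of Welch t-tests, weighted by node sample fraction). Candidates
whose probabilistic (P.) score lands in the top percentile are flagged as
regulators, and the candidate score distribution is calibrated against an
equally sized random control gene set with a two-sample z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorConfig",
    "SampleTreeNode",
    "TightCluster",
    "gibbs_cluster_genes",
    "consensus_tight_clusters",
    "attach_sample_trees",
    "build_sample_tree",
    "score_regulator",
    "assign_regulators",
    "calibrate_with_controls",
    "select_candidates_by_annotation",
]


@dataclass(frozen=True)
class RegulatorConfig:
    """Settings for the regulator pipeline (defaults: ten Gibbs runs,
    50 tight clusters of >= 10 genes, 96 candidates and controls, top 1 %)."""

    n_runs: int = 10
    min_cluster_size: int = 10
    n_clusters_select: int = 50
    top_percent: float = 1.0
    n_candidates: int = 96
    n_controls: int = 96
    consensus_threshold: float = 0.5
    n_components: int = 20
    n_sweeps: int = 100
    burn_in: int = 50
    max_tree_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# Gibbs mixture clustering

# normal-gamma prior on per-cluster per-sample mean/precision; data are
# row-standardized so a unit-scale prior is appropriate
_MU0, _KAPPA0, _ALPHA0, _BETA0 = 0.0, 0.1, 1.0, 1.0
_DIRICHLET_ALPHA = 1.0


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes regularized by the prior, never 0/0
    return (x - mu) / sd


def _prepare_rows(values: pd.DataFrame) -> np.ndarray:
    """Module-network preprocessing: log1p then per-gene z-score.

    RPKM marginals are lognormal-like; the Gaussian mixture and the 2-means
    sample splits behave sensibly on the log scale.
    """
    return _standardize_rows(np.log1p(values.to_numpy(dtype=float)))


class _MixtureState:
    """Sufficient statistics and cached posterior-predictive terms for a
    finite Gaussian mixture with independent normal-gamma priors per
    (cluster, sample) cell. Only the two clusters touched by a move are
    recomputed, keeping each Gibbs step O(K * S)."""

    def __init__(self, x: np.ndarray, z: np.ndarray, k: int) -> None:
        self.x = x
        self.k = k
        n_samples = x.shape[1]
        self.counts = np.bincount(z, minlength=k).astype(float)
        self.sums = np.zeros((k, n_samples))
        self.sqs = np.zeros((k, n_samples))
        for g in range(len(z)):
            self.sums[z[g]] += x[g]
            self.sqs[z[g]] += x[g] ** 2
        self.mu = np.zeros((k, n_samples))
        self.scale2 = np.zeros((k, n_samples))
        self.nu = np.zeros(k)
        self.base = np.zeros(k)
        for c in range(k):
            self._refresh(c)

    def _refresh(self, c: int) -> None:
        n = self.counts[c]
        s = self.sums[c]
        q = self.sqs[c]
        kappa = _KAPPA0 + n
        alpha = _ALPHA0 + n / 2.0
        mean = s / n if n > 0 else np.zeros_like(s)
        ss = q - mean * s
        beta = _BETA0 + 0.5 * ss + (_KAPPA0 * n * mean**2) / (2.0 * kappa)
        nu = 2.0 * alpha
        self.mu[c] = s / kappa
        self.scale2[c] = beta * (kappa + 1.0) / (alpha * kappa)
        self.nu[c] = nu
        n_samples = len(s)
        const = gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0) - 0.5 * np.log(nu * np.pi)
        self.base[c] = n_samples * const - 0.5 * np.log(self.scale2[c]).sum()

    def remove(self, g: int, c: int) -> None:
        self.counts[c] -= 1
        self.sums[c] -= self.x[g]
        self.sqs[c] -= self.x[g] ** 2
        self._refresh(c)

    def add(self, g: int, c: int) -> None:
        self.counts[c] += 1
        self.sums[c] += self.x[g]
        self.sqs[c] += self.x[g] ** 2
        self._refresh(c)

    def log_predictive(self, g: int) -> np.ndarray:
        z2 = (self.x[g][None, :] - self.mu) ** 2 / self.scale2
        tail = np.log1p(z2 / self.nu[:, None]).sum(axis=1)
        return self.base - 0.5 * (self.nu + 1.0) * tail


def _log_marginal_matrix(x: np.ndarray) -> float:
    """Collapsed log marginal likelihood of a gene set (rows) under one
    cluster, independent normal-gamma cells per sample (column)."""
    n, s = x.shape
    if n == 0:
        return 0.0
    kappa_n = _KAPPA0 + n
    alpha_n = _ALPHA0 + n / 2.0
    mean = x.mean(axis=0)
    ss = ((x - mean) ** 2).sum(axis=0)
    beta_n = _BETA0 + 0.5 * ss + (_KAPPA0 * n * mean**2) / (2.0 * kappa_n)
    const = (
        gammaln(alpha_n)
        - gammaln(_ALPHA0)
        + _ALPHA0 * np.log(_BETA0)
        + 0.5 * (np.log(_KAPPA0) - np.log(kappa_n))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return float(s * const - (alpha_n * np.log(beta_n)).sum())


def gibbs_cluster_genes(
    values: pd.DataFrame,
    seed: int,
    n_components: int = 20,
    n_sweeps: int = 100,
    burn_in: int = 50,
) -> pd.Series:
    """One Gibbs-sampler run: a gene partition from a finite Bayesian
    Gaussian mixture (collapsed sampler, symmetric Dirichlet weight prior).

    Assignments are initialized with k-means++ on the standardized rows and
    refined by ``burn_in + n_sweeps`` full Gibbs sweeps; every few sweeps a
    greedy split proposal (2-means within a cluster, accepted when the
    collapsed marginal likelihood plus partition prior improves) is applied,
    because single-gene moves cannot nucleate a new cluster. The final
    sweep's assignment is returned. Deterministic given ``seed``.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 genes")
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = _prepare_rows(values)
    n_genes = x.shape[0]
    k = min(n_components, n_genes)
    rng = np.random.default_rng(seed)
    from scipy.cluster.vq import kmeans2

    with np.errstate(all="ignore"):
        _, z = kmeans2(x, k, minit="++", seed=rng, missing="warn")
    z = z.astype(int)
    state = _MixtureState(x, z, k)
    weight_prior = _DIRICHLET_ALPHA / k

    def try_splits() -> None:
        for c in range(k):
            idx = np.nonzero(z == c)[0]
            if len(idx) < 4:
                continue
            empties = np.nonzero(state.counts == 0)[0]
            if not len(empties):
                continue
            e = int(empties[0])
            with np.errstate(all="ignore"):
                _, sub = kmeans2(x[idx], 2, minit="++", seed=rng, missing="warn")
            i1, i2 = idx[sub == 0], idx[sub == 1]
            if not len(i1) or not len(i2):
                continue
            gain = (
                _log_marginal_matrix(x[i1])
                + _log_marginal_matrix(x[i2])
                - _log_marginal_matrix(x[idx])
                + gammaln(len(i1) + weight_prior)
                + gammaln(len(i2) + weight_prior)
                - gammaln(len(idx) + weight_prior)
                - gammaln(weight_prior)
            )
            if gain > 0:
                for g in i2:
                    state.remove(g, c)
                    z[g] = e
                    state.add(g, e)

    for sweep in range(burn_in + n_sweeps):
        for g in range(n_genes):
            state.remove(g, z[g])
            logp = state.log_predictive(g) + np.log(state.counts + weight_prior)
            logp -= logp.max()
            cdf = np.cumsum(np.exp(logp))
            c_new = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
            z[g] = min(c_new, k - 1)
            state.add(g, z[g])
        if sweep % 5 == 4:
            try_splits()
    return pd.Series(z, index=values.index, name="cluster")


# ---------------------------------------------------------------------------
# Consensus tight clusters


@dataclass
class SampleTreeNode:
    """A node of a recursive binary sample partition."""

    samples: list[str]
    score: float = 0.0
    left: "SampleTreeNode | None" = None
    right: "SampleTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def internal_nodes(self) -> list["SampleTreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def to_indented(self, depth: int = 0) -> str:
        pad = "  " * depth
        if self.is_leaf:
            return f"{pad}- leaf: {','.join(self.samples)}\n"
        out = f"{pad}- split (score {self.score:.3f})\n"
        out += self.left.to_indented(depth + 1)
        out += self.right.to_indented(depth + 1)
        return out

    def to_newick(self) -> str:
        def rec(node: "SampleTreeNode") -> str:
            if node.is_leaf:
                if len(node.samples) == 1:
                    return node.samples[0]
                return "(" + ",".join(node.samples) + ")"
            return f"({rec(node.left)},{rec(node.right)}){node.score:.3f}"

        return rec(self) + ";"


@dataclass
class TightCluster:
    """A consensus gene cluster stable across Gibbs runs."""

    cluster_id: int
    genes: list[str]
    tree: SampleTreeNode | None = None


def consensus_tight_clusters(
    partitions: list[pd.Series], cfg: RegulatorConfig = RegulatorConfig()
) -> list[TightCluster]:
    """Tight clusters from the pair co-clustering frequency graph.

    Gene pairs co-clustered in at least ``consensus_threshold`` of the runs
    form edges; connected components with >= ``min_cluster_size`` genes are
    kept, sorted by decreasing size (ties by first gene ID), and the top
    ``n_clusters_select`` are numbered from 0.
    """
    if not partitions:
        raise ValueError("need >= 1 partition")
    genes = partitions[0].index
    labels = np.stack([p.loc[genes].to_numpy() for p in partitions])
    freq = np.zeros((len(genes), len(genes)))
    for row in labels:
        freq += row[:, None] == row[None, :]
    freq /= len(partitions)
    adj = csr_matrix(freq >= cfg.consensus_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = list(genes[comp == c])
        if len(members) >= cfg.min_cluster_size:
            clusters.append(members)
    if not clusters:
        logger.warning("no consensus component reached min_cluster_size")
    clusters.sort(key=lambda ms: (-len(ms), ms[0]))
    clusters = clusters[: cfg.n_clusters_select]
    return [TightCluster(i, ms) for i, ms in enumerate(clusters)]


# ---------------------------------------------------------------------------
# Sample trees and regulator scores


def _log_marginal_gaussian(x: np.ndarray) -> float:
    """Log marginal likelihood of 1-D data under the normal-gamma prior."""
    n = len(x)
    if n == 0:
        return 0.0
    kappa_n = _KAPPA0 + n
    alpha_n = _ALPHA0 + n / 2.0
    mean = x.mean()
    ss = ((x - mean) ** 2).sum()
    beta_n = _BETA0 + 0.5 * ss + (_KAPPA0 * n * mean**2) / (2.0 * kappa_n)
    return float(
        gammaln(alpha_n)
        - gammaln(_ALPHA0)
        + _ALPHA0 * np.log(_BETA0)
        - alpha_n * np.log(beta_n)
        + 0.5 * (np.log(_KAPPA0) - np.log(kappa_n))
        - 0.5 * n * np.log(2.0 * np.pi)
    )


def _best_two_means_split(values: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Optimal 1-D 2-means split (sorted sweep); None if degenerate.

    Returns a boolean mask for the 'high' side and the Bayesian two-mean
    score: log marginal likelihood gain of two groups over one.
    """
    n = len(values)
    if n < 2 or np.ptp(values) == 0:
        return None
    order = np.argsort(values, kind="stable")
    v = values[order]
    best_sse, best_i = np.inf, None
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    total_sum, total_sq = csum[-1], csq[-1]
    for i in range(1, n):
        sse = (csq[i - 1] - csum[i - 1] ** 2 / i) + (
            (total_sq - csq[i - 1]) - (total_sum - csum[i - 1]) ** 2 / (n - i)
        )
        if sse < best_sse - 1e-12:
            best_sse, best_i = sse, i
    mask = np.zeros(n, dtype=bool)
    mask[order[best_i:]] = True
    score = (
        _log_marginal_gaussian(values[mask])
        + _log_marginal_gaussian(values[~mask])
        - _log_marginal_gaussian(values)
    )
    return mask, score


def build_sample_tree(
    profile: pd.Series, max_depth: int = 3, min_samples: int = 4
) -> SampleTreeNode:
    """Recursive binary sample partition of a cluster's mean profile.

    Each node splits its samples by optimal 1-D 2-means on the profile;
    recursion stops at ``max_depth``, below ``min_samples`` samples, or on a
    constant profile.
    """
    def rec(samples: list[str], depth: int) -> SampleTreeNode:
        node = SampleTreeNode(samples=list(samples))
        if depth >= max_depth or len(samples) < min_samples:
            return node
        vals = profile.loc[samples].to_numpy(dtype=float)
        split = _best_two_means_split(vals)
        if split is None:
            return node
        mask, score = split
        node.score = score
        arr = np.asarray(samples)
        node.left = rec(list(arr[~mask]), depth + 1)
        node.right = rec(list(arr[mask]), depth + 1)
        return node

    return rec(list(profile.index), 0)


def score_regulator(candidate: pd.Series, tree: SampleTreeNode) -> float:
    """Probabilistic (P.) score of a candidate against one sample tree.

    For every internal node, the candidate's expression in the node's two
    sample sets is compared by a two-sided Welch t-test; the node
    contributes ``-log10 p`` weighted by the node's sample fraction.
    Zero-variance candidates contribute 0 at a node.
    """
    internal = tree.internal_nodes()
    if not internal:
        return 0.0
    n_root = len(tree.samples)
    score = 0.0
    for node in internal:
        left = candidate.loc[node.left.samples].to_numpy(dtype=float)
        right = candidate.loc[node.right.samples].to_numpy(dtype=float)
        if np.ptp(np.concatenate([left, right])) == 0:
            continue
        if left.std() == 0 and right.std() == 0:
            # two distinct constants: perfect separation, cap the evidence
            p = np.finfo(float).tiny
        else:
            p = stats.ttest_ind(left, right, equal_var=False).pvalue
            if not np.isfinite(p):
                continue
        p = max(float(p), np.finfo(float).tiny)
        score += (len(node.samples) / n_root) * (-np.log10(p))
    return float(score)


def attach_sample_trees(
    clusters: list[TightCluster],
    values: pd.DataFrame,
    max_depth: int = 3,
) -> None:
    """Build each tight cluster's sample tree from its mean expression profile
    (log1p + per-gene z-score, then averaged over the cluster's genes)."""
    z = _prepare_rows(values)
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    for cl in clusters:
        profile = zdf.loc[cl.genes].mean(axis=0)
        cl.tree = build_sample_tree(profile, max_depth=max_depth)


def assign_regulators(
    candidates: list[str] | pd.Index,
    clusters: list[TightCluster],
    values: pd.DataFrame,
    cfg: RegulatorConfig = RegulatorConfig(),
) -> pd.DataFrame:
    """Score every (candidate, tight cluster) pair and flag regulators.

    Candidate rows go through the same log1p + z-score preprocessing as the
    clustering and the sample trees before scoring (the per-node t-tests are
    affine-invariant, so the z-score itself does not matter; the log does).
    The cutoff is the ``100 - top_percent`` percentile of the pooled
    candidate scores; pairs at or above it are flagged. A candidate may
    regulate several clusters. With an all-equal score pool no pair is
    flagged (degenerate percentile) and a warning is logged.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [c for c in candidates if c not in values.index]
    if missing:
        raise KeyError(f"candidates absent from expression matrix: {missing[:5]}")
    for cl in clusters:
        if cl.tree is None:
            raise ValueError("clusters need sample trees; call attach_sample_trees")
    prepared = pd.DataFrame(
        _prepare_rows(values), index=values.index, columns=values.columns
    )
    rows = []
    for cand in candidates:
        expr = prepared.loc[cand]
        for cl in clusters:
            rows.append(
                {
                    "candidate": cand,
                    "cluster_id": cl.cluster_id,
                    "p_score": score_regulator(expr, cl.tree),
                }
            )
    df = pd.DataFrame(rows)
    scores = df["p_score"].to_numpy()
    if np.ptp(scores) == 0:
        logger.warning("all candidate scores equal; no regulators flagged")
        df["is_regulator"] = False
        return df
    cutoff = float(np.percentile(scores, 100.0 - cfg.top_percent))
    df["is_regulator"] = df["p_score"] >= cutoff
    return df


def calibrate_with_controls(
    assignments: pd.DataFrame,
    values: pd.DataFrame,
    clusters: list[TightCluster],
    cfg: RegulatorConfig = RegulatorConfig(),
    rng: np.random.Generator | None = None,
) -> dict:
    """Two-sample z-test of candidate vs random-control P. scores.

    Controls are ``n_controls`` genes sampled (seeded) from the non-candidate
    genes of ``values`` and scored against the same trees. Returns a dict
    with z, p, the control assignment frame, and summary statistics.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    candidates = list(dict.fromkeys(assignments["candidate"]))
    pool = [g for g in values.index if g not in set(candidates)]
    if len(pool) < cfg.n_controls:
        raise ValueError(
            f"only {len(pool)} non-candidate genes for {cfg.n_controls} controls"
        )
    controls = list(rng.choice(pool, size=cfg.n_controls, replace=False))
    ctrl = assign_regulators(controls, clusters, values, cfg)
    x = assignments["p_score"].to_numpy(dtype=float)
    y = ctrl["p_score"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 scores per set")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        logger.warning("both score sets constant; z undefined")
        return {"z": float("nan"), "p": float("nan"), "controls": ctrl,
                "computable": False}
    z = (x.mean() - y.mean()) / np.sqrt(vx / len(x) + vy / len(y))
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "z": float(z),
        "p": float(p),
        "controls": ctrl,
        "computable": True,
        "candidate_mean": float(x.mean()),
        "control_mean": float(y.mean()),
    }


def select_candidates_by_annotation(
    ann_table: pd.DataFrame,
    universe: list[str] | pd.Index,
    terms: list[str],
    namespace: str | None = None,
    cap: int = 96,
) -> list[str]:
    """Candidate regulators: universe genes annotated with any of ``terms``
    (e.g. transcription factor / signal transduction terms), capped at
    ``cap`` in stable annotation order."""
    t = ann_table
    if namespace is not None:
        t = t[t["namespace"] == namespace]
    sel = t[t["term"].isin(terms)]["gene"]
    universe = set(universe)
    out = [g for g in dict.fromkeys(sel) if g in universe]
    return out[:cap]
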