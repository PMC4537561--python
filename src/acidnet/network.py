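"""Weighted co-expression network construction and module detection.

The core follows the standard weighted-network recipe: Pearson correlation of
(square-root transformed) expression profiles, unsigned soft-thresholded
adjacency ``a_ij = |cor_ij|**beta`` (default beta 6), topological overlap
matrix (TOM), average-linkage hierarchical clustering of ``1 - TOM``, a
deterministic tree cut keeping branches of at least ``min_module_size``
genes (default 30), eigengene-based merging of close modules (dissimilarity
``1 - cor(ME_p, ME_q)`` below ``merge_cut_height``, default 0.25), and the
per-gene statistics used downstream: gene significance (GS, correlation with
a trait), module membership (MM / kME, correlation with the own module
eigengene) and total connectivity (kTotal, adjacency row sum).

Modules are named by the conventional colour sequence in decreasing size
order; ``grey`` is reserved for unassigned genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "NetworkModel",
    "MODULE_COLORS",
    "GREY",
    "correlation_matrix",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "merge_close_modules",
    "build_network",
    "gene_statistics",
    "module_trait_correlation",
    "correlation_pvalue",
]

GREY = "grey"

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass(frozen=True)
class NetworkParams:
    """Network construction settings (defaults: unsigned TOM, beta 6,
    minimum module size 30, merge cut height 0.25, Pearson correlation)."""

    power_beta: float = 6.0
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    cut_search_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.power_beta < 1:
            raise ValueError("power_beta must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.cut_search_floor < 1:
            raise ValueError("cut_search_floor must be in [0, 1)")


@dataclass
class NetworkModel:
    """A fitted co-expression network over one gene universe."""

    genes: pd.Index
    samples: pd.Index
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    linkage: np.ndarray
    module_labels: pd.Series  # gene -> colour, "grey" = unassigned
    eigengenes: pd.DataFrame  # samples x modules (unit-variance MEs)
    variance_explained: dict[str, float]
    params: NetworkParams
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        """Non-grey module colours, largest first."""
        sizes = self.module_labels[self.module_labels != GREY].value_counts()
        return list(sizes.index)

    def module_genes(self, color: str) -> pd.Index:
        return self.genes[(self.module_labels == color).to_numpy()]


def correlation_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Gene x gene Pearson correlation; zero-variance genes are removed.

    Returns the correlation frame and the list of dropped (constant) gene IDs.
    """
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[(sd == 0).to_numpy()])
    if dropped:
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
        values = values.drop(index=dropped)
    if len(values) == 0:
        raise ValueError("no genes left after dropping zero-variance genes")
    cor = np.atleast_2d(np.corrcoef(values.to_numpy()))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=values.index, columns=values.index), dropped


def soft_adjacency(cor: np.ndarray | pd.DataFrame, beta: float = 6.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency ``|cor|**beta`` with unit diagonal."""
    a = np.abs(np.asarray(cor, dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i = sum_u a_iu``
    over ``u != i``; the diagonal is 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # with zero diagonal the u = i, j terms vanish
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def _candidate_cuts(heights: np.ndarray, floor_fraction: float) -> list[float]:
    """Candidate cut heights: midpoints of substantial gaps between
    consecutive merge heights in the upper part of the dendrogram.

    Branch-forming merges sit low while merges that attach unclustered genes
    or join distinct branches sit near the top, so real branch boundaries
    show up as wide gaps. Gaps narrower than a quarter of the widest gap
    above ``floor_fraction * max(height)`` are ignored.
    """
    hmax = float(heights.max())
    floor = floor_fraction * hmax
    upper = np.sort(np.concatenate(([floor], heights[heights >= floor])))
    gaps = np.diff(upper)
    if not len(gaps) or gaps.max() <= 0:
        return [hmax]
    keep = gaps >= 0.25 * gaps.max()
    return [float((upper[i] + upper[i + 1]) / 2.0) for i in np.nonzero(keep)[0]]


def _gap_cut_labels(
    z: np.ndarray, params: "NetworkParams"
) -> tuple[float, np.ndarray]:
    """Pick the candidate cut yielding the most clusters of at least
    ``min_module_size`` genes; ties go to the cut at the widest gap."""
    heights = z[:, 2]
    best = None  # (n_big, gap_width, cut, raw)
    upper = np.sort(heights)
    for cut in _candidate_cuts(heights, params.cut_search_floor):
        raw = fcluster(z, t=cut, criterion="distance")
        sizes = np.bincount(raw)
        n_big = int((sizes >= params.min_module_size).sum())
        below = upper[upper < cut]
        above = upper[upper >= cut]
        width = float(above[0] - below[-1]) if len(below) and len(above) else 0.0
        key = (n_big, width, -cut)
        if best is None or key > best[0]:
            best = (key, cut, raw)
    _, cut, raw = best
    return cut, raw


def detect_modules(
    dissim: np.ndarray, params: NetworkParams = NetworkParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of a dissimilarity matrix plus tree cut.

    The dendrogram is cut at a data-driven gap height (see
    :func:`_gap_cut_labels`); connected branches of at least
    ``min_module_size`` genes become modules (integer labels 1, 2, ... by
    decreasing size), everything else is labelled 0 (grey).
    Returns ``(linkage, labels)``.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if n < 2:
        return np.empty((0, 4)), np.zeros(n, dtype=int)
    z = average(squareform(d, checks=False))
    if n < params.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all grey", n)
        return z, np.zeros(n, dtype=int)
    _, raw = _gap_cut_labels(z, params)
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= params.min_module_size]
    # stable ordering: decreasing size, ties by smallest member index
    order = sorted(
        keep.index, key=lambda c: (-keep[c], int(np.argmax(raw == c)))
    )
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return z, labels


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def module_eigengene(
    values: pd.DataFrame, genes: pd.Index | list[str]
) -> tuple[pd.Series, float]:
    """First principal component of one module's standardized expression.

    Genes are standardized over samples; the eigengene is the leading right
    singular vector, rescaled to unit variance and sign-aligned so that it
    correlates non-negatively with the module's mean expression profile.
    Returns ``(ME, proportion of variance explained)``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("module is empty")
    x = _standardize(values.loc[genes].to_numpy(dtype=float))
    if len(genes) == 1:
        me = x[0]
        var_exp = 1.0
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        me = vt[0]
        total = float((s**2).sum())
        var_exp = float(s[0] ** 2 / total) if total > 0 else 0.0
    me = me - me.mean()
    sd = me.std(ddof=1)
    if sd > 0:
        me = me / sd
    mean_profile = x.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    return pd.Series(me, index=values.columns), var_exp


def _eigengene_frame(
    values: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    mes, var_exp = {}, {}
    for color in labels.unique():
        genes = labels.index[(labels == color).to_numpy()]
        me, ve = module_eigengene(values, genes)
        mes[color] = me
        var_exp[color] = ve
    return pd.DataFrame(mes), var_exp


def merge_close_modules(
    values: pd.DataFrame,
    labels: np.ndarray,
    cut_height: float = 0.25,
) -> np.ndarray:
    """Iteratively merge module pairs whose eigengene dissimilarity
    ``1 - cor(ME_p, ME_q)`` is below ``cut_height`` (closest pair first,
    eigengenes recomputed after each merge). Label 0 (grey) never merges.
    """
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        mes = {
            m: module_eigengene(values, values.index[labels == m])[0] for m in mods
        }
        best, best_d = None, np.inf
        for i, p in enumerate(mods):
            for q in mods[i + 1 :]:
                d = 1.0 - float(np.corrcoef(mes[p], mes[q])[0, 1])
                if d < best_d:
                    best, best_d = (p, q), d
        if best is None or best_d >= cut_height:
            return labels
        p, q = best
        labels[labels == q] = p


def _color_labels(genes: pd.Index, labels: np.ndarray) -> pd.Series:
    """Map integer labels to the colour sequence by decreasing module size."""
    out = pd.Series(GREY, index=genes, name="module")
    sizes = pd.Series(labels[labels != 0]).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(labels == c))))
    if len(order) > len(MODULE_COLORS):
        raise ValueError(f"more modules ({len(order)}) than available colours")
    for color, lab in zip(MODULE_COLORS, order):
        out.iloc[np.nonzero(labels == lab)[0]] = color
    return out


def build_network(
    values: pd.DataFrame, params: NetworkParams = NetworkParams()
) -> NetworkModel:
    """One-step network construction: correlation -> adjacency -> TOM ->
    modules -> merged, colour-named modules with eigengenes."""
    cor, dropped = correlation_matrix(values)
    values = values.loc[cor.index]
    adj = soft_adjacency(cor.to_numpy(), params.power_beta)
    tom = topological_overlap(adj)
    z, labels = detect_modules(1.0 - tom, params)
    labels = merge_close_modules(values, labels, params.merge_cut_height)
    colors = _color_labels(cor.index, labels)
    mes, var_exp = _eigengene_frame(values, colors)
    return NetworkModel(
        genes=cor.index,
        samples=values.columns,
        correlation=cor.to_numpy(),
        adjacency=adj,
        tom=tom,
        linkage=z,
        module_labels=colors,
        eigengenes=mes,
        variance_explained=var_exp,
        params=params,
        dropped_genes=dropped,
    )


def correlation_pvalue(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p for a Pearson correlation via the t transform (n-2 df)."""
    r = np.asarray(r, dtype=float)
    r_c = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p if p.ndim else float(p)


def _cor_with_vector(values: pd.DataFrame, v: np.ndarray) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ vc) / denom
    return np.clip(np.where(np.isfinite(r), r, np.nan), -1.0, 1.0)


def gene_statistics(
    values: pd.DataFrame, model: NetworkModel, trait: pd.Series
) -> pd.DataFrame:
    """Per-gene GS (vs the trait), MM (vs own module eigengene) and kTotal.

    ``values`` must be the same (transformed) matrix the network was built
    from. Grey genes get MM against the grey pseudo-module eigengene.
    """
    trait = trait.loc[model.samples]
    if trait.std(ddof=1) == 0:
        raise ValueError("trait is constant; gene significance undefined")
    values = values.loc[model.genes, model.samples]
    gs = _cor_with_vector(values, trait.to_numpy(dtype=float))
    mm = np.full(len(model.genes), np.nan)
    for color in model.module_labels.unique():
        mask = (model.module_labels == color).to_numpy()
        me = model.eigengenes[color].to_numpy(dtype=float)
        mm[mask] = _cor_with_vector(values.loc[mask], me)
    a = model.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    ktotal = a.sum(axis=1)
    return pd.DataFrame(
        {
            "module": model.module_labels.to_numpy(),
            "gs": gs,
            "abs_gs": np.abs(gs),
            "mm": mm,
            "abs_mm": np.abs(mm),
            "ktotal": ktotal,
        },
        index=model.genes,
    )


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    sig_p: float = 0.001,
) -> pd.DataFrame:
    """Pearson r and two-sided p between each module eigengene and each trait.

    Significance is declared at ``p < sig_p`` (default 0.001).
    """
    n = len(eigengenes)
    if n < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    for module in eigengenes.columns:
        me = eigengenes[module].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].loc[eigengenes.index].to_numpy(dtype=float)
            r = float(np.corrcoef(me, t)[0, 1])
            p = float(correlation_pvalue(r, n))
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "r": r,
                    "p": p,
                    "significant": p < sig_p,
                }
            )
    return pd.DataFrame(rows)
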