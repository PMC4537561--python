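"""Trait-associated gene selection: differential expression plus guide similarity.

Fruit acidity associated genes (FAAGs) are the union of

* **DEGs** — genes differentially expressed between the two genotype groups
  by a weighted two-group proportions test (Baggerly-style beta-binomial
  moment test on per-sample relative abundances), Benjamini-Hochberg
  corrected at ``P_FDR < 0.05``, with low-amplitude genes
  (RPKM range < 5 across all samples) removed; and
* **guide-similar genes** — genes whose between-group mean difference
  exceeds 10 RPKM and whose fold change exceeds 1.5, the filters calibrated
  on the guide gene (an ALMT1-like malate transporter whose own contrast is
  8.53 RPKM and 1.69-fold).

The proportions test treats each sample column as a library: a gene's
per-sample proportion is its RPKM divided by the sample's column total, and
group means/variances are weighted by those totals, so deep (high-signal)
samples carry more weight, after the moment estimator of Baggerly et al.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, group_means

logger = logging.getLogger(__name__)

__all__ = [
    "DiffExprResult",
    "FaagSet",
    "proportions_test",
    "bh_adjust",
    "select_degs",
    "guide_similarity",
    "assemble_faags",
]


@dataclass
class DiffExprResult:
    """Per-gene two-group test results.

    ``table`` columns: mean_a, mean_b, statistic, p, p_fdr, rpkm_range,
    testable. Untestable genes (a group with zero total signal) carry p = 1.
    """

    table: pd.DataFrame
    groups: tuple[str, str]


def _weighted_group_moments(
    props: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean of per-sample proportions and the variance of that mean.

    Weights are the sample column totals. The variance of the weighted mean
    uses the unbiased reliability-weights form
    ``s2 * sum(w^2) / sum(w)^2`` with
    ``s2 = sum w (p - pbar)^2 / (sum w - sum(w^2)/sum(w))``.
    """
    w = weights
    sw = w.sum()
    pbar = (props * w).sum(axis=1) / sw
    denom = sw - (w**2).sum() / sw
    s2 = ((props - pbar[:, None]) ** 2 * w).sum(axis=1) / denom
    var_mean = s2 * (w**2).sum() / sw**2
    return pbar, var_mean


def proportions_test(m: ExpressionMatrix) -> DiffExprResult:
    """Weighted two-group proportions test on per-sample relative abundances.

    Per gene: statistic = difference of the groups' weighted mean proportions
    over the pooled standard error; two-sided p from a t reference with
    Welch-Satterthwaite degrees of freedom.
    """
    a, b = m.groups
    gm = group_means(m)
    out = pd.DataFrame(index=m.gene_ids)
    out["mean_a"] = gm[a]
    out["mean_b"] = gm[b]
    vals = m.values.to_numpy(dtype=float)
    out["rpkm_range"] = vals.max(axis=1) - vals.min(axis=1)

    stat = np.zeros(len(out))
    p = np.ones(len(out))
    testable = np.ones(len(out), dtype=bool)
    totals = vals.sum(axis=0)
    if (totals == 0).any():
        bad = m.sample_ids[totals == 0].tolist()
        raise ValueError(f"samples with zero total signal: {bad}")

    cols_a = m.sample_group.to_numpy() == a
    moments = {}
    for grp, cols in ((a, cols_a), (b, ~cols_a)):
        w = totals[cols]
        props = vals[:, cols] / w[None, :]
        pbar, var_mean = _weighted_group_moments(props, w)
        moments[grp] = (pbar, var_mean, int(cols.sum()))
    pa, va, na = moments[a]
    pb, vb, nb = moments[b]
    diff = pa - pb
    se2 = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    ok = se2 > 0
    stat[ok] = t[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df[ok])
    # zero pooled variance: no evidence either way unless the means differ
    # exactly, which cannot happen with zero within-group variance and
    # identical values; keep statistic 0, p 1
    degenerate = ~ok
    if degenerate.any():
        logger.info("%d genes with zero pooled variance (p set to 1)",
                    int(degenerate.sum()))
        testable[degenerate] = False

    out["statistic"] = stat
    out["p"] = p
    out["testable"] = testable
    out["p_fdr"] = bh_adjust(out["p"].to_numpy())
    return DiffExprResult(out, (a, b))


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending; ``adjusted_i = min_{j >= i} p_(j) * m / j`` capped at 1;
    original order restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def select_degs(
    d: DiffExprResult, alpha: float = 0.05, min_range: float = 5.0
) -> pd.Index:
    """Differentially expressed genes: ``p_fdr < alpha`` and
    RPKM range (max - min over all samples) at least ``min_range``."""
    t = d.table
    keep = (t["p_fdr"] < alpha) & (t["rpkm_range"] >= min_range)
    return t.index[keep.to_numpy()]


def guide_similarity(
    m: ExpressionMatrix,
    guide_id: str,
    min_diff: float = 10.0,
    min_fc: float = 1.5,
    direction: str = "same-as-guide",
) -> pd.Index:
    """Genes expressed similarly to the guide gene.

    A gene passes when its absolute between-group mean difference exceeds
    ``min_diff`` RPKM and its group fold change (larger mean over smaller)
    exceeds ``min_fc``; a zero smaller mean counts as infinite fold. With
    ``direction="same-as-guide"`` the gene's higher-mean group must match
    the guide's; ``direction="either"`` drops that constraint.
    """
    if direction not in ("same-as-guide", "either"):
        raise ValueError(f"unknown direction {direction!r}")
    if guide_id not in m.gene_ids:
        raise KeyError(f"guide gene {guide_id!r} not in expression matrix")
    gm = group_means(m)
    a, b = m.groups
    diff = gm[a] - gm[b]
    lo = np.minimum(gm[a], gm[b])
    hi = np.maximum(gm[a], gm[b])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.inf)
    fc = np.where((hi == 0) & (lo == 0), 1.0, fc)  # all-zero gene: no change
    passes = (np.abs(diff) > min_diff) & (fc > min_fc)
    if direction == "same-as-guide":
        guide_sign = np.sign(diff[guide_id])
        passes &= np.sign(diff) == guide_sign
    return m.gene_ids[passes.to_numpy()]


@dataclass
class FaagSet:
    """The union of DEGs and guide-similar genes with provenance labels."""

    deg_genes: pd.Index
    guide_similar_genes: pd.Index
    guide_id: str

    @property
    def union(self) -> pd.Index:
        return self.deg_genes.union(self.guide_similar_genes, sort=False)

    @property
    def provenance(self) -> pd.Series:
        """Per-gene label: ``deg``, ``similar`` or ``both``."""
        deg = set(self.deg_genes)
        sim = set(self.guide_similar_genes)
        out = {}
        for g in self.union:
            out[g] = "both" if (g in deg and g in sim) else (
                "deg" if g in deg else "similar"
            )
        return pd.Series(out, name="provenance")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "deg": len(self.deg_genes),
            "similar": len(self.guide_similar_genes),
            "union": len(self.union),
        }


def assemble_faags(
    degs: pd.Index, similar: pd.Index, guide_id: str
) -> FaagSet:
    """Assemble the FAAG set from the DEG and guide-similar gene lists."""
    fs = FaagSet(pd.Index(degs), pd.Index(similar), guide_id)
    if guide_id not in fs.union:
        logger.warning("guide gene %s passed neither selection rule", guide_id)
    return fs
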