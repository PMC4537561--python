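"""Guide-calibrated gene selection and subgroup connectivity analysis.

Selection rules are anchored on the guide gene rather than on arbitrary
cutoffs: the *most significant acidity genes* (MSAGs) are all genes whose
absolute gene significance (|GS|, correlation with malate) reaches the
guide gene's own |GS|, and *intramodular hub genes* are the top 12 genes by
|MM| (eigengene-based connectivity) in each selected module.

Subgroup analysis rebuilds the adjacency separately from each genotype
group's samples and compares every gene's total connectivity (kTotal)
against the combined-sample network, classifying the change by sign:

* ``major``     - kTotal up in group B, down in group A
* ``reverse``   - kTotal up in group A, down in group B
* ``down_both`` / ``up_both`` - both deltas share a sign
* ``mixed``     - a delta within tolerance of zero
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import (
    NetworkParams,
    correlation_matrix,
    correlation_pvalue,
    soft_adjacency,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KtotalComparison",
    "select_msags",
    "select_hub_genes",
    "subgroup_ktotal",
    "classify_ktotal_pattern",
    "module_mm_gs_correlation",
    "ktotal_gs_relation",
]

PATTERNS = ("major", "reverse", "down_both", "up_both", "mixed")


def select_msags(stats: pd.DataFrame, guide_id: str) -> tuple[pd.Index, float]:
    """Most significant acidity genes: ``|GS| >= |GS_guide|``.

    ``stats`` is the per-gene table from :func:`acidnet.network.gene_statistics`.
    Returns the selected genes and the guide's |GS| threshold. The guide is a
    member by construction.
    """
    if guide_id not in stats.index:
        raise KeyError(f"guide gene {guide_id!r} not in statistics table")
    threshold = float(stats.loc[guide_id, "abs_gs"])
    sel = stats.index[(stats["abs_gs"] >= threshold).to_numpy()]
    return sel, threshold


def select_hub_genes(
    stats: pd.DataFrame, modules: list[str], top_n: int = 12
) -> pd.DataFrame:
    """Top ``top_n`` genes by |MM| per selected module (intramodular hubs).

    Ties are broken by higher kTotal, then lexicographic gene ID. Modules
    smaller than ``top_n`` return all members with a warning. Returns a frame
    with columns module, rank, gene, mm, abs_mm, ktotal.
    """
    known = set(stats["module"])
    rows = []
    for module in modules:
        if module not in known:
            raise KeyError(f"unknown module {module!r}")
        sub = stats[stats["module"] == module].copy()
        if len(sub) < top_n:
            logger.warning(
                "module %s has only %d genes (< top_n=%d)", module, len(sub), top_n
            )
        sub = sub.sort_values(
            by=["abs_mm", "ktotal"], ascending=[False, False], kind="stable"
        )
        # lexicographic gene ID as the final tie-break
        sub["_gene"] = sub.index
        sub = sub.sort_values(
            by=["abs_mm", "ktotal", "_gene"],
            ascending=[False, False, True],
            kind="stable",
        )
        for rank, (gene, row) in enumerate(sub.head(top_n).iterrows(), start=1):
            rows.append(
                {
                    "module": module,
                    "rank": rank,
                    "gene": gene,
                    "mm": row["mm"],
                    "abs_mm": row["abs_mm"],
                    "ktotal": row["ktotal"],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class KtotalComparison:
    """Per-gene kTotal in the combined network and in each group subnetwork."""

    table: pd.DataFrame  # columns: ktotal_combined, ktotal_group_a, ktotal_group_b
    groups: tuple[str, str]


def _ktotal(values: pd.DataFrame, beta: float) -> np.ndarray:
    cor, dropped = correlation_matrix(values)
    adj = soft_adjacency(cor.to_numpy(), beta)
    np.fill_diagonal(adj, 0.0)
    k = pd.Series(adj.sum(axis=1), index=cor.index)
    # zero-variance genes in a subgroup contribute no connectivity
    return k.reindex(values.index, fill_value=0.0).to_numpy()


def subgroup_ktotal(
    m: ExpressionMatrix,
    genes: list[str] | pd.Index,
    params: NetworkParams = NetworkParams(),
) -> KtotalComparison:
    """Rerun correlation -> soft adjacency (same beta) on all samples and on
    each genotype group's samples, and report per-gene kTotal in each."""
    values = m.values.loc[list(genes)]
    a, b = m.groups
    cols = {}
    for name, samples in (
        ("ktotal_combined", m.sample_ids),
        ("ktotal_group_a", m.group_samples(a)),
        ("ktotal_group_b", m.group_samples(b)),
    ):
        if len(samples) < 3:
            raise ValueError(f"need >= 3 samples for {name}, got {len(samples)}")
        cols[name] = _ktotal(values.loc[:, samples], params.power_beta)
    return KtotalComparison(pd.DataFrame(cols, index=values.index), (a, b))


def classify_ktotal_pattern(
    c: KtotalComparison, gene: str | None = None, eps: float = 1e-9
) -> str | pd.Series:
    """Classify kTotal changes by the signs of (subgroup - combined) deltas.

    With ``gene`` given, returns that gene's pattern string; otherwise a
    Series over all genes. Deltas within ``eps`` of zero give ``mixed``.
    """
    t = c.table
    da = t["ktotal_group_a"] - t["ktotal_combined"]
    db = t["ktotal_group_b"] - t["ktotal_combined"]
    out = pd.Series("mixed", index=t.index, name="pattern")
    out[(db > eps) & (da < -eps)] = "major"
    out[(da > eps) & (db < -eps)] = "reverse"
    out[(da < -eps) & (db < -eps)] = "down_both"
    out[(da > eps) & (db > eps)] = "up_both"
    if gene is not None:
        return out[gene]
    return out


def module_mm_gs_correlation(stats: pd.DataFrame, module: str) -> tuple[float, float]:
    """Pearson r (with two-sided p) between |MM| and |GS| over one module's genes.

    Returns ``(nan, nan)`` when either statistic is constant across members.
    """
    sub = stats[stats["module"] == module]
    if len(sub) < 3:
        raise ValueError(f"module {module!r} has < 3 genes")
    x = sub["abs_mm"].to_numpy(dtype=float)
    y = sub["abs_gs"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant |MM| or |GS| in module %s: r undefined", module)
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(correlation_pvalue(r, len(sub)))


def ktotal_gs_relation(stats: pd.DataFrame) -> tuple[float, float]:
    """Whole-network r^2 (and p) between kTotal and |GS|."""
    if len(stats) < 3:
        raise ValueError("need >= 3 genes")
    x = stats["ktotal"].to_numpy(dtype=float)
    y = stats["abs_gs"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r**2, float(correlation_pvalue(r, len(stats)))
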