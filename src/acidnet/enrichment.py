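"""Hypergeometric term enrichment of module gene sets.

Annotations are consumed as a flat gene -> term table (GO biological
process, GO molecular function, MapMan (sub-)bins, ...), with no ontology
graph propagation. For a module of ``n`` annotated genes drawn from a
namespace background of ``N`` genes of which ``K`` carry a term, the
over-representation p-value is ``P(X >= k)`` and the depletion p-value
``P(X <= k)`` under Hypergeometric(N, K, n). Benjamini-Hochberg correction
is applied across all terms tested within one (namespace, module) pair, and
significance is declared at ``P_FDR < 0.05``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .faag import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["AnnotationMap", "hypergeom_enrich", "read_annotation"]


@dataclass
class AnnotationMap:
    """Flat gene/term annotation with per-namespace backgrounds.

    ``table`` columns: gene, namespace, term, name. ``background_size`` may
    pin the background universe size per namespace (e.g. all annotated
    expressed genes); by default it is the number of distinct annotated
    genes in the namespace.
    """

    table: pd.DataFrame
    background_size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "namespace", "term"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        if "name" not in self.table.columns:
            self.table = self.table.assign(name=self.table["term"])
        self.table = self.table.drop_duplicates(subset=["gene", "namespace", "term"])

    @property
    def namespaces(self) -> list[str]:
        return sorted(self.table["namespace"].unique())

    def namespace_table(self, namespace: str) -> pd.DataFrame:
        return self.table[self.table["namespace"] == namespace]

    def n_background(self, namespace: str) -> int:
        if namespace in self.background_size:
            return int(self.background_size[namespace])
        return int(self.namespace_table(namespace)["gene"].nunique())

    def genes_with_term(self, namespace: str, term: str) -> set[str]:
        t = self.namespace_table(namespace)
        return set(t.loc[t["term"] == term, "gene"])


def read_annotation(
    path: str | Path, background_size: dict[str, int] | None = None
) -> AnnotationMap:
    """Read a tab-separated gene<TAB>namespace<TAB>term<TAB>name table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationMap(df, background_size or {})


def hypergeom_enrich(
    module_genes: list[str] | pd.Index,
    ann: AnnotationMap,
    alpha: float = 0.05,
    module: str = "module",
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of every term in a module.

    Returns a tidy frame with one row per (namespace, term): counts
    (k, n, K, N), ``p_over`` / ``p_under``, per-namespace BH-adjusted
    ``p_fdr_over`` / ``p_fdr_under`` and the resulting ``enriched`` /
    ``repressed`` flags at ``P_FDR < alpha``.
    """
    module_genes = set(module_genes)
    if ann.table.empty:
        raise ValueError("annotation map is empty")
    frames = []
    for namespace in ann.namespaces:
        t = ann.namespace_table(namespace)
        universe = set(t["gene"])
        n_bg = ann.n_background(namespace)
        in_universe = module_genes & universe
        outside = module_genes - universe
        if outside:
            logger.warning(
                "%d/%d module genes not annotated in %s; dropped",
                len(outside), len(module_genes), namespace,
            )
        n = len(in_universe)
        if n_bg < max(n, len(universe)):
            raise ValueError(
                f"background for {namespace} ({n_bg}) smaller than the "
                f"annotated universe ({len(universe)}) or module ({n})"
            )
        rows = []
        term_sizes = t.groupby("term")["gene"].nunique()
        names = t.drop_duplicates("term").set_index("term")["name"]
        counts = (
            t[t["gene"].isin(in_universe)].groupby("term")["gene"].nunique()
        )
        for term, big_k in term_sizes.items():
            if big_k < min_term_size:
                continue
            k = int(counts.get(term, 0))
            p_over = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n))
            p_under = float(stats.hypergeom.cdf(k, n_bg, big_k, n))
            rows.append(
                {
                    "module": module,
                    "namespace": namespace,
                    "term": term,
                    "name": names[term],
                    "k": k,
                    "n": n,
                    "K": int(big_k),
                    "N": n_bg,
                    "p_over": min(p_over, 1.0),
                    "p_under": min(p_under, 1.0),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["p_fdr_over"] = bh_adjust(df["p_over"].to_numpy())
        df["p_fdr_under"] = bh_adjust(df["p_under"].to_numpy())
        df["enriched"] = df["p_fdr_over"] < alpha
        df["repressed"] = df["p_fdr_under"] < alpha
        frames.append(df)
    if not frames:
        raise ValueError("no terms tested (empty term universe)")
    return pd.concat(frames, ignore_index=True)
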