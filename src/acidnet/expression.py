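"""Reading, validation and normalisation of RPKM expression and acidity trait tables.

The pipeline consumes three flat tab-separated inputs:

* a gene-by-sample matrix of RPKM values (first column: gene ID, header row:
  sample IDs),
* sample metadata assigning every sample to one of two genotype groups
  (e.g. ``Ma_`` vs ``mama`` at the apple *Ma* locus) and a replicate label,
* a per-sample table of fruit acidity traits: malate (mg/g FW), titratable
  acidity (mg/ml) and juice pH.

Genes are called *expressed* when at least one of the two genotype-group mean
RPKMs exceeds a threshold (default 0.3), and expression is variance-stabilised
by a square-root transform before any network computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "VennCounts",
    "read_expression",
    "read_traits",
    "group_means",
    "filter_expressed",
    "sqrt_transform",
    "trait_group_summary",
]

TRAIT_COLUMNS = ("malate", "ta", "ph")

#: default expressed-gene cutoff on group-mean RPKM
EXPRESSED_RPKM_THRESHOLD = 0.3


class ExpressionInputError(ValueError):
    """Raised when an expression/trait input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM matrix with a two-group sample design.

    Parameters
    ----------
    values
        DataFrame of RPKM values, genes in rows, samples in columns.
    sample_group
        Series mapping each sample ID to one of exactly two group labels.
    replicate
        Optional series mapping each sample ID to a replicate label.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionInputError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionInputError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionInputError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ExpressionInputError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionInputError(
                f"negative RPKM ({arr[g, s]}) at gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )
        missing = [s for s in v.columns if s not in self.sample_group.index]
        if missing:
            raise ExpressionInputError(
                f"samples not assigned to a group in metadata: {missing}"
            )
        self.sample_group = self.sample_group.loc[v.columns].astype(str)
        labels = sorted(set(self.sample_group))
        if len(labels) != 2:
            raise ExpressionInputError(
                f"expected exactly two sample groups, found {labels}"
            )
        counts = self.sample_group.value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ExpressionInputError(
                f"each group needs >=2 samples, got {small.to_dict()}"
            )
        self._groups = (labels[0], labels[1])
        if self.replicate is not None:
            self.replicate = self.replicate.reindex(v.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, in lexicographic order (so that swapping
        the labels on the samples flips every group contrast's sign)."""
        return self._groups

    def group_samples(self, group: str) -> pd.Index:
        return self.sample_ids[(self.sample_group == group).to_numpy()]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_group,
                                self.replicate)

    def subset_samples(self, samples: Iterable[str]) -> pd.DataFrame:
        return self.values.loc[:, list(samples)]


@dataclass
class TraitTable:
    """Per-sample acidity measurements (any subset of malate / ta / ph)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        unknown = [c for c in v.columns if c not in TRAIT_COLUMNS]
        if unknown:
            raise ExpressionInputError(
                f"unknown trait columns {unknown}; expected subset of {TRAIT_COLUMNS}"
            )
        if v.empty or not len(v.columns):
            raise ExpressionInputError("trait table has no trait columns")
        for col in ("malate", "ta"):
            if col in v.columns and (v[col].dropna() < 0).any():
                raise ExpressionInputError(f"{col} must be >= 0")
        if "ph" in v.columns:
            ph = v["ph"].dropna()
            if ((ph <= 0) | (ph >= 14)).any():
                raise ExpressionInputError("ph must be in (0, 14)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def trait(self, name: str, samples: Iterable[str] | None = None) -> pd.Series:
        s = self.values[name]
        if samples is not None:
            s = s.loc[list(samples)]
        return s

    def check_samples(self, m: ExpressionMatrix) -> None:
        extra = [s for s in self.sample_ids if s not in m.sample_ids]
        if extra:
            raise ExpressionInputError(
                f"trait samples absent from expression matrix: {extra}"
            )


def _read_numeric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy()][0]
                raise ExpressionInputError(
                    f"non-numeric cell {df.loc[row, col]!r} at row {row!r}, "
                    f"column {col!r} in {path}"
                )
            df[col] = coerced
    return df


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated RPKM matrix plus sample metadata.

    The metadata file must be tab-separated with columns
    ``sample_id``, ``group`` and (optionally) ``replicate``.
    """
    values = _read_numeric_table(path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise ExpressionInputError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    replicate = meta["replicate"] if "replicate" in meta.columns else None
    return ExpressionMatrix(values, meta["group"], replicate)


def read_traits(path: str | Path) -> TraitTable:
    """Read a tab-separated per-sample trait table (sample_id + trait columns)."""
    return TraitTable(_read_numeric_table(path))


def group_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean RPKM in each of the two groups.

    Returns a DataFrame indexed by gene with one column per group label.
    """
    out = {}
    for g in m.groups:
        out[g] = m.values.loc[:, m.group_samples(g)].mean(axis=1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class VennCounts:
    both: int
    a_only: int
    b_only: int

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only


def filter_expressed(
    m: ExpressionMatrix, threshold: float = EXPRESSED_RPKM_THRESHOLD
) -> tuple[pd.Index, VennCounts]:
    """Expressed-gene filter on group means.

    A gene is expressed iff its mean RPKM exceeds `threshold` (strictly) in at
    least one group. Also returns the Venn partition of the expressed set into
    genes above threshold in both groups, group A only, and group B only.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    gm = group_means(m)
    a, b = m.groups
    in_a = gm[a] > threshold
    in_b = gm[b] > threshold
    expressed = m.gene_ids[(in_a | in_b).to_numpy()]
    venn = VennCounts(
        both=int((in_a & in_b).sum()),
        a_only=int((in_a & ~in_b).sum()),
        b_only=int((~in_a & in_b).sum()),
    )
    return expressed, venn


def sqrt_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise square root of RPKM (variance stabilisation before networks)."""
    return ExpressionMatrix(np.sqrt(m.values), m.sample_group, m.replicate)


def trait_group_summary(
    traits: TraitTable, sample_group: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Group-wise trait summary: mean, SD, n, and between-group fold change.

    Returns a tidy frame indexed by (trait, group) with columns mean/sd/n and,
    per trait, ``fold_change`` = larger group mean / smaller group mean.
    """
    sg = pd.Series(sample_group)
    sg = sg.loc[[s for s in traits.sample_ids if s in sg.index]]
    rows = []
    for trait in traits.values.columns:
        per_group = {}
        for g in dict.fromkeys(sg):
            vals = traits.values.loc[sg.index[sg == g], trait].dropna()
            per_group[g] = vals
        means = {g: float(v.mean()) for g, v in per_group.items()}
        hi, lo = max(means.values()), min(means.values())
        fold = np.inf if lo == 0 else hi / lo
        for g, v in per_group.items():
            rows.append(
                {
                    "trait": trait,
                    "group": g,
                    "mean": means[g],
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "n": int(len(v)),
                    "fold_change": fold,
                }
            )
    return pd.DataFrame(rows).set_index(["trait", "group"])
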