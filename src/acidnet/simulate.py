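"""Seeded synthetic two-genotype RPKM datasets with planted network structure.

The generator emulates the study design the pipeline targets: a mature-fruit
transcriptome experiment with 29 samples in two genotype groups (17 ``Ma_``
vs 12 ``mama``), a handful of co-expression modules driven by latent sample
factors, a malate-like trait built from those factors, a guide gene with a
controlled between-group mean difference and fold change (emulating the
*Ma1* malate transporter), one planted regulator per selected module whose
expression tracks the binary sample split separating that module's factor,
and a flat gene -> term annotation with one planted term per module.

Expression is generated on a log scale and exponentiated, giving
lognormal-like RPKM marginals that are non-negative without truncation.
Within a module all member genes share a single loading on the module
factor, so at ``noise_sd = 0`` member genes are exact scalar multiples of
each other (pairwise correlation 1); gene-level individuality comes from
per-gene baselines and the Gaussian noise term.

Every dataset is a pure function of its :class:`SimConfig`, including the
seed: the same config yields a bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix, TraitTable

__all__ = [
    "GuideSpec",
    "RegulatorSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "write_dataset",
    "load_config",
]

GUIDE_GENE_ID = "MDP0000252114"  # the apple Ma1 ALMT1-like malate transporter


@dataclass(frozen=True)
class GuideSpec:
    """Planted guide gene: module membership and between-group contrast.

    Defaults mirror the reported guide-gene contrast (mean RPKM difference
    8.53, fold change 1.69 between genotype groups).
    """

    module_index: int = 0
    mean_diff: float = 8.53
    fold_change: float = 1.69


@dataclass(frozen=True)
class RegulatorSpec:
    """One planted regulator per selected module.

    ``separation`` is the log-scale expression shift between the two sides of
    the sample split the regulator tracks; ``noise_sd`` is its own residual
    log-scale noise.
    """

    module_indices: tuple[int, ...] = (0, 2)
    separation: float = 2.0
    noise_sd: float = 0.25


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Group sizes default to 17 + 12 usable samples; five modules of 60 genes
    plus 300 background genes give a network of the scale the desk-size
    analyses use. ``trait_coefficients`` maps module index -> coefficient of
    that module's latent factor in the malate model.
    """

    n_samples_group_a: int = 17
    n_samples_group_b: int = 12
    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    n_background_genes: int = 300
    trait_coefficients: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.2, 1: -0.5}
    )
    guide: GuideSpec = field(default_factory=GuideSpec)
    regulators: RegulatorSpec = field(default_factory=RegulatorSpec)
    noise_sd: float = 0.5
    trait_noise_sd: float = 0.5
    baseline_rpkm: float = 10.0
    baseline_log_sd: float = 0.5
    group_separation: float = 2.0
    low_expression_fraction: float = 0.1
    trait_baseline: float = 5.0
    group_labels: tuple[str, str] = ("Ma_", "mama")
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_group_a < 2 or self.n_samples_group_b < 2:
            raise ValueError("each group needs at least 2 samples")
        if not self.module_sizes:
            raise ValueError("module_sizes must not be empty")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError(f"non-positive module size in {self.module_sizes}")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.guide.fold_change < 1:
            raise ValueError("guide fold change must be >= 1")
        if self.guide.mean_diff <= 0:
            raise ValueError("guide mean difference must be > 0")
        n_mod = len(self.module_sizes)
        for idx in list(self.trait_coefficients) + [self.guide.module_index] + list(
            self.regulators.module_indices
        ):
            if not 0 <= idx < n_mod:
                raise ValueError(f"module index {idx} out of range (0..{n_mod - 1})")
        if self.noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.baseline_rpkm <= 0:
            raise ValueError("baseline_rpkm must be > 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    module_of: dict[str, int]  # gene -> planted module index; -1 = background
    guide_id: str
    regulator_ids: dict[int, str]  # module index -> planted regulator gene
    trait_coefficients: dict[int, float]
    planted_terms: dict[int, str]  # module index -> planted annotation term
    candidate_term: str  # annotation term marking regulator candidates
    group_split: dict[str, str]  # sample -> group label

    def module_genes(self, index: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == index]

    def labels_for(self, genes) -> np.ndarray:
        return np.array([self.module_of.get(g, -1) for g in genes])


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    traits: TraitTable
    annotation: pd.DataFrame  # columns: gene, namespace, term, name
    truth: SimTruth


def _best_binary_split(factor: np.ndarray) -> np.ndarray:
    """Optimal 1-D 2-means split of a latent factor (mask of the high side)."""
    n = len(factor)
    order = np.argsort(factor, kind="stable")
    v = factor[order]
    csum, csq = np.cumsum(v), np.cumsum(v**2)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):
        sse = (csq[i - 1] - csum[i - 1] ** 2 / i) + (
            (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        )
        if sse < best_sse - 1e-12:
            best_sse, best_i = sse, i
    mask = np.zeros(n, dtype=bool)
    mask[order[best_i:]] = True
    return mask


def _centered_group_indicator(groups: np.ndarray, labels: tuple[str, str]) -> np.ndarray:
    # +nB/n for group A, -nA/n for group B: zero mean, A-minus-B contrast = 1
    is_a = groups == labels[0]
    n = len(groups)
    n_a = int(is_a.sum())
    return np.where(is_a, (n - n_a) / n, -n_a / n)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one seeded dataset with planted modules, guide, trait, regulators."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_factor = np.random.default_rng(streams[0])
    rng_load = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    rng_guide = np.random.default_rng(streams[3])
    rng_reg = np.random.default_rng(streams[4])
    rng_bg = np.random.default_rng(streams[5])
    rng_trait = np.random.default_rng(streams[6])
    rng_ann = np.random.default_rng(streams[7])

    la, lb = config.group_labels
    n_a, n_b = config.n_samples_group_a, config.n_samples_group_b
    samples = [f"{la}{i + 1:02d}" for i in range(n_a)] + [
        f"{lb}{i + 1:02d}" for i in range(n_b)
    ]
    groups = np.array([la] * n_a + [lb] * n_b)
    replicate = pd.Series(
        [str(i % 3 + 1) for i in range(n_a + n_b)], index=samples, name="replicate"
    )
    contrast = _centered_group_indicator(groups, config.group_labels)
    n_samples = n_a + n_b
    n_modules = len(config.module_sizes)

    # every planted module carries a between-group component (the gene
    # universe downstream is genotype-associated by construction); direction
    # alternates so some modules sit higher in group A, some in group B
    factors = np.empty((n_modules, n_samples))
    directions = np.array([1.0 if m % 2 == 0 else -1.0 for m in range(n_modules)])
    for m in range(n_modules):
        sep = config.group_separation * directions[m]
        factors[m] = sep * contrast + rng_factor.normal(size=n_samples)

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    module_of: dict[str, int] = {}
    log_base = np.log(config.baseline_rpkm)

    loadings = rng_load.uniform(0.8, 1.2, size=n_modules)  # shared within module
    guide_mod = config.guide.module_index
    for m, size in enumerate(config.module_sizes):
        baselines = log_base + config.baseline_log_sd * rng_load.normal(size=size)
        noise = config.noise_sd * rng_noise.normal(size=(size, n_samples))
        rows = np.exp(baselines[:, None] + loadings[m] * factors[m][None, :] + noise)
        for j in range(size):
            if m == guide_mod and j == 0:
                gid = GUIDE_GENE_ID
            else:
                gid = f"MOD{m:02d}_G{j:03d}"
            gene_ids.append(gid)
            module_of[gid] = m
        gene_rows.append(rows)

    # guide gene: controlled group means, still tracking its module's factor
    mean_b = config.guide.mean_diff / (config.guide.fold_change - 1.0)
    mean_a = config.guide.fold_change * mean_b
    target = np.where(groups == la, mean_a, mean_b)
    coupling = loadings[guide_mod]
    resid = factors[guide_mod] - (
        config.group_separation * directions[guide_mod] * contrast
    )
    gnoise = config.noise_sd * rng_guide.normal(size=n_samples)
    log_mult = coupling * resid + gnoise
    # lognormal mean correction keeps E[guide | group] at the configured target
    guide_values = target * np.exp(
        log_mult - (coupling**2 + config.noise_sd**2) / 2.0
    )
    idx_guide = gene_ids.index(GUIDE_GENE_ID)
    block = int(np.searchsorted(np.cumsum(config.module_sizes), idx_guide, side="right"))
    offset = idx_guide - int(np.sum(config.module_sizes[:block]))
    gene_rows[block][offset] = guide_values

    # planted regulators: track the binary sample split that best separates
    # the module (2-means of the realized mean profile, so the split is
    # recoverable from the expression data, not only from the latent factor)
    regulator_ids: dict[int, str] = {}
    for m in config.regulators.module_indices:
        rows = np.log1p(gene_rows[m])
        rows = (rows - rows.mean(axis=1, keepdims=True)) / np.where(
            rows.std(axis=1, keepdims=True) == 0, 1.0, rows.std(axis=1, keepdims=True)
        )
        high = _best_binary_split(rows.mean(axis=0))
        rid = f"REG_M{m:02d}"
        vals = np.exp(
            log_base
            + config.regulators.separation * (high.astype(float) - 0.5)
            + config.regulators.noise_sd * rng_reg.normal(size=n_samples)
        )
        gene_ids.append(rid)
        module_of[rid] = m
        gene_rows.append(vals[None, :])
        regulator_ids[m] = rid

    # background: independent noise around the baseline; a fraction unexpressed
    n_bg = config.n_background_genes
    if n_bg:
        n_low = int(round(config.low_expression_fraction * n_bg))
        base = np.full(n_bg, log_base)
        base[:n_low] = np.log(0.05)
        base = base + config.baseline_log_sd * rng_bg.normal(size=n_bg)
        rows = np.exp(base[:, None] + config.noise_sd * rng_bg.normal(size=(n_bg, n_samples)))
        for j in range(n_bg):
            gid = f"BG_G{j:04d}"
            gene_ids.append(gid)
            module_of[gid] = -1
        gene_rows.append(rows)

    values = pd.DataFrame(
        np.vstack(gene_rows), index=pd.Index(gene_ids, name="gene"), columns=samples
    )
    expression = ExpressionMatrix(
        values, pd.Series(groups, index=samples, name="group"), replicate
    )

    # trait model: malate = baseline + sum_m coef_m * f_m + noise, floored at 0
    malate = config.trait_baseline + config.trait_noise_sd * rng_trait.normal(
        size=n_samples
    )
    for m, coef in config.trait_coefficients.items():
        malate = malate + coef * factors[m]
    malate = np.clip(malate, 0.0, None)
    ta = np.clip(1.1 * malate + 0.3 * rng_trait.normal(size=n_samples), 0.0, None)
    ph = np.clip(4.2 - 0.12 * malate + 0.1 * rng_trait.normal(size=n_samples), 2.5, 6.5)
    traits = TraitTable(
        pd.DataFrame(
            {"malate": malate, "ta": ta, "ph": ph},
            index=pd.Index(samples, name="sample_id"),
        )
    )

    # annotation: one planted term per module covering >=80 % of its members,
    # a regulator-candidate term, and unstructured background terms
    ann_rows: list[tuple[str, str, str, str]] = []
    planted_terms: dict[int, str] = {}
    for m in range(n_modules):
        term = f"GO:PLANT{m:04d}"
        planted_terms[m] = term
        members = [g for g, mm in module_of.items() if mm == m and not g.startswith("REG_")]
        n_cov = max(1, int(np.ceil(0.85 * len(members))))
        covered = list(rng_ann.choice(members, size=n_cov, replace=False))
        for g in covered:
            ann_rows.append((g, "GO-BP", term, f"planted process {m}"))
    candidate_term = "MM:27.3"
    tf_like = list(regulator_ids.values())
    # decoy candidates come from module members: real candidate regulators
    # (TFs / signal transducers) are themselves network genes
    decoy_pool = [
        g
        for g, mm in module_of.items()
        if mm >= 0 and g not in tf_like and g != GUIDE_GENE_ID
    ]
    # 96 candidates total (planted regulators + decoys), the study's panel size
    n_decoys = min(96 - len(tf_like), len(decoy_pool))
    tf_like += list(rng_ann.choice(decoy_pool, size=n_decoys, replace=False))
    for g in tf_like:
        ann_rows.append((g, "MapMan", candidate_term, "RNA.regulation of transcription"))
    for t in range(10):
        term = f"GO:BGRND{t:04d}"
        members = rng_ann.choice(gene_ids, size=min(30, len(gene_ids)), replace=False)
        for g in members:
            ann_rows.append((g, "GO-BP", term, f"background process {t}"))
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "namespace", "term", "name"]
    ).drop_duplicates(subset=["gene", "namespace", "term"])

    truth = SimTruth(
        module_of=module_of,
        guide_id=GUIDE_GENE_ID,
        regulator_ids=regulator_ids,
        trait_coefficients=dict(config.trait_coefficients),
        planted_terms=planted_terms,
        candidate_term=candidate_term,
        group_split=dict(zip(samples, groups)),
    )
    return SimulatedDataset(expression, traits, annotation, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write expression/metadata/trait/annotation TSVs plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "traits": outdir / "traits.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    m = ds.expression
    m.values.to_csv(paths["expression"], sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "group": m.sample_group.to_numpy(),
            "replicate": (m.replicate if m.replicate is not None else "1"),
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    ds.traits.values.to_csv(paths["traits"], sep="\t")
    ds.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    truth = asdict(ds.truth)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def load_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    if "guide" in raw:
        raw["guide"] = GuideSpec(**raw["guide"])
    if "regulators" in raw:
        spec = dict(raw["regulators"])
        if "module_indices" in spec:
            spec["module_indices"] = tuple(spec["module_indices"])
        raw["regulators"] = RegulatorSpec(**spec)
    if "module_sizes" in raw:
        raw["module_sizes"] = tuple(raw["module_sizes"])
    if "trait_coefficients" in raw:
        raw["trait_coefficients"] = {
            int(k): float(v) for k, v in raw["trait_coefficients"].items()
        }
    if "group_labels" in raw:
        raw["group_labels"] = tuple(raw["group_labels"])
    return SimConfig(**raw)
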